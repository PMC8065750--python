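"""Score one patient on the seven-item posterior-stroke scale.

Builds a single bedside assessment (with one item that could not be
examined), totals it, and maps the total onto the severity strata used
for treatment triage.
"""

from aspos import (
    Assessment,
    ItemResponse,
    build_default_scale,
    score_item,
    severity_group,
    total_score,
)

scale = build_default_scale()
print(f"Instrument: {len(scale)} items, maximum total {scale.max_total}")
for item in scale:
    tag = " (NIHSS-like)" if item.nihss_like else ""
    print(f"  {item.name}: 0-{item.max_code}{tag}")

# The examiner hesitated between 'mild dysarthria' (1) and 'moderate
# dysarthria' (2); the rule is that the higher applicable level counts.
pharynx = score_item({1, 2})

assessment = Assessment(
    patient_id="P001",
    rater_id="R1",
    timepoint="day1_r1",
    responses=(
        ItemResponse("Reactivity", 0),
        ItemResponse("Eyes", 1),          # nystagmus
        ItemResponse("Pharynx", pharynx),
        ItemResponse("Strength", None),   # limb casted: not assessable
        ItemResponse("Balance", 2),       # walks only with help
        ItemResponse("Ataxia", 1),
        ItemResponse("Sensory", 0),
    ),
)

total, n_assessable = total_score(assessment)
group = severity_group(total)
print(f"\nTotal score: {total} from {n_assessable} assessable items")
print(f"Severity group: {group.value}")
print("(HIGH, i.e. a total of 4+, flags sharply increased odds of an")
print(" NIHSS >= 6, the conventional thrombectomy-consideration level.)")
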