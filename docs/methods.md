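# Methods

This note records the statistical model behind the package, the defaults
and why they were chosen, the numerical conventions, and what the
simulation-based tests do and do not demonstrate.

## 1. The instrument

ASPOS is a seven-item ordinal scale for posterior-circulation stroke
severity. Reactivity, Eyes, Pharynx, Strength and Balance score 0–3;
Ataxia and Sensory score 0–2; the maximum total is 19. Scoring
conventions implemented in `aspos.scale`:

* **tie-break** — when several level descriptions apply within one item,
  the higher level is recorded;
* **non-assessable items** — omitted from the total, which is *not*
  rescaled or pro-rated (the NIHSS convention). The attainable maximum
  shrinks accordingly; the count of contributing items is always
  reported alongside the total. An assessment with *no* assessable item
  has no total and is treated as an error;
* **severity strata** — LOW (0–2), INTERMEDIATE (3), HIGH (≥ 4). A total
  of 0, never observed in the development cohort (whose minimum was 1),
  belongs to LOW: LOW is the sub-threshold stratum and 0 < 3;
* item names are fixed identifiers; the clinical level labels are
  metadata, never parsed. The whole instrument serialises to a one-row-
  per-level CSV so variant instruments can be declared without code.

## 2. The synthetic cohort generator

No patient-level data are deposited with the instrument's development
study, so `aspos.simulate` generates cohorts with the statistical
structure the validation design assumes. It is the package's test bed,
not a fit to any real data.

**Latent trait.** Each patient carries θ ~ Exponential(scale 1), a
right-skewed severity trait (most posterior strokes in the development
cohort were mild: median total 2 of 19).

**Items.** Item *j*'s consensus score is the number of its cutpoints
lying at or below θ + σ_j ε, with ε standard normal. The cutpoints act
as a cumulative-threshold (graded-response-style) model: the minimal
mechanism that yields correlated ordinal items, correlated companion
scales, and monotonicity of every item in θ. σ_j (default 0.4 for all
items) is inverse discrimination; σ_j = 0 makes item j a deterministic
step function of θ.

**The off-scale item.** The "Eyes" item is, by default, generated from
an *independent* exponential draw with the same cutpoints (the
`offscale_item`/`offscale_prob` parameters). This reproduces, by
construction, the development study's one anomaly: an oculomotor/visual
item whose marginal distribution looks like the others but which carries
essentially no discriminatory power (item-rest r ≈ 0) and whose removal
raises alpha.

**Raters.** Three of a pool of four trained raters score each patient on
day 1; one of the three, chosen at random, repeats the assessment three
hours later. A rater reproduces the consensus score except, with
probability p_d *per item*, recording one level off (±1, clipped to the
item range). Disagreements are local because the published Bland–Altman
analysis shows total-score differences never exceeding one point.

The default p_d = 0.004 is the value jointly implied by the published
repeatability results: CR = 1.96·SD(d) = 0.46 gives SD(d) ≈ 0.235, and
under the ±1 model Var(d) ≈ 2 · 7 · p_d, hence p_d ≈ 0.004; the same
value predicts ≈ 5.6% of pairs outside the limits of agreement, matching
the published 5.5%. At this level every per-item ICC and κ lands in the
published 0.97–1.00 range.

**Companion scales.** NIHSS (0–42), mRS (0–6), Barthel (0–100 in steps
of 5), GCS (3–15) and IVBSS (0–30) are monotone linear transforms of θ
plus Gaussian noise, rounded to each scale's granularity and clipped to
its range. Slopes are negative for Barthel and GCS (higher = better).
The GCS link is dominated by its ceiling (most patients at 15), which is
what makes its rank correlation with the total only moderate, as in the
development data. The IVBSS maximum is not standardised in the
literature available here; it defaults to 30 and is configurable.

**Day 90.** Recovery is modelled by attenuating θ multiplicatively
(default shift 0.6) and re-applying the same companion links with fresh
noise. Mortality and dropout are not modelled (the development study
reports none).

**Calibration.** Cutpoint quantiles, σ and the links were calibrated
once against the development study's stated margins — median total 2
(observed in ≥ 95% of simulated cohorts), minimum total 1 (the first
Balance cutpoint sits below the latent support: every stroke patient
shows at least a minimal gait/stance finding), roughly a quarter of
patients in HIGH, and companion medians NIHSS 2 / mRS 1 / Barthel 90 /
GCS 15 — and then frozen. Known residuals, stated rather than tuned
away: simulated α ≈ 0.81–0.86 versus the published 0.74 (the latent
model's non-Eyes items are somewhat more homogeneous than real item
content); simulated cohort maxima reach ≈ 12–16 versus the published 11;
and the INTERMEDIATE stratum rarely contains NIHSS ≥ 6 cases at n = 126
under a linear NIHSS link, so the published severity partition (86/9/31
with 0/5/26 severe cases) is used as a printed-count *input* wherever
its exact group percentages or odds ratio are recomputed.

**What passing simulation tests shows.** That the analysis stack
recovers known generative properties (agreement levels, correlation
signs and magnitudes, the off-scale item) under the study's design. It
does **not** show that real posterior-stroke data satisfy the latent
model — real items share method variance, raters drift systematically,
and companion links need not be linear in any latent trait.

## 3. Statistical conventions

* **Variance denominators** — sample (n−1) throughout. Mixing n and n−1
  denominators moves alpha in the third decimal and is the most common
  source of irreproducible item analyses.
* **Item-rest correlation** — Pearson, on raw integer scores, against
  the sum of the *other six* items (corrected item-total). The
  uncorrected variant inflates r and would bias the 0.3
  discriminatory-power flag.
* **ICC form** — ICC(2,1): two-way random effects, absolute agreement,
  single rater; the strictest common form and the natural one for
  interchangeable trained raters. The inter-rater coefficient pools all
  three raters in one ICC rather than averaging pairwise values. The 95%
  CI is the McGraw–Wong F construction with Satterthwaite df (rater df
  k−1, residual df (n−1)(k−1)); it was cross-checked against pingouin's
  ICC(A,1). When the residual mean square is zero (perfect within-
  patient agreement) the interval is undefined and the result is flagged
  `degenerate`, mirroring the dashes in published reliability tables.
  Zero between-patient variance is an error, not a value.
* **Weighted kappa** — quadratic disagreement weights by default (linear
  by flag), built on the full integer range spanned by the data (or an
  explicit category set, as in the per-item tables); CI from the
  Fleiss–Cohen–Everitt large-sample variance, clipped to [−1, 1].
  Quadratic weighting is the variant whose values track ICCs closely,
  which is the pattern the published per-item table shows.
* **Bland–Altman** — d = first − second (sign arbitrary and documented;
  swapping negates the mean and limits, CR is invariant). CR = 1.96·SD(d);
  limits d̄ ± CR; SE of each limit SD·√(3/n); CR's CI from the χ²
  interval for a standard deviation, scaled by 1.96. Zero variance is a
  valid result (CR = 0), not an error.
* **Mann–Whitney** — exact two-sided p by complete enumeration of
  C(n, n_x) labelings whenever both groups have ≤ 8 observations
  (handles ties exactly); otherwise the tie-corrected normal
  approximation *without* continuity correction, so that the two-group
  Kruskal–Wallis H equals z² identically.
* **Kruskal–Wallis** — tie-corrected H, p from χ² with g−1 df; all
  observations identical gives H = 0, p = 1 (valid, uninformative).
* **Spearman** — midrank ties, two-sided p from the t approximation with
  n−2 df.
* **Odds ratio** — cross-product on the 2×2 table; with any zero cell
  the Haldane–Anscombe correction (+0.5 to every cell) is applied and
  flagged, with a Wald CI and p on the log scale. This replaces the
  development study's "logistic regression", which is non-identifiable
  under the complete separation its own counts exhibit (the LOW stratum
  has zero severe cases): plain ML puts the estimate at infinity, and
  the study's printed OR = 141 (95% CI 6.72–2977.66) is not reproducible
  by the cross-product, Haldane or standard Firth closed forms on the
  printed counts — the corrected cross-product on those counts gives
  ≈ 211.4. The package deliberately reports the deterministic corrected
  estimate and does not attempt to match the unexplained value.
* **Report formatting** — percentages carry one decimal in written
  reports; underlying values are stored at full precision.

## 4. Open design points, resolved

* *Which rater feeds the single-rater analyses* (item analysis, validity
  panel) is not determined by the study design; the pipeline defaults to
  the first day-1 rater slot and exposes `designated_timepoint`.
* *Whether an assessment may consist entirely of non-assessable items*:
  treated as an error; a clinician recording nothing has no total.
* *Inter-rater weighted kappa* is not part of the per-item report (the
  published table shows κ only for intra-rater), but `weighted_kappa`
  accepts any paired scores.
* *Totals of 0* map to LOW (see section 1).

## 5. Problem sizes

The test suite and acceptance script use: study-sized cohorts (n = 126)
for pipeline-level checks; n = 2000 cohorts for pattern-level assertions
(ICC > 0.9, item-rest flags, correlation signs); 100 replicate cohorts
of n = 2000 for ICC parameter recovery against the closed-form
generative agreement (exponentially-modified-Gaussian marginals plus the
exact moments of the clipped ±1 error process); 200 cohorts of n = 126
for the median-total calibration check; and 10,000 pairs for the
limits-of-agreement coverage check. These sizes give Monte-Carlo error
comfortably below each assertion's margin.

## 6. Known limitations

* The generator's items are conditionally independent given θ (apart
  from the off-scale mechanism); real symptom clusters (e.g. brainstem
  syndromes) induce residual correlations it does not emulate.
* Rater errors are independent across items and raters; systematic rater
  leniency/severity is representable only through the ICC's rater
  variance component, not generated by default.
* Day-90 outcomes are a deterministic attenuation of day-1 severity plus
  noise; no heterogeneous recovery trajectories.
* The package validates the *analysis machinery*, not the clinical
  instrument: nothing here substitutes for multicentre validation on
  real patients.
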