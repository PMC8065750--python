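"""Synthetic validation cohorts with the structure the psychometric study assumes.

No patient-level data are published for the ASPOS development cohort, so
every downstream stage (internal consistency, reliability, validity) is
exercised on simulated cohorts that reproduce the study design:

* a right-skewed latent severity trait ``theta`` (exponential by default)
  drives the seven ordinal item scores through per-item cumulative
  cutpoints, with Gaussian latent noise controlling item discrimination;
* one item ("Eyes" by default) can be generated from an *independent*
  latent draw, emulating the published finding that the oculomotor/visual
  item carries almost no discriminatory power against the rest of the
  scale while keeping the same marginal distribution;
* each patient is scored on day 1 by three raters drawn from a pool of
  four trained investigators; a rater records the consensus score except
  with a small probability of being one level off (clipped to the item
  range); one of the three repeats the assessment three hours later
  (test-retest);
* companion severity scales (NIHSS, mRS, Barthel Index, GCS, IVBSS) are
  monotone noisy transforms of ``theta`` at day 1, and of an attenuated
  ``theta`` at day 90 (recovery), rounded to each scale's granularity and
  clipped to its range.

Default parameters are calibrated so a cohort of n=126 reproduces the
development study's margins: median total score 2 with observed range
about 1-11, median NIHSS 2, median mRS 1, median Barthel 90, median
GCS 15, and roughly a quarter of patients in the HIGH (total >= 4)
severity stratum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientRatersError
from .scale import (
    DAY1_SLOTS,
    RETEST_SLOT,
    ScaleDefinition,
    build_default_scale,
)

__all__ = [
    "CompanionLink",
    "CohortParams",
    "CohortTable",
    "default_params",
    "generate_cohort",
    "select_rater_pair",
    "COMPANION_RANGES",
]

#: Declared (min, max, step) of each companion scale.
COMPANION_RANGES: dict[str, tuple[int, int, int]] = {
    "NIHSS": (0, 42, 1),
    "mRS": (0, 6, 1),
    "Barthel": (0, 100, 5),
    "GCS": (3, 15, 1),
    "IVBSS": (0, 30, 1),
}


@dataclass(frozen=True)
class CompanionLink:
    """Monotone noisy map from the latent trait to one companion scale.

    ``value = clip(round_to_step(intercept + slope * theta + noise_sd * eps))``
    with ``eps`` standard normal.  ``slope`` is negative for scales where
    higher means better (Barthel, GCS).
    """

    intercept: float
    slope: float
    noise_sd: float
    lo: int
    hi: int
    step: int = 1

    def apply(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raw = self.intercept + self.slope * theta + self.noise_sd * rng.standard_normal(
            theta.shape
        )
        stepped = np.round(raw / self.step) * self.step
        return np.clip(stepped, self.lo, self.hi).astype(int)


def _expon_cutpoints(quantiles: Sequence[float], scale: float) -> tuple[float, ...]:
    """Cutpoints on the latent scale placed at exponential quantiles."""
    return tuple(-scale * math.log1p(-q) for q in quantiles)


# Population quantiles at which each item's cutpoints sit on the latent
# severity scale.  Chosen so the total-score distribution has median 2,
# about a quarter of patients at 4+, and an observed maximum near 11 in
# cohorts of ~126.  The first Balance cutpoint sits below the support of
# the latent trait (every stroke patient shows at least a minimal gait or
# stance finding), which reproduces the study's observed floor of 1.
_ITEM_CUTPOINT_QUANTILES: dict[str, tuple[float, ...]] = {
    "Reactivity": (0.91, 0.997, 0.9997),
    "Eyes": (0.75, 0.96, 0.996),
    "Pharynx": (0.71, 0.97, 0.9987),
    "Strength": (0.885, 0.993, 0.9995),
    "Balance": (0.885, 0.995),  # first cutpoint set separately below
    "Ataxia": (0.46, 0.96),
    "Sensory": (0.80, 0.982),
}

_BALANCE_FLOOR_CUTPOINT = -1.4  # latent units, 3.5 noise SDs below zero


def _default_cutpoints(theta_scale: float = 1.0) -> dict[str, tuple[float, ...]]:
    cuts = {
        name: _expon_cutpoints(qs, theta_scale)
        for name, qs in _ITEM_CUTPOINT_QUANTILES.items()
    }
    cuts["Balance"] = (_BALANCE_FLOOR_CUTPOINT * theta_scale,) + cuts["Balance"]
    return cuts


@dataclass(frozen=True)
class CohortParams:
    """Full parameterisation of a synthetic validation cohort."""

    n_patients: int = 126
    theta_scale: float = 1.0
    #: per item, strictly increasing cutpoints on the latent scale
    item_cutpoints: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_cutpoints
    )
    #: SD of the Gaussian latent noise added per item before thresholding
    #: (inverse discrimination); a float applies to every item, a mapping
    #: sets it per item.
    item_noise_sd: float | Mapping[str, float] = 0.4
    #: item generated from an independent latent draw (same marginal law)
    offscale_item: Optional[str] = "Eyes"
    offscale_prob: float = 1.0
    #: probability that a rater records an item one level off (+-1, clipped)
    rater_disagreement: float = 0.004
    retest_disagreement: float = 0.004
    #: multiplicative attenuation of theta at day 90 (recovery)
    recovery_shift: float = 0.6
    companion_links: Mapping[str, CompanionLink] = field(
        default_factory=lambda: {
            "NIHSS": CompanionLink(0.0, 2.9, 0.5, *COMPANION_RANGES["NIHSS"]),
            "mRS": CompanionLink(0.4, 0.9, 0.3, *COMPANION_RANGES["mRS"]),
            "Barthel": CompanionLink(100.0, -12.0, 4.0, *COMPANION_RANGES["Barthel"]),
            "GCS": CompanionLink(15.55, -0.75, 0.4, *COMPANION_RANGES["GCS"]),
            "IVBSS": CompanionLink(0.0, 2.2, 0.7, *COMPANION_RANGES["IVBSS"]),
        }
    )
    n_rater_pool: int = 4
    seed: int = 0

    def validate(self, scale: ScaleDefinition) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be at least 2")
        if self.theta_scale <= 0:
            raise ConfigurationError("theta_scale must be positive")
        for p, label in (
            (self.rater_disagreement, "rater_disagreement"),
            (self.retest_disagreement, "retest_disagreement"),
            (self.offscale_prob, "offscale_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{label} must lie in [0, 1], got {p}")
        if not 0.0 < self.recovery_shift <= 1.0:
            raise ConfigurationError(
                f"recovery_shift must lie in (0, 1], got {self.recovery_shift}"
            )
        for it_name, sd in self._noise_map(scale).items():
            if sd < 0:
                raise ConfigurationError(
                    f"item_noise_sd must be non-negative (item {it_name!r})"
                )
        if self.n_rater_pool < 3:
            raise ConfigurationError("rater pool must allow 3 day-1 raters")
        for it in scale.items:
            cuts = self.item_cutpoints.get(it.name)
            if cuts is None:
                raise ConfigurationError(f"no cutpoints for item {it.name!r}")
            if len(cuts) != it.max_code:
                raise ConfigurationError(
                    f"item {it.name!r} needs {it.max_code} cutpoints, got {len(cuts)}"
                )
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ConfigurationError(
                    f"cutpoints for {it.name!r} must be strictly increasing: {cuts}"
                )
        if self.offscale_item is not None and self.offscale_item not in scale.item_names:
            raise ConfigurationError(f"unknown offscale item {self.offscale_item!r}")
        for name, link in self.companion_links.items():
            if link.noise_sd < 0 or link.step <= 0 or link.hi <= link.lo:
                raise ConfigurationError(f"invalid companion link for {name!r}")

    def _noise_map(self, scale: ScaleDefinition) -> dict[str, float]:
        if isinstance(self.item_noise_sd, Mapping):
            missing = set(scale.item_names) - set(self.item_noise_sd)
            if missing:
                raise ConfigurationError(f"item_noise_sd missing items {sorted(missing)}")
            return {it: float(self.item_noise_sd[it]) for it in scale.item_names}
        return {it: float(self.item_noise_sd) for it in scale.item_names}

    def to_json(self) -> str:
        d = asdict(self)
        d["item_cutpoints"] = {k: list(v) for k, v in self.item_cutpoints.items()}
        d["companion_links"] = {k: asdict(v) for k, v in self.companion_links.items()}
        if isinstance(self.item_noise_sd, Mapping):
            d["item_noise_sd"] = dict(self.item_noise_sd)
        return json.dumps(d, indent=2, sort_keys=True)


def default_params(seed: int = 0, n_patients: int = 126, **overrides) -> CohortParams:
    """The calibrated study-design parameters (n=126 unless overridden)."""
    return CohortParams(n_patients=n_patients, seed=seed, **overrides)


@dataclass
class CohortTable:
    """A simulated (or loaded) validation cohort.

    Attributes
    ----------
    ratings:
        Long table with columns ``patient_id, rater_id, timepoint, item,
        score`` covering the three day-1 raters and the retest.
    companions:
        Long table with columns ``patient_id, day, scale, value`` for the
        five companion scales at day 1 and day 90.
    theta:
        True latent severity per patient (None for loaded cohorts).
    consensus:
        Patients x items frame of noise-free consensus scores (None for
        loaded cohorts).
    """

    ratings: pd.DataFrame
    companions: pd.DataFrame
    scale: ScaleDefinition
    theta: Optional[np.ndarray] = None
    consensus: Optional[pd.DataFrame] = None
    params: Optional[CohortParams] = None

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.ratings["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.ratings["patient_id"].nunique()

    def item_matrix(self, timepoint: str = "day1_r1") -> pd.DataFrame:
        """Patients x items score matrix for one timepoint slot."""
        sub = self.ratings[self.ratings["timepoint"] == timepoint]
        mat = sub.pivot(index="patient_id", columns="item", values="score")
        return mat.loc[:, list(self.scale.item_names)].sort_index()

    def totals(self, timepoint: str = "day1_r1") -> pd.Series:
        """Total score per patient at one timepoint (assessable items only)."""
        sub = self.ratings[self.ratings["timepoint"] == timepoint]
        return sub.groupby("patient_id")["score"].sum().sort_index()

    def companion(self, scale_name: str, day: int) -> pd.Series:
        sub = self.companions[
            (self.companions["scale"] == scale_name) & (self.companions["day"] == day)
        ]
        return sub.set_index("patient_id")["value"].sort_index()

    def retest_rater_ids(self) -> pd.Series:
        sub = self.ratings[self.ratings["timepoint"] == RETEST_SLOT]
        return sub.groupby("patient_id")["rater_id"].first().sort_index()


def _consensus_scores(
    theta_eff: np.ndarray, cutpoints: Sequence[float]
) -> np.ndarray:
    """Ordinal score = number of cutpoints at or below the effective latent."""
    cuts = np.asarray(cutpoints, dtype=float)
    return (theta_eff[:, None] >= cuts[None, :]).sum(axis=1)


def _rater_perturb(
    consensus: np.ndarray,
    max_codes: np.ndarray,
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """With probability ``p`` per cell, shift one level up or down, clipped."""
    shape = consensus.shape
    hit = rng.random(shape) < p
    direction = rng.integers(0, 2, size=shape) * 2 - 1
    shifted = consensus + hit * direction
    return np.clip(shifted, 0, max_codes[None, :])


def generate_cohort(params: Optional[CohortParams] = None) -> CohortTable:
    """Simulate one cohort under the study design; deterministic given the seed."""
    scale = build_default_scale()
    if params is None:
        params = default_params()
    params.validate(scale)
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    items = list(scale.item_names)
    max_codes = np.array([scale.item(it).max_code for it in items])

    theta = rng.exponential(params.theta_scale, size=n)

    # independent latent for the off-scale item, used where flagged
    theta_off = rng.exponential(params.theta_scale, size=n)
    off_mask = rng.random(n) < params.offscale_prob

    noise_map = params._noise_map(scale)
    consensus = np.empty((n, len(items)), dtype=int)
    for j, it in enumerate(items):
        base = theta.copy()
        if params.offscale_item == it:
            base[off_mask] = theta_off[off_mask]
        eff = base + noise_map[it] * rng.standard_normal(n)
        consensus[:, j] = _consensus_scores(eff, params.item_cutpoints[it])

    # three day-1 raters per patient, drawn from the pool without replacement
    pool = np.array([f"R{i + 1}" for i in range(params.n_rater_pool)])
    rater_order = np.argsort(rng.random((n, params.n_rater_pool)), axis=1)[:, :3]
    slot_raters = pool[rater_order]  # n x 3 rater ids

    observed = {
        slot: _rater_perturb(consensus, max_codes, params.rater_disagreement, rng)
        for slot in DAY1_SLOTS
    }
    retest_slot_idx = rng.integers(0, 3, size=n)
    observed[RETEST_SLOT] = _rater_perturb(
        consensus, max_codes, params.retest_disagreement, rng
    )

    width = max(3, len(str(n)))
    patient_ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])

    frames = []
    for s_idx, slot in enumerate(DAY1_SLOTS + (RETEST_SLOT,)):
        if slot == RETEST_SLOT:
            raters = slot_raters[np.arange(n), retest_slot_idx]
        else:
            raters = slot_raters[:, s_idx]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(patient_ids, len(items)),
                    "rater_id": np.repeat(raters, len(items)),
                    "timepoint": slot,
                    "item": np.tile(items, n),
                    "score": observed[slot].ravel(),
                }
            )
        )
    ratings = pd.concat(frames, ignore_index=True)

    comp_frames = []
    for day, th in ((1, theta), (90, params.recovery_shift * theta)):
        for name, link in params.companion_links.items():
            comp_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids,
                        "day": day,
                        "scale": name,
                        "value": link.apply(th, rng),
                    }
                )
            )
    companions = pd.concat(comp_frames, ignore_index=True)

    consensus_df = pd.DataFrame(consensus, index=patient_ids, columns=items)
    consensus_df.index.name = "patient_id"
    return CohortTable(
        ratings=ratings,
        companions=companions,
        scale=scale,
        theta=theta,
        consensus=consensus_df,
        params=params,
    )


_PAIR_CHOICES = ((0, 1), (0, 2), (1, 2))


def select_rater_pair(cohort: CohortTable, seed: int = 0) -> pd.DataFrame:
    """Pick, per patient, a uniformly random unordered pair of day-1 raters.

    This mirrors the repeatability design, where the total-score
    difference between two randomly selected investigators feeds the
    Bland-Altman analysis.  Returns a frame with columns ``patient_id,
    timepoint_a, timepoint_b, total_a, total_b``.
    """
    present = set(cohort.ratings["timepoint"].unique())
    day1 = [s for s in DAY1_SLOTS if s in present]
    if len(day1) < 2:
        raise InsufficientRatersError(
            f"need at least 2 day-1 rater slots, found {sorted(present)}"
        )
    totals = {slot: cohort.totals(slot) for slot in day1}
    patients = totals[day1[0]].index
    rng = np.random.default_rng(seed)
    if len(day1) == 2:
        pick = np.zeros(len(patients), dtype=int)
        choices = ((0, 1),)
    else:
        pick = rng.integers(0, len(_PAIR_CHOICES), size=len(patients))
        choices = _PAIR_CHOICES
    rows = []
    for pid, c in zip(patients, pick):
        a, b = choices[c]
        rows.append(
            {
                "patient_id": pid,
                "timepoint_a": day1[a],
                "timepoint_b": day1[b],
                "total_a": int(totals[day1[a]].loc[pid]),
                "total_b": int(totals[day1[b]].loc[pid]),
            }
        )
    return pd.DataFrame(rows)
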