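"""Inter- and intra-rater reliability: ICC(2,1), weighted kappa, Bland-Altman.

Conventions chosen for a panel of interchangeable trained raters:

* the intraclass correlation is ICC(2,1) -- two-way random effects,
  absolute agreement, single rater -- the strictest common form, with
  the 95% confidence interval from the standard F-distribution
  construction (McGraw & Wong);
* Cohen's kappa is weighted quadratically by default (linear available),
  with the large-sample Fleiss-Cohen-Everitt variance for the CI;
* Bland-Altman repeatability uses the coefficient of repeatability
  CR = 1.96 * SD of the paired differences, i.e. the half-width of the
  limits of agreement around the mean difference; limit CIs use
  SE = SD * sqrt(3/n) and the CR CI uses the chi-square interval for a
  standard deviation scaled by 1.96.

When raters agree perfectly on every patient while patients differ, the
ICC is exactly 1 but its F-based interval is undefined; such results are
returned with ``degenerate=True`` and no CI, matching the dashes seen in
published reliability tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError
from .scale import DAY1_SLOTS, RETEST_SLOT
from .simulate import CohortTable

__all__ = [
    "ICCResult",
    "KappaResult",
    "BlandAltmanResult",
    "icc_two_way",
    "weighted_kappa",
    "bland_altman",
    "reliability_table",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    ms_patient: float
    ms_rater: float
    ms_error: float
    n: int
    k: int
    degenerate: bool = False


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    weights: str
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    cr: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    ci_cr: tuple[float, float]
    n_outside: int
    n: int


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (patients x raters) ANOVA mean squares without replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(block, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``block`` is an n x k complete matrix of scores (patients in rows,
    raters or occasions in columns).  The 95% CI follows the
    McGraw & Wong F-based construction.
    """
    x = np.asarray(pd.DataFrame(block), dtype=float)
    if np.isnan(x).any():
        raise InvalidInputError("ratings block must be complete")
    n, k = x.shape
    if n < 3 or k < 2:
        raise InvalidInputError(f"need n >= 3 patients and k >= 2 raters, got {n}x{k}")
    msr, msc, mse = _anova_mean_squares(x)
    if msr <= 1e-14:
        raise UndefinedStatisticError(
            "zero between-patient variance; the ICC is undefined"
        )
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse <= 1e-14:
        # no residual variance: icc = 1 when raters also agree perfectly;
        # either way the F-based interval is undefined
        return ICCResult(float(icc), None, None, msr, msc, mse, n, k, degenerate=True)

    # Satterthwaite df for the rater/error mixture (rater df k-1, error
    # df (n-1)(k-1)), then F-based bounds
    fj = msc / mse
    ap = k * icc
    bp = n * (1 + (k - 1) * icc) - k * icc
    v = ((n - 1) * (k - 1) * (ap * fj + bp) ** 2) / (
        (n - 1) * ap**2 * fj**2 + bp**2
    )
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return ICCResult(
        float(icc), float(lower), float(upper), msr, msc, mse, n, k, degenerate=False
    )


def _disagreement_weights(categories: np.ndarray, scheme: str) -> np.ndarray:
    span = categories[-1] - categories[0]
    diff = np.abs(categories[:, None] - categories[None, :]) / span
    if scheme == "quadratic":
        return diff**2
    if scheme == "linear":
        return diff
    raise InvalidInputError(f"unknown weighting scheme {scheme!r}")


def weighted_kappa(
    x: Sequence[int],
    y: Sequence[int],
    weights: str = "quadratic",
    categories: Optional[Sequence[int]] = None,
    alpha: float = 0.05,
) -> KappaResult:
    """Weighted Cohen's kappa for paired ordinal scores.

    Categories default to the full integer range spanned by the observed
    scores.  The CI uses the large-sample variance of the weighted kappa
    estimator (Fleiss, Cohen & Everitt).
    """
    xa = np.asarray(x, dtype=int)
    ya = np.asarray(y, dtype=int)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size == 0:
        raise InvalidInputError("weighted_kappa needs two equal-length 1-d score arrays")
    n = xa.size
    if categories is None:
        lo = int(min(xa.min(), ya.min()))
        hi = int(max(xa.max(), ya.max()))
        categories = np.arange(lo, hi + 1)
    else:
        categories = np.asarray(sorted(categories), dtype=int)
    if categories.size < 2:
        raise UndefinedStatisticError(
            "only one score category present in both raters; kappa undefined"
        )
    cat_index = {c: i for i, c in enumerate(categories.tolist())}
    try:
        xi = np.array([cat_index[v] for v in xa.tolist()])
        yi = np.array([cat_index[v] for v in ya.tolist()])
    except KeyError as exc:
        raise InvalidInputError(f"score {exc.args[0]} outside declared categories") from exc

    r = categories.size
    obs = np.zeros((r, r))
    np.add.at(obs, (xi, yi), 1.0)
    p = obs / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)

    w = _disagreement_weights(categories.astype(float), weights)
    v = 1.0 - w  # agreement weights in [0, 1]
    po = float(np.sum(p * v))
    pe = float(pi @ v @ pj)
    if 1.0 - pe <= 1e-14:
        raise UndefinedStatisticError(
            "chance agreement is 1 (degenerate marginals); kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance
    vbar_i = v @ pj  # expected agreement weight given row category
    vbar_j = pi @ v
    term = (v - (vbar_i[:, None] + vbar_j[None, :]) * (1.0 - kappa)) ** 2
    var = (np.sum(p * term) - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = np.sqrt(max(var, 0.0))
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(max(-1.0, kappa - _Z95 * se)),
        ci_high=float(min(1.0, kappa + _Z95 * se)),
        weights=weights,
        n=n,
    )


def bland_altman(
    first: Sequence[float],
    second: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
) -> BlandAltmanResult:
    """Bland-Altman repeatability of paired totals.

    Accepts either two paired score sequences or a single sequence of
    differences.  Differences are ``first - second``; the sign is
    arbitrary and swapping the pair order negates the mean difference
    and the limits while leaving the CR unchanged.
    """
    a = np.asarray(first, dtype=float)
    if second is None:
        d = a
    else:
        b = np.asarray(second, dtype=float)
        if a.shape != b.shape:
            raise InvalidInputError("paired score sequences must have equal length")
        d = a - b
    n = d.size
    if n < 3:
        raise InvalidInputError(f"Bland-Altman needs at least 3 pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    z = stats.norm.ppf(1 - alpha / 2)
    cr = z * sd
    loa_low, loa_high = mean - cr, mean + cr
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    if sd > 0:
        chi_hi = stats.chi2.ppf(1 - alpha / 2, n - 1)
        chi_lo = stats.chi2.ppf(alpha / 2, n - 1)
        ci_cr = (z * sd * np.sqrt((n - 1) / chi_hi), z * sd * np.sqrt((n - 1) / chi_lo))
    else:
        ci_cr = (0.0, 0.0)
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        cr=float(cr),
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_mean=(mean - z * se_mean, mean + z * se_mean),
        ci_loa_low=(loa_low - z * se_loa, loa_low + z * se_loa),
        ci_loa_high=(loa_high - z * se_loa, loa_high + z * se_loa),
        ci_cr=(float(ci_cr[0]), float(ci_cr[1])),
        n_outside=outside,
        n=n,
    )


def reliability_table(
    cohort: CohortTable, kappa_weights: str = "quadratic"
) -> pd.DataFrame:
    """Per-item reliability report (one row per scale item).

    Inter-rater: ICC(2,1) over the three day-1 raters.  Intra-rater:
    ICC(2,1) and weighted kappa between the retest rater's day-1 scores
    and the 3-hour retest.  The inter-rater column pools all three
    raters in a single ICC rather than averaging pairwise coefficients.
    """
    mats = {slot: cohort.item_matrix(slot) for slot in DAY1_SLOTS + (RETEST_SLOT,)}
    retest_rater = cohort.retest_rater_ids()
    # which day-1 slot the retest rater occupied, per patient
    rater_by_slot = {
        slot: cohort.ratings[cohort.ratings["timepoint"] == slot]
        .groupby("patient_id")["rater_id"]
        .first()
        for slot in DAY1_SLOTS
    }
    patients = mats[DAY1_SLOTS[0]].index
    first_pass = pd.DataFrame(index=patients, columns=mats[RETEST_SLOT].columns, dtype=int)
    for slot in DAY1_SLOTS:
        mask = rater_by_slot[slot].loc[patients] == retest_rater.loc[patients]
        if mask.any():
            first_pass.loc[mask[mask].index] = mats[slot].loc[mask[mask].index]

    rows = []
    for item in cohort.scale.item_names:
        inter_block = np.column_stack([mats[s][item].to_numpy() for s in DAY1_SLOTS])
        intra_block = np.column_stack(
            [first_pass[item].to_numpy(dtype=int), mats[RETEST_SLOT][item].to_numpy()]
        )
        inter = icc_two_way(inter_block)
        intra = icc_two_way(intra_block)
        kap = weighted_kappa(
            intra_block[:, 0],
            intra_block[:, 1],
            weights=kappa_weights,
            categories=range(cohort.scale.item(item).max_code + 1),
        )
        rows.append(
            {
                "item": item,
                "inter_icc": inter.icc,
                "inter_ci_low": inter.ci_low,
                "inter_ci_high": inter.ci_high,
                "intra_icc": intra.icc,
                "intra_ci_low": intra.ci_low,
                "intra_ci_high": intra.ci_high,
                "kappa": kap.kappa,
                "kappa_ci_low": kap.ci_low,
                "kappa_ci_high": kap.ci_high,
            }
        )
    return pd.DataFrame(rows)
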