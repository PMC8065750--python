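"""Construct and predictive validity, plus the severity-threshold analysis.

Construct validity is the Spearman correlation of the day-1 ASPOS total
with the same-day companion scales (NIHSS, Barthel Index, mRS, GCS,
IVBSS); predictive validity correlates the day-1 total with the day-90
NIHSS, Barthel and mRS.  The threshold analysis stratifies patients by
ASPOS severity group (LOW 0-2, INTERMEDIATE 3, HIGH >= 4), compares the
NIHSS distribution across strata by Kruskal-Wallis, and expresses the
INTERMEDIATE-vs-LOW contrast for severe stroke (NIHSS >= cutoff,
default 6, the conventional thrombectomy threshold) as an odds ratio.

With a zero cell the plain maximum-likelihood logistic odds ratio is
infinite (complete separation), so the odds ratio applies the
Haldane-Anscombe correction -- add 0.5 to every cell -- with a Wald CI
on the log scale, and flags that the correction fired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError
from .scale import SeverityGroup, severity_group
from .simulate import CohortTable

__all__ = [
    "SpearmanResult",
    "GroupComparisonResult",
    "OddsRatioResult",
    "ThresholdResult",
    "spearman",
    "kruskal_wallis",
    "mann_whitney",
    "odds_ratio",
    "threshold_analysis",
    "validity_report",
    "NIHSS_SEVERE_CUTOFF",
]

NIHSS_SEVERE_CUTOFF = 6
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float  # H (Kruskal-Wallis) or U (Mann-Whitney)
    df_or_sizes: tuple[int, ...]
    p_value: float
    medians: tuple[float, ...]
    method: str


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool
    table: tuple[int, int, int, int]


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (midrank ties), p from the t approximation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("spearman needs two equal-length 1-d sequences")
    n = xa.size
    if n < 4:
        raise InvalidInputError(f"spearman needs n >= 4, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise UndefinedStatisticError("constant variable; rank correlation undefined")
    rho, p = stats.spearmanr(xa, ya)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H; p from chi-square with g-1 df.

    If every observation is identical, H = 0 and p = 1 (a valid, fully
    uninformative result rather than an error).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise InvalidInputError("kruskal_wallis needs >= 2 non-empty groups")
    if sum(a.size for a in arrays) < 5:
        raise InvalidInputError("kruskal_wallis needs total n >= 5")
    medians = tuple(float(np.median(a)) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(
            0.0, (len(arrays) - 1,), 1.0, medians, "kruskal-wallis"
        )
    h, p = stats.kruskal(*arrays)
    return GroupComparisonResult(
        float(h), (len(arrays) - 1,), float(p), medians, "kruskal-wallis"
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x, y) pairs with x > y, ties counting 1/2."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> GroupComparisonResult:
    """Mann-Whitney U with exact enumeration for small samples.

    When both groups have at most ``exact_max_n`` observations the
    two-sided p-value is computed by enumerating every possible
    assignment of the pooled values to the two groups (which handles
    ties exactly); otherwise the tie-corrected normal approximation is
    used, without continuity correction so that the two-group
    Kruskal-Wallis H equals z**2.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise InvalidInputError("mann_whitney needs two non-empty samples")
    nx, ny = xa.size, ya.size
    u = _u_statistic(xa, ya)
    mu = nx * ny / 2.0
    medians = (float(np.median(xa)), float(np.median(ya)))

    if nx <= exact_max_n and ny <= exact_max_n:
        # the pooled midranks are invariant under relabelling, so U for a
        # permuted split is just the rank sum of the selected positions
        ranks = stats.rankdata(np.concatenate([xa, ya]))
        offset = nx * (nx + 1) / 2.0
        count = 0
        total = 0
        obs_dev = abs(u - mu) - 1e-12
        for comb in combinations(range(nx + ny), nx):
            u_perm = sum(ranks[i] for i in comb) - offset
            total += 1
            if abs(u_perm - mu) >= obs_dev:
                count += 1
        return GroupComparisonResult(
            u, (nx, ny), count / total, medians, "mann-whitney-exact"
        )

    pooled = np.concatenate([xa, ya])
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return GroupComparisonResult(u, (nx, ny), 1.0, medians, "mann-whitney-normal")
    z = (u - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return GroupComparisonResult(u, (nx, ny), min(p, 1.0), medians, "mann-whitney-normal")


def odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Odds ratio of a 2x2 table ``[[a, b], [c, d]]`` with zero-cell handling.

    Rows are the two groups compared, columns outcome yes/no, so the
    estimate is ``(a/b) / (c/d)``.  If any cell is zero the
    Haldane-Anscombe correction adds 0.5 to every cell before the
    cross-product; the CI is Wald on the log scale and the p-value comes
    from the Wald z statistic.
    """
    cells = (a, b, c, d)
    if any((not float(v).is_integer()) or v < 0 for v in cells):
        raise InvalidInputError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    if a + b + c + d == 0:
        raise UndefinedStatisticError("empty contingency table")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise UndefinedStatisticError(
            f"a margin of the 2x2 table {cells} is zero; no odds ratio exists"
        )
    correction = 0 in (a, b, c, d)
    if correction:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
    else:
        aa, bb, cc, dd = (float(v) for v in (a, b, c, d))
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(est)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OddsRatioResult(
        or_estimate=float(est),
        ci_low=float(math.exp(log_or - _Z95 * se)),
        ci_high=float(math.exp(log_or + _Z95 * se)),
        p_value=float(p),
        correction_applied=correction,
        table=(a, b, c, d),
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Severity-stratum breakdown of severe stroke by the NIHSS cutoff."""

    groups: pd.DataFrame  # group, n, pct, n_severe
    cutoff: int
    kruskal: Optional[GroupComparisonResult]
    odds_intermediate_vs_low: Optional[OddsRatioResult]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def threshold_analysis(
    totals: Sequence[int],
    nihss: Sequence[float],
    cutoff: int = NIHSS_SEVERE_CUTOFF,
) -> ThresholdResult:
    """Stratify by severity group and quantify the step in severe-stroke odds.

    Reports, per stratum, the patient count, its percentage of the
    cohort, and the number of patients at or above the NIHSS cutoff;
    the Kruskal-Wallis comparison of NIHSS across the strata present;
    and the INTERMEDIATE-vs-LOW odds ratio for NIHSS >= cutoff.
    """
    t = np.asarray(totals, dtype=int)
    s = np.asarray(nihss, dtype=float)
    if t.shape != s.shape or t.ndim != 1 or t.size == 0:
        raise InvalidInputError("totals and nihss must be equal-length 1-d sequences")
    n = t.size
    labels = np.array([severity_group(v).value for v in t])
    order = [g.value for g in SeverityGroup]
    warnings: list[str] = []
    rows = []
    group_scores: dict[str, np.ndarray] = {}
    for g in order:
        mask = labels == g
        ng = int(mask.sum())
        if ng == 0:
            warnings.append(f"severity group {g} is empty and was dropped")
            continue
        group_scores[g] = s[mask]
        rows.append(
            {
                "group": g,
                "n": ng,
                "pct": 100.0 * ng / n,
                "n_severe": int(np.sum(s[mask] >= cutoff)),
            }
        )
    groups_df = pd.DataFrame(rows)

    kw = None
    if len(group_scores) >= 2 and n >= 5:
        kw = kruskal_wallis(list(group_scores.values()))

    orr = None
    if "LOW" in group_scores and "INTERMEDIATE" in group_scores:
        inter = group_scores["INTERMEDIATE"]
        low = group_scores["LOW"]
        a = int(np.sum(inter >= cutoff))
        b = inter.size - a
        c = int(np.sum(low >= cutoff))
        d = low.size - c
        try:
            orr = odds_ratio(a, b, c, d)
        except UndefinedStatisticError as exc:
            warnings.append(f"INTERMEDIATE-vs-LOW odds ratio undefined: {exc}")
    else:
        warnings.append(
            "INTERMEDIATE-vs-LOW odds ratio not computed (a stratum is empty)"
        )
    return ThresholdResult(
        groups=groups_df,
        cutoff=cutoff,
        kruskal=kw,
        odds_intermediate_vs_low=orr,
        warnings=tuple(warnings),
    )


#: (companion scale, day) pairs of the correlation panel, in report order.
VALIDITY_PANEL: tuple[tuple[str, int], ...] = (
    ("NIHSS", 1),
    ("Barthel", 1),
    ("mRS", 1),
    ("GCS", 1),
    ("IVBSS", 1),
    ("NIHSS", 90),
    ("Barthel", 90),
    ("mRS", 90),
)


def validity_report(
    cohort: CohortTable, timepoint: str = "day1_r1"
) -> pd.DataFrame:
    """Construct + predictive Spearman panel of the day-1 total score.

    Day-1 rows measure construct validity; day-90 rows measure how well
    the admission total predicts outcome.  Correlation signs are
    reported as computed (Barthel and GCS run opposite to severity, so
    negative coefficients are expected).
    """
    totals = cohort.totals(timepoint)
    rows = []
    for scale_name, day in VALIDITY_PANEL:
        comp = cohort.companion(scale_name, day)
        joined = pd.concat([totals, comp], axis=1, join="inner")
        res = spearman(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append(
            {
                "scale": scale_name,
                "day": day,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
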