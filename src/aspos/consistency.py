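"""Internal consistency: Cronbach's alpha and corrected item-rest analysis.

Implements the classical item analysis reported for multi-item clinical
scales: the overall alpha coefficient, the corrected item-rest (a.k.a.
item-total) Pearson correlation quantifying each item's discriminatory
power, and alpha recomputed with each item deleted.  Conventions:

* sample (n-1 denominator) variances throughout -- mixing denominators
  shifts alpha in the third decimal and is the most common source of
  irreproducible item analyses;
* "rest" excludes the item itself (corrected item-total correlation),
  because the uncorrected variant inflates the correlation that is then
  judged against the 0.3 discriminatory-power threshold;
* flags follow the conventional cutoffs: alpha >= 0.7 (Nunnally) for
  acceptable consistency, item-rest r < 0.3 for poor discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "ConsistencyResult",
    "cronbach_alpha",
    "item_rest_correlation",
    "alpha_if_deleted",
    "item_analysis",
    "NUNNALLY_ALPHA",
    "DISCRIMINATION_THRESHOLD",
]

NUNNALLY_ALPHA = 0.7
DISCRIMINATION_THRESHOLD = 0.3


def _as_matrix(m) -> pd.DataFrame:
    df = pd.DataFrame(m)
    if df.isna().any().any():
        raise InvalidInputError("item score matrix must be complete (no missing cells)")
    return df.astype(float)


def cronbach_alpha(m) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(var_i) / var_total)``.

    ``m`` is a patients x items matrix (DataFrame or array-like) with no
    missing cells; variances use the n-1 denominator.
    """
    df = _as_matrix(m)
    n, k = df.shape
    if k < 2:
        raise InvalidInputError(f"alpha needs at least 2 items, got {k}")
    if n < 3:
        raise InvalidInputError(f"alpha needs at least 3 rows, got {n}")
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total score has zero variance; alpha undefined")
    item_vars = df.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def item_rest_correlation(m, item) -> float:
    """Pearson correlation between one item and the sum of the others."""
    df = _as_matrix(m)
    if item not in df.columns:
        raise InvalidInputError(f"unknown item {item!r}; columns are {list(df.columns)}")
    col = df[item].to_numpy()
    rest = df.drop(columns=[item]).sum(axis=1).to_numpy()
    if np.std(col) == 0:
        raise UndefinedStatisticError(f"item {item!r} is constant; correlation undefined")
    if np.std(rest) == 0:
        raise UndefinedStatisticError(
            f"rest-sum excluding {item!r} is constant; correlation undefined"
        )
    return float(np.corrcoef(col, rest)[0, 1])


def alpha_if_deleted(m, item) -> float:
    """Cronbach's alpha of the scale with one item removed."""
    df = _as_matrix(m)
    if item not in df.columns:
        raise InvalidInputError(f"unknown item {item!r}; columns are {list(df.columns)}")
    if df.shape[1] < 3:
        raise InvalidInputError("alpha-if-deleted needs at least 3 items")
    return cronbach_alpha(df.drop(columns=[item]))


@dataclass(frozen=True)
class ConsistencyResult:
    """Scale-level alpha plus the per-item discrimination table."""

    alpha: float
    item_rest: pd.Series  # per item, ordered as the scale
    alpha_deleted: pd.Series
    meets_nunnally: bool
    low_discrimination: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Per-item report shaped like a published item-analysis table."""
        return pd.DataFrame(
            {
                "item": self.item_rest.index,
                "item_rest_correlation": self.item_rest.to_numpy(),
                "alpha_if_deleted": self.alpha_deleted.to_numpy(),
                "low_discrimination": [
                    it in self.low_discrimination for it in self.item_rest.index
                ],
            }
        )


def item_analysis(m) -> ConsistencyResult:
    """Full item analysis: alpha, item-rest correlations, alpha-if-deleted."""
    df = _as_matrix(m)
    alpha = cronbach_alpha(df)
    items = list(df.columns)
    rest = pd.Series([item_rest_correlation(df, it) for it in items], index=items)
    deleted = pd.Series([alpha_if_deleted(df, it) for it in items], index=items)
    low = tuple(it for it in items if rest[it] < DISCRIMINATION_THRESHOLD)
    return ConsistencyResult(
        alpha=alpha,
        item_rest=rest,
        alpha_deleted=deleted,
        meets_nunnally=alpha >= NUNNALLY_ALPHA,
        low_discrimination=low,
    )
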