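"""Reading and writing the canonical delimited-text tables.

Ratings are stored long (one row per patient / rater / timepoint / item
score), because a non-assessable item is then naturally represented by
the absence of its row.  Companion scales are stored long as well
(patient, day, scale, value).  All files are comma-separated UTF-8 with
a header row.  Validation is strict: unknown items, out-of-range scores
and duplicate keys are rejected with the offending row numbers so a
malformed export can be fixed at the source.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ParseError
from .scale import TIMEPOINTS, ScaleDefinition, build_default_scale
from .simulate import COMPANION_RANGES, CohortTable

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_companions",
    "write_companions",
    "read_cohort",
    "write_cohort",
    "ratings_to_wide",
]

RATINGS_COLUMNS = ["patient_id", "rater_id", "timepoint", "item", "score"]
COMPANIONS_COLUMNS = ["patient_id", "day", "scale", "value"]


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: expected header {expected}, found {list(df.columns)}"
        )


def read_ratings(path, scale: Optional[ScaleDefinition] = None) -> pd.DataFrame:
    """Load and validate a long-format ratings table.

    Row numbers in error messages count from 1 at the first data row.
    """
    if scale is None:
        scale = build_default_scale()
    df = pd.read_csv(path, dtype={"patient_id": str, "rater_id": str})
    _check_header(df, RATINGS_COLUMNS, path)

    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        rows = (df.index[bad_tp] + 1).tolist()
        raise ParseError(
            f"{path}: unknown timepoint at row(s) {rows}; expected one of {TIMEPOINTS}"
        )
    bad_item = ~df["item"].isin(scale.item_names)
    if bad_item.any():
        rows = (df.index[bad_item] + 1).tolist()
        vals = df.loc[bad_item, "item"].unique().tolist()
        raise ParseError(
            f"{path}: unknown item(s) {vals} at row(s) {rows}; "
            f"expected one of {scale.item_names}"
        )
    if df["score"].isna().any():
        rows = (df.index[df["score"].isna()] + 1).tolist()
        raise ParseError(f"{path}: missing score at row(s) {rows}")
    try:
        df["score"] = df["score"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer score ({exc})") from exc
    for it in scale.items:
        mask = (df["item"] == it.name) & (
            (df["score"] < 0) | (df["score"] > it.max_code)
        )
        if mask.any():
            rows = (df.index[mask] + 1).tolist()
            vals = df.loc[mask, "score"].tolist()
            raise ParseError(
                f"{path}: score(s) {vals} at row(s) {rows} outside the valid "
                f"range 0-{it.max_code} for item {it.name!r}"
            )
    key = ["patient_id", "rater_id", "timepoint", "item"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ParseError(
            f"{path}: duplicate (patient, rater, timepoint, item) at rows {rows}"
        )
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    df.loc[:, RATINGS_COLUMNS].to_csv(path, index=False)


def read_companions(path) -> pd.DataFrame:
    """Load and validate a long-format companion-scale table."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_header(df, COMPANIONS_COLUMNS, path)
    bad_scale = ~df["scale"].isin(COMPANION_RANGES)
    if bad_scale.any():
        rows = (df.index[bad_scale] + 1).tolist()
        raise ParseError(
            f"{path}: unknown companion scale at row(s) {rows}; "
            f"expected one of {sorted(COMPANION_RANGES)}"
        )
    bad_day = ~df["day"].isin((1, 90))
    if bad_day.any():
        rows = (df.index[bad_day] + 1).tolist()
        raise ParseError(f"{path}: day must be 1 or 90, bad row(s) {rows}")
    for name, (lo, hi, _step) in COMPANION_RANGES.items():
        mask = (df["scale"] == name) & ((df["value"] < lo) | (df["value"] > hi))
        if mask.any():
            rows = (df.index[mask] + 1).tolist()
            raise ParseError(
                f"{path}: {name} value(s) outside {lo}-{hi} at row(s) {rows}"
            )
    dup = df.duplicated(subset=["patient_id", "day", "scale"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ParseError(f"{path}: duplicate (patient, day, scale) at rows {rows}")
    return df


def write_companions(df: pd.DataFrame, path) -> None:
    df.loc[:, COMPANIONS_COLUMNS].to_csv(path, index=False)


def write_cohort(cohort: CohortTable, outdir) -> dict[str, Path]:
    """Write a cohort as ratings.csv + companions.csv (+ params sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratings": outdir / "ratings.csv",
        "companions": outdir / "companions.csv",
    }
    write_ratings(cohort.ratings, paths["ratings"])
    write_companions(cohort.companions, paths["companions"])
    if cohort.params is not None:
        paths["params"] = outdir / "params.json"
        paths["params"].write_text(cohort.params.to_json(), encoding="utf-8")
    return paths


def read_cohort(ratings_path, companions_path=None) -> CohortTable:
    """Assemble a CohortTable from text tables (no latent trait available)."""
    scale = build_default_scale()
    ratings = read_ratings(ratings_path, scale)
    if companions_path is not None:
        companions = read_companions(companions_path)
    else:
        companions = pd.DataFrame(columns=COMPANIONS_COLUMNS)
    return CohortTable(ratings=ratings, companions=companions, scale=scale)


def ratings_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Convenience wide export: one row per (patient, rater, timepoint)."""
    return (
        df.pivot(
            index=["patient_id", "rater_id", "timepoint"], columns="item", values="score"
        )
        .reset_index()
        .rename_axis(columns=None)
    )
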