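"""End-to-end validation runs: simulate or load, then every analysis stage.

``run_full_validation`` chains the stages the development study reports:
item analysis (internal consistency), per-item inter-/intra-rater
reliability, Bland-Altman repeatability of the total between two
randomly selected raters, the construct/predictive Spearman panel, and
the severity-threshold analysis.  Every random choice (rater pairing,
designated rater) derives from the run seed, so a rerun with the same
configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .consistency import ConsistencyResult, item_analysis
from .errors import ConfigurationError, PipelineError
from .io import read_cohort, write_cohort
from .reliability import BlandAltmanResult, bland_altman, reliability_table
from .simulate import CohortParams, CohortTable, default_params, generate_cohort, select_rater_pair
from .validity import (
    NIHSS_SEVERE_CUTOFF,
    ThresholdResult,
    threshold_analysis,
    validity_report,
)

__all__ = ["RunConfig", "ValidationReport", "run_full_validation", "write_report"]

log = logging.getLogger("aspos")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one validation run.

    Exactly one of ``params`` (simulate) or ``ratings_path`` (load) must
    be set.  ``designated_timepoint`` selects whose day-1 scores feed
    the single-rater analyses (item analysis, validity panel).
    """

    params: Optional[CohortParams] = None
    ratings_path: Optional[str] = None
    companions_path: Optional[str] = None
    seed: int = 0
    designated_timepoint: str = "day1_r1"
    kappa_weights: str = "quadratic"
    nihss_cutoff: int = NIHSS_SEVERE_CUTOFF

    def __post_init__(self) -> None:
        if (self.params is None) == (self.ratings_path is None):
            raise ConfigurationError(
                "exactly one of simulation params or a ratings path must be given"
            )


@dataclass
class ValidationReport:
    """Machine-readable twin of the study's result tables."""

    consistency: ConsistencyResult
    reliability: pd.DataFrame
    bland_altman: BlandAltmanResult
    bland_altman_pairs: pd.DataFrame
    validity: pd.DataFrame
    threshold: ThresholdResult
    provenance: dict


def run_full_validation(config: RunConfig) -> ValidationReport:
    """Execute simulate-or-load followed by every analysis stage."""
    stage = "input"
    try:
        if config.params is not None:
            cohort = generate_cohort(config.params)
            source = f"simulated(seed={config.params.seed}, n={config.params.n_patients})"
        else:
            cohort = read_cohort(config.ratings_path, config.companions_path)
            source = f"loaded({config.ratings_path})"
        log.info("cohort ready: %s patients from %s", cohort.n_patients, source)

        stage = "consistency"
        matrix = cohort.item_matrix(config.designated_timepoint)
        consistency = item_analysis(matrix)
        log.info("alpha = %.4f", consistency.alpha)

        stage = "reliability"
        rel = reliability_table(cohort, kappa_weights=config.kappa_weights)

        stage = "bland-altman"
        pairs = select_rater_pair(cohort, seed=config.seed)
        ba = bland_altman(pairs["total_a"], pairs["total_b"])
        log.info("CR = %.3f from %d pairs", ba.cr, ba.n)

        stage = "validity"
        val = validity_report(cohort, timepoint=config.designated_timepoint)
        totals = cohort.totals(config.designated_timepoint)
        nihss = cohort.companion("NIHSS", 1)
        joined = pd.concat([totals, nihss], axis=1, join="inner")
        thr = threshold_analysis(
            joined.iloc[:, 0], joined.iloc[:, 1], cutoff=config.nihss_cutoff
        )
    except Exception as exc:
        raise PipelineError(f"validation aborted at stage {stage!r}: {exc}") from exc

    provenance = {
        "software": f"aspos {__version__}",
        "source": source,
        "seed": config.seed,
        "designated_timepoint": config.designated_timepoint,
        "kappa_weights": config.kappa_weights,
        "nihss_cutoff": config.nihss_cutoff,
        "n_patients": int(cohort.n_patients),
    }
    return ValidationReport(
        consistency=consistency,
        reliability=rel,
        bland_altman=ba,
        bland_altman_pairs=pairs,
        validity=val,
        threshold=thr,
        provenance=provenance,
    )


def _fmt(x: float, nd: int = 6) -> float:
    return float(f"{x:.{nd}g}")


def write_report(report: ValidationReport, outdir) -> dict[str, Path]:
    """Write every sub-report as CSV plus a provenance/summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cons = report.consistency.to_frame()
    cons_path = outdir / "consistency.csv"
    cons.to_csv(cons_path, index=False)
    paths["consistency"] = cons_path

    rel_path = outdir / "reliability.csv"
    report.reliability.to_csv(rel_path, index=False)
    paths["reliability"] = rel_path

    val_path = outdir / "validity.csv"
    report.validity.to_csv(val_path, index=False)
    paths["validity"] = val_path

    thr_path = outdir / "threshold.csv"
    thr = report.threshold.groups.copy()
    thr["pct"] = thr["pct"].round(1)
    thr.to_csv(thr_path, index=False)
    paths["threshold"] = thr_path

    ba = report.bland_altman
    summary = {
        "provenance": report.provenance,
        "cronbach_alpha": _fmt(report.consistency.alpha),
        "meets_nunnally": report.consistency.meets_nunnally,
        "low_discrimination_items": list(report.consistency.low_discrimination),
        "bland_altman": {
            "mean_diff": _fmt(ba.mean_diff),
            "cr": _fmt(ba.cr),
            "cr_ci": [_fmt(v) for v in ba.ci_cr],
            "loa": [_fmt(ba.loa_low), _fmt(ba.loa_high)],
            "n_outside": ba.n_outside,
            "pct_outside": _fmt(100.0 * ba.n_outside / ba.n, 3),
        },
        "threshold": {
            "cutoff": report.threshold.cutoff,
            "kruskal_H": _fmt(report.threshold.kruskal.statistic)
            if report.threshold.kruskal
            else None,
            "kruskal_p": _fmt(report.threshold.kruskal.p_value)
            if report.threshold.kruskal
            else None,
            "odds_ratio": _fmt(report.threshold.odds_intermediate_vs_low.or_estimate)
            if report.threshold.odds_intermediate_vs_low
            else None,
            "warnings": list(report.threshold.warnings),
        },
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    paths["summary"] = summary_path
    return paths
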