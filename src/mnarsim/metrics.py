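"""Replication-level aggregation: relative bias, coverage, prevention.

Relative bias of an estimator of a nonzero true coefficient is

    100 * (true - mean estimate) / true   [%],

so attenuation toward zero is positive.  95% coverage is the
percentage of replications whose Wald 95% CI contains the truth.  The
potential for preventing bias compares a condition in which extreme
outcome scorers are totally missing (relative bias R1) with the same
condition in which they are merely under-represented (R2):

    prevention = 100 * (R1 - R2) / R1   [%].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import FitResult

__all__ = [
    "relative_bias",
    "coverage95",
    "prevention_percentage",
    "PredictorSummary",
    "ScenarioSummary",
    "summarize_fits",
    "format_table",
    "summaries_to_frame",
]


def relative_bias(mean_estimate: float, true_value: float) -> float:
    """Percent attenuation of the estimate relative to the truth."""
    if true_value == 0:
        raise ValueError("relative bias is undefined for a zero true value")
    return 100.0 * (true_value - mean_estimate) / true_value


def coverage95(
    fits: list[FitResult], true_value: float, predictor: int
) -> float:
    """Percent of converged replications whose 95% CI covers the truth."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("coverage requires at least one converged fit")
    hits = sum(
        1 for f in fits
        if f.ci(predictor)[0] <= true_value <= f.ci(predictor)[1]
    )
    return 100.0 * hits / len(fits)


def prevention_percentage(r1: float, r2: float) -> float | None:
    """Share of the extreme-scorers-missing bias R1 removed when extreme
    scorers are present (bias R2).  Undefined (None) when R1 = 0."""
    if r1 == 0:
        return None
    if r2 == 0:
        return 100.0
    if r1 == r2:
        return 0.0
    return 100.0 * (r1 - r2) / r1


@dataclass(frozen=True)
class PredictorSummary:
    mean_estimate: float
    mean_se: float
    relative_bias: float
    coverage95: float


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregated results of one scenario x estimator cell."""

    scenario_id: str
    method: str
    x1: PredictorSummary
    x2: PredictorSummary
    n_replications: int
    n_converged: int


def summarize_fits(
    fits: list[FitResult],
    true1: float,
    true2: float,
    scenario_id: str = "",
    method: str = "",
) -> ScenarioSummary:
    """Aggregate one scenario's replication fits (converged fits only)."""
    if not fits:
        raise ValueError("no fits to summarize")
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to summarize")

    def one(pred: int, truth: float) -> PredictorSummary:
        est = np.array([f.estimate(pred) for f in conv])
        se = np.array([f.se(pred) for f in conv])
        return PredictorSummary(
            mean_estimate=float(est.mean()),
            mean_se=float(se.mean()),
            relative_bias=relative_bias(float(est.mean()), truth),
            coverage95=coverage95(conv, truth, pred),
        )

    return ScenarioSummary(
        scenario_id=scenario_id,
        method=method or (conv[0].method if conv else ""),
        x1=one(1, true1),
        x2=one(2, true2),
        n_replications=len(fits),
        n_converged=len(conv),
    )


def format_table(summaries: list[ScenarioSummary]) -> str:
    """Plain-text table of scenario summaries (2-dp estimates/SEs,
    integer coverage, mirroring the usual reporting convention)."""
    lines = [
        f"{'scenario':<50}{'method':<10}"
        f"{'x1 est(SE) cov':>20}{'x2 est(SE) cov':>20}"
    ]
    for s in summaries:
        c1 = (
            f"{s.x1.mean_estimate:.2f} ({s.x1.mean_se:.2f}) "
            f"{s.x1.coverage95:.0f}"
        )
        c2 = (
            f"{s.x2.mean_estimate:.2f} ({s.x2.mean_se:.2f}) "
            f"{s.x2.coverage95:.0f}"
        )
        lines.append(f"{s.scenario_id:<50}{s.method:<10}{c1:>20}{c2:>20}")
    return "\n".join(lines)


def summaries_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "scenario": s.scenario_id,
            "method": s.method,
            "est_x1": s.x1.mean_estimate,
            "se_x1": s.x1.mean_se,
            "relbias_x1": s.x1.relative_bias,
            "coverage_x1": s.x1.coverage95,
            "est_x2": s.x2.mean_estimate,
            "se_x2": s.x2.mean_se,
            "relbias_x2": s.x2.relative_bias,
            "coverage_x2": s.x2.coverage95,
            "n_replications": s.n_replications,
            "n_converged": s.n_converged,
        })
    return pd.DataFrame(rows)
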