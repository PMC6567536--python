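"""Scenario grid orchestration.

A :class:`Scenario` bundles everything one simulation condition needs:
the population, the non-response model, the observed scale and the
estimator set.  ``run_scenario`` executes the replication loop
(generate -> impose missingness -> ordinalize -> fit) with
deterministic per-replication seeds, so results are byte-identical
across runs and across worker counts.  ``run_paper_grid`` sweeps the
full study grid — six liability-dependency pairs x two response rates
x extreme scorers present/absent — plus optional follow-up conditions
(5-category, 2-category and continuous outcome at 50% response).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import OrdinalSpec, ordinalize
from .estimators import FitResult, MISettings, fit
from .metrics import (
    ScenarioSummary,
    format_table,
    prevention_percentage,
    summaries_to_frame,
    summarize_fits,
)
from .missingness import MissingnessScenario, apply_missingness
from .population import PopulationParams, generate_complete_sample

__all__ = [
    "Scenario",
    "DEPENDENCY_GRID",
    "paper_grid",
    "run_replication",
    "run_scenario",
    "run_paper_grid",
]

# (b_non1, b_non2) pairs of the study grid
DEPENDENCY_GRID: tuple[tuple[float, float], ...] = (
    (0.3, 0.0),
    (0.1, 0.1),
    (0.3, 0.1),
    (0.0, 0.3),
    (0.1, 0.3),
    (0.3, 0.3),
)


@dataclass(frozen=True)
class Scenario:
    """Full specification of one simulation condition."""

    population: PopulationParams = field(default_factory=PopulationParams)
    missingness: MissingnessScenario = field(default_factory=MissingnessScenario)
    ordinal: OrdinalSpec = field(default_factory=OrdinalSpec)
    estimators: tuple[str, ...] = ("CC",)
    n: int = 1000
    n_replications: int = 500
    mi_settings: MISettings = field(default_factory=MISettings)

    @property
    def scenario_id(self) -> str:
        return f"{self.missingness.label()}_{self.ordinal.label()}"

    def seed_key(self) -> int:
        """Stable 32-bit key derived from the scenario configuration
        (not from object identity), for seed derivation."""
        desc = "|".join([
            repr(self.population), repr(self.missingness),
            repr(self.ordinal), str(self.n),
        ])
        return zlib.crc32(desc.encode()) & 0x7FFFFFFF


def _replication_seeds(
    scen: Scenario, base_seed: int, rep: int
) -> list[np.random.SeedSequence]:
    ss = np.random.SeedSequence([base_seed, scen.seed_key(), rep])
    return ss.spawn(3)  # sample, liability, imputation


def run_replication(
    scen: Scenario, base_seed: int, rep: int
) -> dict[str, FitResult]:
    """One replication: simulate, impose missingness, fit each estimator."""
    s_sample, s_liab, s_mi = _replication_seeds(scen, base_seed, rep)
    sample = generate_complete_sample(scen.population, scen.n, s_sample)
    obs = apply_missingness(sample, scen.missingness, s_liab)
    if scen.ordinal.continuous_passthrough:
        analysis_obs = obs
    else:
        y_ord = ordinalize(obs.y_obs, scen.ordinal, sd=scen.population.sd_y)
        analysis_obs = obs.with_outcome(y_ord)
    results: dict[str, FitResult] = {}
    for method in scen.estimators:
        results[method] = fit(
            analysis_obs, method, mi_settings=scen.mi_settings, seed=s_mi
        )
    return results


def run_scenario(
    scen: Scenario,
    base_seed: int = 0,
    n_replications: int | None = None,
    n_jobs: int = 1,
) -> tuple[dict[str, ScenarioSummary], pd.DataFrame]:
    """Run all replications of one scenario.

    Returns per-estimator summaries and a tidy per-replication frame
    (one row per scenario x replication x method x predictor).
    Infeasible scenarios (e.g. a liability model explaining more than
    the total variance) fail before any replication runs.
    """
    scen.missingness.residual_variance(scen.population)  # surface errors early
    reps = n_replications if n_replications is not None else scen.n_replications

    if n_jobs != 1:
        from joblib import Parallel, delayed

        all_fits = Parallel(n_jobs=n_jobs)(
            delayed(run_replication)(scen, base_seed, r) for r in range(reps)
        )
    else:
        all_fits = [run_replication(scen, base_seed, r) for r in range(reps)]

    truth1 = scen.population.b_pred1
    truth2 = scen.population.b_pred2
    summaries: dict[str, ScenarioSummary] = {}
    rows = []
    for method in scen.estimators:
        fits = [d[method] for d in all_fits]
        summaries[method] = summarize_fits(
            fits, truth1, truth2, scenario_id=scen.scenario_id, method=method
        )
        for r, f in enumerate(fits):
            for pred in (1, 2):
                lo, hi = f.ci(pred)
                rows.append({
                    "scenario": scen.scenario_id,
                    "replication": r,
                    "method": method,
                    "predictor": f"x{pred}",
                    "estimate": f.estimate(pred),
                    "se": f.se(pred),
                    "ci_low": lo,
                    "ci_high": hi,
                    "converged": f.converged,
                })
    return summaries, pd.DataFrame(rows)


def paper_grid(
    estimators: tuple[str, ...] = ("CC", "FIML", "MI"),
    n_replications: int = 500,
    m_imputations: int = 50,
    population: PopulationParams | None = None,
    follow_up: bool = False,
) -> list[Scenario]:
    """Build the study's scenario list.

    The main grid crosses the six dependency pairs with response rates
    0.70/0.50 and with extreme scorers present vs totally missing, on
    the 4-category scale.  ``follow_up`` appends the 50%-response
    variants with 5 categories, 2 categories and the continuous
    outcome (linear regression, complete cases).
    """
    pop = population or PopulationParams()
    mi = MISettings(m_imputations=m_imputations)
    scenarios = []
    for b1, b2 in DEPENDENCY_GRID:
        for rr in (0.70, 0.50):
            for removed in (False, True):
                scenarios.append(Scenario(
                    population=pop,
                    missingness=MissingnessScenario(
                        b_non1=b1, b_non2=b2, response_rate=rr,
                        extremes_removed=removed,
                    ),
                    ordinal=OrdinalSpec(n_categories=4),
                    estimators=estimators,
                    n_replications=n_replications,
                    mi_settings=mi,
                ))
    if follow_up:
        for spec, methods in (
            (OrdinalSpec(n_categories=5), ("CC",)),
            (OrdinalSpec(n_categories=2), ("CC",)),
            (OrdinalSpec.continuous(), ("linear_CC",)),
        ):
            for b1, b2 in DEPENDENCY_GRID:
                for removed in (False, True):
                    scenarios.append(Scenario(
                        population=pop,
                        missingness=MissingnessScenario(
                            b_non1=b1, b_non2=b2, response_rate=0.50,
                            extremes_removed=removed,
                        ),
                        ordinal=spec,
                        estimators=methods,
                        n_replications=n_replications,
                        mi_settings=mi,
                    ))
    return scenarios


def _prevention_frame(summary: pd.DataFrame) -> pd.DataFrame:
    """Pair extremes-missing (R1) with extremes-present (R2) cells and
    compute the preventable-bias percentage."""
    rows = []
    missing = summary[summary["scenario"].str.contains("extremes_missing")]
    for _, row in missing.iterrows():
        partner_id = row["scenario"].replace("extremes_missing", "extremes_present")
        partner = summary[
            (summary["scenario"] == partner_id)
            & (summary["method"] == row["method"])
        ]
        if partner.empty:
            continue
        p = partner.iloc[0]
        for pred in ("x1", "x2"):
            r1 = row[f"relbias_{pred}"]
            r2 = p[f"relbias_{pred}"]
            prevented = prevention_percentage(r1, r2) if r1 != 0 else None
            rows.append({
                "scenario": row["scenario"],
                "method": row["method"],
                "predictor": pred,
                "relbias_extremes_missing": r1,
                "relbias_extremes_present": r2,
                "prevention_pct": prevented,
            })
    return pd.DataFrame(rows)


def _bar_chart(df: pd.DataFrame, value: str, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    labels = df["scenario"] + "/" + df.get("predictor", df.get("method", ""))
    ax.bar(range(len(df)), df[value].fillna(0.0))
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel(value)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_paper_grid(
    n_replications: int = 500,
    base_seed: int = 0,
    out_dir: str | Path = "results",
    estimators: tuple[str, ...] = ("CC", "FIML", "MI"),
    m_imputations: int = 50,
    follow_up: bool = False,
    n_jobs: int = 1,
    make_figures: bool = True,
) -> pd.DataFrame:
    """Run the full grid and write tables, tidy fits and figure data.

    Outputs under ``out_dir``: ``fits.csv`` (per replication),
    ``summary.csv`` (per scenario x method), ``table_rr70.txt`` /
    ``table_rr50.txt`` (formatted main-grid tables), ``prevention.csv``
    and, when ``make_figures``, bar charts of relative bias, coverage
    and prevention.  Failures of individual scenarios are recorded in
    ``errors.txt`` and do not stop the sweep.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = paper_grid(
        estimators=estimators,
        n_replications=n_replications,
        m_imputations=m_imputations,
        follow_up=follow_up,
    )
    all_summaries: list[ScenarioSummary] = []
    tidy_frames: list[pd.DataFrame] = []
    errors: list[str] = []
    for scen in scenarios:
        try:
            summaries, tidy = run_scenario(scen, base_seed, n_jobs=n_jobs)
        except Exception as exc:  # keep sweeping on per-scenario failure
            errors.append(f"{scen.scenario_id}: {exc}")
            continue
        all_summaries.extend(summaries.values())
        tidy_frames.append(tidy)

    summary = summaries_to_frame(all_summaries)
    summary.to_csv(out / "summary.csv", index=False)
    pd.concat(tidy_frames, ignore_index=True).to_csv(
        out / "fits.csv", index=False
    )
    for rr, name in ((0.7, "table_rr70.txt"), (0.5, "table_rr50.txt")):
        rows = [
            s for s in all_summaries
            if f"rr={rr:g}" in s.scenario_id and "cat" in s.scenario_id
            and s.scenario_id.endswith("4cat")
        ]
        (out / name).write_text(format_table(rows) + "\n")
    prevention = _prevention_frame(summary)
    prevention.to_csv(out / "prevention.csv", index=False)
    if errors:
        (out / "errors.txt").write_text("\n".join(errors) + "\n")
    if make_figures:
        long = summary.melt(
            id_vars=["scenario", "method"],
            value_vars=["relbias_x1", "relbias_x2"],
            var_name="predictor", value_name="relbias",
        )
        long["predictor"] = long["predictor"].str.replace("relbias_", "")
        _bar_chart(long, "relbias", "Relative bias (%)", out / "relative_bias.png")
        longc = summary.melt(
            id_vars=["scenario", "method"],
            value_vars=["coverage_x1", "coverage_x2"],
            var_name="predictor", value_name="coverage",
        )
        longc["predictor"] = longc["predictor"].str.replace("coverage_", "")
        _bar_chart(longc, "coverage", "95% coverage (%)", out / "coverage.png")
        if not prevention.empty:
            _bar_chart(
                prevention, "prevention_pct",
                "Potential for preventing bias (%)", out / "prevention.png",
            )
    return summary
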