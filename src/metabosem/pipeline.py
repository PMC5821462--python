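"""End-to-end orchestration and the a-priori power simulation.

``run_pipeline`` sequences the full analysis on a synthetic cohort:
generate → group contrasts → exploratory factor analysis → PLS-DA (with
permutation test) → the three structural equation models (fit, standardize,
RMSEA, modification indices) → Monte-Carlo power simulation, writing every
artifact (CSV/TSV/JSON) plus a provenance report into an output directory.

The power simulation draws skewed data from a Beta(1, 7) distribution scaled
to a (min, max) range, shifts one group by a percentage of the control mean,
and counts two-sample t-test rejections.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import factors, group_stats, models, sem
from .cohort import Cohort, CohortConfig, generate_cohort

__all__ = [
    "PowerSimConfig",
    "simulate_power",
    "sem_analysis_matrix",
    "RunReport",
    "run_pipeline",
]

log = logging.getLogger("metabosem")


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

@dataclass
class PowerSimConfig:
    """A-priori Monte-Carlo power study on skewed (Beta(1,7)-shaped) data."""

    alpha_shape: float = 1.0
    beta_shape: float = 7.0
    value_range: tuple[float, float] = (0.0, 1.0)   # mean ± 3 SD from prior data
    effect_size_pct: float = 20.0                   # shift of the control mean
    n_per_group: tuple[int, ...] = (20, 50, 100, 137)
    reps: int = 500
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.alpha_shape <= 0 or self.beta_shape <= 0:
            raise ValueError("beta-distribution shapes must be positive")
        if not self.value_range[0] < self.value_range[1]:
            raise ValueError("value_range must satisfy min < max")
        if self.reps < 100:
            raise ValueError("reps must be >= 100")


def simulate_power(config: PowerSimConfig) -> pd.DataFrame:
    """Rejection rate of a two-sided two-sample t test per group size.

    Control draws are Beta(a, b) scaled to ``value_range``; the treated group
    is shifted by ``effect_size_pct`` % of the control population mean.
    Returns one row per n with power and its Monte-Carlo standard error.
    """
    config.validate()
    lo, hi = config.value_range
    span = hi - lo
    mean_ctrl = lo + span * config.alpha_shape / (config.alpha_shape + config.beta_shape)
    shift = config.effect_size_pct / 100.0 * mean_ctrl
    rng = np.random.default_rng(config.seed % (2**31))
    rows = []
    for n in config.n_per_group:
        rej = 0
        for _ in range(config.reps):
            a = lo + span * rng.beta(config.alpha_shape, config.beta_shape, size=n)
            b = lo + span * rng.beta(config.alpha_shape, config.beta_shape, size=n) + shift
            _, p = stats.ttest_ind(a, b)
            rej += p < config.alpha
        power = rej / config.reps
        rows.append({
            "n_per_group": n,
            "power": power,
            "mc_se": float(np.sqrt(power * (1 - power) / config.reps)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SEM data preparation
# ---------------------------------------------------------------------------

def sem_analysis_matrix(cohort, config: CohortConfig, columns: list[str]) -> pd.DataFrame:
    """Observed-variable matrix for SEM fitting: log10 for variables generated
    on the log scale, then z-scoring of every column (binary indicators are
    centred/scaled like any numeric 0/1 column).  Standardized estimates are
    invariant to this rescaling under the fix-first-loading convention."""
    df = cohort.data if hasattr(cohort, "data") else cohort
    out = {}
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        vs = config.variables.get(col)
        if vs is not None and any(gd.dist == "log" for gd in vs["groups"].values()):
            x = np.log10(x)
        elif col == "Matsuda":
            x = np.log10(x)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"column {col!r} is constant; cannot enter the SEM")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Artifacts and provenance of one full pipeline run."""

    seed: int
    config_digest: str
    comparison_table: pd.DataFrame | None = None
    factor_solutions: dict = field(default_factory=dict)
    plsda_metrics: dict | None = None
    sem_fits: dict = field(default_factory=dict)
    power_result: pd.DataFrame | None = None
    stages: dict = field(default_factory=dict)   # stage -> "ok" | "failed: ..." | "skipped"

    @property
    def provenance(self) -> str:
        return hashlib.sha256(f"{self.config_digest}:{self.seed}".encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "provenance": self.provenance,
            "stages": self.stages,
            "plsda": self.plsda_metrics,
            "sem": {k: v.to_dict() for k, v in self.sem_fits.items()},
            "power": None if self.power_result is None else self.power_result.to_dict("records"),
        }


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir=None,
    *,
    n_permutations: int = 1000,
    power_config: PowerSimConfig | None = None,
    with_modification_indices: bool = True,
) -> RunReport:
    """Execute the full analysis on a synthetic cohort and (optionally) write
    all artifacts under ``out_dir``.  A stage failure is logged and recorded;
    downstream stages that depend on it are marked skipped."""
    config = config or CohortConfig.default()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed, config_digest=config.digest)

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
                report.stages[name] = "ok"
                log.info("stage %s ok (%.1fs)", name, time.time() - t0)
            except Exception as exc:  # noqa: BLE001 - stage isolation is the point
                report.stages[name] = f"failed: {exc}"
                log.error("stage %s failed: %s", name, exc)
        return wrap

    cohort_holder: dict = {}

    @stage("generate")
    def _generate():
        cohort = generate_cohort(config, seed)
        cohort_holder["cohort"] = cohort
        if out is not None:
            cohort.to_csv(out / "cohort.csv")

    cohort = cohort_holder.get("cohort")
    if cohort is None:
        for name in ("contrast", "factors", "plsda", "sem", "power"):
            report.stages[name] = "skipped"
        return report

    @stage("contrast")
    def _contrast():
        plan = group_stats.default_variable_plan(config)
        table = group_stats.build_comparison_table(cohort, plan)
        report.comparison_table = table
        if out is not None:
            table.to_csv(out / "comparison_table.tsv", sep="\t", index=False)

    @stage("factors")
    def _factors():
        for panel, n_factors in (("AA", 2), ("AC", 4)):
            names = [v for b, mem in config.factor_blocks.items() if b.startswith(panel)
                     for v in mem]
            X = sem_analysis_matrix(cohort, config, names)
            sol = factors.fit_efa(X, n_factors=n_factors)
            report.factor_solutions[panel] = sol
            if out is not None:
                sol.to_json(out / f"factors_{panel.lower()}.json")

    @stage("plsda")
    def _plsda():
        from . import plsda as plsda_mod

        met_cols = config.metabolites + ["CRP", "IL6", "TNFa"]
        X = sem_analysis_matrix(cohort, config, met_cols)
        y = cohort.data["group"].to_numpy()
        res = plsda_mod.fit_plsda(X.to_numpy(), y, n_components=3, cv_folds=8, seed=seed)
        res.permutation_p = plsda_mod.permutation_test(
            X.to_numpy(), y, n_components=3, n_perm=n_permutations, cv_folds=8, seed=seed
        )
        report.plsda_metrics = {
            "explained_x_variance": res.explained_x_variance.tolist(),
            **res.metrics(),
            "variables": met_cols,
        }
        if out is not None:
            pd.DataFrame(res.x_scores, columns=[f"comp{i+1}" for i in range(3)]).assign(
                group=y
            ).to_csv(out / "plsda_scores.tsv", sep="\t", index=False)
            (out / "plsda_metrics.json").write_text(json.dumps(report.plsda_metrics, indent=2))

    @stage("sem")
    def _sem():
        for name, spec_fn in (
            ("model1", models.model1_spec),
            ("model2", models.model2_spec),
            ("model3", models.model3_spec),
        ):
            spec = spec_fn()
            data = sem_analysis_matrix(cohort, config, list(spec.observed_vars))
            fit = sem.fit_ml(spec, data)
            report.sem_fits[name] = fit
            payload = fit.to_dict()
            if with_modification_indices and fit.converged and fit.df >= 1:
                mi = sem.modification_indices(fit)
                payload["modification_indices"] = dict(list(mi.items())[:20])
            if out is not None:
                (out / f"sem_{name}.json").write_text(
                    json.dumps(payload, indent=2, default=float)
                )

    @stage("power")
    def _power():
        cfg = power_config or PowerSimConfig(seed=seed)
        result = simulate_power(cfg)
        report.power_result = result
        if out is not None:
            result.to_csv(out / "power.tsv", sep="\t", index=False)

    if out is not None:
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=float))
    return report
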