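"""Catalog of the study's three structural equation models.

Model 1 ("obesity first"): a latent Obesity construct (BMI, abdominal
circumference, % fat) drives two amino-acid factors, which drive four
acylcarnitine factors; metabolite factors predict inflammation (TNFα/IL-6),
fatty liver (ultrasound + transaminases), the Matsuda index and CRP.

Model 2 ("family history first"): an exogenous family-history-of-obesity
latent (maternal, paternal, second-degree flags) determines the metabolite
factors and obesity; obesity becomes a downstream consequence.

Model 3: family history predicts obesity, which drives the model-1 cascade,
with no direct family-history → metabolite paths.

The exact arrow inventory beyond the in-text enumerations is a conservative
reconstruction from the published figure legends; CRP is kept as a standalone
observed outcome of Obesity and NAFLD rather than an INFL indicator.

``recovery_submodel`` exposes small fully-parameterised sub-models (loadings
0.8 in the standardized metric, unit exogenous latent variance) whose single
structural path carries a published standardized estimate, for
simulate → fit → standardize parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import sem
from .cohort import simulate_from_sem

__all__ = [
    "StudyModelCatalog",
    "model1_spec",
    "model2_spec",
    "model3_spec",
    "model_text",
    "recovery_submodel",
    "run_recovery",
    "REFERENCE_STD_BETAS",
]

# standardized path estimates quoted in the study's text, keyed (model, path)
REFERENCE_STD_BETAS: dict[tuple[str, str], float] = {
    ("model1", "AA1~Obesity"): 0.37,
    ("model1", "AA2~Obesity"): 0.44,
    ("model1", "AC1~AA2"): 0.65,
    ("model1", "AC2~AA2"): -0.43,
    ("model1", "AC4~AA2"): 0.28,
    ("model1", "INFL~AC1"): 0.23,
    ("model1", "INFL~AC3"): 0.48,
    ("model1", "INFL~AC4"): -0.45,
    ("model1", "INFL~AA1"): -0.67,
    ("model1", "INFL~AA2"): 0.49,
    ("model1", "NAFLD~AC2"): -1.52,
    ("model1", "NAFLD~AC3"): 3.48,
    ("model1", "NAFLD~AC4"): -2.42,
    ("model1", "Matsuda~AC3"): 1.39,
    ("model1", "Matsuda~AC4"): 0.72,
    ("model1", "Matsuda~AA2"): -0.41,
    ("model2", "Obesity~FHOB"): 0.32,
    ("model3", "Obesity~FHOB"): 0.32,
}


def model_text(name: str) -> str:
    """Plain-text model file for ``model1`` / ``model2`` / ``model3``."""
    if name not in ("model1", "model2", "model3"):
        raise ValueError(f"unknown model {name!r}")
    return resources.files("metabosem.data.models").joinpath(f"{name}.txt").read_text()


def model1_spec() -> sem.SemModelSpec:
    return sem.parse_model(model_text("model1"))


def model2_spec() -> sem.SemModelSpec:
    return sem.parse_model(model_text("model2"))


def model3_spec() -> sem.SemModelSpec:
    return sem.parse_model(model_text("model3"))


@dataclass(frozen=True)
class StudyModelCatalog:
    model1: sem.SemModelSpec
    model2: sem.SemModelSpec
    model3: sem.SemModelSpec
    reference_std_betas: dict[tuple[str, str], float]

    @classmethod
    def load(cls) -> "StudyModelCatalog":
        return cls(
            model1=model1_spec(),
            model2=model2_spec(),
            model3=model3_spec(),
            reference_std_betas=dict(REFERENCE_STD_BETAS),
        )


# ---------------------------------------------------------------------------
# Parameter-recovery sub-models
# ---------------------------------------------------------------------------

_RECOVERY = {
    # two latents, six indicators, one structural path each
    "fhob_obesity": {
        "text": (
            "FHOB =~ MomFHOB + DadFHOB + IndFHOB\n"
            "Obesity =~ BMI + Abd_circumf + FAT\n"
            "Obesity ~ FHOB\n"
        ),
        "path": "Obesity~FHOB",
        "beta": REFERENCE_STD_BETAS[("model2", "Obesity~FHOB")],
    },
    "obesity_aa": {
        "text": (
            "Obesity =~ BMI + Abd_circumf + FAT\n"
            "AA1 =~ Arginine + Glycine + Leucine + Phenylalanine + Valine\n"
            "AA1 ~ Obesity\n"
        ),
        "path": "AA1~Obesity",
        "beta": REFERENCE_STD_BETAS[("model1", "AA1~Obesity")],
    },
}

_LOADING = 0.8  # standardized loading used for all recovery indicators


def recovery_submodel(name: str):
    """Return ``(fit_spec, gen_spec, params, path_label, beta)``.

    ``gen_spec`` has every parameter free (identification "none") and
    ``params`` values it in the standardized metric: loadings 0.8, unit
    exogenous latent variance, unit total variance everywhere, so the
    structural path equals its standardized value ``beta`` by construction.
    ``fit_spec`` is the same model under the fix-first-loading convention,
    ready for :func:`metabosem.sem.fit_ml`.
    """
    if name not in _RECOVERY:
        raise ValueError(f"unknown recovery sub-model {name!r}; have {sorted(_RECOVERY)}")
    entry = _RECOVERY[name]
    gen_spec = sem.parse_model(entry["text"], identification="none")
    fit_spec = sem.parse_model(entry["text"], identification="fix_first_loading")
    beta = entry["beta"]
    params: dict[str, float] = {}
    exogenous = {s for _, s, _ in gen_spec.paths} - {t for t, _, _ in gen_spec.paths}
    for lat, ind, _ in gen_spec.loadings:
        params[f"{lat}=~{ind}"] = _LOADING
        params[f"{ind}~~{ind}"] = 1.0 - _LOADING**2
    for lat in gen_spec.latent_vars:
        params[f"{lat}~~{lat}"] = 1.0 if lat in exogenous else 1.0 - beta**2
    params[entry["path"]] = beta
    return fit_spec, gen_spec, params, entry["path"], beta


def run_recovery(
    name: str,
    n: int = 137,
    n_reps: int = 200,
    seed: int = 0,
) -> dict:
    """Simulate → fit → standardize ``n_reps`` times; report the mean
    recovered standardized structural path against its generating value."""
    fit_spec, gen_spec, params, path, beta = recovery_submodel(name)
    recovered = []
    failures = 0
    for r in range(n_reps):
        data = simulate_from_sem(gen_spec, params, n, seed=(seed + 7919 * r) % (2**31))
        try:
            fit = sem.fit_ml(fit_spec, data)
            if not fit.converged:
                failures += 1
                continue
            recovered.append(fit.standardized[path])
        except sem.SemError:
            failures += 1
    recovered = np.asarray(recovered)
    return {
        "name": name,
        "path": path,
        "generating_beta": beta,
        "mean_recovered": float(recovered.mean()) if recovered.size else float("nan"),
        "sd_recovered": float(recovered.std(ddof=1)) if recovered.size > 1 else float("nan"),
        "n_reps": n_reps,
        "n_ok": int(recovered.size),
        "failures": failures,
        "n": n,
    }
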