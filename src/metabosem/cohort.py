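"""Synthetic three-group cohort generator.

Emulates a cross-sectional study of normoglycemic adults split into a lean
group (G1, BMI < 25), an obese group without fatty liver (G2, BMI > 30) and an
obese group with ultrasound-diagnosed NAFLD (G3, BMI > 30).  Per-group means
with 95% confidence intervals drive marginal distributions (log-normal where
the printed interval is asymmetric, i.e. was back-transformed from log10),
family-history flags are assigned by exact per-group counts so that the
descriptive margins reproduce exactly, and the 31-analyte metabolite panel is
drawn from a block-structured correlation matrix whose blocks are the factor
groups (AA1, AA2, AC1-AC4) used downstream by the factor analysis and the
structural equation models.

A second mode, :func:`simulate_from_sem`, draws multivariate-normal data
exactly from the implied covariance of a specified SEM, for
parameter-recovery testing.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import sem

__all__ = [
    "GROUPS",
    "OGTT_MINUTES",
    "CohortConfigError",
    "CohortConfig",
    "Cohort",
    "ci_to_sd",
    "generate_cohort",
    "simulate_from_sem",
]

GROUPS = ("G1", "G2", "G3")
OGTT_MINUTES = (0, 30, 60, 90, 120)

# relative CI asymmetry above which a printed interval is treated as
# back-transformed from log10
_ASYMMETRY_TOL = 0.10
# lower clip for arithmetic-scale positive variables, as fraction of the mean
_POSITIVE_FLOOR = 0.01

_BOOL_COLUMNS = ("MomFHOB", "DadFHOB", "IndFHOB", "FHDiab", "USG", "NAFLD")


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


def ci_to_sd(mean: float, ci_low: float, ci_high: float, n: float, log_scale: bool = False) -> float:
    """Recover a standard deviation from a mean and its 95% CI.

    ``sd = sqrt(n) * (ci_high - ci_low) / (2 * 1.96)``.  With ``log_scale``
    the endpoints are first taken to log10, so the result is the SD of the
    log10-transformed variable.
    """
    if ci_low > ci_high:
        raise CohortConfigError(f"ci_low {ci_low} exceeds ci_high {ci_high}")
    if n < 2:
        raise CohortConfigError("need n >= 2 to recover an SD from a CI")
    if log_scale:
        if ci_low <= 0:
            raise CohortConfigError("log-scale CI endpoints must be positive")
        if ci_low == ci_high:
            return 0.0
        ci_low, ci_high = np.log10(ci_low), np.log10(ci_high)
    return float(np.sqrt(n) * (ci_high - ci_low) / (2.0 * 1.96))


def _decide_scale(mean: float, lo: float, hi: float) -> str:
    """Log scale when the printed CI is asymmetric about the mean."""
    if not lo < mean < hi:
        return "arith"  # CI does not bracket the mean; recentred, hence symmetric
    width = hi - lo
    if width <= 0:
        return "arith"
    asym = abs((hi - mean) - (mean - lo))
    return "log" if asym > _ASYMMETRY_TOL * width else "arith"


@dataclass(frozen=True)
class _GroupDist:
    """Marginal distribution of one variable in one group."""

    dist: str   # "log" (log10-normal) or "arith" (normal)
    loc: float  # log10 median, or mean
    scale: float  # sd on the generation scale


@dataclass
class CohortConfig:
    """Generator configuration; ``CohortConfig.default()`` loads the packaged
    calibration encoding the study's printed descriptive tables."""

    group_sizes: dict[str, int]
    variables: dict[str, dict]           # name -> {category, series, groups: {g: _GroupDist}}
    factor_blocks: dict[str, list[str]]
    rho_within: float
    rho_between: float
    series_correlation: float
    sex_female_pct: dict[str, float]
    family_history: dict
    raw: dict = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------------
    @classmethod
    def default(cls) -> "CohortConfig":
        text = resources.files("metabosem.data").joinpath("default_config.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        group_sizes = {g: int(v) for g, v in d["group_sizes"].items()}
        for g, n_g in group_sizes.items():
            if n_g <= 0:
                raise CohortConfigError(f"group size for {g} must be positive, got {n_g}")
        variables: dict[str, dict] = {}
        for name, vspec in d["variables"].items():
            explicit_scale = vspec.get("scale")
            if explicit_scale is None:
                # a variable is treated as log10-analysed if ANY group's
                # printed CI is asymmetric about its mean
                decisions = [
                    _decide_scale(float(gd["mean"]), float(gd["ci"][0]), float(gd["ci"][1]))
                    for gd in vspec["groups"].values()
                    if "ci" in gd
                ]
                scale = "log" if "log" in decisions else "arith"
            else:
                scale = explicit_scale
            groups: dict[str, _GroupDist] = {}
            for g, gd in vspec["groups"].items():
                mean = float(gd["mean"])
                n_g = group_sizes[g]
                if "sd" in gd:
                    sd = float(gd["sd"])
                    groups[g] = _GroupDist("arith", mean, sd)
                    continue
                if "ci" in gd:
                    lo, hi = (float(x) for x in gd["ci"])
                    if not lo < mean < hi:  # printed typo: recentre width on the mean
                        w = hi - lo
                        lo, hi = mean - w / 2.0, mean + w / 2.0
                    if scale == "log":
                        groups[g] = _GroupDist("log", float(np.log10(mean)),
                                               ci_to_sd(mean, lo, hi, n_g, log_scale=True))
                    else:
                        groups[g] = _GroupDist("arith", mean, ci_to_sd(mean, lo, hi, n_g))
                elif "sd_log10" in vspec or "sd_log10" in gd:
                    sdl = float(gd.get("sd_log10", vspec.get("sd_log10")))
                    groups[g] = _GroupDist("log", float(np.log10(mean)), sdl)
                else:
                    raise CohortConfigError(f"variable {name}/{g}: need ci, sd or sd_log10")
            variables[name] = {
                "category": vspec.get("category", "other"),
                "series": vspec.get("series"),
                "groups": groups,
            }
        met = d.get("metabolite_correlation", {})
        cfg = cls(
            group_sizes=group_sizes,
            variables=variables,
            factor_blocks={k: list(v) for k, v in d["factor_blocks"].items()},
            rho_within=float(met.get("rho_within", 0.6)),
            rho_between=float(met.get("rho_between", 0.1)),
            series_correlation=float(d.get("series_correlation", 0.6)),
            sex_female_pct={g: float(v) for g, v in d["sex_female_pct"].items()},
            family_history=d["family_history"],
            raw=copy.deepcopy(d),
        )
        cfg.validate()
        return cfg

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for g, n_g in self.group_sizes.items():
            if n_g <= 0:
                raise CohortConfigError(f"group size for {g} must be positive, got {n_g}")
        if not 0 <= self.rho_between <= self.rho_within < 1:
            raise CohortConfigError(
                f"need 0 <= rho_between <= rho_within < 1, got "
                f"rho_within={self.rho_within}, rho_between={self.rho_between}"
            )
        members = [v for block in self.factor_blocks.values() for v in block]
        if len(set(members)) != len(members):
            raise CohortConfigError("a metabolite appears in more than one factor block")
        for m in members:
            if m not in self.variables:
                raise CohortConfigError(f"factor-block member {m!r} has no variable entry")
        self._metabolite_correlation()  # raises if non-PD
        fh = self.family_history
        for key in ("mother", "father", "indirect", "direct", "any"):
            for g, cnt in fh[key].items():
                if cnt < 0 or cnt > self.group_sizes[g]:
                    raise CohortConfigError(
                        f"family-history count {key}/{g} = {cnt} exceeds group size"
                    )
        for g in self.group_sizes:
            m, f = fh["mother"][g], fh["father"][g]
            d, i, a = fh["direct"][g], fh["indirect"][g], fh["any"][g]
            ov_mf = m + f - d
            if not 0 <= ov_mf <= min(m, f):
                raise CohortConfigError(f"infeasible mother/father/direct counts in {g}")
            ov_di = d + i - a
            if not 0 <= ov_di <= min(d, i):
                raise CohortConfigError(f"infeasible direct/indirect/any counts in {g}")

    def scaled(self, factor: float) -> "CohortConfig":
        """Same calibration with all group sizes (and family-history counts)
        multiplied by ``factor`` — for large-n moment and recovery checks.
        Rounded counts are nudged to keep the direct/any overlaps feasible."""
        raw = copy.deepcopy(self.raw)
        raw["group_sizes"] = {g: max(2, round(v * factor)) for g, v in raw["group_sizes"].items()}
        # freeze marginal SDs at the values implied by the ORIGINAL group
        # sizes: a larger cohort means more subjects, not wider distributions
        for name, vspec in raw["variables"].items():
            dists = self.variables[name]["groups"]
            for g, gd in vspec["groups"].items():
                dist = dists[g]
                gd.pop("ci", None)
                gd.pop("sd", None)
                gd.pop("sd_log10", None)
                if dist.dist == "log":
                    gd["mean"] = float(10.0 ** dist.loc)
                    gd["sd_log10"] = dist.scale
                    vspec["scale"] = "log"
                else:
                    gd["mean"] = dist.loc
                    gd["sd"] = dist.scale
            vspec.pop("sd_log10", None)
        fh = raw["family_history"]
        for g, n_g in raw["group_sizes"].items():
            m = min(round(fh["mother"][g] * factor), n_g)
            f = min(round(fh["father"][g] * factor), n_g)
            i = min(round(fh["indirect"][g] * factor), n_g)
            d = int(np.clip(round(fh["direct"][g] * factor), max(m, f), min(m + f, n_g)))
            a = int(np.clip(round(fh["any"][g] * factor), max(d, i), min(d + i, n_g)))
            fh["mother"][g], fh["father"][g], fh["indirect"][g] = m, f, i
            fh["direct"][g], fh["any"][g] = d, a
        return CohortConfig.from_dict(raw)

    # -- derived structure --------------------------------------------------
    @property
    def metabolites(self) -> list[str]:
        return [v for block in self.factor_blocks.values() for v in block]

    def _metabolite_correlation(self) -> np.ndarray:
        names = self.metabolites
        p = len(names)
        R = np.full((p, p), self.rho_between)
        start = 0
        spans = {}
        for bname, block in self.factor_blocks.items():
            k = len(block)
            R[start:start + k, start:start + k] = self.rho_within
            spans[bname] = (start, start + k)
            start += k
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R)[0] <= 1e-10:
            blocks = list(spans.items())
            for a in range(len(blocks)):
                for b in range(a + 1, len(blocks)):
                    (na, (sa, ea)), (nb, (sb, eb)) = blocks[a], blocks[b]
                    idx = np.r_[sa:ea, sb:eb]
                    sub = R[np.ix_(idx, idx)]
                    if np.linalg.eigvalsh(sub)[0] <= 1e-10:
                        raise CohortConfigError(
                            f"metabolite correlation not positive definite for blocks "
                            f"{na} / {nb}"
                        )
            raise CohortConfigError("metabolite correlation matrix not positive definite")
        return R

    @property
    def digest(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    """Generated cohort: one row per subject, plus a config/seed fingerprint."""

    data: pd.DataFrame
    config_digest: str
    seed: int

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        df = pd.read_csv(path)
        for col in _BOOL_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(int)
        return df


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    """Stable per-stream generator: adding a variable never perturbs the
    draws of any other variable."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(stream.encode())])


def _equicorr_normal(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    return rng.standard_normal((n, k)) @ L.T


def _transform(z: np.ndarray, dist: _GroupDist, positive: bool) -> np.ndarray:
    if dist.dist == "log":
        return 10.0 ** (dist.loc + dist.scale * z)
    x = dist.loc + dist.scale * z
    if positive:
        x = np.maximum(x, _POSITIVE_FLOOR * abs(dist.loc))
    return x


def _exact_subset(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    return rng.choice(pool, size=k, replace=False) if k > 0 else np.array([], dtype=pool.dtype)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate a cohort whose per-group sizes, family-history counts and
    per-variable moments follow ``config`` (counts exactly; moments in
    distribution).  Identical ``(config, seed)`` yields identical cohorts."""
    config.validate()
    sizes = [config.group_sizes[g] for g in GROUPS]
    n = sum(sizes)
    group_col = np.repeat(GROUPS, sizes)
    group_slices = {}
    start = 0
    for g, sz in zip(GROUPS, sizes):
        group_slices[g] = np.arange(start, start + sz)
        start += sz

    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "group": group_col,
    })

    # sex: exact per-group female counts
    sex = np.empty(n, dtype=object)
    rng_sex = _rng_for(seed, "Sex")
    for g in GROUPS:
        idx = group_slices[g]
        n_f = int(round(config.sex_female_pct[g] / 100.0 * len(idx)))
        females = _exact_subset(rng_sex, idx, n_f)
        sex[idx] = "M"
        sex[females] = "F"
    df["Sex"] = sex

    metab = set(config.metabolites)
    series_vars: dict[str, list[str]] = {}
    for name, vs in config.variables.items():
        if vs["series"]:
            series_vars.setdefault(vs["series"], []).append(name)

    # independent scalar variables, one seeded stream each
    for name, vs in config.variables.items():
        if name in metab or vs["series"]:
            continue
        z = _rng_for(seed, f"var:{name}").standard_normal(n)
        x = np.empty(n)
        for g in GROUPS:
            idx = group_slices[g]
            x[idx] = _transform(z[idx], vs["groups"][g], positive=True)
        df[name] = x

    # OGTT series: equicorrelated across the 5 time points
    for series_name, names in series_vars.items():
        names = sorted(names, key=lambda s: int(s.rsplit("_", 1)[1]))
        z = _equicorr_normal(_rng_for(seed, f"series:{series_name}"), n, len(names),
                             config.series_correlation)
        for k_t, name in enumerate(names):
            vs = config.variables[name]
            x = np.empty(n)
            for g in GROUPS:
                idx = group_slices[g]
                x[idx] = _transform(z[idx, k_t], vs["groups"][g], positive=True)
            df[name] = x

    # metabolite panel: joint block-correlated draw
    met_names = config.metabolites
    R = config._metabolite_correlation()
    L = np.linalg.cholesky(R)
    z = _rng_for(seed, "metabolites").standard_normal((n, len(met_names))) @ L.T
    for k_m, name in enumerate(met_names):
        vs = config.variables[name]
        x = np.empty(n)
        for g in GROUPS:
            idx = group_slices[g]
            x[idx] = _transform(z[idx, k_m], vs["groups"][g], positive=True)
        df[name] = x

    # Matsuda insulin sensitivity index from the generated OGTT series
    from .group_stats import matsuda_index

    glu = df[[f"Glucose_{t}" for t in OGTT_MINUTES]].to_numpy()
    ins = df[[f"Insulin_{t}" for t in OGTT_MINUTES]].to_numpy()
    df["Matsuda"] = matsuda_index(glu, ins)

    # family history: exact per-group counts with exact direct/any overlaps
    fh = config.family_history
    mom = np.zeros(n, dtype=int)
    dad = np.zeros(n, dtype=int)
    ind = np.zeros(n, dtype=int)
    rng_fh = _rng_for(seed, "family_history")
    for g in GROUPS:
        idx = group_slices[g]
        m_n, f_n = fh["mother"][g], fh["father"][g]
        d_n, i_n, a_n = fh["direct"][g], fh["indirect"][g], fh["any"][g]
        mom_set = _exact_subset(rng_fh, idx, m_n)
        ov_mf = m_n + f_n - d_n
        dad_set = np.concatenate([
            _exact_subset(rng_fh, mom_set, ov_mf),
            _exact_subset(rng_fh, np.setdiff1d(idx, mom_set), f_n - ov_mf),
        ])
        direct_set = np.union1d(mom_set, dad_set)
        ov_di = d_n + i_n - a_n
        ind_set = np.concatenate([
            _exact_subset(rng_fh, direct_set, ov_di),
            _exact_subset(rng_fh, np.setdiff1d(idx, direct_set), i_n - ov_di),
        ])
        mom[mom_set.astype(int)] = 1
        dad[dad_set.astype(int)] = 1
        ind[ind_set.astype(int)] = 1
    df["MomFHOB"] = mom
    df["DadFHOB"] = dad
    df["IndFHOB"] = ind

    # family history of diabetes: overall fraction, apportioned across groups
    total_diab = int(round(fh["diabetes_fraction"] * n))
    per_group = _largest_remainder(total_diab, np.array(sizes, dtype=float))
    diab = np.zeros(n, dtype=int)
    rng_diab = _rng_for(seed, "fh_diabetes")
    for g, k in zip(GROUPS, per_group):
        diab[_exact_subset(rng_diab, group_slices[g], int(k)).astype(int)] = 1
    df["FHDiab"] = diab

    # NAFLD status and its ultrasound indicator
    df["NAFLD"] = (df["group"] == "G3").astype(int)
    df["USG"] = df["NAFLD"]

    return Cohort(data=df, config_digest=f"{config.digest}:{seed}", seed=int(seed))


def simulate_from_sem(
    spec: sem.SemModelSpec,
    params: dict[str, float],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` iid multivariate-normal rows with covariance equal to the
    model-implied covariance of ``spec`` at ``params`` (columns follow
    ``spec.observed_vars``)."""
    sigma = sem.implied_covariance(spec, params)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise sem.SemError(
            "implied covariance is not positive definite for the supplied parameters"
        ) from exc
    rng = np.random.default_rng([int(seed) % (2**31), zlib.crc32(b"simulate_from_sem")])
    return rng.standard_normal((n, sigma.shape[0])) @ L.T
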