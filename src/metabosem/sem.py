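"""Covariance-structure SEM with latent variables.

A model is a directed graph over observed and latent variables expressed in a
small plain-text syntax::

    Obesity =~ BMI + Abd_circumf + FAT     # measurement (latent =~ indicators)
    AA1 ~ Obesity                          # structural regression
    BMI ~~ FAT                             # (residual) covariance
    F =~ 1*x1 + x2                         # fixed loading

Internally the model is held in RAM form: an asymmetric path matrix ``A``
(loadings and regressions), a symmetric matrix ``S`` of variances and
covariances, and a selector ``F`` picking out the observed rows.  The implied
covariance of the observed variables is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and maximum-likelihood estimation minimises the discrepancy

    F_ML = ln|Sigma| - ln|S_obs| + tr(S_obs Sigma^-1) - p

by quasi-Newton iteration with an analytic gradient.  Standard errors come
from the inverse expected information, the chi-square statistic is
``(n-1) * F_ML``, and RMSEA confidence limits are obtained by inverting the
noncentral chi-square distribution.  Modification indices are univariate
score tests for parameters fixed at zero.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SemError",
    "SemModelSpec",
    "SemFit",
    "parse_model",
    "render_model",
    "free_parameters",
    "implied_covariance",
    "fml",
    "fit_ml",
    "standardize",
    "rmsea",
    "modification_indices",
]

RELEVANCE_THRESHOLD = 0.2  # |std beta| above this is flagged as relevant

_NAME = r"[A-Za-z][A-Za-z0-9_:%.]*"
_NAME_RE = re.compile(_NAME)
_TERM_RE = re.compile(rf"^(?:(?P<fix>[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\*)?(?P<name>{_NAME})$")


class SemError(ValueError):
    """Raised for model-specification or estimation failures."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SemModelSpec:
    """Declarative latent-variable model.

    ``loadings`` are (latent, indicator, fixed) triples, ``paths`` are
    (target, source, fixed) triples and ``covariances`` are (a, b, fixed)
    pairs; ``fixed`` is None for a free parameter.  ``identification`` is one
    of ``fix_first_loading`` (first indicator loading of each latent fixed at
    1), ``fix_latent_variance`` ((residual) variance of each latent fixed at
    1) or ``none`` (caller supplies every value, used for data generation).
    """

    observed_vars: tuple[str, ...]
    latent_vars: tuple[str, ...]
    loadings: tuple[tuple[str, str, float | None], ...] = ()
    paths: tuple[tuple[str, str, float | None], ...] = ()
    covariances: tuple[tuple[str, str, float | None], ...] = ()
    identification: str = "fix_first_loading"

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.observed_vars + self.latent_vars

    def with_identification(self, identification: str) -> "SemModelSpec":
        return replace(self, identification=identification)

    def validate(self) -> None:
        if not self.observed_vars:
            raise SemError("model has no observed variables")
        if self.identification not in ("fix_first_loading", "fix_latent_variance", "none"):
            raise SemError(f"unknown identification convention {self.identification!r}")
        names = self.all_vars
        if len(set(names)) != len(names):
            raise SemError("duplicate variable names in model")
        known = set(names)
        for lat, ind, _ in self.loadings:
            if lat not in self.latent_vars:
                raise SemError(f"loading source {lat!r} is not a latent variable")
            if ind not in known:
                raise SemError(f"unknown indicator {ind!r}")
        for tgt, src, _ in self.paths:
            if tgt not in known or src not in known:
                raise SemError(f"unknown variable in path {tgt!r} ~ {src!r}")
        for lat in self.latent_vars:
            has_ind = any(l == lat for l, _, _ in self.loadings)
            has_path = any(lat in (t, s) for t, s, _ in self.paths)
            if not (has_ind or has_path):
                raise SemError(f"latent variable {lat!r} has no indicator and no path")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        edges: dict[str, list[str]] = {}
        for lat, ind, _ in self.loadings:
            edges.setdefault(lat, []).append(ind)
        for tgt, src, _ in self.paths:
            edges.setdefault(src, []).append(tgt)
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {v: WHITE for v in self.all_vars}

        def visit(v: str, trail: list[str]) -> None:
            colour[v] = GREY
            trail.append(v)
            for w in edges.get(v, ()):
                if colour[w] == GREY:
                    cyc = trail[trail.index(w):] + [w]
                    raise SemError("cyclic directed paths: " + " -> ".join(cyc))
                if colour[w] == WHITE:
                    visit(w, trail)
            trail.pop()
            colour[v] = BLACK

        for v in self.all_vars:
            if colour[v] == WHITE:
                visit(v, [])


def parse_model(text: str, identification: str = "fix_first_loading") -> SemModelSpec:
    """Parse the plain-text model syntax into a :class:`SemModelSpec`."""
    loadings: list[tuple[str, str, float | None]] = []
    paths: list[tuple[str, str, float | None]] = []
    covariances: list[tuple[str, str, float | None]] = []
    latent: list[str] = []
    order: list[str] = []  # first-appearance order of every name

    def note(name: str) -> None:
        if name not in order:
            order.append(name)

    def parse_terms(rhs: str, lineno: int) -> list[tuple[str, float | None]]:
        out = []
        for raw in rhs.split("+"):
            m = _TERM_RE.match(raw.strip())
            if not m:
                raise SemError(f"line {lineno}: cannot parse term {raw.strip()!r}")
            fix = float(m.group("fix")) if m.group("fix") is not None else None
            out.append((m.group("name"), fix))
        return out

    any_statement = False
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        any_statement = True
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            lat = lhs.strip()
            if not _NAME_RE.fullmatch(lat):
                raise SemError(f"line {lineno}: invalid latent name {lat!r}")
            if lat not in latent:
                latent.append(lat)
            note(lat)
            for name, fix in parse_terms(rhs, lineno):
                note(name)
                loadings.append((lat, name, fix))
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            a = lhs.strip()
            terms = parse_terms(rhs, lineno)
            if len(terms) != 1:
                raise SemError(f"line {lineno}: covariance takes a single right-hand term")
            b, fix = terms[0]
            note(a)
            note(b)
            covariances.append((a, b, fix))
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            tgt = lhs.strip()
            if not _NAME_RE.fullmatch(tgt):
                raise SemError(f"line {lineno}: invalid target name {tgt!r}")
            note(tgt)
            for name, fix in parse_terms(rhs, lineno):
                note(name)
                paths.append((tgt, name, fix))
        else:
            raise SemError(f"line {lineno}: no operator (=~, ~ or ~~) in {line!r}")
    if not any_statement:
        raise SemError("empty model text")

    observed = tuple(v for v in order if v not in latent)
    spec = SemModelSpec(
        observed_vars=observed,
        latent_vars=tuple(latent),
        loadings=tuple(loadings),
        paths=tuple(paths),
        covariances=tuple(covariances),
        identification=identification,
    )
    spec.validate()
    return spec


def render_model(spec: SemModelSpec) -> str:
    """Render a spec back to model syntax; ``parse_model(render_model(s))``
    reproduces ``s`` up to variable-appearance order."""
    lines = []
    for lat in spec.latent_vars:
        terms = [(ind, fix) for l, ind, fix in spec.loadings if l == lat]
        if terms:
            rhs = " + ".join(f"{fix:g}*{ind}" if fix is not None else ind for ind, fix in terms)
            lines.append(f"{lat} =~ {rhs}")
    targets: dict[str, list[tuple[str, float | None]]] = {}
    for tgt, src, fix in spec.paths:
        targets.setdefault(tgt, []).append((src, fix))
    for tgt, terms in targets.items():
        rhs = " + ".join(f"{fix:g}*{src}" if fix is not None else src for src, fix in terms)
        lines.append(f"{tgt} ~ {rhs}")
    for a, b, fix in spec.covariances:
        lines.append(f"{a} ~~ {f'{fix:g}*' if fix is not None else ''}{b}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# RAM index: map free parameters / fixed values onto A and S
# ---------------------------------------------------------------------------

_KIND_A, _KIND_SDIAG, _KIND_SOFF = 0, 1, 2


class _RAMIndex:
    """Placement of every model parameter in the RAM matrices."""

    def __init__(self, spec: SemModelSpec):
        spec.validate()
        self.spec = spec
        self.names = spec.all_vars
        self.idx = {v: i for i, v in enumerate(self.names)}
        self.t = len(self.names)
        self.q = len(spec.observed_vars)
        self.obs_idx = np.arange(self.q)  # observed come first in all_vars

        t = self.t
        self.A0 = np.zeros((t, t))
        self.S0 = np.zeros((t, t))
        self.free: list[tuple[int, int, int, str]] = []  # (kind, i, j, label)
        seen_labels: set[str] = set()

        def add_free(kind: int, i: int, j: int, label: str) -> None:
            if label in seen_labels:
                raise SemError(f"duplicate parameter {label!r}")
            seen_labels.add(label)
            self.free.append((kind, i, j, label))

        ident = spec.identification
        endogenous = {tgt for tgt, _, _ in spec.paths} | {ind for _, ind, _ in spec.loadings}

        # loadings: A[indicator, latent]
        first_done: set[str] = set()
        for lat, ind, fix in spec.loadings:
            i, j = self.idx[ind], self.idx[lat]
            label = f"{lat}=~{ind}"
            if fix is not None:
                self.A0[i, j] = fix
                first_done.add(lat)
            elif ident == "fix_first_loading" and lat not in first_done and not any(
                f is not None for l, _, f in spec.loadings if l == lat
            ):
                self.A0[i, j] = 1.0
                first_done.add(lat)
            else:
                add_free(_KIND_A, i, j, label)

        # structural paths: A[target, source]
        for tgt, src, fix in spec.paths:
            i, j = self.idx[tgt], self.idx[src]
            label = f"{tgt}~{src}"
            if fix is not None:
                self.A0[i, j] = fix
            else:
                add_free(_KIND_A, i, j, label)

        # variances: one per variable (residual variance for endogenous vars)
        fixed_var = {}
        for a, b, fix in spec.covariances:
            if a == b and fix is not None:
                fixed_var[a] = fix
        for v in self.names:
            i = self.idx[v]
            if v in fixed_var:
                self.S0[i, i] = fixed_var[v]
            elif ident == "fix_latent_variance" and v in spec.latent_vars:
                self.S0[i, i] = 1.0
            else:
                add_free(_KIND_SDIAG, i, i, f"{v}~~{v}")

        # covariances
        for a, b, fix in spec.covariances:
            if a == b:
                if fix is None:
                    raise SemError(f"use plain variance for {a}~~{a} without a value")
                continue
            i, j = self.idx[a], self.idx[b]
            if fix is not None:
                self.S0[i, j] = self.S0[j, i] = fix
            else:
                add_free(_KIND_SOFF, i, j, f"{a}~~{b}")

        self.labels = [lab for _, _, _, lab in self.free]
        self.m = len(self.labels)
        self._endogenous = endogenous

    # -- matrix assembly ----------------------------------------------------
    def build(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.A0.copy()
        S = self.S0.copy()
        for val, (kind, i, j, _) in zip(theta, self.free):
            if kind == _KIND_A:
                A[i, j] = val
            elif kind == _KIND_SDIAG:
                S[i, i] = val
            else:
                S[i, j] = S[j, i] = val
        return A, S

    def theta_from_dict(self, params: dict[str, float]) -> np.ndarray:
        theta = np.empty(self.m)
        for k, lab in enumerate(self.labels):
            if lab not in params:
                raise SemError(f"missing value for parameter {lab!r}")
            theta[k] = params[lab]
        return theta

    def full_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance over ALL variables, (I-A)^-1 S (I-A)^-T."""
        A, S = self.build(theta)
        I = np.eye(self.t)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - acyclic models invert
            raise SemError("singular (I - A); check model paths") from exc
        return B @ S @ B.T

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        M = self.full_covariance(theta)
        return M[: self.q, : self.q]

    def deriv_stack(self, theta: np.ndarray) -> np.ndarray:
        """d Sigma / d theta_k for every free parameter, shape (m, q, q)."""
        A, S = self.build(theta)
        B = np.linalg.inv(np.eye(self.t) - A)
        M = B @ S @ B.T
        G = B[: self.q, :]  # F B
        q = self.q
        out = np.empty((self.m, q, q))
        for k, (kind, i, j, _) in enumerate(self.free):
            if kind == _KIND_A:
                # d Sigma = F(B E_ij M + M E_ji B^T)F^T with M = B S B^T
                d = np.outer(G[:, i], M[:q, j])
                out[k] = d + d.T
            elif kind == _KIND_SDIAG:
                out[k] = np.outer(G[:, i], G[:, i])
            else:
                d = np.outer(G[:, i], G[:, j])
                out[k] = d + d.T
        return out


# ---------------------------------------------------------------------------
# Discrepancy function and fitting
# ---------------------------------------------------------------------------

def free_parameters(spec: SemModelSpec) -> list[str]:
    """Labels of the free parameters of ``spec`` in their internal order."""
    return list(_RAMIndex(spec).labels)


def implied_covariance(spec: SemModelSpec, params: dict[str, float]) -> np.ndarray:
    """Model-implied covariance matrix over ``spec.observed_vars``."""
    ram = _RAMIndex(spec)
    sigma = ram.sigma(ram.theta_from_dict(params))
    return 0.5 * (sigma + sigma.T)  # exact symmetry


def fml(sample_cov: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy ln|Sigma| - ln|S| + tr(S Sigma^-1) - p (>= 0, 0 at S)."""
    p = sample_cov.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(sample_cov)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise SemError("covariance matrix not positive definite")
    return float(logdet_m - logdet_s + np.trace(np.linalg.solve(sigma, sample_cov)) - p)


@dataclass
class SemFit:
    """Result of :func:`fit_ml`."""

    spec: SemModelSpec
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    standardized: dict[str, float] = field(default_factory=dict)
    relevance_flags: dict[str, bool] = field(default_factory=dict)
    fml: float = np.nan
    chi2: float = np.nan
    df: int = 0
    n: int = 0
    rmsea: tuple[float, float, float] | None = None
    converged: bool = False
    n_iter: int = 0
    heywood: bool = False
    sample_cov: np.ndarray | None = None
    _theta: np.ndarray | None = None
    _ram: _RAMIndex | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable summary."""
        return {
            "estimates": self.estimates,
            "std_estimates": self.standardized,
            "se": self.standard_errors,
            "fml": self.fml,
            "chi2": self.chi2,
            "df": self.df,
            "n": self.n,
            "rmsea": None
            if self.rmsea is None
            else {"est": self.rmsea[0], "lo": self.rmsea[1], "hi": self.rmsea[2]},
            "converged": self.converged,
            "heywood": self.heywood,
            "relevant_paths": [k for k, v in self.relevance_flags.items() if v],
        }


def _sample_cov_from_data(data, spec: SemModelSpec) -> tuple[np.ndarray, int]:
    import pandas as pd

    if isinstance(data, pd.DataFrame):
        missing = [v for v in spec.observed_vars if v not in data.columns]
        if missing:
            raise SemError(f"data is missing observed variables {missing}")
        X = data.loc[:, list(spec.observed_vars)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(spec.observed_vars):
            raise SemError("data column count does not match spec.observed_vars")
    X = X[~np.isnan(X).any(axis=1)]  # listwise deletion
    n = X.shape[0]
    if n <= X.shape[1]:
        raise SemError(f"need more rows ({n}) than observed variables ({X.shape[1]})")
    return np.cov(X, rowvar=False, ddof=1), n


def _start_values(ram: _RAMIndex, sample_cov: np.ndarray) -> np.ndarray:
    """Documented deterministic starts: loadings 1, paths 0, observed residual
    variances at half the sample variance, latent variances at 5% of the mean
    observed variance."""
    mean_var = float(np.mean(np.diag(sample_cov)))
    theta = np.empty(ram.m)
    for k, (kind, i, j, lab) in enumerate(ram.free):
        if kind == _KIND_A:
            theta[k] = 1.0 if "=~" in lab else 0.0
        elif kind == _KIND_SDIAG:
            if i < ram.q:
                theta[k] = 0.5 * sample_cov[i, i]
            else:
                theta[k] = 0.05 * mean_var
        else:
            theta[k] = 0.0
    return theta


def fit_ml(
    spec: SemModelSpec,
    data=None,
    *,
    sample_cov: np.ndarray | None = None,
    n: int | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> SemFit:
    """Fit ``spec`` by maximum likelihood to raw data or to ``(sample_cov, n)``.

    ``chi2 = (n - 1) * F_ML`` at the minimum; standard errors are from the
    inverse expected information.  Negative variance estimates are flagged
    (``heywood``) but not constrained.
    """
    ram = _RAMIndex(spec)
    if data is not None:
        S_obs, n = _sample_cov_from_data(data, spec)
    else:
        if sample_cov is None or n is None:
            raise SemError("provide raw data or sample_cov together with n")
        S_obs = np.asarray(sample_cov, dtype=float)
    if S_obs.shape != (ram.q, ram.q):
        raise SemError("sample covariance has wrong dimension")
    sign, logdet_s = np.linalg.slogdet(S_obs)
    if sign <= 0:
        raise SemError("sample covariance is not positive definite")
    p_star = ram.q * (ram.q + 1) // 2
    df = p_star - ram.m
    if df < 0:
        raise SemError(f"model has more free parameters ({ram.m}) than moments ({p_star})")

    q = ram.q
    BIG = 1e10

    def objective(theta: np.ndarray):
        A, S = ram.build(theta)
        I = np.eye(ram.t)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError:
            return BIG, np.zeros_like(theta)
        M = B @ S @ B.T
        Sigma = M[:q, :q]
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            # gentle push back towards PD region
            w = np.linalg.eigvalsh(0.5 * (Sigma + Sigma.T))
            return BIG * (1.0 + abs(float(w[0]))), np.zeros_like(theta)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(L))))
        Sig_inv = np.linalg.inv(Sigma)
        f = logdet_m - logdet_s + float(np.sum(Sig_inv * S_obs)) - q
        C = Sig_inv - Sig_inv @ S_obs @ Sig_inv
        G = B[:q, :]
        GtCG = G.T @ C @ G                       # dF/dS over all variables
        dFdA = 2.0 * GtCG @ S @ B.T              # dF/dA over all variables
        grad = np.empty(ram.m)
        for k, (kind, i, j, _) in enumerate(ram.free):
            if kind == _KIND_A:
                grad[k] = dFdA[i, j]
            elif kind == _KIND_SDIAG:
                grad[k] = GtCG[i, i]
            else:
                grad[k] = 2.0 * GtCG[i, j]
        return f, grad

    def expected_information_f(theta: np.ndarray) -> np.ndarray:
        """Expected information in the F_ML metric, 0.5 tr(S^-1 Dj S^-1 Dk)."""
        Sigma = ram.sigma(theta)
        Sig_inv = np.linalg.inv(Sigma)
        D = ram.deriv_stack(theta)
        Wd = np.einsum("ab,mbc,cd->mad", Sig_inv, D, Sig_inv, optimize=True)
        return 0.5 * np.einsum("mab,kab->mk", Wd, D, optimize=True)

    def lm_polish(x, f_min, grad, max_steps: int = 100):
        """Damped Fisher scoring (Levenberg-Marquardt on F_ML)."""
        lam = 1e-6
        steps = 0
        for _ in range(max_steps):
            if np.max(np.abs(grad)) < 10 * gtol:
                break
            info_f = expected_information_f(x)
            improved = False
            for _ in range(12):
                damped = info_f + lam * np.diag(np.maximum(np.diag(info_f), 1e-8))
                try:
                    d = np.linalg.solve(damped, -grad)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                f_try, g_try = objective(x + d)
                if f_try < f_min - 1e-13:
                    gain = f_min - f_try
                    x, f_min, grad = x + d, f_try, g_try
                    lam = max(lam / 3, 1e-9)
                    improved = True
                    break
                lam *= 10
            steps += 1
            if not improved or gain < 1e-13:
                break
        return x, f_min, grad, steps

    # First a quasi-Newton pass with the analytic gradient, then damped
    # Fisher scoring to polish.  On near-singular problems (Heywood-boundary
    # or collinear-factor solutions) the gradient cannot be driven to gtol in
    # statistically unidentified directions; the fit is accepted as converged
    # when the attainable chi-square improvement (quadratic approximation,
    # (n-1)/2 g' I^+ g) is negligible.
    x = _start_values(ram, S_obs)
    n_iter_total = 0
    strict = False
    for _ in range(2):
        res = optimize.minimize(
            objective, x, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": max_iter},
        )
        n_iter_total += res.nit
        x = res.x
        f_min, grad = objective(x)
        if res.success or np.max(np.abs(grad)) < 10 * gtol:
            strict = True
            break
        x, f_min, grad, steps = lm_polish(x, f_min, grad)
        n_iter_total += steps
        if np.max(np.abs(grad)) < 10 * gtol:
            strict = True
            break
    gradmax = float(np.max(np.abs(grad)))
    if strict:
        converged = True
    else:
        info_f = expected_information_f(x)
        potential_chi2 = 0.5 * (n - 1) * float(
            grad @ np.linalg.pinv(info_f, rcond=1e-10) @ grad
        )
        converged = bool(potential_chi2 < 0.05)
    if f_min >= BIG:
        raise SemError("estimation failed: implied covariance not positive definite")
    theta = x
    estimates = dict(zip(ram.labels, theta.tolist()))
    heywood = any(
        theta[k] < 0 for k, (kind, _, _, _) in enumerate(ram.free) if kind == _KIND_SDIAG
    )
    if heywood:
        warnings.warn("negative variance estimate (Heywood case)", stacklevel=2)

    # expected information and standard errors
    Sigma = ram.sigma(theta)
    Sig_inv = np.linalg.inv(Sigma)
    deriv = ram.deriv_stack(theta)               # (m, q, q)
    W = np.einsum("ab,mbc,cd->mad", Sig_inv, deriv, Sig_inv)
    info = 0.5 * (n - 1) * np.einsum("mab,kab->mk", W, deriv)
    try:
        acov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        acov = np.linalg.pinv(info)
    diag = np.diag(acov)
    ses = {
        lab: (float(np.sqrt(d)) if d > 0 else float("nan"))
        for lab, d in zip(ram.labels, diag)
    }

    chi2 = max(float((n - 1) * f_min), 0.0)
    fit = SemFit(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        fml=float(f_min),
        chi2=chi2,
        df=df,
        n=int(n),
        rmsea=rmsea(chi2, df, n) if df >= 1 else None,
        converged=converged,
        n_iter=int(n_iter_total),
        heywood=heywood,
        sample_cov=S_obs,
        _theta=theta,
        _ram=ram,
    )
    if converged:
        standardize(fit)
    return fit


# ---------------------------------------------------------------------------
# Standardized solution
# ---------------------------------------------------------------------------

def standardize(fit: SemFit) -> dict[str, float]:
    """Standardized estimates: each path/loading rescaled by the model-implied
    SD ratio of source and target; covariances become correlations.  Flags
    paths with |std beta| > 0.2 in ``fit.relevance_flags``."""
    if not fit.converged:
        raise SemError("cannot standardize a non-converged fit")
    ram = fit._ram if fit._ram is not None else _RAMIndex(fit.spec)
    theta = fit._theta if fit._theta is not None else ram.theta_from_dict(fit.estimates)
    M = ram.full_covariance(theta)
    var = np.diag(M).copy()
    if np.all(var <= 0):
        raise SemError("zero or negative implied variance; cannot standardize")
    if np.any(var <= 0):
        # Heywood solution: entries touching the offending variable become NaN
        bad = [ram.names[i] for i in np.nonzero(var <= 0)[0]]
        warnings.warn(
            f"non-positive implied variance for {bad}; affected standardized "
            "estimates reported as NaN",
            stacklevel=2,
        )
        fit.heywood = True
        var = np.where(var > 0, var, np.nan)
    sd = np.sqrt(var)
    A, S = ram.build(theta)
    out: dict[str, float] = {}
    flags: dict[str, bool] = {}
    spec = fit.spec
    for lat, ind, fix in spec.loadings:
        i, j = ram.idx[ind], ram.idx[lat]
        out[f"{lat}=~{ind}"] = float(A[i, j] * sd[j] / sd[i])
    for tgt, src, fix in spec.paths:
        i, j = ram.idx[tgt], ram.idx[src]
        label = f"{tgt}~{src}"
        val = float(A[i, j] * sd[j] / sd[i])
        out[label] = val
        flags[label] = abs(val) > RELEVANCE_THRESHOLD
    for a, b, fix in spec.covariances:
        if a == b:
            continue
        i, j = ram.idx[a], ram.idx[b]
        out[f"{a}~~{b}"] = float(S[i, j] / (sd[i] * sd[j]))
    fit.standardized = out
    fit.relevance_flags = flags
    return out


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def rmsea(chi2: float, df: int, n: int, ci_level: float = 0.90) -> tuple[float, float, float]:
    """RMSEA point estimate sqrt(max(chi2 - df, 0) / (df (n-1))) with a
    confidence interval from noncentral chi-square inversion."""
    if df < 1:
        raise SemError("RMSEA undefined for df = 0")
    if n < 2:
        raise SemError("RMSEA requires n >= 2")
    denom = df * (n - 1)
    est = float(np.sqrt(max(chi2 - df, 0.0) / denom))
    tail = (1.0 - ci_level) / 2.0

    def lam_to_rmsea(lam: float) -> float:
        return float(np.sqrt(max(lam, 0.0) / denom))

    def solve(target: float) -> float:
        """Find lambda with P(X2_{df,lam} <= chi2) = target (cdf decreasing in lam)."""
        f0 = stats.ncx2.cdf(chi2, df, 1e-12) - target
        if f0 <= 0:
            return 0.0
        hi = max(4.0 * chi2, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) - target > 0:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover
                return hi
        return float(optimize.brentq(lambda lam: stats.ncx2.cdf(chi2, df, lam) - target, 1e-12, hi))

    lam_lo = solve(1.0 - tail)   # lower RMSEA bound
    lam_hi = solve(tail)         # upper RMSEA bound
    return est, lam_to_rmsea(lam_lo), lam_to_rmsea(lam_hi)


# ---------------------------------------------------------------------------
# Modification indices
# ---------------------------------------------------------------------------

def _candidate_entries(ram: _RAMIndex) -> list[tuple[int, int, int, str]]:
    """Admissible fixed-at-zero parameters: cross-loadings, absent structural
    paths among latents, and absent residual covariances among observed."""
    spec = ram.spec
    present_A = {(i, j) for kind, i, j, _ in ram.free if kind == _KIND_A}
    present_A |= {(i, j) for (i, j) in zip(*np.nonzero(ram.A0))}
    present_S = {(i, j) for kind, i, j, _ in ram.free if kind == _KIND_SOFF}
    present_S |= {(min(i, j), max(i, j)) for (i, j) in zip(*np.nonzero(ram.S0)) if i != j}
    cands: list[tuple[int, int, int, str]] = []
    for lat in spec.latent_vars:
        j = ram.idx[lat]
        for ind in spec.observed_vars:
            i = ram.idx[ind]
            if (i, j) not in present_A:
                cands.append((_KIND_A, i, j, f"{lat}=~{ind}"))
    for src in spec.latent_vars:
        for tgt in spec.latent_vars:
            if src == tgt:
                continue
            i, j = ram.idx[tgt], ram.idx[src]
            if (i, j) not in present_A:
                cands.append((_KIND_A, i, j, f"{tgt}~{src}"))
    for ai in range(ram.q):
        for bi in range(ai + 1, ram.q):
            if (ai, bi) not in present_S and (bi, ai) not in present_S:
                cands.append((_KIND_SOFF, ai, bi,
                              f"{ram.names[ai]}~~{ram.names[bi]}"))
    return cands


def modification_indices(fit: SemFit, candidates: list[str] | None = None) -> dict[str, float]:
    """Univariate score-test modification indices for fixed-at-zero parameters.

    Each MI estimates the chi-square drop from freeing one parameter,
    ``MI = u_c^2 / (I_cc - I_cf I_ff^-1 I_fc)`` with the score ``u_c`` and the
    expected information ``I`` evaluated at the ML solution.  Parameters with
    a singular conditional information are reported as NaN with a warning.
    Returned sorted in decreasing order; free parameters never appear.
    """
    if not fit.converged:
        raise SemError("modification indices require a converged fit")
    if fit.df < 1:
        raise SemError("modification indices require df >= 1")
    ram = fit._ram if fit._ram is not None else _RAMIndex(fit.spec)
    theta = fit._theta if fit._theta is not None else ram.theta_from_dict(fit.estimates)
    n = fit.n
    S_obs = fit.sample_cov
    q = ram.q
    A, S = ram.build(theta)
    B = np.linalg.inv(np.eye(ram.t) - A)
    M = B @ S @ B.T
    G = B[:q, :]
    Sigma = M[:q, :q]
    Sig_inv = np.linalg.inv(Sigma)
    C = Sig_inv - Sig_inv @ S_obs @ Sig_inv

    cand_entries = _candidate_entries(ram)
    if candidates is not None:
        wanted = set(candidates)
        cand_entries = [c for c in cand_entries if c[3] in wanted]
    if not cand_entries:
        return {}

    # derivative of Sigma for each candidate: u v^T + v u^T
    U = np.empty((len(cand_entries), q))
    V = np.empty((len(cand_entries), q))
    for k, (kind, i, j, _) in enumerate(cand_entries):
        if kind == _KIND_A:
            U[k] = G[:, i]
            V[k] = M[:q, j]
        else:
            U[k] = G[:, i]
            V[k] = G[:, j]

    deriv_free = ram.deriv_stack(theta)                        # (m, q, q)
    W_free = np.einsum("ab,mbc,cd->mad", Sig_inv, deriv_free, Sig_inv)
    info_ff = 0.5 * (n - 1) * np.einsum("mab,kab->mk", W_free, deriv_free)

    # score u_c = -(n-1)/2 * tr(C dSigma_c) = -(n-1) * u^T C v
    u_c = -(n - 1) * np.einsum("ka,ab,kb->k", U, C, V)
    # I_fc = (n-1)/2 tr(W_f dSigma_c) = (n-1) u^T W_f v
    I_fc = (n - 1) * np.einsum("mab,ka,kb->mk", W_free, U, V)
    # I_cc = (n-1)/2 tr(Sig^-1 dSig_c Sig^-1 dSig_c)
    SU = U @ Sig_inv
    SV = V @ Sig_inv
    tr_uvuv = np.einsum("ka,ka->k", SU, V) ** 2
    tr_uuvv = np.einsum("ka,ka->k", SU, U) * np.einsum("ka,ka->k", SV, V)
    I_cc = (n - 1) * (tr_uvuv + tr_uuvv)

    try:
        sol = np.linalg.solve(info_ff, I_fc)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(info_ff, I_fc, rcond=None)[0]
    denom = I_cc - np.einsum("mk,mk->k", I_fc, sol)
    mi = np.full(len(cand_entries), np.nan)
    good = denom > 1e-10
    mi[good] = u_c[good] ** 2 / denom[good]
    if not np.all(good):
        warnings.warn(
            f"{int(np.sum(~good))} modification indices undefined (singular information)",
            stacklevel=2,
        )
    out = {lab: float(v) for (_, _, _, lab), v in zip(cand_entries, mi)}
    return dict(sorted(out.items(), key=lambda kv: (-(kv[1] if np.isfinite(kv[1]) else -np.inf))))
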