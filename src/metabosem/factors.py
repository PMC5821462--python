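"""Exploratory factor analysis of the metabolite panel.

Principal-axis extraction on the correlation matrix with iterated
communalities, optional varimax rotation, and factor-count selection by
Horn's parallel analysis or the Kaiser rule.  Each variable is assigned to
the factor on which it loads most strongly in absolute value; the resulting
blocks (amino acids into two factors, acylcarnitines into four) define the
measurement model used by the structural equation models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FactorError", "FactorSolution", "select_n_factors", "fit_efa", "varimax"]


class FactorError(ValueError):
    pass


@dataclass
class FactorSolution:
    """EFA result: standardized loadings, rotation, per-variable factor
    assignment and per-factor explained-variance proportions."""

    variables: list[str]
    loadings: np.ndarray          # (p, n_factors)
    communalities: np.ndarray     # (p,)
    rotation: str
    n_factors: int
    assignment: dict[str, int]    # variable -> factor index (0-based)
    explained_variance: np.ndarray
    selection_rule: str = "fixed"
    heywood: bool = False
    n_iter: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "variables": self.variables,
            "loadings": self.loadings.tolist(),
            "rotation": self.rotation,
            "n_factors": self.n_factors,
            "assignment": self.assignment,
            "explained_variance": self.explained_variance.tolist(),
            "selection_rule": self.selection_rule,
            "heywood": self.heywood,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_corr(corr: np.ndarray) -> np.ndarray:
    R = np.asarray(corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise FactorError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise FactorError("correlation matrix must have unit diagonal")
    if not np.allclose(R, R.T, atol=1e-8):
        raise FactorError("correlation matrix must be symmetric")
    return 0.5 * (R + R.T)


def select_n_factors(
    corr: np.ndarray,
    rule: str = "parallel_analysis",
    n_obs: int | None = None,
    reps: int = 100,
    seed: int = 0,
) -> int:
    """Number of factors to retain.

    ``parallel_analysis``: eigenvalues of the observed correlation matrix are
    compared rank-by-rank against the 95th percentile of eigenvalues from
    ``reps`` standard-normal datasets of the same (n_obs, p) shape; retained
    while the observed eigenvalue exceeds its threshold.  ``kaiser``: count of
    eigenvalues above 1.
    """
    R = _check_corr(corr)
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    if rule == "kaiser":
        return int(np.sum(eig > 1.0))
    if rule != "parallel_analysis":
        raise FactorError(f"unknown selection rule {rule!r}")
    if n_obs is None or n_obs < 3:
        raise FactorError("parallel_analysis requires the sample size n_obs")
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    sims = np.empty((reps, p))
    for r in range(reps):
        X = rng.standard_normal((n_obs, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    thresh = np.percentile(sims, 95, axis=0)
    below = np.nonzero(~(eig > thresh))[0]
    return int(below[0]) if below.size else p


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (communalities are preserved)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    Rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        Rot = u @ vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return L @ Rot


def fit_efa(
    data: np.ndarray,
    n_factors: int,
    rotation: str = "varimax",
    variables: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> FactorSolution:
    """Principal-axis factoring with iterated communalities.

    Columns are standardized internally; starting communalities are squared
    multiple correlations.  Heywood cases (communality reaching 1) are clipped
    to 0.999 and flagged.  Assignment is by maximum |loading|; ties go to the
    lower factor index with a warning.
    """
    X = np.asarray(data, dtype=float)
    if hasattr(data, "columns") and variables is None:
        variables = list(data.columns)
    n, p = X.shape
    if variables is None:
        variables = [f"v{j}" for j in range(p)]
    if not 1 <= n_factors <= p:
        raise FactorError(f"n_factors must be in [1, {p}]")
    if n <= p:
        warnings.warn(f"n = {n} <= p = {p}: factor solution may be unstable", stacklevel=2)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.nonzero(sd <= 0)[0][0])
        raise FactorError(f"constant column {variables[j]!r}")
    R = np.corrcoef(X, rowvar=False)

    # starting communalities: squared multiple correlations
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.999)
    heywood = False
    it = 0
    last_change = np.inf
    for it in range(1, max_iter + 1):
        Rred = R.copy()
        np.fill_diagonal(Rred, h2)
        w, V = np.linalg.eigh(Rred)
        order = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[order], 0.0, None)
        L = V[:, order] * np.sqrt(lam)
        h2_new = np.sum(L**2, axis=1)
        if np.any(h2_new > 0.999):
            heywood = True
        h2_new = np.clip(h2_new, None, 0.999)  # hard communality ceiling
        change = float(np.max(np.abs(h2_new - h2)))
        if change < tol:
            h2 = h2_new
            break
        # damp whenever the change stops shrinking (period-2 cycles under
        # Heywood clipping); averaging does not move the fixed point
        h2 = 0.5 * (h2 + h2_new) if change > 0.999 * last_change else h2_new
        last_change = change
    else:
        raise FactorError(
            f"principal-axis iteration did not converge in {max_iter} steps "
            f"(last max communality change {last_change:.2e})"
        )
    if heywood:
        warnings.warn("Heywood case: communality clipped to 0.999", stacklevel=2)

    if rotation == "varimax":
        L = varimax(L)
    elif rotation != "none":
        raise FactorError(f"unknown rotation {rotation!r}")

    # orient each factor to have positive loading sum (sign is arbitrary)
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs

    assignment: dict[str, int] = {}
    absL = np.abs(L)
    for j, name in enumerate(variables):
        best = absL[j].max()
        ties = np.nonzero(np.isclose(absL[j], best, rtol=0, atol=1e-12))[0]
        if ties.size > 1:
            warnings.warn(f"{name}: tied loadings, assigned to factor {ties[0]}", stacklevel=2)
        assignment[name] = int(ties[0])
    explained = np.sum(L**2, axis=0) / p
    return FactorSolution(
        variables=list(variables),
        loadings=L,
        communalities=np.sum(L**2, axis=1),
        rotation=rotation,
        n_factors=n_factors,
        assignment=assignment,
        explained_variance=explained,
        heywood=heywood,
        n_iter=it,
    )
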