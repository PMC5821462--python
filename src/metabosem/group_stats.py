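"""Descriptive-table group contrasts.

One-way ANOVA with Fisher LSD post-hoc lettering for continuous variables
(log10-analysed when flagged skewed, summaries back-transformed by
antilogarithm), Pearson chi-square for categorical variables,
Benjamini-Hochberg FDR over the metabolic/inflammatory family, and the
composite (Matsuda) whole-body insulin sensitivity index from the 5-point
OGTT.

Homogeneous-group letters follow the descriptive-table convention: groups are
ordered by decreasing mean, 'a' goes to the largest, and groups whose Fisher
LSD pairwise p-value is above alpha share a letter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupStatsError",
    "log10_normalize",
    "anova_oneway",
    "fisher_lsd",
    "chi_square_independence",
    "bh_fdr",
    "matsuda_index",
    "build_comparison_table",
    "default_variable_plan",
]


class GroupStatsError(ValueError):
    pass


def log10_normalize(values):
    """log10-transform a positive series; returns (transformed, back_transform)
    where ``back_transform`` inverts by antilogarithm."""
    x = np.asarray(values, dtype=float)
    bad = np.nonzero(~(x > 0))[0]
    if bad.size:
        raise GroupStatsError(f"non-positive values at positions {bad.tolist()[:10]}")
    return np.log10(x), lambda y: np.power(10.0, np.asarray(y, dtype=float))


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    parts = [values[groups == g] for g in labels]
    if len(parts) < 2:
        raise GroupStatsError("need at least 2 groups")
    for g, part in zip(labels, parts):
        if len(part) < 2:
            raise GroupStatsError(f"group {g!r} has fewer than 2 observations")
    return labels, parts


def anova_oneway(values, groups):
    """Classical one-way ANOVA decomposition.

    Returns ``(F, df_between, df_within, p)``; p from the upper tail of the F
    distribution.
    """
    labels, parts = _split_groups(values, groups)
    k = len(parts)
    n = sum(len(p) for p in parts)
    grand = np.concatenate(parts).mean()
    ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df_b, df_w = k - 1, n - k
    if ssw <= 0:
        raise GroupStatsError("zero within-group variance; ANOVA degenerate")
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def fisher_lsd(values, groups, alpha: float = 0.05):
    """Fisher least-significant-difference post hoc: unadjusted pairwise t
    tests on the pooled ANOVA mean-square error.

    Returns ``(pairwise, letters)`` where ``pairwise`` is a DataFrame of
    two-sided p-values and ``letters`` maps each group to its homogeneous-group
    label(s), assigned in decreasing-mean order ('a' contains the largest
    mean).
    """
    labels, parts = _split_groups(values, groups)
    k = len(parts)
    n = sum(len(p) for p in parts)
    df_w = n - k
    mse = sum(((p - p.mean()) ** 2).sum() for p in parts) / df_w
    if mse <= 0:
        raise GroupStatsError("zero within-group variance; LSD degenerate")
    means = np.array([p.mean() for p in parts])
    sizes = np.array([len(p) for p in parts])
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (means[i] - means[j]) / se
            P[i, j] = P[j, i] = 2.0 * stats.t.sf(abs(t), df_w)
    pairwise = pd.DataFrame(P, index=labels, columns=labels)

    # letters: maximal runs of mutually non-different groups in mean order
    order = np.argsort(-means)  # descending
    intervals: list[tuple[int, int]] = []
    for a in range(k):
        b = a
        while b + 1 < k and all(
            P[order[x], order[y]] >= alpha
            for x in range(a, b + 2) for y in range(x + 1, b + 2)
        ):
            b += 1
        if not intervals or b > intervals[-1][1]:  # skip runs nested in the previous one
            intervals.append((a, b))
    letters_by_group: dict = {g: "" for g in labels}
    for letter_idx, (a, b) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for pos in range(a, b + 1):
            letters_by_group[labels[order[pos]]] += letter
    return pairwise, letters_by_group


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected_below_5: bool


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Flags (does not reject) tables with any expected cell count below 5.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise GroupStatsError("contingency table must be at least 2x2")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise GroupStatsError("table needs non-negative counts and a positive total")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise GroupStatsError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p), bool(np.any(expected < 5)))


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise GroupStatsError("p_values must be a non-empty 1-d series")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise GroupStatsError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def matsuda_index(glucose_series, insulin_series):
    """Composite insulin sensitivity index from 5-point OGTT series:
    ``10000 / sqrt(G0 * I0 * Gmean * Imean)`` with arithmetic means over the
    0-120 min samples (glucose mg/dl, insulin uU/ml).  Accepts a single
    series or an (n, 5) matrix."""
    G = np.atleast_2d(np.asarray(glucose_series, dtype=float))
    I = np.atleast_2d(np.asarray(insulin_series, dtype=float))
    if G.shape[1] != 5 or I.shape[1] != 5:
        raise GroupStatsError("glucose and insulin series need exactly 5 OGTT time points")
    if np.any(~(G > 0)) or np.any(~(I > 0)):
        raise GroupStatsError("OGTT values must be strictly positive")
    out = 10000.0 / np.sqrt(G[:, 0] * I[:, 0] * G.mean(axis=1) * I.mean(axis=1))
    return out[0] if np.asarray(glucose_series).ndim == 1 else out


# ---------------------------------------------------------------------------
# Comparison table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanEntry:
    variable: str
    kind: str            # "continuous" | "categorical"
    log_skewed: bool     # analyse on log10 scale
    fdr_member: bool     # include in the BH family


def default_variable_plan(config) -> list[PlanEntry]:
    """Descriptive-table plan for a generated cohort: Age/Sex/anthropometrics
    without FDR, everything below (insulin sensitivity incl. the computed
    Matsuda index, lipids/liver, inflammation, metabolites) in one BH family.
    Skew flags follow each variable's generation scale."""
    plan = [PlanEntry("Age", "continuous", True, False),
            PlanEntry("Sex", "categorical", False, False)]
    insulin_done = False
    for name, vs in config.variables.items():
        if name == "Age":
            continue
        anthro = vs["category"] == "anthropometric"
        if name.startswith("Insulin_"):
            # the table reports the Matsuda index, not raw insulin
            if not insulin_done:
                plan.append(PlanEntry("Matsuda", "continuous", True, True))
                insulin_done = True
            continue
        log_flag = any(gd.dist == "log" for gd in vs["groups"].values())
        plan.append(PlanEntry(name, "continuous", log_flag, not anthro))
    plan.extend([
        PlanEntry("MomFHOB", "categorical", False, False),
        PlanEntry("DadFHOB", "categorical", False, False),
        PlanEntry("IndFHOB", "categorical", False, False),
    ])
    return plan


def build_comparison_table(
    cohort,
    variable_plan: list[PlanEntry] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable group contrasts in descriptive-table layout.

    Continuous variables: one-way ANOVA (on log10 values when flagged skewed)
    with Fisher LSD letters; per-group mean and 95% CI back-transformed to the
    original scale for log-analysed variables.  Categorical variables: Pearson
    chi-square on the variable-by-group contingency table.  BH-FDR q-values
    are computed over the plan's ``fdr_member`` rows only; other rows carry NA,
    as the anthropometric block does in the study table.
    """
    df = cohort.data if hasattr(cohort, "data") else cohort
    if variable_plan is None:
        raise GroupStatsError("a variable plan is required (see default_variable_plan)")
    groups = df["group"].to_numpy()
    labels = list(pd.unique(groups))
    rows = []
    for entry in variable_plan:
        if entry.variable not in df.columns:
            raise GroupStatsError(f"variable {entry.variable!r} not in cohort")
        col = df[entry.variable]
        row: dict = {"variable": entry.variable, "test": None, "p": np.nan}
        if entry.kind == "continuous":
            vals = col.to_numpy(dtype=float)
            if entry.log_skewed:
                tvals, back = log10_normalize(vals)
            else:
                tvals, back = vals, (lambda y: np.asarray(y, dtype=float))
            _, _, _, p = anova_oneway(tvals, groups)
            _, letters = fisher_lsd(tvals, groups, alpha=alpha)
            for g in labels:
                part = tvals[groups == g]
                m, se = part.mean(), part.std(ddof=1) / np.sqrt(len(part))
                tcrit = stats.t.ppf(0.975, len(part) - 1)
                lo, hi = back(m - tcrit * se), back(m + tcrit * se)
                row[f"{g}_mean"] = float(back(m))
                row[f"{g}_lo"], row[f"{g}_hi"] = float(lo), float(hi)
                row[f"{g}_letters"] = letters[g]
            row["test"] = "anova"
            row["p"] = p
        else:
            tab = pd.crosstab(col, df["group"]).reindex(columns=labels)
            res = chi_square_independence(tab.to_numpy())
            if res.expected_below_5:
                warnings.warn(
                    f"{entry.variable}: expected cell count below 5", stacklevel=2
                )
            for g in labels:
                row[f"{g}_mean"] = np.nan
                row[f"{g}_lo"] = row[f"{g}_hi"] = np.nan
                row[f"{g}_letters"] = ""
            row["test"] = "chi_square"
            row["p"] = res.p
        row["fdr_q"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    fam = [e.variable for e in variable_plan if e.fdr_member]
    if fam:
        out.loc[fam, "fdr_q"] = bh_fdr(out.loc[fam, "p"].to_numpy())
    return out.reset_index()
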