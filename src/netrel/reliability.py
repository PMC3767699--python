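"""Test–retest reliability of connectivity and graph metrics.

The reliability estimator is the one-way random-effects, single-measure
intraclass correlation coefficient: with n subjects measured in k sessions,
a one-way ANOVA with random subject effects splits the total variance into
between-subject (MS_b) and within-subject (MS_w) mean squares and

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w),

negative estimates clamped to 0 (flagged). ICC values are graded poor
[0, 0.25), low [0.25, 0.4), fair [0.4, 0.6), good [0.6, 0.75) and excellent
[0.75, 1]; the boundaries are half-open on the left with the upper end
closed at 1.

Because binary networks depend on the sparsity threshold, every metric's
ICC is a function of sparsity; the area under each subject's
metric-vs-sparsity curve (AUC, trapezoidal) gives the complementary
threshold-independent scalar whose ICC is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "GRADES",
    "icc",
    "grade",
    "auc",
    "edge_reliability",
    "metric_reliability",
    "session_similarity",
    "strength_reliability_correlation",
    "session_difference_tests",
    "reliability_anova",
]

GRADES = ("poor", "low", "fair", "good", "excellent")
_GRADE_EDGES = (0.25, 0.4, 0.6, 0.75)


@dataclass
class ReliabilityResult:
    icc: float
    ms_between: float
    ms_within: float
    k: int
    grade: str | None
    clamped: bool


def icc(table: np.ndarray) -> ReliabilityResult:
    """One-way random-effects single-measure ICC of an n x k table.

    Rows are subjects, columns repeated sessions. Zero total variance makes
    the coefficient undefined: the result carries icc = NaN and no grade.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 subjects, k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("table contains non-finite values")
    n, k = x.shape
    subject_means = x.mean(axis=1)
    grand = x.mean()
    ms_b = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    ms_w = np.sum((x - subject_means[:, None]) ** 2) / (n * (k - 1))
    if ms_b + ms_w == 0.0:
        return ReliabilityResult(float("nan"), 0.0, 0.0, k, None, False)
    raw = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    clamped = bool(raw < 0.0)
    value = max(raw, 0.0)
    return ReliabilityResult(float(value), float(ms_b), float(ms_w), k,
                             grade(value), clamped)


def grade(icc_value: float) -> str:
    """Reliability grade of a clamped ICC value in [0, 1]."""
    if not 0.0 <= icc_value <= 1.0:
        raise ValueError(f"ICC value {icc_value} outside [0, 1]")
    for g, upper in zip(GRADES, _GRADE_EDGES):
        if icc_value < upper:
            return g
    return "excellent"


def auc(curve: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal area under a metric-vs-sparsity curve.

    NaN points are dropped pairwise: interior gaps are bridged by a single
    trapezoid between the surrounding finite points, leading/trailing gaps
    shrink the integration range. Requires >= 2 finite points.
    """
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if curve.shape != grid.shape:
        raise ValueError("curve and grid must have the same length")
    mask = np.isfinite(curve)
    if mask.sum() < 2:
        raise ValueError("need at least two finite curve points")
    return float(np.trapezoid(curve[mask], grid[mask]))


def _edge_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def edge_reliability(r_values: np.ndarray,
                     channel_ids: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, dict]:
    """Per-edge ICC of raw correlation values across sessions.

    ``r_values`` is (n_subjects, n_sessions, n_channels, n_channels).
    Returns a frame with one row per unique edge (node_i, node_j, icc,
    ms_b, ms_w, grade, clamped) and a summary dict with the mean, SD and
    grade histogram (counts and fractions).
    """
    r = np.asarray(r_values, dtype=float)
    if r.ndim != 4:
        raise ValueError("expected subjects x sessions x channels x channels")
    n_sub, n_ses, n_ch, _ = r.shape
    iu, ju = _edge_index(n_ch)
    rows = []
    for i, j in zip(iu, ju):
        res = icc(r[:, :, i, j])
        rows.append((int(i), int(j), res.icc, res.ms_between, res.ms_within,
                     res.grade, res.clamped))
    df = pd.DataFrame(rows, columns=["node_i", "node_j", "icc", "ms_b",
                                     "ms_w", "grade", "clamped"])
    if channel_ids is not None:
        df.insert(0, "edge", [f"{channel_ids[i]}-{channel_ids[j]}"
                              for i, j in zip(df.node_i, df.node_j)])
    finite = df.icc.dropna()
    counts = {g: int((df.grade == g).sum()) for g in GRADES}
    total = max(len(df), 1)
    summary = {
        "n_edges": len(df),
        "mean_icc": float(finite.mean()) if len(finite) else float("nan"),
        "sd_icc": float(finite.std(ddof=1)) if len(finite) > 1 else float("nan"),
        "grade_counts": counts,
        "grade_fractions": {g: counts[g] / total for g in GRADES},
    }
    return df, summary


def metric_reliability(curves: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ICC-vs-sparsity profiles and AUC-based scalar ICC per metric/node.

    ``curves`` is long-format with columns (subject, session, node, metric,
    sparsity, value). Returns:

    * a per-sparsity frame (node, metric, sparsity, icc, grade) — sparsity
      points where any subject/session value is missing are dropped;
    * an AUC frame (node, metric, auc_icc, grade, ms_b, ms_w, clamped,
      grid_lo, grid_hi) where each subject's AUC integrates that subject's
      finite curve points (the integration range shrinks when leading or
      trailing stretches are missing).
    """
    required = {"subject", "session", "node", "metric", "sparsity", "value"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves frame lacks columns {sorted(missing)}")
    profile_rows = []
    auc_rows = []
    for (node, metric), grp in curves.groupby(["node", "metric"], sort=True):
        wide = grp.pivot_table(index=["subject", "session"], columns="sparsity",
                               values="value", dropna=False)
        grid = wide.columns.to_numpy(dtype=float)
        subjects = sorted({s for s, _ in wide.index})
        sessions = sorted({k for _, k in wide.index})
        cube = np.stack([
            np.stack([wide.loc[(s, k)].to_numpy(dtype=float)
                      for k in sessions]) for s in subjects
        ])  # subjects x sessions x grid
        # (a) threshold-dependent profile
        for gi, s_val in enumerate(grid):
            tab = cube[:, :, gi]
            if not np.all(np.isfinite(tab)):
                continue
            res = icc(tab)
            profile_rows.append((node, metric, float(s_val), res.icc,
                                 res.grade))
        # (b) threshold-independent AUC ICC
        try:
            aucs = np.array([[auc(cube[si, ki], grid)
                              for ki in range(len(sessions))]
                             for si in range(len(subjects))])
        except ValueError:
            continue
        finite_cols = np.isfinite(cube).all(axis=(0, 1))
        if finite_cols.any():
            lo, hi = grid[finite_cols][0], grid[finite_cols][-1]
        else:
            lo = hi = float("nan")
        res = icc(aucs)
        auc_rows.append((node, metric, res.icc, res.grade, res.ms_between,
                         res.ms_within, res.clamped, lo, hi))
    profile = pd.DataFrame(profile_rows, columns=["node", "metric",
                                                  "sparsity", "icc", "grade"])
    auc_icc = pd.DataFrame(auc_rows, columns=["node", "metric", "auc_icc",
                                              "grade", "ms_b", "ms_w",
                                              "clamped", "grid_lo", "grid_hi"])
    return profile, auc_icc


def session_similarity(r_values: np.ndarray) -> pd.DataFrame:
    """Between-session Pearson similarity of edge vectors.

    One row per subject (correlating that subject's 1035-edge vectors of
    sessions 1 and 2) plus a "group" row correlating the group-mean edge
    vectors; two-sided p from the t distribution with n_edges - 2 df.
    """
    r = np.asarray(r_values, dtype=float)
    if r.ndim != 4 or r.shape[1] != 2:
        raise ValueError("expected subjects x 2 sessions x channels x channels")
    iu, ju = _edge_index(r.shape[2])
    rows = []
    for s in range(r.shape[0]):
        v1, v2 = r[s, 0, iu, ju], r[s, 1, iu, ju]
        rr, p = stats.pearsonr(v1, v2)
        rows.append((str(s + 1), float(rr), float(p)))
    g1 = r[:, 0, iu, ju].mean(axis=0)
    g2 = r[:, 1, iu, ju].mean(axis=0)
    rr, p = stats.pearsonr(g1, g2)
    rows.append(("group", float(rr), float(p)))
    return pd.DataFrame(rows, columns=["subject", "r", "p"])


def strength_reliability_correlation(edge_iccs: np.ndarray,
                                     group_mean_edges: np.ndarray,
                                     ) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between group-level edge
    strength and edge reliability."""
    x = np.asarray(group_mean_edges, dtype=float)
    y = np.asarray(edge_iccs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("strength and ICC vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least three finite pairs")
    if x[mask].std() == 0 or y[mask].std() == 0:
        raise ValueError("degenerate variance; correlation undefined")
    r, p = stats.pearsonr(x[mask], y[mask])
    return float(r), float(p)


def paired_t(session1: np.ndarray, session2: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test (two-sided).

    All differences exactly zero -> (0.0, 1.0); zero difference variance
    with nonzero mean -> (signed inf, 0.0).
    """
    d = np.asarray(session1, dtype=float) - np.asarray(session2, dtype=float)
    if len(d) < 3:
        raise ValueError("need n >= 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def session_difference_tests(aucs: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test on per-subject session AUCs for every metric (and
    signal, when present).

    ``aucs`` columns: subject, session, metric, value and optionally
    signal. Returns one row per metric (x signal) with t and two-sided p.
    """
    required = {"subject", "session", "metric", "value"}
    if required - set(aucs.columns):
        raise ValueError(f"need columns {sorted(required)}")
    keys = ["metric"] + (["signal"] if "signal" in aucs.columns else [])
    rows = []
    for key, grp in aucs.groupby(keys, sort=True):
        wide = grp.pivot_table(index="subject", columns="session",
                               values="value", dropna=False)
        if wide.shape[1] != 2:
            continue
        wide = wide.dropna()    # subjects with an undefined AUC drop out
        if len(wide) < 3:
            continue
        t, p = paired_t(wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy())
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, t, p))
    return pd.DataFrame(rows, columns=keys + ["t", "p"])


def reliability_anova(table: pd.DataFrame, unit: str = "node",
                      factors: tuple[str, str] = ("metric", "signal"),
                      value: str = "icc",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-factor repeated-measures ANOVA on reliability values.

    ``table`` holds one value per unit x factor-level combination (for the
    nodal analysis: nodes as observational units, metric type and signal
    type as within-unit factors). Returns (anova table with F and p for
    both main effects and the interaction, post-hoc paired t-tests between
    factor levels). A fully degenerate table (all values identical) yields
    F = 0, p = 1 for every effect.
    """
    from statsmodels.stats.anova import AnovaRM

    cols = {unit, value, *factors}
    if cols - set(table.columns):
        raise ValueError(f"need columns {sorted(cols)}")
    pivot = table.pivot_table(index=unit, columns=list(factors), values=value,
                              dropna=False)
    if pivot.isna().any().any():
        raise ValueError("incomplete crossed design")

    effects = [factors[0], factors[1], f"{factors[0]}:{factors[1]}"]
    if np.allclose(table[value].to_numpy(), table[value].iloc[0]):
        anova = pd.DataFrame({"effect": effects,
                              "F": [0.0] * 3, "p": [1.0] * 3})
    else:
        fit = AnovaRM(table, depvar=value, subject=unit,
                      within=list(factors)).fit()
        res = fit.anova_table
        anova = pd.DataFrame({
            "effect": effects,
            "F": [res.loc[factors[0], "F Value"],
                  res.loc[factors[1], "F Value"],
                  res.loc[f"{factors[0]}:{factors[1]}", "F Value"]],
            "p": [res.loc[factors[0], "Pr > F"],
                  res.loc[factors[1], "Pr > F"],
                  res.loc[f"{factors[0]}:{factors[1]}", "Pr > F"]],
        })

    posthoc_rows = []
    for factor in factors:
        # marginal means per unit, averaging over the other factor
        means = table.pivot_table(index=unit, columns=factor, values=value,
                                  aggfunc="mean")
        levels = list(means.columns)
        for a_i in range(len(levels)):
            for b_i in range(a_i + 1, len(levels)):
                a, b = levels[a_i], levels[b_i]
                t, p = paired_t(means[a].to_numpy(), means[b].to_numpy())
                posthoc_rows.append((factor, str(a), str(b), t, p))
    posthoc = pd.DataFrame(posthoc_rows,
                           columns=["factor", "level_a", "level_b", "t", "p"])
    return anova, posthoc
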