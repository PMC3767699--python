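"""Intraclass correlation, grading, AUC summaries and the session-level
statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netrel.reliability import (GRADES, auc, edge_reliability, grade, icc,
                                metric_reliability, paired_t,
                                reliability_anova,
                                session_difference_tests, session_similarity,
                                strength_reliability_correlation)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_perfect_reliability():
    res = icc(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
    assert res.icc == 1.0 and res.ms_within == 0.0 and not res.clamped


def test_icc_hand_worked_anova():
    """Rows (1,2),(2,3),(3,4): MS_b = 2, MS_w = 0.5, ICC = 1.5/2.5 = 0.6."""
    res = icc(np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]))
    assert res.ms_between == pytest.approx(2.0)
    assert res.ms_within == pytest.approx(0.5)
    assert res.icc == pytest.approx(0.6)
    assert res.grade == "good"


def test_icc_negative_clamped_to_zero():
    res = icc(np.array([[1.0, 2.0], [2.0, 1.0]]))
    assert res.icc == 0.0 and res.clamped and res.grade == "poor"


def test_icc_zero_variance_undefined():
    res = icc(np.full((4, 2), 3.0))
    assert np.isnan(res.icc) and res.grade is None


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc(np.array([[1.0, 2.0]]))               # single subject
    with pytest.raises(ValueError):
        icc(np.array([[1.0], [2.0]]))             # single session
    with pytest.raises(ValueError):
        icc(np.array([[1.0, np.nan], [2.0, 1.0]]))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
       seed=st.integers(0, 1000))
def test_icc_affine_invariance(a, b, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
    assert icc(a * x + b).icc == pytest.approx(icc(x).icc, abs=1e-9)


def test_icc_estimator_consistency(rng):
    """Mean estimate tracks the planted variance ratio sb^2/(sb^2+sw^2)."""
    rho = 0.6
    estimates = []
    for _ in range(200):
        subj = rng.normal(0, np.sqrt(rho), (1000, 1))
        x = subj + rng.normal(0, np.sqrt(1 - rho), (1000, 2))
        estimates.append(icc(x).icc)
    assert np.mean(estimates) == pytest.approx(rho, abs=0.02)


def test_icc_agrees_with_pingouin():
    """Independent route: pingouin's ICC1 on the same table."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, (15, 2)) + rng.normal(0, 1, (15, 1))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(15), 2),
        "session": np.tile([1, 2], 15),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="session",
                                   ratings="score")
    icc1 = ref.loc[ref.Type.isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
    assert icc(x).icc == pytest.approx(icc1, abs=1e-9)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value, expected", [
    (0.0, "poor"), (0.24999, "poor"), (0.25, "low"), (0.39, "low"),
    (0.4, "fair"), (0.59, "fair"), (0.6, "good"), (0.74, "good"),
    (0.75, "excellent"), (0.8, "excellent"), (1.0, "excellent"),
])
def test_grade_boundaries(value, expected):
    assert grade(value) == expected


def test_grade_out_of_range_rejected():
    with pytest.raises(ValueError):
        grade(-0.1)
    with pytest.raises(ValueError):
        grade(1.1)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(0.0, 1.0, allow_nan=False))
def test_grades_partition_unit_interval(value):
    assert grade(value) in GRADES


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

GRID99 = np.round(np.arange(1, 100) * 0.01, 2)


def test_auc_constant_curve():
    assert auc(np.full(99, 3.0), GRID99) == pytest.approx(3.0 * 0.98)


def test_auc_linear_curve_exact():
    assert auc(GRID99.copy(), GRID99) == pytest.approx(
        (0.99**2 - 0.01**2) / 2.0, abs=1e-12)


def test_auc_matches_refined_riemann_sum(rng):
    values = rng.standard_normal(99).cumsum()
    coarse = auc(values, GRID99)
    fine_grid = np.linspace(0.01, 0.99, 99 * 64 - 63)
    fine_vals = np.interp(fine_grid, GRID99, values)
    riemann = np.sum((fine_vals[1:] + fine_vals[:-1]) / 2.0
                     * np.diff(fine_grid))
    assert coarse == pytest.approx(riemann, abs=1e-6)


def test_auc_missing_handling():
    vals = np.array([np.nan, 1.0, 2.0, np.nan, 4.0, np.nan])
    grid = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    # leading/trailing gaps shrink the range, interior gap is bridged
    expected = (1.5 * 0.1) + (3.0 * 0.2)
    assert auc(vals, grid) == pytest.approx(expected)
    with pytest.raises(ValueError):
        auc(np.array([np.nan, 1.0]), np.array([0.1, 0.2]))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 100))
def test_auc_linearity(a, b, seed):
    rng = np.random.default_rng(seed)
    c1, c2 = rng.standard_normal((2, 99))
    assert auc(a * c1 + b * c2, GRID99) == pytest.approx(
        a * auc(c1, GRID99) + b * auc(c2, GRID99), abs=1e-9)


# ---------------------------------------------------------------------------
# edge reliability
# ---------------------------------------------------------------------------

def _edge_stack(rng, n_sub=12, n_ch=8, noise=0.1):
    base = rng.uniform(-0.5, 0.8, (n_ch, n_ch))
    base = (base + base.T) / 2
    subj = rng.normal(0, 0.2, (n_sub, 1, n_ch, n_ch))
    subj = (subj + np.swapaxes(subj, 2, 3)) / 2
    sess = rng.normal(0, noise, (n_sub, 2, n_ch, n_ch))
    sess = (sess + np.swapaxes(sess, 2, 3)) / 2
    r = base + subj + sess
    for s in range(n_sub):
        for k in range(2):
            np.fill_diagonal(r[s, k], 1.0)
    return np.clip(r, -1, 1)


def test_edge_reliability_counts_and_summary(rng):
    r = _edge_stack(rng)
    df, summary = edge_reliability(r)
    assert len(df) == 8 * 7 // 2
    assert summary["n_edges"] == 28
    assert sum(summary["grade_counts"].values()) == 28
    assert sum(summary["grade_fractions"].values()) == pytest.approx(1.0)
    assert 0.0 <= summary["mean_icc"] <= 1.0


def test_edge_reliability_planted_limit(rng):
    """Session 2 identical to session 1 -> every edge excellent."""
    r = _edge_stack(rng)
    r[:, 1] = r[:, 0]
    df, summary = edge_reliability(r)
    assert (df.grade == "excellent").all()
    assert summary["mean_icc"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# metric reliability
# ---------------------------------------------------------------------------

def _curves_frame(rng, reliable=True, n_sub=10):
    grid = np.round(np.arange(0.1, 1.0, 0.1), 2)
    rows = []
    for subj in range(n_sub):
        offset = rng.normal(0, 1.0)
        for sess in (1, 2):
            bump = rng.normal(0, 0.05) if reliable else rng.normal(0, 1.0)
            for s in grid:
                rows.append((subj, sess, "global", "m", s,
                             offset * reliable + bump + 2 * s))
    return pd.DataFrame(rows, columns=["subject", "session", "node",
                                       "metric", "sparsity", "value"])


def test_identical_sessions_give_unit_icc_profile(rng):
    df = _curves_frame(rng)
    df2 = df[df.session == 1].copy()
    df2["session"] = 2
    both = pd.concat([df[df.session == 1], df2])
    profile, auc_icc = metric_reliability(both)
    assert (profile.icc == 1.0).all()
    assert (auc_icc.auc_icc == 1.0).all()


def test_auc_icc_is_icc_of_aucs(rng):
    """Compositional identity: the scalar equals icc() of per-subject AUCs."""
    df = _curves_frame(rng)
    _, auc_icc = metric_reliability(df)
    grid = np.round(np.arange(0.1, 1.0, 0.1), 2)
    table = np.array([
        [auc(df[(df.subject == s) & (df.session == k)]
             .sort_values("sparsity").value.to_numpy(), grid)
         for k in (1, 2)]
        for s in sorted(df.subject.unique())])
    assert auc_icc.auc_icc.iloc[0] == pytest.approx(icc(table).icc)


def test_planted_contrast_high_vs_shuffled(rng):
    high = _curves_frame(rng, reliable=True)
    low = _curves_frame(rng, reliable=False)
    _, h = metric_reliability(high)
    _, l = metric_reliability(low)
    assert h.auc_icc.iloc[0] > 0.9
    assert l.auc_icc.iloc[0] < 0.4


def test_missing_sparsity_points_dropped_from_profile(rng):
    df = _curves_frame(rng)
    df.loc[(df.subject == 0) & (df.sparsity == 0.1), "value"] = np.nan
    profile, auc_icc = metric_reliability(df)
    assert 0.1 not in set(profile.sparsity)
    assert auc_icc.grid_lo.iloc[0] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# session similarity + strength-reliability + paired tests
# ---------------------------------------------------------------------------

def test_session_similarity_identical_sessions(rng):
    r = _edge_stack(rng, n_sub=5)
    r[:, 1] = r[:, 0]
    out = session_similarity(r)
    assert len(out) == 6                       # 5 subjects + group row
    assert out.subject.iloc[-1] == "group"
    assert np.allclose(out.r, 1.0)


def test_session_similarity_independent_sessions(rng):
    n_ch = 46
    ts = rng.standard_normal((2, 2, n_ch, 400))
    r = np.empty((2, 2, n_ch, n_ch))
    for s in range(2):
        for k in range(2):
            r[s, k] = np.corrcoef(ts[s, k])
    out = session_similarity(r)
    assert np.all(np.abs(out.r[:2]) < 0.1)     # 1035 independent edges


def test_strength_reliability_correlation(rng):
    strength = rng.uniform(0, 1, 500)
    monotone = 0.2 + 0.7 * strength + rng.normal(0, 0.01, 500)
    r, p = strength_reliability_correlation(monotone, strength)
    assert r > 0.95 and p < 1e-10
    independent = rng.uniform(0, 1, 500)
    r2, p2 = strength_reliability_correlation(independent, strength)
    assert abs(r2) < 0.15
    with pytest.raises(ValueError, match="degenerate"):
        strength_reliability_correlation(np.full(10, 0.5), np.arange(10.0))


def test_paired_t_hand_worked():
    t, p = paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
    assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-4)
    assert t == pytest.approx(3.4641, abs=1e-4)
    t0, p0 = paired_t(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
    assert t0 == 0.0 and p0 == 1.0


def test_paired_t_matches_scipy(rng):
    from scipy import stats
    a, b = rng.standard_normal((2, 20))
    t, p = paired_t(a, b)
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


def test_session_difference_tests_grid(rng):
    rows = []
    for sig in ("HbO", "HbR", "HbT"):
        for metric in ("Cp", "Lp", "Q"):
            for subj in range(10):
                base = rng.normal(0, 1)
                rows.append((subj, 1, metric, sig, base))
                rows.append((subj, 2, metric, sig, base + rng.normal(0, 0.2)))
    df = pd.DataFrame(rows, columns=["subject", "session", "metric",
                                     "signal", "value"])
    out = session_difference_tests(df)
    assert len(out) == 9                       # 3 metrics x 3 signals
    assert {"metric", "signal", "t", "p"} <= set(out.columns)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _anova_table(rng, betweenness_shift=0.0, n_nodes=20):
    rows = []
    for node in range(n_nodes):
        base = rng.uniform(0.4, 0.8)
        for metric in ("degree", "efficiency", "betweenness"):
            for sig in ("HbO", "HbR", "HbT"):
                v = base + rng.normal(0, 0.05)
                if metric == "betweenness":
                    v -= betweenness_shift
                rows.append((node, metric, sig, float(np.clip(v, 0, 1))))
    return pd.DataFrame(rows, columns=["node", "metric", "signal", "icc"])


def test_anova_all_identical_cells(rng):
    df = _anova_table(rng)
    df["icc"] = 0.5
    anova, posthoc = reliability_anova(df)
    assert np.allclose(anova.F, 0.0) and np.allclose(anova.p, 1.0)
    assert len(posthoc) == 6                   # C(3,2) per factor


def test_anova_detects_planted_metric_effect(rng):
    detected = 0
    for _ in range(20):
        df = _anova_table(rng, betweenness_shift=0.3)
        anova, posthoc = reliability_anova(df)
        if anova.loc[anova.effect == "metric", "p"].iloc[0] < 0.05:
            detected += 1
    assert detected >= 19
    # post-hoc table covers every level pair with p-values
    assert {"factor", "level_a", "level_b", "t", "p"} <= set(posthoc.columns)
    assert (posthoc.p <= 1.0).all()


def test_anova_incomplete_design_rejected(rng):
    df = _anova_table(rng).iloc[:-1]
    with pytest.raises(ValueError, match="incomplete"):
        reliability_anova(df)
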