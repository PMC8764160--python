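"""Two-group statistics: rank-sum, FDR, t-test, ROC/AUC, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from mstates import StateProcess, simulate_state_sequence
from mstates.metrics import Segmentation, compute_metrics, extract_runs
from mstates.stats import (
    clinical_correlation,
    fdr_adjust,
    rank_sum_test,
    roc_auc,
    syntax_comparison,
    two_sample_t_test,
)


def test_rank_sum_exact_hand_case():
    """{1,2,3} vs {10,11,12}: one-sided tail 1/20, two-sided p = 0.1."""
    res = rank_sum_test([1, 2, 3], [10, 11, 12])
    assert res.p_value == pytest.approx(0.1)
    assert res.statistic == 0.0  # U of group 1
    assert "exact" in res.method


def test_rank_sum_identical_groups():
    res = rank_sum_test([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
    assert res.p_value == pytest.approx(1.0)


def test_rank_sum_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.standard_normal(6)
        y = rng.standard_normal(8) + 0.5
        ours = rank_sum_test(x, y)
        _, p = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
        assert ours.p_value == pytest.approx(p, abs=1e-12)


def test_rank_sum_large_n_uses_normal_approximation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(19)
    y = rng.standard_normal(19) + 0.8
    res = rank_sum_test(x, y)
    _, p = sstats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    assert res.p_value == pytest.approx(p)
    assert "normal" in res.method


@given(st.integers(0, 1000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_rank_sum_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(7)
    y = rng.standard_normal(6) + 0.3
    p1 = rank_sum_test(x, y).p_value
    p2 = rank_sum_test(np.exp(x), np.exp(y)).p_value  # strictly monotone
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_fdr_hand_computation():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert fdr_adjust([0.37])[0] == pytest.approx(0.37)


@given(st.integers(0, 1000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_fdr_properties(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=12)
    q = fdr_adjust(p)
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p


def test_t_test_cases():
    res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)

    rng = np.random.default_rng(2)
    x = rng.normal(0.0, 1e-6, size=4)
    y = 1.0 + rng.normal(0.0, 1e-6, size=4)
    assert two_sample_t_test(x, y).p_value < 0.01

    # affine invariance
    a = rng.standard_normal(6)
    b = rng.standard_normal(6) + 0.4
    p1 = two_sample_t_test(a, b).p_value
    p2 = two_sample_t_test(3 * a + 7, 3 * b + 7).p_value
    assert p1 == pytest.approx(p2)

    # degenerate zero-variance groups
    assert two_sample_t_test([2, 2], [2, 2]).p_value == 1.0
    assert two_sample_t_test([2, 2], [3, 3]).p_value == 0.0


def test_roc_extremes():
    perfect = roc_auc([1, 2, 3], [10, 11, 12])
    assert perfect.auc == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    v = rng.standard_normal(2000)
    same = roc_auc(v[:1000], v[1000:])
    assert same.auc == pytest.approx(0.5, abs=0.05)


@given(st.integers(0, 1000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_auc_equals_u_statistic(seed):
    """AUC = U/(n1 n2) on arbitrary inputs, including ties."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 12, size=2)
    x = rng.integers(0, 5, size=n1).astype(float)  # heavy ties
    y = rng.integers(0, 5, size=n2).astype(float)
    roc = roc_auc(x, y)
    u1 = rank_sum_test(x, y).statistic if n1 >= 2 and n2 >= 2 else None
    auc1 = u1 / (n1 * n2)
    assert roc.auc == pytest.approx(max(auc1, 1 - auc1), abs=1e-12)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    x = rng.integers(0, 6, size=15).astype(float)
    y = rng.integers(1, 7, size=12).astype(float)
    labels = np.r_[np.ones(15), np.zeros(12)]
    skl = roc_auc_score(labels, np.r_[x, y])
    ours = roc_auc(x, y)
    assert ours.auc == pytest.approx(max(skl, 1 - skl), abs=1e-12)


def test_spearman_hand_values():
    assert clinical_correlation([1, 2, 3, 4], [10, 20, 30, 40]).statistic \
        == pytest.approx(1.0)
    assert clinical_correlation([1, 2, 3, 4], [8, 6, 4, 2]).statistic \
        == pytest.approx(-1.0)
    res = clinical_correlation([1, 2, 3], [2, 1, 3])
    assert res.statistic == pytest.approx(0.5)
    const = clinical_correlation([1, 1, 1], [2, 3, 4])
    assert np.isnan(const.statistic)  # undefined, reported as missing


def _syntax_frame_from_process(proc_g1, proc_g2, n_per_group, seed):
    rows = []
    classes = ["A", "B", "C", "D"]
    s = seed
    for grp, proc in (("g1", proc_g1), ("g2", proc_g2)):
        for i in range(n_per_group):
            s += 1
            labels = simulate_state_sequence(proc, 20.0, 125.0, seed=s)
            seg = Segmentation(labels, 125.0, classes)
            m = compute_metrics(extract_runs(seg), seg,
                                subject_id=f"{grp}_{i}")
            row = {"subject_id": m.subject_id, "group": grp}
            row.update({f"syntax_{k}": v for k, v in m.syntax.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def test_syntax_comparison_identical_groups_not_significant():
    proc = StateProcess.uniform(4, 80.0)
    df = _syntax_frame_from_process(proc, proc, 10, seed=50)
    results = syntax_comparison(df, df["group"], fdr_q=0.01)
    assert len(results) == 12
    assert not any(r.significant for r in results)
    assert all(r.q_value >= r.p_value - 1e-12 for r in results)


def test_syntax_comparison_detects_doubled_transition():
    """Doubling g2's A->B switching probability flags the AB doublet in
    most replicates at n = 19 + 19."""
    tm1 = np.full((4, 4), 1 / 3)
    np.fill_diagonal(tm1, 0.0)
    tm2 = tm1.copy()
    tm2[0] = [0.0, 2 / 3, 1 / 6, 1 / 6]
    p1 = StateProcess(tm1, 80.0)
    p2 = StateProcess(tm2, 80.0)
    hits = 0
    n_rep = 10
    for r in range(n_rep):
        df = _syntax_frame_from_process(p1, p2, 19, seed=1000 * r)
        results = {t.metric_name: t for t in
                   syntax_comparison(df, df["group"], fdr_q=0.01)}
        hits += bool(results["syntax_AB"].significant)
    assert hits >= 0.8 * n_rep


def test_syntax_comparison_input_validation():
    proc = StateProcess.uniform(4, 80.0)
    df = _syntax_frame_from_process(proc, proc, 3, seed=9)
    with pytest.raises(ValueError, match="2 groups"):
        syntax_comparison(df, ["g1"] * len(df))
    df2 = df.copy()
    df2.loc[0, "syntax_AB"] = np.nan
    with pytest.raises(ValueError, match="missing syntax"):
        syntax_comparison(df2, df2["group"])
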