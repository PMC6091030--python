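import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from spongetrace import (
    AnalysisConfig,
    DomainError,
    ExpressionMatrix,
    StateError,
    apply_thresholds,
    average_linkage_cluster,
    bh_adjust,
    differential_expression,
    hypergeometric_enrichment,
    preprocess,
)
from spongetrace.diffexpr import log2fc_from_signed_fc, signed_fc_from_log2fc

from _oracles import oracle_hypergeom_upper_tail, oracle_welch_t


def make_matrix(values, scale="log2", n_case=None):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    n_case = n_case if n_case is not None else n_samp // 2
    samples = [f"s{j}" for j in range(n_samp)]
    groups = {s: ("case" if j < n_case else "ctrl") for j, s in enumerate(samples)}
    return ExpressionMatrix([f"g{i}" for i in range(n_feat)], samples, values, scale, groups)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def test_log2_then_median_centre():
    mat = make_matrix([[2.0, 8.0]], scale="linear")
    out = preprocess(mat, log2=True, median_center_genes=True)
    np.testing.assert_allclose(out.values, [[-1.0, 1.0]])
    assert out.scale == "log2"


def test_median_centring_idempotent():
    rng = np.random.default_rng(0)
    mat = make_matrix(rng.normal(5, 2, (12, 6)))
    once = preprocess(mat, median_center_genes=True)
    twice = preprocess(once, median_center_genes=True)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


def test_row_medians_zero_after_centring():
    rng = np.random.default_rng(1)
    mat = make_matrix(rng.normal(0, 3, (30, 6)))
    out = preprocess(mat, median_center_genes=True)
    np.testing.assert_allclose(np.median(out.values, axis=1), 0.0, atol=1e-12)


def test_log2_state_and_domain_errors():
    with pytest.raises(StateError):
        preprocess(make_matrix([[1.0, 2.0]], scale="log2"), log2=True)
    with pytest.raises(DomainError):
        # bypass the linear-positivity validator to exercise the op's own check
        mat = make_matrix([[1.0, 2.0]], scale="linear")
        mat.values[0, 0] = -1.0
        preprocess(mat, log2=True)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def test_flat_feature_is_null():
    rec = differential_expression(make_matrix([[3.0, 3.0, 3.0, 3.0]]), "case", "ctrl")[0]
    assert rec.log2fc == 0.0 and rec.signed_fc == 1.0 and rec.call == "ns"


def test_down_call_at_minus_2_526_fold():
    """A clean 2.526-fold knockdown reduction is called down."""
    effect = np.log2(2.526)
    base = np.array([[10.0, 10.01, 9.99, 10.0 + effect, 10.01 + effect, 9.99 + effect]])
    rec = differential_expression(make_matrix(base), "case", "ctrl")[0]
    assert rec.call == "down"
    assert rec.signed_fc == pytest.approx(-2.526, abs=1e-3)
    assert rec.q_bh <= 0.05


def test_welch_matches_textbook():
    case, ctrl = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    rec = differential_expression(make_matrix([case + ctrl]), "case", "ctrl")[0]
    t_ref, p_ref, _ = oracle_welch_t(case, ctrl)
    assert rec.t_stat == pytest.approx(t_ref, abs=1e-12)
    assert rec.p_raw == pytest.approx(p_ref, abs=1e-12)
    assert rec.log2fc == pytest.approx(-3.0)


def test_signed_fc_log2fc_bijection():
    for lfc in [-3.2, -1.0, -1e-9, 0.0, 0.3, 2.526, 5.0]:
        sfc = signed_fc_from_log2fc(lfc)
        assert abs(sfc) >= 1.0
        assert log2fc_from_signed_fc(sfc) == pytest.approx(lfc, abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def test_bh_single_p():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_matches_statsmodels_on_random_p():
    rng = np.random.default_rng(42)
    p = rng.uniform(0, 1, 200)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
@settings(max_examples=60, derandomize=True)
def test_bh_monotone_and_bounded(p):
    q = bh_adjust(p)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Threshold gate
# ---------------------------------------------------------------------------

def test_threshold_boundaries(config):
    from spongetrace.diffexpr import DERecord

    near = DERecord("a", np.log2(1.9), 1.9, 5.0, 1e-4, 1e-3, "ns")
    edge = DERecord("b", 1.0, 2.0, 5.0, 1e-4, 0.05, "up")
    up, down = apply_thresholds([near, edge], config)
    assert [r.feature_id for r in up] == ["b"] and down == []


def test_planted_counts_recovered_exactly():
    rng = np.random.default_rng(8)
    base = rng.uniform(6, 10, size=30)
    effects = np.array([2.0] * 10 + [-2.0] * 5 + [0.0] * 15)  # |FC| = 4 planted
    vals = base[:, None] + np.where(np.arange(6) < 3, effects[:, None], 0.0)
    recs = differential_expression(make_matrix(vals), "case", "ctrl")
    up, down = apply_thresholds(recs)
    assert (len(up), len(down)) == (10, 5)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_identical_rows_merge_at_zero():
    mat = make_matrix([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
    dend = average_linkage_cluster(mat, axis="features")
    assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)


def test_three_leaf_upgma_matches_hand_computation():
    rows = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [1.0, 2.0, 3.0, 5.0],
        [4.0, 2.0, 1.0, -1.0],
    ])
    d = lambda a, b: 1.0 - np.corrcoef(rows[a], rows[b])[0, 1]
    d01, d02, d12 = d(0, 1), d(0, 2), d(1, 2)
    # closest pair is (0,1); it then joins leaf 2 at the average distance
    assert d01 < min(d02, d12)
    dend = average_linkage_cluster(make_matrix(rows), axis="features")
    assert sorted(dend.merges[0, :2]) == [0, 1]
    assert dend.heights[0] == pytest.approx(d01)
    assert dend.heights[1] == pytest.approx((d02 + d12) / 2.0)


def test_merge_count_and_monotone_heights():
    rng = np.random.default_rng(2)
    mat = make_matrix(rng.normal(0, 1, (14, 8)))
    dend = average_linkage_cluster(mat, axis="features")
    assert dend.merges.shape[0] == 13
    assert np.all(np.diff(dend.heights) >= -1e-12)


def test_constant_row_is_named():
    mat = make_matrix([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
    with pytest.raises(DomainError, match="g0"):
        average_linkage_cluster(mat, axis="features")


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def test_enrichment_edge_cases():
    bg = [f"g{i}" for i in range(20)]
    de = bg[:5]
    recs = hypergeometric_enrichment(de, bg, {"all": bg, "none": bg[10:15]})
    by_id = {r.set_id: r for r in recs}
    assert by_id["all"].p_hyper == pytest.approx(1.0)  # set == background
    assert by_id["none"].overlap_count == 0
    assert by_id["none"].p_hyper == pytest.approx(1.0)  # P(X >= 0) = 1


def test_enrichment_exact_combinatorial_case():
    bg = [f"g{i}" for i in range(20)]
    de = bg[:5]
    rec = hypergeometric_enrichment(de, bg, {"hit": de})[0]
    assert rec.p_hyper == pytest.approx(1.0 / 15504.0, rel=1e-9)
    assert rec.p_hyper == pytest.approx(oracle_hypergeom_upper_tail(5, 20, 5, 5), rel=1e-12)


def test_enrichment_validates_inputs():
    from spongetrace import ValidationError

    with pytest.raises(ValidationError):
        hypergeometric_enrichment(["x"], ["a", "b"], {})
    with pytest.raises(ValidationError):
        hypergeometric_enrichment([], [], {})


# ---------------------------------------------------------------------------
# Statistical calibration properties
# ---------------------------------------------------------------------------

def test_null_false_discovery_proportion_controlled():
    """With no planted signal the realised FDP at q <= 0.05 stays near nominal."""
    rng = np.random.default_rng(123)
    fdps = []
    for _ in range(20):
        vals = rng.normal(8.0, 0.25, size=(1000, 6))
        recs = differential_expression(make_matrix(vals), "case", "ctrl")
        n_disc = sum(r.q_bh <= 0.05 for r in recs)
        fdps.append(1.0 if n_disc > 0 else 0.0)  # every discovery is false
    mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps)) if np.std(fdps) > 0 else 0.05
    assert np.mean(fdps) <= 0.05 + 3 * max(mc_se, 0.05)


def test_planted_de_sensitivity():
    """|log2FC| = 2 effects at noise SD 0.25, n = 3/group: sensitivity >= 0.9."""
    rng = np.random.default_rng(7)
    n_true, n_null = 100, 400
    base = rng.uniform(6, 10, size=n_true + n_null)
    effects = np.array([2.0] * n_true + [0.0] * n_null)
    signs = rng.choice([1.0, -1.0], size=n_true + n_null)
    vals = (
        base[:, None]
        + np.where(np.arange(6) < 3, (effects * signs)[:, None], 0.0)
        + rng.normal(0, 0.25, size=(n_true + n_null, 6))
    )
    recs = differential_expression(make_matrix(vals), "case", "ctrl")
    hit = sum(r.call != "ns" for r in recs[:n_true])
    assert hit / n_true >= 0.9
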