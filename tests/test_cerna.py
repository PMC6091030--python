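import itertools
import json

import numpy as np
import pytest

from spongetrace import (
    ContractError,
    ConventionError,
    ValidationError,
    build_network,
    check_direction_consistency,
    export_network,
    load_network,
    select_sponged_mirnas,
    select_target_mrnas,
)
from spongetrace.cerna import CeRNATriplet
from spongetrace.diffexpr import DERecord
from spongetrace.mre import DuplexAlignment, MRESite, sites_to_table

from _oracles import oracle_consistency, oracle_sponged


def de(feature_id, call, fc=None):
    fc = fc if fc is not None else {"up": 3.0, "down": -3.0, "ns": 1.1}[call]
    lfc = np.log2(abs(fc)) * (1 if fc > 0 else -1)
    return DERecord(feature_id, lfc, fc, 4.0, 0.001, 0.01 if call != "ns" else 0.9, call)


def site(mirna_id, target_id, start=10, score=145.0, energy=-50.0):
    aln = DuplexAlignment(score, energy, "", "", "", (1, 22), (start, start + 22))
    return MRESite(mirna_id, target_id, start, start + 22, aln, True)


# ---------------------------------------------------------------------------
# miRNA selection (sponge logic)
# ---------------------------------------------------------------------------

def test_sponged_selection_truth_table():
    """Selected iff the miRNA has an MRE and moves opposite to the lncRNA."""
    for lnc_sign, mir_call, has_mre in itertools.product(
        ["up", "down"], ["up", "down", "ns"], [True, False]
    ):
        table = sites_to_table([site("mir1", "lnc")] if has_mre else [])
        got = select_sponged_mirnas(table, [de("mir1", mir_call)], lnc_sign)
        assert (got == ["mir1"]) == oracle_sponged(lnc_sign, mir_call, has_mre)


def test_sponged_selection_requires_de_lncrna():
    with pytest.raises(ValidationError):
        select_sponged_mirnas(sites_to_table([]), [], "ns")


# ---------------------------------------------------------------------------
# mRNA selection
# ---------------------------------------------------------------------------

def test_target_selection_patterns():
    table = sites_to_table([site("mir1", m) for m in ("m_good", "m_ns", "m_disc")])
    kd = [de("m_good", "down"), de("m_ns", "ns"), de("m_disc", "down"), de("m_no_site", "down")]
    disease = [de("m_good", "up"), de("m_disc", "down"), de("m_no_site", "up")]
    strict = select_target_mrnas(
        table, kd, disease, lnc_disease_sign="up", lnc_kd_sign="down",
        require_disease_mrna_concordance=True,
    )
    assert strict == ["m_good"]
    loose = select_target_mrnas(
        table, kd, disease, lnc_disease_sign="up", lnc_kd_sign="down",
        require_disease_mrna_concordance=False,
    )
    assert set(strict) <= set(loose)
    assert "m_ns" not in loose  # not DE on knockdown
    assert "m_no_site" not in loose  # not a predicted target


def test_concordance_filter_is_a_subset_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(25):
        mrnas = [f"m{i}" for i in range(12)]
        table = sites_to_table(
            [site("mir1", m) for m in mrnas if rng.random() < 0.7]
        )
        calls = ["up", "down", "ns"]
        kd = [de(m, calls[rng.integers(3)]) for m in mrnas]
        disease = [de(m, calls[rng.integers(3)]) for m in mrnas]
        kwargs = dict(lnc_disease_sign="up", lnc_kd_sign="down")
        on = select_target_mrnas(table, kd, disease, require_disease_mrna_concordance=True, **kwargs)
        off = select_target_mrnas(table, kd, disease, require_disease_mrna_concordance=False, **kwargs)
        assert set(on) <= set(off)


# ---------------------------------------------------------------------------
# Direction consistency
# ---------------------------------------------------------------------------

def test_reported_three_dataset_pattern_is_consistent():
    """The reference sponge pattern: lncRNA +3.11 / miRNA -2.27 (disease),
    mRNA +2.02 (disease), lncRNA -2.52 / mRNA -3.09 (knockdown)."""
    assert check_direction_consistency(3.11, -2.27, -3.09,
                                       fc_mrna_disease=2.02, fc_lnc_kd=-2.52)


def test_mirna_not_opposite_is_inconsistent():
    assert not check_direction_consistency(3.11, 2.27, -3.09)


def test_consistency_matches_boolean_oracle_exhaustively():
    for signs in itertools.product([1, -1], repeat=5):
        s_lnc, s_mir, s_mrna_kd, s_mrna_dis, s_lnc_kd = signs
        got = check_direction_consistency(
            2.0 * s_lnc, 2.0 * s_mir, 2.0 * s_mrna_kd,
            fc_mrna_disease=2.0 * s_mrna_dis, fc_lnc_kd=2.0 * s_lnc_kd,
        )
        want = oracle_consistency(
            {"lnc_dis": s_lnc, "mir_dis": s_mir, "mrna_kd": s_mrna_kd,
             "mrna_dis": s_mrna_dis, "lnc_kd": s_lnc_kd}
        )
        assert got == want
    # optional arguments omitted: only the lncRNA/miRNA opposition matters
    for s_lnc, s_mir, s_kd in itertools.product([1, -1], repeat=3):
        got = check_direction_consistency(2.0 * s_lnc, 2.0 * s_mir, 2.0 * s_kd)
        assert got == oracle_consistency({"lnc_dis": s_lnc, "mir_dis": s_mir, "mrna_kd": s_kd})


def test_sub_unit_fold_change_is_a_convention_error():
    with pytest.raises(ConventionError):
        check_direction_consistency(0.5, -2.0, -2.0)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def make_triplet(lnc="lnc1", mir="mir1", mrna="m1", consistent=True):
    fc_mir = -2.27 if consistent else 2.27
    return CeRNATriplet(
        lnc, mir, mrna,
        fc_lnc_disease=3.11, fc_mir_disease=fc_mir, fc_lnc_kd=-2.52,
        fc_mrna_kd=-3.09, fc_mrna_disease=2.02,
        mre_lnc=(site(mir, lnc),), mre_utr=(site(mir, mrna),),
        consistent=consistent,
    )


def test_single_triplet_network_shape():
    net = build_network([make_triplet()])
    assert (net.n_nodes, net.n_edges) == (3, 5)
    d = net.to_dict()
    assert {e["type"] for e in d["edges"]} == {
        "sequence_match", "positive_correlation", "negative_correlation"
    }


def test_shared_lncrna_networks_deduplicate():
    t1 = make_triplet(mrna="m1")
    t2 = make_triplet(mrna="m2")
    net = build_network([t1, t2])
    assert net.n_nodes == 4  # lnc, mir shared; two mRNAs
    # lnc-mir edges shared: 5 + 5 - 2 shared (sequence_match + negative corr)
    assert net.n_edges == 8


def test_inconsistent_triplet_rejected_by_builder():
    with pytest.raises(ContractError):
        build_network([make_triplet(consistent=False)])


def test_edge_type_constraints_hold_structurally():
    rng = np.random.default_rng(5)
    triplets = [
        make_triplet(mir=f"mir{rng.integers(3)}", mrna=f"m{rng.integers(5)}")
        for _ in range(10)
    ]
    net = build_network(triplets)
    classes = {n["id"]: n["class"] for n in net.to_dict()["nodes"]}
    for e in net.to_dict()["edges"]:
        pair = {classes[e["source"]], classes[e["target"]]}
        if e["type"] == "sequence_match":
            assert pair in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"})
        if e["type"] == "positive_correlation":
            assert pair == {"lncRNA", "mRNA"}
        if e["type"] == "negative_correlation":
            assert "miRNA" in {classes[e["source"]], classes[e["target"]]}
        assert e["source"] != e["target"]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def test_empty_network_export(tmp_path):
    from spongetrace.cerna import CeRNANetwork

    p = tmp_path / "net.json"
    export_network(CeRNANetwork(), p)
    assert json.loads(p.read_text()) == {"nodes": [], "edges": []}


def test_network_round_trip(tmp_path):
    net = build_network([make_triplet()])
    p = tmp_path / "net.json"
    export_network(net, p)
    assert load_network(p) == net


def test_node_order_is_lexicographic(tmp_path):
    net = build_network([make_triplet(lnc="z_lnc", mir="a_mir", mrna="m_m")])
    p = tmp_path / "net.json"
    export_network(net, p)
    ids = [n["id"] for n in json.loads(p.read_text())["nodes"]]
    assert ids == sorted(ids)
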