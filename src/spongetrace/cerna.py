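"""ceRNA triplet selection and typed network construction.

The sponge model: an up-regulated lncRNA sequesters miRNAs through its
MREs, de-repressing those miRNAs' mRNA targets.  Integration therefore
demands direction consistency across three datasets — the lncRNA and the
miRNA must move in opposite directions in the disease data, and the mRNA
must follow the lncRNA both in the knockdown data and (optionally) in the
disease data.

The resulting network has typed edges: ``sequence_match`` for predicted
binding (lncRNA–miRNA, miRNA–mRNA), ``negative_correlation`` for the
miRNA's repressive relations, and ``positive_correlation`` for the
lncRNA–mRNA co-expression the sponge model implies.  Edge types are
asserted from the model, not recomputed from expression; empirical
correlation lives in the qPCR validation module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .datamodel import ContractError, ConventionError, ValidationError
from .diffexpr import DERecord
from .mre import MRESite

__all__ = [
    "CeRNATriplet",
    "CeRNANetwork",
    "EDGE_TYPES",
    "select_sponged_mirnas",
    "select_target_mrnas",
    "check_direction_consistency",
    "build_triplets",
    "build_network",
    "export_network",
    "load_network",
    "TRIPLET_TABLE_SCHEMA",
]

EDGE_TYPES = ("sequence_match", "positive_correlation", "negative_correlation")

TRIPLET_TABLE_SCHEMA = [
    "lncrna_id",
    "mirna_id",
    "mrna_id",
    "fc_lnc_disease",
    "fc_mir_disease",
    "fc_mrna_disease",
    "fc_lnc_kd",
    "fc_mrna_kd",
    "n_mre_lnc",
    "n_mre_utr",
    "consistent",
]


def _sign(fc: float, name: str) -> int:
    if abs(fc) < 1.0:
        raise ConventionError(
            f"{name}: signed fold change must satisfy |fc| >= 1, got {fc}"
        )
    return 1 if fc > 0 else -1


@dataclass(frozen=True)
class CeRNATriplet:
    """A lncRNA–miRNA–mRNA candidate with its cross-dataset fold changes."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    fc_lnc_disease: float
    fc_mir_disease: float
    fc_lnc_kd: float
    fc_mrna_kd: float
    fc_mrna_disease: float | None
    mre_lnc: tuple[MRESite, ...]
    mre_utr: tuple[MRESite, ...]
    consistent: bool

    def __post_init__(self) -> None:
        if not self.mre_lnc or not self.mre_utr:
            raise ValidationError(
                "an emitted triplet requires MRE evidence on both the lncRNA "
                "and the mRNA 3'UTR"
            )
        expected = check_direction_consistency(
            self.fc_lnc_disease,
            self.fc_mir_disease,
            self.fc_mrna_kd,
            fc_mrna_disease=self.fc_mrna_disease,
            fc_lnc_kd=self.fc_lnc_kd,
        )
        if self.consistent != expected:
            raise ValidationError(
                "consistency flag does not match check_direction_consistency"
            )


# ---------------------------------------------------------------------------
# Selection filters
# ---------------------------------------------------------------------------

def select_sponged_mirnas(
    lnc_site_table: pd.DataFrame,
    mirna_de: Sequence[DERecord],
    lnc_sign: str,
) -> list[str]:
    """miRNAs with >= 1 passing MRE on the lncRNA and a DE call opposite to it.

    ``lnc_site_table`` is an interaction table restricted to the focal
    lncRNA (columns mirna_id/target_id at minimum); ``lnc_sign`` is the
    lncRNA's disease call ("up" or "down").
    """
    if lnc_sign not in ("up", "down"):
        raise ValidationError(
            f"focal lncRNA must be differentially expressed (up/down), got {lnc_sign!r}"
        )
    opposite = "down" if lnc_sign == "up" else "up"
    with_mre = set(lnc_site_table["mirna_id"]) if len(lnc_site_table) else set()
    calls = {r.feature_id: r.call for r in mirna_de}
    return sorted(m for m in with_mre if calls.get(m) == opposite)


def select_target_mrnas(
    interaction_table: pd.DataFrame,
    kd_de: Sequence[DERecord],
    disease_de: Sequence[DERecord],
    *,
    lnc_disease_sign: str,
    lnc_kd_sign: str = "down",
    require_disease_mrna_concordance: bool = True,
) -> list[str]:
    """mRNAs targeted by a selected miRNA and differentially expressed on knockdown.

    With the concordance flag set, the mRNA must additionally follow the
    lncRNA in both datasets: its knockdown call equals ``lnc_kd_sign`` and
    its disease call equals ``lnc_disease_sign``.
    """
    targeted = set(interaction_table["target_id"]) if len(interaction_table) else set()
    kd_calls = {r.feature_id: r.call for r in kd_de}
    dis_calls = {r.feature_id: r.call for r in disease_de}
    out = []
    for mrna in targeted:
        kd_call = kd_calls.get(mrna, "ns")
        if kd_call == "ns":
            continue
        if require_disease_mrna_concordance:
            if kd_call != lnc_kd_sign or dis_calls.get(mrna, "ns") != lnc_disease_sign:
                continue
        out.append(mrna)
    return sorted(out)


def check_direction_consistency(
    fc_lnc_disease: float,
    fc_mir_disease: float,
    fc_mrna_kd: float,
    fc_mrna_disease: float | None = None,
    fc_lnc_kd: float | None = None,
) -> bool:
    """True iff the fold-change signs fit the sponge model.

    Required: the lncRNA and miRNA move oppositely in the disease data.
    When given: the mRNA follows the lncRNA in the knockdown data, and the
    mRNA follows the lncRNA in the disease data.
    """
    s_lnc = _sign(fc_lnc_disease, "fc_lnc_disease")
    s_mir = _sign(fc_mir_disease, "fc_mir_disease")
    s_mrna_kd = _sign(fc_mrna_kd, "fc_mrna_kd")
    if s_lnc != -s_mir:
        return False
    if fc_lnc_kd is not None:
        if s_mrna_kd != _sign(fc_lnc_kd, "fc_lnc_kd"):
            return False
    if fc_mrna_disease is not None:
        if _sign(fc_mrna_disease, "fc_mrna_disease") != s_lnc:
            return False
    return True


def build_triplets(
    lncrna_id: str,
    selected_mirnas: Sequence[str],
    selected_mrnas: Sequence[str],
    lnc_sites: Sequence[MRESite],
    utr_sites: Sequence[MRESite],
    disease_de: Mapping[str, DERecord],
    mirna_de: Mapping[str, DERecord],
    kd_de: Mapping[str, DERecord],
) -> list[CeRNATriplet]:
    """Assemble candidate triplets from the selection results.

    Every (selected miRNA, selected mRNA) pair with MRE evidence on both
    the lncRNA and the mRNA 3'UTR becomes a triplet carrying its five
    fold changes and a direction-consistency flag.
    """
    if lncrna_id not in disease_de:
        raise ValidationError(f"focal lncRNA {lncrna_id!r} absent from disease DE")
    if lncrna_id not in kd_de:
        raise ValidationError(f"focal lncRNA {lncrna_id!r} absent from knockdown DE")
    lnc_sites_by_mir: dict[str, list[MRESite]] = {}
    for s in lnc_sites:
        if s.target_id == lncrna_id:
            lnc_sites_by_mir.setdefault(s.mirna_id, []).append(s)
    utr_sites_by_pair: dict[tuple[str, str], list[MRESite]] = {}
    for s in utr_sites:
        utr_sites_by_pair.setdefault((s.mirna_id, s.target_id), []).append(s)

    triplets = []
    for mir in selected_mirnas:
        for mrna in selected_mrnas:
            mre_lnc = lnc_sites_by_mir.get(mir, [])
            mre_utr = utr_sites_by_pair.get((mir, mrna), [])
            if not mre_lnc or not mre_utr:
                continue
            fc_mrna_dis = (
                disease_de[mrna].signed_fc if mrna in disease_de else None
            )
            consistent = check_direction_consistency(
                disease_de[lncrna_id].signed_fc,
                mirna_de[mir].signed_fc,
                kd_de[mrna].signed_fc,
                fc_mrna_disease=fc_mrna_dis,
                fc_lnc_kd=kd_de[lncrna_id].signed_fc,
            )
            triplets.append(
                CeRNATriplet(
                    lncrna_id,
                    mir,
                    mrna,
                    fc_lnc_disease=disease_de[lncrna_id].signed_fc,
                    fc_mir_disease=mirna_de[mir].signed_fc,
                    fc_lnc_kd=kd_de[lncrna_id].signed_fc,
                    fc_mrna_kd=kd_de[mrna].signed_fc,
                    fc_mrna_disease=fc_mrna_dis,
                    mre_lnc=tuple(mre_lnc),
                    mre_utr=tuple(mre_utr),
                    consistent=consistent,
                )
            )
    return triplets


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class CeRNANetwork:
    """Typed undirected multigraph of lncRNA/miRNA/mRNA relations.

    Backed by a :class:`networkx.MultiGraph` whose edge keys are the edge
    types, which structurally forbids duplicate (source, target, type).
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, node_id: str, molecule_class: str) -> None:
        existing = self.graph.nodes.get(node_id)
        if existing and existing["molecule_class"] != molecule_class:
            raise ValidationError(
                f"node {node_id!r} already present with class "
                f"{existing['molecule_class']!r}"
            )
        self.graph.add_node(node_id, molecule_class=molecule_class)

    def add_edge(self, source: str, target: str, edge_type: str, evidence) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValidationError(f"unknown edge type {edge_type!r}")
        if source == target:
            raise ValidationError(f"self-edge on {source!r}")
        if edge_type == "sequence_match":
            classes = {
                self.graph.nodes[source]["molecule_class"],
                self.graph.nodes[target]["molecule_class"],
            }
            if classes not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
                raise ValidationError(
                    "sequence_match edges connect only lncRNA-miRNA or miRNA-mRNA"
                )
        if self.graph.has_edge(source, target, key=edge_type):
            old = self.graph.edges[source, target, edge_type]["evidence"]
            merged = sorted(set(old) | set(evidence))
            self.graph.edges[source, target, edge_type]["evidence"] = merged
        else:
            self.graph.add_edge(
                source, target, key=edge_type, evidence=sorted(set(evidence))
            )

    def to_dict(self) -> dict:
        nodes = [
            {"id": n, "class": d["molecule_class"]}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        edges = []
        for u, v, key, d in self.graph.edges(keys=True, data=True):
            a, b = sorted((u, v))
            edges.append(
                {"source": a, "target": b, "type": key, "evidence": list(d["evidence"])}
            )
        edges.sort(key=lambda e: (e["source"], e["target"], e["type"]))
        return {"nodes": nodes, "edges": edges}

    def __eq__(self, other) -> bool:
        return isinstance(other, CeRNANetwork) and self.to_dict() == other.to_dict()


def _site_evidence(site: MRESite) -> str:
    # 1-based inclusive interval in rendered evidence
    return (
        f"{site.mirna_id}@{site.target_id}:{site.start + 1}-{site.end}"
        f"(S={site.alignment.score:g},E={site.alignment.energy:g})"
    )


def build_network(triplets: Sequence[CeRNATriplet]) -> CeRNANetwork:
    """Typed network from consistent triplets (5 edges per triplet, deduplicated).

    Per triplet: sequence_match lncRNA–miRNA and miRNA–mRNA (carrying the
    MRE site evidence), negative_correlation miRNA–lncRNA and miRNA–mRNA,
    positive_correlation lncRNA–mRNA.
    """
    net = CeRNANetwork()
    for t in triplets:
        if not t.consistent:
            raise ContractError(
                f"inconsistent triplet ({t.lncrna_id}, {t.mirna_id}, {t.mrna_id}) "
                "passed to build_network"
            )
        net.add_node(t.lncrna_id, "lncRNA")
        net.add_node(t.mirna_id, "miRNA")
        net.add_node(t.mrna_id, "mRNA")
        lnc_ev = [_site_evidence(s) for s in t.mre_lnc]
        utr_ev = [_site_evidence(s) for s in t.mre_utr]
        model_ev = [f"sponge model: {t.lncrna_id}-{t.mirna_id}-{t.mrna_id}"]
        net.add_edge(t.lncrna_id, t.mirna_id, "sequence_match", lnc_ev)
        net.add_edge(t.mirna_id, t.mrna_id, "sequence_match", utr_ev)
        net.add_edge(t.mirna_id, t.lncrna_id, "negative_correlation", model_ev)
        net.add_edge(t.mirna_id, t.mrna_id, "negative_correlation", model_ev)
        net.add_edge(t.lncrna_id, t.mrna_id, "positive_correlation", model_ev)
    return net


def export_network(network: CeRNANetwork, path) -> None:
    """Write the network as deterministic JSON (nodes sorted by id)."""
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh, indent=2, sort_keys=False)
        fh.write("\n")


def load_network(path) -> CeRNANetwork:
    with open(path) as fh:
        data = json.load(fh)
    net = CeRNANetwork()
    for node in data["nodes"]:
        net.add_node(node["id"], node["class"])
    for edge in data["edges"]:
        net.add_edge(edge["source"], edge["target"], edge["type"], edge["evidence"])
    return net


def triplets_to_records(triplets: Sequence[CeRNATriplet]) -> list[dict]:
    """Rows for the triplet summary table (three-dataset fold-change layout)."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "fc_lnc_disease": t.fc_lnc_disease,
                "fc_mir_disease": t.fc_mir_disease,
                "fc_mrna_disease": "" if t.fc_mrna_disease is None else t.fc_mrna_disease,
                "fc_lnc_kd": t.fc_lnc_kd,
                "fc_mrna_kd": t.fc_mrna_kd,
                "n_mre_lnc": len(t.mre_lnc),
                "n_mre_utr": len(t.mre_utr),
                "consistent": t.consistent,
            }
        )
    return rows
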