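"""End-to-end orchestration: three DE analyses + MRE scans -> sponge network.

Stage order mirrors the integration design: preprocess and call
differential expression on the disease lncRNA+mRNA, disease miRNA and
knockdown datasets; scan every miRNA against the focal lncRNA; keep
miRNAs with a binding site whose disease direction opposes the lncRNA;
scan the kept miRNAs against the mRNA 3'UTRs; keep target mRNAs that
respond to the knockdown (and, by default, follow the lncRNA in the
disease data); assemble direction-consistent triplets and the typed
network; optionally attach qPCR and luciferase validation statistics.

Every filter is logged with before/after counts, and the machine-readable
report echoes the effective configuration so a run is reproducible from
its own output.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import (
    AnalysisConfig,
    ExpressionMatrix,
    SequenceRecord,
    ValidationError,
    write_results_table,
)
from .diffexpr import DE_TABLE_SCHEMA, DERecord, differential_expression, preprocess
from .mre import MRESite, predict_sites, sites_to_table, SITE_TABLE_SCHEMA
from .cerna import (
    build_network,
    build_triplets,
    export_network,
    select_sponged_mirnas,
    select_target_mrnas,
    triplets_to_records,
    TRIPLET_TABLE_SCHEMA,
)
from .qpcr import correlate_pairs, group_comparison, luciferase_analysis, relative_quantities
from .synthetic import SyntheticBundle

__all__ = ["PipelineInputs", "PipelineReport", "run_pipeline", "inputs_from_bundle"]

logger = logging.getLogger("spongetrace")


@dataclass
class PipelineInputs:
    """All inputs of one pipeline run."""

    disease_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    kd_expr: ExpressionMatrix
    mirnas: list[SequenceRecord]
    lncrna: SequenceRecord
    utrs: list[SequenceRecord]
    focal_lncrna_id: str
    disease_case: str = "PCOS"
    disease_control: str = "control"
    kd_case: str = "knockdown"
    kd_control: str = "control"
    ct_table: pd.DataFrame | None = None
    ct_calibrator_group: str | None = None
    luciferase_table: pd.DataFrame | None = None


def inputs_from_bundle(bundle: SyntheticBundle) -> PipelineInputs:
    from .synthetic import (
        DISEASE_CASE, DISEASE_CONTROL, KD_CASE, KD_CONTROL, QPCR_GROUP_MATURE,
    )

    return PipelineInputs(
        disease_expr=bundle.disease_expr,
        mirna_expr=bundle.mirna_expr,
        kd_expr=bundle.kd_expr,
        mirnas=bundle.mirnas,
        lncrna=bundle.lncrna,
        utrs=bundle.utrs,
        focal_lncrna_id=bundle.truth["lncrna_id"],
        disease_case=DISEASE_CASE,
        disease_control=DISEASE_CONTROL,
        kd_case=KD_CASE,
        kd_control=KD_CONTROL,
        ct_table=bundle.ct_table,
        ct_calibrator_group=QPCR_GROUP_MATURE,
        luciferase_table=bundle.luciferase_table,
    )


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    counts: dict = field(default_factory=dict)
    network_summary: dict = field(default_factory=dict)
    triplets: list = field(default_factory=list)
    validation: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "network_summary": self.network_summary,
                "triplets": self.triplets,
                "validation": self.validation,
                "config": self.config,
                "version": self.version,
                "started": self.started,
                "finished": self.finished,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        return cls(**json.loads(text))


def _de_dict(records: list[DERecord]) -> dict[str, DERecord]:
    return {r.feature_id: r for r in records}


def _de_rows(records: list[DERecord]) -> list[dict]:
    return [
        {
            "feature_id": r.feature_id,
            "log2fc": r.log2fc,
            "signed_fc": r.signed_fc,
            "t": r.t_stat,
            "p": r.p_raw,
            "q": r.q_bh,
            "call": r.call,
        }
        for r in records
    ]


def _site_rows(sites: list[MRESite]) -> list[dict]:
    return [
        {
            "mirna_id": s.mirna_id,
            "target_id": s.target_id,
            "start_1based": s.start + 1,
            "end_1based": s.end,
            "score": s.alignment.score,
            "energy": s.alignment.energy,
        }
        for s in sites
    ]


def _ensure_log2(matrix: ExpressionMatrix, name: str) -> ExpressionMatrix:
    if matrix.scale == "linear":
        logger.info("%s: log2-transforming linear matrix", name)
        return preprocess(matrix, log2=True)
    return matrix


def run_pipeline(
    config: AnalysisConfig | None,
    inputs: PipelineInputs,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Execute all stages; optionally write every intermediate artifact."""
    config = config or AnalysisConfig()
    report = PipelineReport(config=config.to_dict())
    report.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    counts = report.counts

    # --- differential expression on the three datasets
    disease_de = differential_expression(
        _ensure_log2(inputs.disease_expr, "disease"), inputs.disease_case,
        inputs.disease_control, config,
    )
    mirna_de = differential_expression(
        _ensure_log2(inputs.mirna_expr, "miRNA"), inputs.disease_case,
        inputs.disease_control, config,
    )
    kd_de = differential_expression(
        _ensure_log2(inputs.kd_expr, "knockdown"), inputs.kd_case,
        inputs.kd_control, config,
    )
    for name, de in (("disease", disease_de), ("mirna", mirna_de), ("kd", kd_de)):
        counts[f"de_{name}_features"] = len(de)
        counts[f"de_{name}_up"] = sum(r.call == "up" for r in de)
        counts[f"de_{name}_down"] = sum(r.call == "down" for r in de)
        logger.info(
            "DE %s: %d features, %d up / %d down",
            name, len(de), counts[f"de_{name}_up"], counts[f"de_{name}_down"],
        )

    disease_map, mirna_map, kd_map = _de_dict(disease_de), _de_dict(mirna_de), _de_dict(kd_de)
    focal = inputs.focal_lncrna_id
    if focal not in disease_map:
        raise ValidationError(f"focal lncRNA {focal!r} absent from the disease dataset")
    if focal not in kd_map:
        raise ValidationError(f"focal lncRNA {focal!r} absent from the knockdown dataset")
    lnc_sign = disease_map[focal].call
    if lnc_sign == "ns":
        raise ValidationError(
            f"focal lncRNA {focal!r} is not differentially expressed in the disease data"
        )
    lnc_kd_call = kd_map[focal].call
    if lnc_kd_call == "ns":
        raise ValidationError(
            f"focal lncRNA {focal!r} shows no knockdown response; the knockdown "
            "dataset cannot inform target selection"
        )

    # --- MRE scan of every miRNA against the focal lncRNA
    lnc_sites = predict_sites(inputs.mirnas, [inputs.lncrna], config)
    counts["lnc_mre_sites"] = len(lnc_sites)
    counts["mirnas_with_mre"] = len({s.mirna_id for s in lnc_sites})
    logger.info(
        "MRE scan: %d sites on %s from %d of %d miRNAs",
        len(lnc_sites), focal, counts["mirnas_with_mre"], len(inputs.mirnas),
    )

    # --- sponge-candidate miRNAs: binding site + opposite disease direction
    selected_mirnas = select_sponged_mirnas(sites_to_table(lnc_sites), mirna_de, lnc_sign)
    counts["selected_mirnas"] = len(selected_mirnas)
    logger.info(
        "sponged-miRNA filter: %d -> %d", counts["mirnas_with_mre"], len(selected_mirnas)
    )

    # --- target scan of the selected miRNAs against all 3'UTRs
    kept = [m for m in inputs.mirnas if m.seq_id in selected_mirnas]
    utr_sites = predict_sites(kept, inputs.utrs, config)
    counts["utr_mre_sites"] = len(utr_sites)
    counts["predicted_target_mrnas"] = len({s.target_id for s in utr_sites})
    selected_mrnas = select_target_mrnas(
        sites_to_table(utr_sites), kd_de, disease_de,
        lnc_disease_sign=lnc_sign,
        lnc_kd_sign=lnc_kd_call,
        require_disease_mrna_concordance=config.require_disease_mrna_concordance,
    )
    counts["selected_mrnas"] = len(selected_mrnas)
    logger.info(
        "target-mRNA filter: %d -> %d", counts["predicted_target_mrnas"], len(selected_mrnas)
    )

    # --- triplets and network
    triplets = build_triplets(
        focal, selected_mirnas, selected_mrnas, lnc_sites, utr_sites,
        disease_map, mirna_map, kd_map,
    )
    consistent = [t for t in triplets if t.consistent]
    counts["candidate_triplets"] = len(triplets)
    counts["consistent_triplets"] = len(consistent)
    logger.info("triplets: %d candidates, %d consistent", len(triplets), len(consistent))
    network = build_network(consistent)
    report.network_summary = {"n_nodes": network.n_nodes, "n_edges": network.n_edges}
    report.triplets = triplets_to_records(consistent)

    # --- optional wet-lab-style validation statistics
    if inputs.ct_table is not None:
        report.validation["qpcr"] = _qpcr_validation(
            inputs.ct_table, inputs.ct_calibrator_group, focal,
            consistent,
        )
    if inputs.luciferase_table is not None:
        luc = luciferase_analysis(inputs.luciferase_table)
        report.validation["luciferase"] = {
            "relative_activity": luc.relative_activity,
            "percent_change": luc.percent_change,
            "p_values": luc.p_values,
            "interaction_call": luc.interaction_call,
        }

    report.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()

    if outdir is not None:
        _write_artifacts(
            Path(outdir), report, disease_de, mirna_de, kd_de,
            lnc_sites, utr_sites, consistent, network,
        )
    return report


def _qpcr_validation(ct_table, calibrator, focal, consistent_triplets) -> dict:
    groups = sorted(ct_table["group"].unique())
    calibrator = calibrator or groups[0]
    rqs = relative_quantities(ct_table, calibrator)
    out: dict = {"calibrator_group": calibrator, "comparisons": {}}
    if len(groups) == 2:
        a, b = groups
        for gene, sub in rqs.groupby("gene_id", sort=True):
            cmp = group_comparison(sub, a, b)
            out["comparisons"][str(gene)] = {
                "group_a": cmp.group_a,
                "group_b": cmp.group_b,
                "mean_a": cmp.mean_a,
                "sem_a": cmp.sem_a,
                "mean_b": cmp.mean_b,
                "sem_b": cmp.sem_b,
                "fold_ratio": cmp.fold_ratio,
                "direction": cmp.direction,
                "p": cmp.p_two_tailed,
            }
    # co-expression of the focal lncRNA with each partner mRNA
    mrnas = {t.mrna_id for t in consistent_triplets}
    by_gene = {g: sub.set_index("sample_id")["rq"] for g, sub in rqs.groupby("gene_id")}
    if focal in by_gene:
        for mrna in sorted(mrnas & set(by_gene)):
            paired = pd.concat([by_gene[focal], by_gene[mrna]], axis=1, join="inner")
            if len(paired) >= 3:
                r, p = correlate_pairs(paired.iloc[:, 0], paired.iloc[:, 1])
                out.setdefault("coexpression", {})[f"{focal}~{mrna}"] = {"r": r, "p": p}
    return out


def _write_artifacts(
    outdir: Path, report, disease_de, mirna_de, kd_de, lnc_sites, utr_sites,
    consistent, network,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_results_table(_de_rows(disease_de), outdir / "de_disease.tsv", DE_TABLE_SCHEMA)
    write_results_table(_de_rows(mirna_de), outdir / "de_mirna.tsv", DE_TABLE_SCHEMA)
    write_results_table(_de_rows(kd_de), outdir / "de_kd.tsv", DE_TABLE_SCHEMA)
    write_results_table(_site_rows(lnc_sites), outdir / "lnc_sites.tsv", SITE_TABLE_SCHEMA)
    write_results_table(_site_rows(utr_sites), outdir / "utr_sites.tsv", SITE_TABLE_SCHEMA)
    write_results_table(
        triplets_to_records(consistent), outdir / "triplets.tsv", TRIPLET_TABLE_SCHEMA
    )
    export_network(network, outdir / "network.json")
    (outdir / "report.json").write_text(report.to_json() + "\n")
    logger.info("artifacts written to %s", outdir)
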