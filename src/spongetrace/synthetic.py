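"""Synthetic study generator with a planted sponge triplet.

Emulates the statistical structure of the three-dataset design the
pipeline integrates: a disease lncRNA+mRNA expression matrix, a disease
miRNA matrix, and a knockdown lncRNA+mRNA matrix, plus the sequence set,
a qPCR Ct table and a dual-luciferase replicate table.  One consistent
lncRNA–miRNA–mRNA triplet is planted (up-regulated lncRNA sponging a
down-regulated miRNA whose target mRNA follows the lncRNA), together
with decoy miRNAs and mRNAs that each violate exactly one selection
condition, so every filter of the pipeline is individually exercised and
the end-to-end run is verifiable by exact recovery.

Noise model: Gaussian in log2 expression space (the standard model for
array intensities), Gaussian Ct noise, multiplicative Gaussian
luminescence noise.  Determinism: one global seed is split into named
per-component streams (seeded as [seed, crc32(name)]), so adding a new
generator never perturbs existing streams and identical seeds give
bitwise-identical bundles.

Random decoy sequences are screened so that no decoy shares a 7-nt seed
complement (exact or single-wobble) with any miRNA in the bundle; binding
sites exist exactly where they are planted.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    SequenceRecord,
    ValidationError,
)
from .cerna import check_direction_consistency
from .diffexpr import log2fc_from_signed_fc

__all__ = [
    "TruthSpec",
    "SyntheticBundle",
    "RecoverabilityWarning",
    "simulate_bundle",
    "simulate_expression",
    "simulate_ct_table",
    "simulate_luciferase",
    "reverse_complement_rna",
]

_BASES = np.array(list("ACGU"))
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}

DISEASE_CASE, DISEASE_CONTROL = "PCOS", "control"
KD_CASE, KD_CONTROL = "knockdown", "control"
QPCR_GROUP_IMMATURE, QPCR_GROUP_MATURE = "CC_MI_GV", "CC_MII"

LNC_ID, MIR_ID, MRNA_ID = "LNC_FOCAL", "MIR_TRUE", "MRNA_TRUE"

MIRNA_DECOY_KINDS = ("dir_up", "dir_ns", "no_mre")
MRNA_DECOY_KINDS = ("kd_ns", "disease_discordant", "no_site")


class RecoverabilityWarning(UserWarning):
    """A planted effect is too small to clear the fold-change gate reliably."""


def _default_qpcr_means() -> dict:
    # group mean relative quantities per assayed gene (immature, mature),
    # realising the worked-example fold ratios 4.95, 5.23 and 2.73
    return {
        LNC_ID: {QPCR_GROUP_IMMATURE: 5.13, QPCR_GROUP_MATURE: 0.98},
        MIR_ID: {QPCR_GROUP_IMMATURE: 0.20, QPCR_GROUP_MATURE: 0.99},
        MRNA_ID: {QPCR_GROUP_IMMATURE: 2.73, QPCR_GROUP_MATURE: 1.0},
    }


def _default_qpcr_references() -> dict:
    return {LNC_ID: "GAPDH", MIR_ID: "U6", MRNA_ID: "GAPDH"}


@dataclass
class TruthSpec:
    """Ground truth and noise levels for a synthetic bundle.

    Planted signed fold changes default to |FC| = 4 with the sponge sign
    pattern (lncRNA up and mRNA up in disease, miRNA down in disease,
    lncRNA and mRNA down on knockdown); see the methods note for why the
    magnitude keeps a margin above the 2.0 fold-change gate.
    """

    n_decoys_per_class: int = 50
    n_background: int = 100
    n_per_group: int = 3
    noise_sd_log2: float = 0.25

    fc_lnc_disease: float = 4.0
    fc_mir_disease: float = -4.0
    fc_mrna_disease: float = 4.0
    fc_lnc_kd: float = -4.0
    fc_mrna_kd: float = -4.0

    mirna_length: int = 22
    lncrna_length: int = 4000
    utr_length: int = 500
    lnc_site_start: int = 100  # planted site of the true miRNA on the lncRNA
    utr_site_start: int = 100  # planted site on each targeted 3'UTR

    ct_sd: float = 0.1
    qpcr_n_per_group: int = 30
    qpcr_group_means: dict = field(default_factory=_default_qpcr_means)
    qpcr_references: dict = field(default_factory=_default_qpcr_references)

    luciferase_cv: float = 0.05
    luciferase_wt_effect: float = 0.4  # WT activity ratio under the miRNA mimic
    luciferase_replicates: int = 3

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_log2", "ct_sd", "luciferase_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not check_direction_consistency(
            self.fc_lnc_disease,
            self.fc_mir_disease,
            self.fc_mrna_kd,
            fc_mrna_disease=self.fc_mrna_disease,
            fc_lnc_kd=self.fc_lnc_kd,
        ):
            raise ValidationError("planted triplet fold changes are not direction-consistent")
        if self.lnc_site_start + self.mirna_length > self.lncrna_length:
            raise ValidationError("planted lncRNA site exceeds the lncRNA length")
        if self.utr_site_start + self.mirna_length > self.utr_length:
            raise ValidationError("planted 3'UTR site exceeds the UTR length")
        small = [
            name
            for name in (
                "fc_lnc_disease", "fc_mir_disease", "fc_mrna_disease",
                "fc_lnc_kd", "fc_mrna_kd",
            )
            if abs(getattr(self, name)) < 2.0
        ]
        if small:
            warnings.warn(
                f"planted effects below the default fold-change gate: {small}",
                RecoverabilityWarning,
                stacklevel=2,
            )


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground-truth record."""

    disease_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    kd_expr: ExpressionMatrix
    mirnas: list[SequenceRecord]
    lncrna: SequenceRecord
    utrs: list[SequenceRecord]
    ct_table: pd.DataFrame
    luciferase_table: pd.DataFrame
    truth: dict


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def reverse_complement_rna(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _seed_complement_kmers(mirna: str, lo: int = 2, hi: int = 8) -> set[str]:
    """Target-strand 7-mers pairing the miRNA seed: exact + single G:U wobble."""
    seed = mirna[lo - 1 : hi]
    exact = reverse_complement_rna(seed)
    kmers = {exact}
    for i, base in enumerate(reversed(seed)):  # position i of the target k-mer
        if base == "G":
            kmers.add(exact[:i] + "U" + exact[i + 1 :])
        elif base == "U":
            kmers.add(exact[:i] + "G" + exact[i + 1 :])
    return kmers


def _screen(seq: str, forbidden: set[str], rng: np.random.Generator, k: int = 7) -> str:
    """Redraw any window containing a forbidden k-mer until the sequence is clean."""
    s = list(seq)
    for _ in range(500):
        hits = [i for i in range(len(s) - k + 1) if "".join(s[i : i + k]) in forbidden]
        if not hits:
            return "".join(s)
        for i in hits:
            s[i : i + k] = list(_random_seq(rng, k))
    raise RuntimeError("sequence screening did not converge")  # pragma: no cover


def _plant(seq: str, insert: str, start: int) -> str:
    return seq[:start] + insert + seq[start + len(insert) :]


def _make_mirnas(spec: TruthSpec, rng: np.random.Generator) -> tuple[list[SequenceRecord], dict]:
    """True + decoy miRNAs, mutually screened so no miRNA's seed complement
    occurs inside another miRNA's planted insert (the reverse complement)."""
    ids = [MIR_ID] + [
        f"MIR_DECOY_{MIRNA_DECOY_KINDS[i % 3]}_{i:03d}"
        for i in range(spec.n_decoys_per_class)
    ]
    seqs: list[str] = []
    kmer_sets: list[set[str]] = []
    for _ in ids:
        for _ in range(500):
            cand = _random_seq(rng, spec.mirna_length)
            cand_rc = reverse_complement_rna(cand)
            cand_kmers = _seed_complement_kmers(cand)
            clash = any(
                any(k in reverse_complement_rna(s) for k in cand_kmers)
                or any(k in cand_rc for k in ks)
                for s, ks in zip(seqs, kmer_sets)
            )
            if not clash:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a non-clashing miRNA")
        seqs.append(cand)
        kmer_sets.append(cand_kmers)
    records = [SequenceRecord(i, s, "miRNA") for i, s in zip(ids, seqs)]
    kinds = {MIR_ID: "true"}
    for i in range(spec.n_decoys_per_class):
        kinds[ids[i + 1]] = MIRNA_DECOY_KINDS[i % 3]
    return records, kinds


def _make_sequences(spec: TruthSpec, seed: int) -> tuple[list[SequenceRecord], SequenceRecord, list[SequenceRecord], dict]:
    rng = _stream(seed, "sequences")
    mirnas, mir_kinds = _make_mirnas(spec, rng)
    forbidden: set[str] = set()
    for m in mirnas:
        forbidden |= _seed_complement_kmers(m.residues)

    # lncRNA: every miRNA that is supposed to have an MRE gets its own site
    with_lnc_mre = [m for m in mirnas if mir_kinds[m.seq_id] in ("true", "dir_up", "dir_ns")]
    spacing = spec.mirna_length + 38  # sites comfortably non-overlapping
    needed = spec.lnc_site_start + spacing * len(with_lnc_mre) + 100
    lnc_len = max(spec.lncrna_length, needed)
    lnc_seq = _screen(_random_seq(rng, lnc_len), forbidden, rng)
    lnc_sites: dict[str, tuple[int, int]] = {}
    for k, m in enumerate(with_lnc_mre):
        start = spec.lnc_site_start + k * spacing
        lnc_seq = _plant(lnc_seq, reverse_complement_rna(m.residues), start)
        lnc_sites[m.seq_id] = (start, start + len(m))
    lncrna = SequenceRecord(LNC_ID, lnc_seq, "lncRNA")

    # 3'UTRs: the true mRNA and the decoys that are genuine targets of the
    # true miRNA carry its site; "no_site" decoys stay clean
    mrna_ids = [MRNA_ID] + [
        f"MRNA_DECOY_{MRNA_DECOY_KINDS[i % 3]}_{i:03d}"
        for i in range(spec.n_decoys_per_class)
    ]
    true_insert = reverse_complement_rna(mirnas[0].residues)
    mrna_kinds = {MRNA_ID: "true"}
    for i in range(spec.n_decoys_per_class):
        mrna_kinds[mrna_ids[i + 1]] = MRNA_DECOY_KINDS[i % 3]
    utrs = []
    utr_sites: dict[str, tuple[int, int]] = {}
    for mid in mrna_ids:
        seq = _screen(_random_seq(rng, spec.utr_length), forbidden, rng)
        kind = mrna_kinds[mid]
        if kind in ("true", "kd_ns", "disease_discordant"):
            seq = _plant(seq, true_insert, spec.utr_site_start)
            utr_sites[mid] = (spec.utr_site_start, spec.utr_site_start + len(true_insert))
        utrs.append(SequenceRecord(mid, seq, "utr3"))
    truth_seq = {
        "lnc_sites": lnc_sites,
        "utr_sites": utr_sites,
        "mirna_kinds": mir_kinds,
        "mrna_kinds": mrna_kinds,
    }
    return mirnas, lncrna, utrs, truth_seq


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(
    effects: Mapping[str, float],
    case_group: str,
    control_group: str,
    n_per_group: int,
    noise_sd: float,
    rng: np.random.Generator,
    sample_prefix: str = "s",
) -> ExpressionMatrix:
    """Linear-scale matrix: log2 baseline + planted case effect + Gaussian noise.

    ``effects`` maps feature_id -> signed log2 effect in the case group
    (0 = null feature).
    """
    feature_ids = list(effects)
    samples = [f"{sample_prefix}_case_{i+1}" for i in range(n_per_group)] + [
        f"{sample_prefix}_ctrl_{i+1}" for i in range(n_per_group)
    ]
    groups = {s: (case_group if "case" in s else control_group) for s in samples}
    baseline = rng.uniform(6.0, 10.0, size=len(feature_ids))
    eff = np.array([effects[f] for f in feature_ids])
    is_case = np.array([groups[s] == case_group for s in samples], dtype=float)
    log2_vals = (
        baseline[:, None]
        + eff[:, None] * is_case[None, :]
        + rng.normal(0.0, noise_sd, size=(len(feature_ids), len(samples)))
    )
    return ExpressionMatrix(feature_ids, samples, 2.0 ** log2_vals, "linear", groups)


def _planted_effects(spec: TruthSpec) -> dict:
    lg = log2fc_from_signed_fc
    disease: dict[str, float] = {LNC_ID: lg(spec.fc_lnc_disease), MRNA_ID: lg(spec.fc_mrna_disease)}
    kd: dict[str, float] = {LNC_ID: lg(spec.fc_lnc_kd), MRNA_ID: lg(spec.fc_mrna_kd)}
    mir: dict[str, float] = {MIR_ID: lg(spec.fc_mir_disease)}
    for i in range(spec.n_decoys_per_class):
        kind = MIRNA_DECOY_KINDS[i % 3]
        mid = f"MIR_DECOY_{kind}_{i:03d}"
        mir[mid] = {"dir_up": -lg(spec.fc_mir_disease), "dir_ns": 0.0, "no_mre": lg(spec.fc_mir_disease)}[kind]
        kind = MRNA_DECOY_KINDS[i % 3]
        rid = f"MRNA_DECOY_{kind}_{i:03d}"
        disease[rid] = {
            "kd_ns": lg(spec.fc_mrna_disease),
            "disease_discordant": -lg(spec.fc_mrna_disease),
            "no_site": lg(spec.fc_mrna_disease),
        }[kind]
        kd[rid] = {
            "kd_ns": 0.0,
            "disease_discordant": lg(spec.fc_mrna_kd),
            "no_site": lg(spec.fc_mrna_kd),
        }[kind]
    for i in range(spec.n_background):
        disease[f"BG_GENE_{i:03d}"] = 0.0
        kd[f"BG_GENE_{i:03d}"] = 0.0
        if i < spec.n_background // 2:
            mir[f"BG_MIR_{i:03d}"] = 0.0
    return {"disease": disease, "mirna": mir, "kd": kd}


# ---------------------------------------------------------------------------
# Validation tables
# ---------------------------------------------------------------------------

def simulate_ct_table(spec: TruthSpec, seed: int | None = None) -> pd.DataFrame:
    """Ct table realising the planted per-group relative-quantity means.

    Ct(target) = gene baseline − log2(planted group mean) + N(0, ct_sd);
    Ct(reference) is constant per gene's reference assay ± the same noise.
    """
    rng = _stream(spec.rng_seed if seed is None else seed, "ct")
    ref_baseline = {"GAPDH": 18.0, "U6": 20.0}
    rows = []
    for gene, group_means in spec.qpcr_group_means.items():
        ref = spec.qpcr_references.get(gene, "GAPDH")
        base = float(rng.uniform(24.0, 30.0))
        for group, mean_rq in group_means.items():
            for i in range(spec.qpcr_n_per_group):
                ct_t = base - np.log2(mean_rq) + rng.normal(0.0, spec.ct_sd)
                ct_r = ref_baseline.get(ref, 19.0) + rng.normal(0.0, spec.ct_sd)
                rows.append(
                    {
                        "sample_id": f"{group}_{i+1:02d}",
                        "group": group,
                        "gene_id": gene,
                        "reference_id": ref,
                        "ct_target": float(ct_t),
                        "ct_reference": float(ct_r),
                    }
                )
    return pd.DataFrame(rows)


def simulate_luciferase(spec: TruthSpec, seed: int | None = None) -> pd.DataFrame:
    """WT/MUT x mimic/control replicates with a WT-only planted repression."""
    rng = _stream(spec.rng_seed if seed is None else seed, "luciferase")
    rows = []
    for construct in ("WT", "MUT"):
        for mimic in ("mir", "control"):
            effect = spec.luciferase_wt_effect if (construct, mimic) == ("WT", "mir") else 1.0
            for rep in range(1, spec.luciferase_replicates + 1):
                renilla = 1e5 * (1.0 + rng.normal(0.0, spec.luciferase_cv))
                firefly = renilla * effect * (1.0 + rng.normal(0.0, spec.luciferase_cv))
                rows.append(
                    {
                        "construct": construct,
                        "mimic": mimic,
                        "replicate": rep,
                        "firefly": float(firefly),
                        "renilla": float(renilla),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write every component of the bundle as plain-text pipeline inputs."""
    import json
    from pathlib import Path

    from .datamodel import write_expression_table, write_sequences

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in (
        ("disease", bundle.disease_expr),
        ("mirna", bundle.mirna_expr),
        ("kd", bundle.kd_expr),
    ):
        write_expression_table(mat, out / f"{name}_expr.tsv")
        pd.DataFrame(
            {"sample_id": mat.sample_ids, "group": [mat.groups[s] for s in mat.sample_ids]}
        ).to_csv(out / f"{name}_groups.tsv", sep="\t", index=False)
    write_sequences(bundle.mirnas, out / "mirnas.fasta")
    write_sequences([bundle.lncrna], out / "lncrna.fasta")
    write_sequences(bundle.utrs, out / "utrs.fasta")
    bundle.ct_table.to_csv(out / "ct.tsv", sep="\t", index=False)
    bundle.luciferase_table.to_csv(out / "luciferase.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2) + "\n")


def simulate_bundle(spec: TruthSpec | None = None) -> SyntheticBundle:
    """Generate all pipeline inputs plus the ground-truth record."""
    spec = spec or TruthSpec()
    seed = spec.rng_seed
    mirnas, lncrna, utrs, truth_seq = _make_sequences(spec, seed)
    effects = _planted_effects(spec)
    disease = simulate_expression(
        effects["disease"], DISEASE_CASE, DISEASE_CONTROL,
        spec.n_per_group, spec.noise_sd_log2, _stream(seed, "disease_expr"), "dis",
    )
    mirna_mat = simulate_expression(
        effects["mirna"], DISEASE_CASE, DISEASE_CONTROL,
        spec.n_per_group, spec.noise_sd_log2, _stream(seed, "mirna_expr"), "mir",
    )
    kd = simulate_expression(
        effects["kd"], KD_CASE, KD_CONTROL,
        spec.n_per_group, spec.noise_sd_log2, _stream(seed, "kd_expr"), "kd",
    )
    truth = {
        "lncrna_id": LNC_ID,
        "mirna_id": MIR_ID,
        "mrna_id": MRNA_ID,
        "planted_fc": {
            "lnc_disease": spec.fc_lnc_disease,
            "mir_disease": spec.fc_mir_disease,
            "mrna_disease": spec.fc_mrna_disease,
            "lnc_kd": spec.fc_lnc_kd,
            "mrna_kd": spec.fc_mrna_kd,
        },
        "planted_log2_effects": effects,
        **truth_seq,
    }
    return SyntheticBundle(
        disease_expr=disease,
        mirna_expr=mirna_mat,
        kd_expr=kd,
        mirnas=mirnas,
        lncrna=lncrna,
        utrs=utrs,
        ct_table=simulate_ct_table(spec),
        luciferase_table=simulate_luciferase(spec),
        truth=truth,
    )
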