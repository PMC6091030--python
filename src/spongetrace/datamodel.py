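"""Shared data types, validation and file I/O.

Everything downstream consumes the containers defined here: expression
matrices with two-group labels, RNA sequence records, and the analysis
configuration that carries every tunable threshold of the pipeline.

File formats are deliberately plain: TSV tables (header row = sample IDs,
first column = feature IDs), standard FASTA, and TSV result tables with a
declared column schema. Scale (linear vs log2) is never guessed from the
data — it is an explicit argument everywhere, because silent log/linear
confusion is the classic failure mode of expression re-analysis.

Coordinate convention: all in-memory intervals are 0-based half-open;
rendered reports are 1-based inclusive (so a site written ``502–522`` spans
21 nt, matching the usual wet-lab convention for target sequences).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SpongetraceError",
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "SchemaError",
    "ContractError",
    "ConventionError",
    "DomainError",
    "StateError",
    "InferenceError",
    "ExpressionMatrix",
    "FeatureAnnotation",
    "SequenceRecord",
    "AnalysisConfig",
    "read_expression_table",
    "write_expression_table",
    "read_sequences",
    "write_sequences",
    "write_results_table",
    "read_results_table",
]


# ---------------------------------------------------------------------------
# Error taxonomy.  ValidationError and its subclasses map to CLI exit code 2,
# InferenceError to exit code 3.
# ---------------------------------------------------------------------------

class SpongetraceError(Exception):
    """Base class for all typed errors raised by this package."""


class ValidationError(SpongetraceError):
    """Input fails a structural or semantic contract."""


class FormatError(ValidationError):
    """A file does not parse under its declared format."""


class ConfigurationError(ValidationError):
    """Configuration is inconsistent with the supplied data."""


class SchemaError(ValidationError):
    """A record does not match its declared column schema."""


class ContractError(ValidationError):
    """An internal API precondition was violated by the caller."""


class ConventionError(ValidationError):
    """A value violates the signed fold-change convention (|fc| >= 1)."""


class DomainError(ValidationError):
    """A numeric value lies outside the mathematical domain of an operation."""


class StateError(ValidationError):
    """An operation was requested in an incompatible object state."""


class InferenceError(SpongetraceError):
    """A statistical operation cannot be carried out (e.g. too few samples)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

VALID_SCALES = ("linear", "log2")
MOLECULE_CLASSES = ("lncRNA", "mRNA", "miRNA")
SEQUENCE_ROLES = ("miRNA", "lncRNA", "utr3")
RNA_ALPHABET = frozenset("ACGU")
MIRNA_LENGTH_RANGE = (18, 26)


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table with two-group sample labels.

    ``values`` holds abundances in the units declared by ``scale``
    ("linear": strictly positive intensities; "log2": log2 intensities).
    ``groups`` maps every sample ID to its group label.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise FormatError(f"duplicate feature IDs: {sorted(dup_f)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise FormatError(f"duplicate sample IDs: {sorted(dup_s)}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite (no NA/inf)")
        if self.scale == "linear" and np.any(self.values <= 0):
            raise ValidationError("linear-scale expression values must be strictly positive")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ConfigurationError(f"samples missing from group map: {missing}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of all samples belonging to ``group``."""
        idx = [j for j, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not idx:
            raise ConfigurationError(f"unknown or empty group label {group!r}")
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.feature_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.scale,
            dict(self.groups),
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Maps a feature ID to its molecule class and optional display name."""

    feature_id: str
    molecule_class: str
    display_name: str | None = None

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValidationError(
                f"molecule_class must be one of {MOLECULE_CLASSES}, got {self.molecule_class!r}"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence normalised to uppercase {A,C,G,U}.

    DNA input (T) is accepted and mapped to U on construction.  miRNAs are
    constrained to the mature-miRNA length range of 18–26 nt.
    """

    seq_id: str
    residues: str
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_rna(self.residues, context=self.seq_id))
        if self.role not in SEQUENCE_ROLES:
            raise ValidationError(f"role must be one of {SEQUENCE_ROLES}, got {self.role!r}")
        n = len(self.residues)
        if self.role == "miRNA" and not (MIRNA_LENGTH_RANGE[0] <= n <= MIRNA_LENGTH_RANGE[1]):
            raise ValidationError(
                f"miRNA {self.seq_id!r} has length {n}, outside "
                f"{MIRNA_LENGTH_RANGE[0]}-{MIRNA_LENGTH_RANGE[1]} nt"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_rna(seq: str, context: str = "") -> str:
    """Uppercase and map T->U; reject empty or non-ACGU sequences.

    Idempotent: normalising a normalised sequence is the identity.
    """
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise FormatError(f"empty sequence{f' for {context!r}' if context else ''}")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"illegal residue(s) {sorted(bad)} in sequence"
            f"{f' {context!r}' if context else ''} after T->U normalisation"
        )
    return s


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline.

    fc_threshold / q_threshold gate differential-expression calls
    (inclusive comparisons: |signed FC| >= fc_threshold, q <= q_threshold).
    mre_score_threshold / mre_energy_threshold gate predicted miRNA binding
    sites (score is dimensionless, energy a pairing-count proxy in
    pseudo-kcal/mol, <= 0 favourable).  seed_span is the miRNA seed region,
    1-based inclusive positions from the 5' end.
    """

    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    mre_score_threshold: float = 110.0
    mre_energy_threshold: float = -14.0
    seed_span: tuple[int, int] = (2, 8)
    require_disease_mrna_concordance: bool = True
    rng_seed: int = 0
    scan_window: int = 40
    scan_step: int = 5

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ConfigurationError("fc_threshold must be >= 1 (linear fold change)")
        if not (0 < self.q_threshold < 1):
            raise ConfigurationError("q_threshold must lie strictly between 0 and 1")
        lo, hi = self.seed_span
        if not (1 <= lo <= hi <= MIRNA_LENGTH_RANGE[0]):
            raise ConfigurationError(
                f"seed_span {self.seed_span} must lie within every valid miRNA "
                f"(1..{MIRNA_LENGTH_RANGE[0]})"
            )
        if self.scan_window <= 0 or self.scan_step <= 0:
            raise ConfigurationError("scan_window and scan_step must be positive")
        if self.scan_window > 60:
            raise ConfigurationError("scan_window must be <= 60 nt")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_span"] = list(self.seed_span)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        if "seed_span" in kwargs:
            kwargs["seed_span"] = tuple(kwargs["seed_span"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Expression-table I/O
# ---------------------------------------------------------------------------

def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def read_expression_table(
    path, group_map: Mapping[str, str], scale: str
) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample IDs, column 1 = feature IDs).

    ``scale`` must be stated explicitly by the caller; it is never inferred
    from the values.
    """
    if scale not in VALID_SCALES:
        raise ConfigurationError(f"scale must be one of {VALID_SCALES}, got {scale!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    dup = _duplicates(feature_ids)
    if dup:
        raise FormatError(f"duplicate feature IDs in {path}: {sorted(dup)}")
    dup = _duplicates(sample_ids)
    if dup:
        raise FormatError(f"duplicate sample IDs in {path}: {sorted(dup)}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in expression table {path}: {exc}") from exc
    if np.any(pd.isna(values)):
        raise FormatError(f"missing (NA) cell in expression table {path}")
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise ConfigurationError(f"samples missing from group map: {missing}")
    groups = {s: group_map[s] for s in sample_ids}
    return ExpressionMatrix(feature_ids, sample_ids, values, scale, groups)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix as a TSV with full float precision (repr round-trip)."""
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

def read_sequences(path, role: str) -> list[SequenceRecord]:
    """Read a FASTA file, normalising every sequence (T->U, uppercase)."""
    if role not in SEQUENCE_ROLES:
        raise ValidationError(f"role must be one of {SEQUENCE_ROLES}, got {role!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq), role))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_sequences(records: Sequence[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Results-table I/O
# ---------------------------------------------------------------------------

def _format_cell(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float) or isinstance(value, np.floating):
        if math.isnan(value):
            raise ValidationError("NaN is not representable in a results table")
        return f"{value:.6g}"
    return str(value)


def write_results_table(records: Sequence, path, schema: Sequence[str]) -> None:
    """Write homogeneous records (dataclasses or mappings) as a TSV.

    Column order follows ``schema`` exactly; floats are rendered at 6
    significant digits.  An empty record list yields a header-only file.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            data = dataclasses.asdict(rec)
        elif isinstance(rec, Mapping):
            data = dict(rec)
        else:
            raise SchemaError(f"record {rec!r} is neither a dataclass nor a mapping")
        missing = [c for c in schema if c not in data]
        if missing:
            raise SchemaError(f"record missing schema field(s) {missing}")
        rows.append([_format_cell(data[c]) for c in schema])
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", header=0)
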