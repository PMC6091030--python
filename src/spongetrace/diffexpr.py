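"""Differential expression, clustering preprocessing and set enrichment.

The DE caller follows the classic two-colour-array workflow: log2-scale
intensities, per-feature Welch two-tailed t-test between two groups,
geometric-mean fold change (difference of group means of log2 values),
Benjamini–Hochberg FDR across all features, and an inclusive fold-change +
q-value gate (|signed FC| >= 2.0, q <= 0.05 by default).

Signed fold-change convention: ratios >= 1 are reported as-is (positive),
ratios < 1 as the negative reciprocal, so −2.52 means 2.52-fold down and
|signed FC| >= 1 always holds.

Also provided: median-centring preprocessing, average-linkage (UPGMA)
hierarchical clustering on 1 − Pearson r distances, and one-sided
hypergeometric over-representation testing for gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datamodel import (
    AnalysisConfig,
    ConfigurationError,
    DomainError,
    ExpressionMatrix,
    InferenceError,
    StateError,
    ValidationError,
)

__all__ = [
    "DERecord",
    "EnrichmentRecord",
    "Dendrogram",
    "DE_TABLE_SCHEMA",
    "preprocess",
    "differential_expression",
    "bh_adjust",
    "apply_thresholds",
    "average_linkage_cluster",
    "hypergeometric_enrichment",
    "signed_fc_from_log2fc",
    "log2fc_from_signed_fc",
]

DE_TABLE_SCHEMA = ["feature_id", "log2fc", "signed_fc", "t", "p", "q", "call"]


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression result."""

    feature_id: str
    log2fc: float
    signed_fc: float
    t_stat: float
    p_raw: float
    q_bh: float
    call: str  # "up" | "down" | "ns"


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation result for one gene set."""

    set_id: str
    overlap_count: int
    set_size: int
    de_count: int
    background_size: int
    p_hyper: float
    q_bh: float


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage format.

    ``merges`` is the (n−1, 4) scipy linkage matrix; ``leaf_labels`` the
    identifiers of the n leaves in input order; ``metric`` a human-readable
    distance label.
    """

    merges: np.ndarray
    leaf_labels: list[str]
    metric: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


# ---------------------------------------------------------------------------
# Fold-change convention
# ---------------------------------------------------------------------------

def signed_fc_from_log2fc(log2fc: float) -> float:
    """Map log2 fold change to the signed linear convention (0 -> +1)."""
    ratio = 2.0 ** float(log2fc)
    return ratio if ratio >= 1.0 else -1.0 / ratio


def log2fc_from_signed_fc(signed_fc: float) -> float:
    """Inverse of :func:`signed_fc_from_log2fc` on its range (|fc| >= 1)."""
    fc = float(signed_fc)
    if abs(fc) < 1.0:
        raise DomainError(f"signed fold change must satisfy |fc| >= 1, got {fc}")
    return np.log2(fc) if fc > 0 else -np.log2(-fc)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    matrix: ExpressionMatrix, log2: bool = False, median_center_genes: bool = False
) -> ExpressionMatrix:
    """Log2-transform and/or median-centre every feature row.

    Median-centring subtracts each row's median so every feature row has
    median 0 afterwards; it is idempotent.
    """
    if log2:
        if matrix.scale == "log2":
            raise StateError("matrix is already on the log2 scale")
        if np.any(matrix.values <= 0):
            raise DomainError("log2 transform requires strictly positive values")
    out = matrix.copy()
    if log2:
        out.values = np.log2(out.values)
        out.scale = "log2"
    if median_center_genes:
        out.values = out.values - np.median(out.values, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _welch_t(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(case, control, equal_var=False)
    if np.isnan(t):
        # degenerate: zero variance in both groups
        if np.isclose(case.mean(), control.mean()):
            return 0.0, 1.0
        return (np.inf if case.mean() > control.mean() else -np.inf), 0.0
    return float(t), float(p)


def differential_expression(
    matrix: ExpressionMatrix,
    case_group: str,
    control_group: str,
    config: AnalysisConfig | None = None,
) -> list[DERecord]:
    """Per-feature Welch t-test and fold change of case vs control.

    The matrix must be on the log2 scale; log2fc is the difference of group
    means of log2 values (a geometric-mean ratio on the linear scale).
    """
    config = config or AnalysisConfig()
    if matrix.scale != "log2":
        raise StateError("differential_expression requires a log2-scale matrix")
    case_idx = matrix.group_columns(case_group)
    ctrl_idx = matrix.group_columns(control_group)
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise InferenceError("each group needs at least 2 samples for a t-test")
    case = matrix.values[:, case_idx]
    ctrl = matrix.values[:, ctrl_idx]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    t_p = [_welch_t(case[i], ctrl[i]) for i in range(matrix.n_features)]
    p_raw = np.array([p for _, p in t_p])
    q_bh = bh_adjust(p_raw)
    records = []
    for i, fid in enumerate(matrix.feature_ids):
        sfc = signed_fc_from_log2fc(log2fc[i])
        call = _assign_call(sfc, q_bh[i], config)
        records.append(
            DERecord(fid, float(log2fc[i]), sfc, t_p[i][0], float(p_raw[i]), float(q_bh[i]), call)
        )
    return records


def _assign_call(signed_fc: float, q: float, config: AnalysisConfig) -> str:
    if q <= config.q_threshold:
        if signed_fc >= config.fc_threshold:
            return "up"
        if signed_fc <= -config.fc_threshold:
            return "down"
    return "ns"


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped to 1 and returned in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def apply_thresholds(
    records: Sequence[DERecord], config: AnalysisConfig | None = None
) -> tuple[list[DERecord], list[DERecord]]:
    """Partition records into (up, down) lists; ns records are dropped.

    Calls are re-derived from the stored fold change and q under ``config``,
    so the same records can be re-gated at different thresholds.
    """
    config = config or AnalysisConfig()
    up = [r for r in records if _assign_call(r.signed_fc, r.q_bh, config) == "up"]
    down = [r for r in records if _assign_call(r.signed_fc, r.q_bh, config) == "down"]
    return up, down


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def average_linkage_cluster(matrix: ExpressionMatrix, axis: str = "features") -> Dendrogram:
    """UPGMA clustering on 1 − Pearson correlation distances.

    ``axis`` selects whether rows ("features") or columns ("samples") are the
    leaves.  A constant leaf (zero variance) has no defined correlation and
    raises a DomainError naming it.
    """
    if axis not in ("features", "samples"):
        raise ValidationError("axis must be 'features' or 'samples'")
    data = matrix.values if axis == "features" else matrix.values.T
    labels = matrix.feature_ids if axis == "features" else matrix.sample_ids
    if data.shape[0] < 2:
        raise ValidationError("clustering requires at least 2 leaves")
    sd = data.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise DomainError(
            f"zero-variance leaf (correlation undefined): {labels[int(flat[0])]!r}"
        )
    dist = 1.0 - np.corrcoef(data)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrise rounding noise
    merges = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(merges, list(labels), metric="1 - Pearson r")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    de_ids: Iterable[str],
    background_ids: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> list[EnrichmentRecord]:
    """One-sided (over-representation) hypergeometric test per gene set.

    Each set is intersected with the background first; p = P(X >= k) for the
    observed overlap k; BH correction is applied across sets; results are
    sorted by ascending p (ties by set_id).
    """
    background = set(background_ids)
    if not background:
        raise ValidationError("background gene list is empty")
    de = set(de_ids)
    stray = de - background
    if stray:
        raise ValidationError(f"DE IDs not contained in background: {sorted(stray)[:5]}")
    N, n = len(background), len(de)
    rows = []
    for set_id, members in gene_sets.items():
        mem = set(members) & background
        K = len(mem)
        k = len(mem & de)
        # upper tail P(X >= k) of Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, k, K, p))
    q = bh_adjust([p for *_, p in rows]) if rows else np.array([])
    records = [
        EnrichmentRecord(set_id, k, K, n, N, p, float(q[i]))
        for i, (set_id, k, K, p) in enumerate(rows)
    ]
    records.sort(key=lambda r: (r.p_hyper, r.set_id))
    return records
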