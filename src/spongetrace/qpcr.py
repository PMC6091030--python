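"""ΔΔCt relative quantification, group comparisons, co-expression and
dual-luciferase statistics.

Relative quantity per sample: ΔCt = Ct(target) − Ct(reference);
ΔΔCt = ΔCt − mean ΔCt of the calibrator group; RQ = 2^(−ΔΔCt), assuming
a fixed amplification efficiency of 2.0 per cycle.  Group comparisons
report mean ± SEM per group, the larger/smaller fold ratio with a
direction label (rounded to 2 decimals in reports), and a Welch
two-tailed t-test p-value.

The dual-luciferase analysis normalises firefly luminescence to the
co-transfected renilla control per replicate; a construct's relative
activity is mean(normalised, miRNA mimic) / mean(normalised, control
mimic), and "direct binding" is called when the wild-type construct is
significantly repressed while the mutated-site construct is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DomainError,
    InferenceError,
    ValidationError,
)

__all__ = [
    "CT_COLUMNS",
    "LUCIFERASE_COLUMNS",
    "GroupComparison",
    "LuciferaseResult",
    "validate_ct_table",
    "validate_luciferase_table",
    "relative_quantities",
    "group_comparison",
    "correlate_pairs",
    "luciferase_analysis",
    "significance_stars",
]

CT_COLUMNS = ["sample_id", "group", "gene_id", "reference_id", "ct_target", "ct_reference"]
LUCIFERASE_COLUMNS = ["construct", "mimic", "replicate", "firefly", "renilla"]

CT_RANGE = (0.0, 45.0)
MIN_GROUP_N = 3
MIN_REPLICATES = 3


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of relative quantities."""

    gene_id: str
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    ratio: float  # larger mean / smaller mean, unrounded
    direction: str  # "higher in <group>" (or "equal")
    p_two_tailed: float

    @property
    def fold_ratio(self) -> float:
        """Reported fold ratio, rounded to 2 decimals."""
        return round(self.ratio, 2)


@dataclass(frozen=True)
class LuciferaseResult:
    """Per-construct repression statistics and the interaction call."""

    relative_activity: dict[str, float]  # construct -> mir/control activity ratio
    percent_change: dict[str, float]  # construct -> (1 - relative activity) * 100
    p_values: dict[str, float]  # construct -> Welch two-tailed p
    interaction_call: str  # "direct binding" | "no interaction"


def significance_stars(p: float) -> str:
    """Figure-legend convention: ** for p <= 0.01, * for p <= 0.05."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Ct tables and the ΔΔCt method
# ---------------------------------------------------------------------------

def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct table missing column(s) {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(ct[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"missing or non-numeric {col} measurement")
        if ((vals <= CT_RANGE[0]) | (vals >= CT_RANGE[1])).any():
            raise ValidationError(
                f"{col} values must lie strictly within {CT_RANGE} cycles"
            )
    counts = ct.groupby(["gene_id", "group"])["sample_id"].count()
    if (counts < MIN_GROUP_N).any():
        low = counts[counts < MIN_GROUP_N]
        raise ValidationError(
            f"every (gene, group) needs >= {MIN_GROUP_N} replicates; short: "
            f"{low.index.tolist()}"
        )
    return ct


def relative_quantities(ct: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample RQ = 2^(−ΔΔCt), calibrated per gene to ``calibrator_group``.

    The calibrator group's RQs have geometric mean 1 by construction.
    Returns the input rows with added columns delta_ct, delta_delta_ct, rq.
    """
    ct = validate_ct_table(ct.copy())
    if not (ct["group"] == calibrator_group).any():
        raise ValidationError(f"calibrator group {calibrator_group!r} absent from Ct table")
    ct["delta_ct"] = ct["ct_target"].astype(float) - ct["ct_reference"].astype(float)
    out = []
    for gene, sub in ct.groupby("gene_id", sort=False):
        cal = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if cal.empty:
            raise ValidationError(
                f"gene {gene!r} has no measurement in calibrator group "
                f"{calibrator_group!r}"
            )
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal.mean()
        sub["rq"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def group_comparison(rqs: pd.DataFrame, group_a: str, group_b: str) -> GroupComparison:
    """Compare RQ levels of two groups (single gene).

    ``rqs`` must contain columns group and rq for exactly one gene (a
    gene_id column, when present, must be single-valued).
    """
    if "gene_id" in rqs.columns:
        genes = rqs["gene_id"].unique()
        if len(genes) != 1:
            raise ValidationError(
                f"group_comparison expects one gene at a time, got {list(genes)}"
            )
        gene = str(genes[0])
    else:
        gene = ""
    a = rqs.loc[rqs["group"] == group_a, "rq"].to_numpy(dtype=float)
    b = rqs.loc[rqs["group"] == group_b, "rq"].to_numpy(dtype=float)
    if len(a) < MIN_GROUP_N or len(b) < MIN_GROUP_N:
        raise InferenceError(
            f"both groups need >= {MIN_GROUP_N} samples "
            f"(got {len(a)} in {group_a!r}, {len(b)} in {group_b!r})"
        )
    mean_a, mean_b = a.mean(), b.mean()
    sem_a = a.std(ddof=1) / np.sqrt(len(a))
    sem_b = b.std(ddof=1) / np.sqrt(len(b))
    if mean_a <= 0 or mean_b <= 0:
        raise DomainError("group mean RQ must be positive")
    if mean_a == mean_b:
        ratio, direction = 1.0, "equal"
    elif mean_a > mean_b:
        ratio, direction = mean_a / mean_b, f"higher in {group_a}"
    else:
        ratio, direction = mean_b / mean_a, f"higher in {group_b}"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        p = 1.0
    return GroupComparison(
        gene, group_a, group_b,
        float(mean_a), float(sem_a), float(mean_b), float(sem_b),
        float(ratio), direction, float(p),
    )


def correlate_pairs(rq_x: Sequence[float], rq_y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation of paired expression levels with two-tailed p."""
    x = np.asarray(rq_x, dtype=float)
    y = np.asarray(rq_y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    if x.size < 3:
        raise InferenceError("correlation requires n >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Dual-luciferase reporter analysis
# ---------------------------------------------------------------------------

def validate_luciferase_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LUCIFERASE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"luciferase table missing column(s) {missing}")
    for col in ("firefly", "renilla"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise ValidationError(f"{col} luminescence must be positive and numeric")
    counts = table.groupby(["construct", "mimic"])["replicate"].count()
    if (counts < MIN_REPLICATES).any():
        low = counts[counts < MIN_REPLICATES]
        raise ValidationError(
            f"every (construct, mimic) cell needs >= {MIN_REPLICATES} replicates; "
            f"short: {low.index.tolist()}"
        )
    return table


def luciferase_analysis(
    table: pd.DataFrame,
    *,
    mir_mimic: str = "mir",
    control_mimic: str = "control",
    wt_construct: str = "WT",
    mut_construct: str = "MUT",
    alpha: float = 0.05,
) -> LuciferaseResult:
    """Normalised-activity analysis of a WT/MUT x mimic/control reporter assay.

    "direct binding" is called iff the WT construct is significantly
    repressed by the miRNA mimic (p <= alpha, reduction > 0) while the MUT
    construct is not.
    """
    table = validate_luciferase_table(table.copy())
    table["normalised"] = table["firefly"].astype(float) / table["renilla"].astype(float)
    relative, percent, pvals = {}, {}, {}
    for construct in (wt_construct, mut_construct):
        sub = table[table["construct"] == construct]
        mir = sub.loc[sub["mimic"] == mir_mimic, "normalised"].to_numpy(dtype=float)
        ctl = sub.loc[sub["mimic"] == control_mimic, "normalised"].to_numpy(dtype=float)
        if len(mir) == 0 or len(ctl) == 0:
            raise ValidationError(
                f"construct {construct!r} is missing a mimic cell "
                f"({mir_mimic!r}: {len(mir)}, {control_mimic!r}: {len(ctl)})"
            )
        activity = mir.mean() / ctl.mean()
        relative[construct] = float(activity)
        percent[construct] = float((1.0 - activity) * 100.0)
        t, p = stats.ttest_ind(mir, ctl, equal_var=False)
        pvals[construct] = 1.0 if np.isnan(t) else float(p)
    wt_repressed = pvals[wt_construct] <= alpha and percent[wt_construct] > 0
    mut_repressed = pvals[mut_construct] <= alpha and percent[mut_construct] > 0
    call = "direct binding" if (wt_repressed and not mut_repressed) else "no interaction"
    return LuciferaseResult(relative, percent, pvals, call)
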