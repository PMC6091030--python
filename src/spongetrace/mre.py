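"""Seed-weighted miRNA response element (MRE) prediction.

A miRNA binds a target antiparallel, so the reversed miRNA (read 3'->5')
is locally aligned against target windows read 5'->3'.  Column scores:
Watson–Crick pair +5, G:U wobble +2, mismatch −3; a gap costs −8 for its
first column and −2 for each further column of the same gap.  Every
substitution column whose miRNA position falls in the seed region
(positions 2–8 from the 5' end by default) has its score doubled, which
makes seed complementarity the dominant determinant of the score, as it is
for real miRNA target recognition.

The energy proxy counts base pairs, E = −(3·#GC + 2·#AU + 1·#GU)
pseudo-kcal/mol; it orders duplexes by pairing strength without a
nearest-neighbour thermodynamic model.

A site passes when score >= mre_score_threshold (default 80) and
E <= mre_energy_threshold (default −14).  Scanning slides a 40-nt window in
5-nt steps, keeps the best alignment per window, and resolves overlaps
greedily by descending score (tie: leftmost, then longest).

Alignments are exact (full Gotoh dynamic programming per window, no
heuristic seeding); a batched score-only DP over all windows is used to
skip the traceback for windows that cannot pass the score threshold, which
leaves results identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    ContractError,
    SequenceRecord,
    ValidationError,
)

__all__ = [
    "DuplexAlignment",
    "MRESite",
    "SITE_TABLE_SCHEMA",
    "align_duplex",
    "scan_target",
    "predict_sites",
    "predict_interactions",
    "recompute_alignment_score",
]

MATCH_WC = 5.0
MATCH_GU = 2.0
MISMATCH = -3.0
GAP_OPEN = -8.0   # first column of a gap
GAP_EXTEND = -2.0  # each subsequent column of the same gap
SEED_MULTIPLIER = 2.0
MAX_WINDOW = 60

SITE_TABLE_SCHEMA = ["mirna_id", "target_id", "start_1based", "end_1based", "score", "energy"]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_NEG = -1e18

# pair score lookup: rows = miRNA base, cols = target base
_PAIR_SCORE = np.full((4, 4), MISMATCH)
for _a, _b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_SCORE[_CODE[_a], _CODE[_b]] = MATCH_WC
for _a, _b in (("G", "U"), ("U", "G")):
    _PAIR_SCORE[_CODE[_a], _CODE[_b]] = MATCH_GU

_PAIR_ENERGY = {frozenset("GC"): 3.0, frozenset("AU"): 2.0, frozenset("GU"): 1.0}


@dataclass(frozen=True)
class DuplexAlignment:
    """One local miRNA:target duplex.

    ``aligned_mirna`` reads 3'->5' (the orientation in which the miRNA lies
    along the target), ``aligned_target`` 5'->3'.  ``pairing`` uses '|' for
    Watson–Crick, ':' for G:U wobble, ' ' for mismatch or gap.
    ``mirna_span`` is 1-based inclusive from the miRNA 5' end;
    ``target_span`` is 0-based half-open on the scanned sequence.
    """

    score: float
    energy: float
    aligned_mirna: str
    aligned_target: str
    pairing: str
    mirna_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class MRESite:
    """A predicted miRNA binding site on a target transcript."""

    mirna_id: str
    target_id: str
    start: int  # 0-based half-open on the target
    end: int
    alignment: DuplexAlignment
    passes_thresholds: bool


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=len(seq))


def _seed_multipliers(mirna_len: int, seed_span: tuple[int, int]) -> np.ndarray:
    """Per-position multipliers indexed along the *reversed* miRNA."""
    lo, hi = seed_span
    # reversed index i corresponds to miRNA 1-based position mirna_len - i
    pos = mirna_len - np.arange(mirna_len)
    return np.where((pos >= lo) & (pos <= hi), SEED_MULTIPLIER, 1.0)


# ---------------------------------------------------------------------------
# Full alignment with traceback
# ---------------------------------------------------------------------------

def align_duplex(
    mirna: SequenceRecord, window: str, config: AnalysisConfig | None = None
) -> DuplexAlignment | None:
    """Best positive-scoring local duplex of ``mirna`` against ``window``.

    Returns None when no alignment scores above zero.  Ties on score are
    broken deterministically: smallest target start, then longest alignment.
    """
    config = config or AnalysisConfig()
    if not window:
        raise ContractError("alignment window is empty")
    if len(window) > MAX_WINDOW:
        raise ContractError(f"alignment window exceeds {MAX_WINDOW} nt: {len(window)}")
    q = mirna.residues[::-1]
    t = window
    m, w = len(q), len(t)
    qc, tc = _encode(q), _encode(t)
    mult = _seed_multipliers(m, config.seed_span)

    # Gotoh local alignment over value tuples (score, -origin, length) so the
    # lexicographic max implements the documented tie-breaking.  States:
    # M = column with both residues, X = gap in miRNA (target consumed),
    # Y = gap in target (miRNA consumed).
    dead = (_NEG, 0, 0)
    M = [[dead] * (w + 1) for _ in range(m + 1)]
    X = [[dead] * (w + 1) for _ in range(m + 1)]
    Y = [[dead] * (w + 1) for _ in range(m + 1)]
    bp_M = [[None] * (w + 1) for _ in range(m + 1)]
    bp_X = [[None] * (w + 1) for _ in range(m + 1)]
    bp_Y = [[None] * (w + 1) for _ in range(m + 1)]

    best = (0.0, 0, 0)
    best_cell = None
    for i in range(1, m + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        sub_row = _PAIR_SCORE[qc[i - 1]] * mult[i - 1]
        for j in range(1, w + 1):
            sub = sub_row[tc[j - 1]]
            # --- M: extend any state diagonally, or start fresh at (i, j)
            cand = (0.0, -(j - 1), 0)
            src = "start"
            for prev, tag in ((Mp[j - 1], "M"), (Xp[j - 1], "X"), (Yp[j - 1], "Y")):
                if prev > cand:
                    cand, src = prev, tag
            Mi[j] = (cand[0] + sub, cand[1], cand[2] + 1)
            bp_M[i][j] = src
            # --- X: gap in miRNA, consumes t[j-1]
            cand, src = dead, None
            for prev, tag, cost in (
                (Mi[j - 1], "M", GAP_OPEN),
                (Xi[j - 1], "X", GAP_EXTEND),
                (Yi[j - 1], "Y", GAP_OPEN),
            ):
                if prev[0] > _NEG / 2:
                    moved = (prev[0] + cost, prev[1], prev[2] + 1)
                    if moved > cand:
                        cand, src = moved, tag
            Xi[j] = cand
            bp_X[i][j] = src
            # --- Y: gap in target, consumes q[i-1]
            cand, src = dead, None
            for prev, tag, cost in (
                (Mp[j], "M", GAP_OPEN),
                (Yp[j], "Y", GAP_EXTEND),
                (Xp[j], "X", GAP_OPEN),
            ):
                if prev[0] > _NEG / 2:
                    moved = (prev[0] + cost, prev[1], prev[2] + 1)
                    if moved > cand:
                        cand, src = moved, tag
            Yi[j] = cand
            bp_Y[i][j] = src
            # local alignments end on a substitution column
            if Mi[j] > best:
                best = Mi[j]
                best_cell = (i, j)

    if best_cell is None or best[0] <= 0:
        return None

    # traceback
    cols: list[tuple[str, str]] = []
    state = "M"
    i, j = best_cell
    while True:
        if state == "M":
            cols.append((q[i - 1], t[j - 1]))
            prev = bp_M[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append(("-", t[j - 1]))
            prev = bp_X[i][j]
            j = j - 1
        else:
            cols.append((q[i - 1], "-"))
            prev = bp_Y[i][j]
            i = i - 1
        if prev == "start":
            break
        state = prev
    cols.reverse()
    t_start, t_end = j, best_cell[1]
    qi_start, qi_end = i, best_cell[0]  # 0-based half-open on reversed miRNA
    mirna_span = (m - qi_end + 1, m - qi_start)

    aligned_mirna = "".join(a for a, _ in cols)
    aligned_target = "".join(b for _, b in cols)
    pairing = "".join(_pair_symbol(a, b) for a, b in cols)
    energy = -sum(
        _PAIR_ENERGY[frozenset((a, b))]
        for a, b in cols
        if "-" not in (a, b) and frozenset((a, b)) in _PAIR_ENERGY
    )
    return DuplexAlignment(
        score=float(best[0]),
        energy=float(energy),
        aligned_mirna=aligned_mirna,
        aligned_target=aligned_target,
        pairing=pairing,
        mirna_span=mirna_span,
        target_span=(t_start, t_end),
    )


def _pair_symbol(a: str, b: str) -> str:
    if "-" in (a, b):
        return " "
    key = frozenset((a, b))
    if key in (frozenset("AU"), frozenset("GC")):
        return "|"
    if key == frozenset("GU"):
        return ":"
    return " "


def recompute_alignment_score(
    alignment: DuplexAlignment, mirna: SequenceRecord, config: AnalysisConfig | None = None
) -> float:
    """Re-derive the score from the alignment trace (consistency check)."""
    config = config or AnalysisConfig()
    m = len(mirna)
    mult = _seed_multipliers(m, config.seed_span)
    # reversed-miRNA index of the first aligned miRNA residue
    qi = m - alignment.mirna_span[1]
    total = 0.0
    in_gap = False
    for a, b in zip(alignment.aligned_mirna, alignment.aligned_target):
        if "-" in (a, b):
            total += GAP_EXTEND if in_gap else GAP_OPEN
            in_gap = True
            if a != "-":  # gap in target still consumes a miRNA residue
                qi += 1
            continue
        in_gap = False
        total += _PAIR_SCORE[_CODE[a], _CODE[b]] * mult[qi]
        qi += 1
    return total


# ---------------------------------------------------------------------------
# Batched score-only DP (window prefilter)
# ---------------------------------------------------------------------------

def _best_window_scores(
    qc: np.ndarray, mult: np.ndarray, windows: np.ndarray
) -> np.ndarray:
    """Best local-alignment score for each window (vectorised over windows)."""
    nw, w = windows.shape
    m = qc.size
    Mp = np.full((nw, w + 1), _NEG)
    Xp = np.full((nw, w + 1), _NEG)
    Yp = np.full((nw, w + 1), _NEG)
    best = np.zeros(nw)
    for i in range(1, m + 1):
        subs = _PAIR_SCORE[qc[i - 1], windows] * mult[i - 1]  # (nw, w)
        Mc = np.full((nw, w + 1), _NEG)
        Xc = np.full((nw, w + 1), _NEG)
        Yc = np.full((nw, w + 1), _NEG)
        for j in range(1, w + 1):
            prev = np.maximum(np.maximum(Mp[:, j - 1], Xp[:, j - 1]), np.maximum(Yp[:, j - 1], 0.0))
            Mc[:, j] = prev + subs[:, j - 1]
            Xc[:, j] = np.maximum(
                np.maximum(Mc[:, j - 1], Yc[:, j - 1]) + GAP_OPEN, Xc[:, j - 1] + GAP_EXTEND
            )
            Yc[:, j] = np.maximum(
                np.maximum(Mp[:, j], Xp[:, j]) + GAP_OPEN, Yp[:, j] + GAP_EXTEND
            )
            np.maximum(best, Mc[:, j], out=best)
        Mp, Xp, Yp = Mc, Xc, Yc
    return best


# ---------------------------------------------------------------------------
# Window scanning
# ---------------------------------------------------------------------------

def scan_target(
    mirna: SequenceRecord, target: SequenceRecord, config: AnalysisConfig | None = None
) -> list[MRESite]:
    """All passing, mutually non-overlapping MRE sites on ``target``.

    Sites are resolved greedily by descending score (tie: leftmost, then
    longest) and returned sorted by target start.  A target shorter than
    the miRNA yields an empty list.
    """
    config = config or AnalysisConfig()
    if target.role not in ("lncRNA", "utr3"):
        raise ContractError(f"scan target role must be lncRNA or utr3, got {target.role!r}")
    t = target.residues
    L, m = len(t), len(mirna)
    if L < m:
        return []
    w = min(config.scan_window, L)
    starts = list(range(0, L - w + 1, config.scan_step))
    if starts[-1] != L - w:
        starts.append(L - w)

    qc = _encode(mirna.residues[::-1])
    mult = _seed_multipliers(m, config.seed_span)
    tc = _encode(t)
    windows = np.stack([tc[s : s + w] for s in starts])
    scores = _best_window_scores(qc, mult, windows)

    candidates: dict[tuple[int, int], MRESite] = {}
    for s, sc in zip(starts, scores):
        if sc < config.mre_score_threshold:
            continue
        aln = align_duplex(mirna, t[s : s + w], config)
        if aln is None:
            continue
        a, b = aln.target_span
        start, end = s + a, s + b
        aln = replace(aln, target_span=(start, end))
        passes = (
            aln.score >= config.mre_score_threshold
            and aln.energy <= config.mre_energy_threshold
        )
        if not passes:
            continue
        site = MRESite(mirna.seq_id, target.seq_id, start, end, aln, True)
        prior = candidates.get((start, end))
        if prior is None or site.alignment.score > prior.alignment.score:
            candidates[(start, end)] = site

    # greedy non-overlap resolution: descending score, tie leftmost, then longest
    ordered = sorted(
        candidates.values(),
        key=lambda s: (-s.alignment.score, s.start, -(s.end - s.start)),
    )
    chosen: list[MRESite] = []
    for site in ordered:
        if all(site.end <= c.start or site.start >= c.end for c in chosen):
            chosen.append(site)
    chosen.sort(key=lambda s: s.start)
    return chosen


def predict_sites(
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    config: AnalysisConfig | None = None,
) -> list[MRESite]:
    """Passing MRE sites for every (miRNA, target) pair, stably ordered."""
    config = config or AnalysisConfig()
    for records, what in ((mirnas, "miRNA"), (targets, "target")):
        ids = [r.seq_id for r in records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate {what} sequence IDs")
    sites: list[MRESite] = []
    for mir in mirnas:
        for tgt in targets:
            sites.extend(scan_target(mir, tgt, config))
    sites.sort(key=lambda s: (s.mirna_id, s.target_id, s.start))
    return sites


def predict_interactions(
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Interaction table: one row per passing site, ordered by (miRNA, target, start).

    Coordinates are 0-based half-open in ``start``/``end``; the TSV writer in
    the CLI renders them 1-based inclusive.
    """
    sites = predict_sites(mirnas, targets, config)
    return sites_to_table(sites)


def sites_to_table(sites: Sequence[MRESite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "start": s.start,
                "end": s.end,
                "score": s.alignment.score,
                "energy": s.alignment.energy,
            }
            for s in sites
        ],
        columns=["mirna_id", "target_id", "start", "end", "score", "energy"],
    )
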