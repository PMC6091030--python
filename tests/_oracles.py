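"""Independent reference implementations used as test oracles.

Each function re-derives a quantity from first principles, in a coding
style deliberately different from the package (top-down recursion, scalar
formulas, exhaustive enumeration), so agreement is informative.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations


# ---------------------------------------------------------------------------
# Duplex alignment: exhaustive top-down DP over (i, j, state)
# ---------------------------------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def oracle_best_duplex_score(
    mirna: str,
    window: str,
    seed_span: tuple[int, int] = (2, 8),
    match=5.0,
    wobble=2.0,
    mismatch=-3.0,
    gap_open=-8.0,
    gap_extend=-2.0,
    seed_mult=2.0,
) -> float:
    """Best local alignment score of reversed miRNA vs window (score only).

    Gap convention: the first column of a gap costs gap_open, each further
    column of the same gap gap_extend.
    """
    q = mirna[::-1]
    t = window
    m, w = len(q), len(t)

    def col_score(i: int, j: int) -> float:
        a, b = q[i], t[j]
        if (a, b) in _WC:
            s = match
        elif (a, b) in _WOBBLE:
            s = wobble
        else:
            s = mismatch
        pos = m - i  # 1-based miRNA position from the 5' end
        if seed_span[0] <= pos <= seed_span[1]:
            s *= seed_mult
        return s

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int, state: str) -> float:
        """Best score of a local alignment whose last column is (i, j, state).

        state 'S': substitution column consuming q[i] and t[j];
        state 'T': gap column consuming t[j] only; 'Q': gap column consuming
        q[i] only.  Returns -inf when impossible.
        """
        if state == "S":
            base = col_score(i, j)
            prev = 0.0  # a local alignment may start here
            if i > 0 and j > 0:
                prev = max(
                    prev,
                    end_at(i - 1, j - 1, "S"),
                    end_at(i - 1, j - 1, "T"),
                    end_at(i - 1, j - 1, "Q"),
                )
            return base + prev
        if state == "T":
            if j == 0:
                return -math.inf
            opts = [
                end_at(i, j - 1, "S") + gap_open,
                end_at(i, j - 1, "T") + gap_extend,
                end_at(i, j - 1, "Q") + gap_open,
            ]
            return max(opts)
        if i == 0:
            return -math.inf
        opts = [
            end_at(i - 1, j, "S") + gap_open,
            end_at(i - 1, j, "Q") + gap_extend,
            end_at(i - 1, j, "T") + gap_open,
        ]
        return max(opts)

    best = 0.0
    for i in range(m):
        for j in range(w):
            best = max(best, end_at(i, j, "S"))
    return best


# ---------------------------------------------------------------------------
# Welch two-sample t-test, textbook formulas
# ---------------------------------------------------------------------------

def oracle_welch_t(xs, ys):
    """(t, p, df) by the Welch–Satterthwaite formulas and the t CDF."""
    from scipy.stats import t as tdist  # distribution only, not the test

    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p, df


# ---------------------------------------------------------------------------
# Exact hypergeometric upper tail by combinatorial counting
# ---------------------------------------------------------------------------

def oracle_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by binomial coefficients."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


# ---------------------------------------------------------------------------
# Sponge-model boolean logic
# ---------------------------------------------------------------------------

def oracle_consistency(signs: dict) -> bool:
    """Truth of the sponge sign pattern from plain boolean conditions.

    ``signs`` holds +1/-1 for keys lnc_dis, mir_dis, mrna_kd and optionally
    mrna_dis, lnc_kd.
    """
    ok = signs["lnc_dis"] == -signs["mir_dis"]
    if "lnc_kd" in signs:
        ok = ok and signs["mrna_kd"] == signs["lnc_kd"]
    if "mrna_dis" in signs:
        ok = ok and signs["mrna_dis"] == signs["lnc_dis"]
    return ok


def oracle_sponged(lnc_sign: str, mir_call: str, has_mre: bool) -> bool:
    """Plain-language restatement of the sponged-miRNA selection rule."""
    if not has_mre:
        return False
    if lnc_sign == "up":
        return mir_call == "down"
    return mir_call == "up"
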