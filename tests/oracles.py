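"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or textbook
formulas, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def gotoh_local_score(s1: str, s2: str, match: float = 2.0, mismatch: float = -3.0,
                      gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Local affine-gap alignment score by explicit dynamic programming.

    ``gap_open`` is the score of the first gap column and ``gap_extend`` of
    each further column (a length-k gap scores open + (k-1)*extend).
    """
    n, m = len(s1), len(s2)
    neg = float("-inf")
    best = 0.0
    h = [[0.0] * (m + 1) for _ in range(n + 1)]  # match/mismatch state
    e = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in s1 (consume s2)
    f = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in s2 (consume s1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            diag = max(h[i - 1][j - 1], e[i - 1][j - 1], f[i - 1][j - 1], 0.0)
            h[i][j] = diag + sub
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend,
                          f[i][j - 1] + gap_open)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend,
                          e[i - 1][j] + gap_open)
            best = max(best, h[i][j], e[i][j], f[i][j])
    return best


def best_chain_score_bruteforce(anchors, orientation: str, gap_open: float,
                                gap_extend_per_rank: float, max_rank_gap: int,
                                score_fn) -> float:
    """Maximum chain score over all subsets, validated by ``score_fn``.

    ``anchors`` must be sorted by a_rank; ``score_fn`` is the shared scoring
    contract (returns None for invalid chains).
    """
    best = 0.0
    n = len(anchors)
    for r in range(1, n + 1):
        for subset in combinations(range(n), r):
            chain = [anchors[i] for i in subset]
            s = score_fn(chain, orientation, gap_open, gap_extend_per_rank, max_rank_gap)
            if s is not None and s > best:
                best = s
    return best


def best_chain_score_dfs(anchors, orientation: str, gap_open: float,
                         gap_extend_per_rank: float, max_rank_gap: int) -> float:
    """Best chain score by exhaustive depth-first chain extension.

    Enumerates every valid monotone chain explicitly (not via the DP
    recurrence), so it is an independent check of the chain dynamic program.
    """
    sign = 1 if orientation == "same" else -1
    n = len(anchors)
    best = 0.0

    def extend(last: int, score: float) -> None:
        nonlocal best
        best = max(best, score)
        a_last = anchors[last]
        for j in range(last + 1, n):
            a = anchors[j]
            da = a.a_rank - a_last.a_rank
            db = sign * (a.b_rank - a_last.b_rank)
            if da < 1 or db < 1 or da > max_rank_gap or db > max_rank_gap:
                continue
            skipped = (da - 1) + (db - 1)
            pen = (gap_open if skipped > 0 else 0.0) + gap_extend_per_rank * skipped
            extend(j, score + 1.0 - pen)

    for i in range(n):
        extend(i, 1.0)
    return best


def rbh_bruteforce(score_table: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Reciprocal best pairs straight from the definition on a score table.

    Keys are (left_gene, right_gene); ties broken lexicographically on the
    partner id (matching the documented tie rule with equal identities).
    """
    lefts = {a for a, _ in score_table}
    rights = {b for _, b in score_table}
    best_l = {
        a: min((b for b in rights if (a, b) in score_table),
               key=lambda b: (-score_table[(a, b)], b), default=None)
        for a in lefts
    }
    best_r = {
        b: min((a for a in lefts if (a, b) in score_table),
               key=lambda a: (-score_table[(a, b)], a), default=None)
        for b in rights
    }
    return {(a, b) for a, b in score_table if best_l[a] == b and best_r[b] == a}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct combinatorial sum."""
    total = math.comb(N, n)
    acc = 0
    for kk in range(k, min(K, n) + 1):
        acc += math.comb(K, kk) * math.comb(N - K, n - kk)
    return acc / total


def tmm_factor_direct(obs, ref, lib_obs: float, lib_ref: float,
                      trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Direct evaluation of the doubly trimmed weighted mean of M-values."""
    import numpy as np

    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    keep = (obs > 0) & (ref > 0)
    y, r = obs[keep], ref[keep]
    m = np.log2((y / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((y / lib_obs) * (r / lib_ref))
    w = (lib_obs - y) / (lib_obs * y) + (lib_ref - r) / (lib_ref * r)
    n = len(m)

    def avg_rank(v):
        # 1-based average ranks (ties share their mean rank)
        order = v.argsort(kind="stable")
        ranks = np.empty(n, dtype=float)
        i = 0
        sv = v[order]
        while i < n:
            j = i
            while j + 1 < n and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rank_m, rank_a = avg_rank(m), avg_rank(a)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    return float(2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))
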