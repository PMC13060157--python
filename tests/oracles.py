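"""Independent brute-force oracles used to cross-check the package.

Everything here is written by enumeration or closed form, deliberately
sharing no code with the implementation under test.
"""

import itertools
import math


def lev_matrix(a: str, b: str) -> int:
    """Textbook full-matrix edit distance (N never matches)."""
    m, n = len(a), len(b)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        ca = a[i - 1]
        for j in range(1, n + 1):
            cb = b[j - 1]
            cost = 0 if (ca == cb and ca != "N" and cb != "N") else 1
            D[i][j] = min(D[i - 1][j - 1] + cost, D[i - 1][j] + 1, D[i][j - 1] + 1)
    return D[m][n]


def brute_adapter_match(seq, spec):
    """Exhaustive anchored scan mirroring the matcher's stated definition.

    Enumerates every candidate: the full adapter against every span inside
    the search window, plus every adapter suffix of length >= min_overlap
    anchored at position 0. Returns the best (distance, start, end,
    matched_length) by (d, start, end, -matched_length), or None.
    """
    adapter = spec.tso_sequence
    L = len(adapter)
    window = seq[: min(len(seq), spec.search_window)]
    n = len(window)
    candidates = []
    max_d_full = int(spec.max_error_rate * L)
    for s in range(n):
        for e in range(s + 1, min(n, s + L + max_d_full) + 1):
            if abs((e - s) - L) > max_d_full:
                continue
            d = lev_matrix(adapter, window[s:e])
            if d <= max_d_full:
                candidates.append((d, s, e, -L))
    for k in range(1, L - spec.min_overlap + 1):
        matched = L - k
        max_d = int(spec.max_error_rate * matched)
        limit = min(n, matched + max_d)
        for e in range(1, limit + 1):
            d = lev_matrix(adapter[k:], window[:e])
            if d <= max_d:
                candidates.append((d, 0, e, -matched))
    if not candidates:
        return None
    d, s, e, neg = min(candidates)
    return d, s, e, -neg


def brute_polya_3prime(seq, min_run, max_mismatches, base="A"):
    """Enumerate every substring of the terminal 50 nt; pick the valid run
    with the 3'-most end, then the smallest start."""
    lo = max(0, len(seq) - 50)
    region = seq[lo:]
    best = None
    for i in range(len(region)):
        for j in range(i + min_run, len(region) + 1):
            sub = region[i:j]
            if sub[0] != base or sub[-1] != base:
                continue
            if sum(1 for c in sub if c != base) > max_mismatches:
                continue
            key = (-j, i)
            if best is None or key < best[0]:
                best = (key, (lo + i, j - i))
    return None if best is None else best[1]


def pearson_direct(x, y):
    """Product-moment correlation from its definition, in pure Python."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def brute_optimal_matching(points_x, points_y, max_dist):
    """Maximum-cardinality, then minimum-total-distance matching by
    enumeration over all injective pairings (feasible for <= ~6 a side)."""
    nx, ny = len(points_x), len(points_y)
    dist = [
        [math.dist(px, py) for py in points_y] for px in points_x
    ]
    idx_y = list(range(ny))
    for k in range(min(nx, ny), -1, -1):
        best_key = None
        best_pairs = frozenset()
        for xs in itertools.combinations(range(nx), k):
            for ys in itertools.permutations(idx_y, k):
                if any(dist[i][j] > max_dist for i, j in zip(xs, ys)):
                    continue
                total = sum(dist[i][j] for i, j in zip(xs, ys))
                if best_key is None or -total > best_key:
                    best_key = -total
                    best_pairs = frozenset(zip(xs, ys))
        if best_key is not None:
            return k, best_pairs
    return 0, frozenset()
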