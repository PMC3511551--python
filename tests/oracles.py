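"""Independent brute-force reference implementations.

Everything here is written as plain O(n^2)-O(n^3) loops straight from the
defining formulas, deliberately sharing no code with the package, so the
package implementations can be checked against them.
"""

from __future__ import annotations

import math
from statistics import median


def ranks_avg(v):
    """Average ranks by sorting positions, ties averaged by hand."""
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_brute(x, y):
    return pearson_brute(ranks_avg(x), ranks_avg(y))


def kendall_brute(x, y):
    """tau-b from explicit pair enumeration."""
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tie_x) * (n0 - tie_y))


def weighted_rank_brute(x, y):
    R = ranks_avg(x)
    S = ranks_avg(y)
    n = len(x)
    w = sum(
        (R[i] - S[i]) ** 2 * ((n - R[i] + 1) + (n - S[i] + 1)) for i in range(n)
    )
    return 1 - 6 * w / (n**4 + n**3 - n**2 - n)


def hoeffding_brute(x, y):
    """Hoeffding's D from per-point loops over the defining rank sums."""
    n = len(x)
    R = ranks_avg(x)
    S = ranks_avg(y)
    Q = []
    for i in range(n):
        q = 1.0
        for j in range(n):
            if j == i:
                continue
            if x[j] < x[i] and y[j] < y[i]:
                q += 1.0
            elif x[j] == x[i] and y[j] == y[i]:
                q += 0.25
            elif x[j] == x[i] and y[j] < y[i]:
                q += 0.5
            elif x[j] < x[i] and y[j] == y[i]:
                q += 0.5
        Q.append(q)
    d1 = sum((q - 1) * (q - 2) for q in Q)
    d2 = sum((R[i] - 1) * (R[i] - 2) * (S[i] - 1) * (S[i] - 2) for i in range(n))
    d3 = sum((R[i] - 2) * (S[i] - 2) * (Q[i] - 1) for i in range(n))
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    return 30.0 * num / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4))


def dcov2_brute(x, y):
    """Squared distance covariance by explicit double centering."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A = center(a)
    B = center(b)
    return sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / (n * n)


def theil_sen_brute(x, y):
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i in range(len(x))
        for j in range(i + 1, len(x))
        if x[j] != x[i]
    ]
    return median(slopes)


def rank_theil_sen_brute(x, y):
    return theil_sen_brute(ranks_avg(x), ranks_avg(y))


BRUTE = {
    "pearson": pearson_brute,
    "spearman": spearman_brute,
    "kendall": kendall_brute,
    "weighted_rank": weighted_rank_brute,
    "hoeffding": hoeffding_brute,
    "dcov": dcov2_brute,
    "theil_sen": theil_sen_brute,
    "rank_theil_sen": rank_theil_sen_brute,
}
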