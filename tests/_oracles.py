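"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain, slow loops so it
shares no code path with the package implementations it checks.
"""

from itertools import combinations

import numpy as np


def ssgsea_brute(expr_col_values, gene_ids, gene_set, alpha):
    """Literal running-sum ssGSEA for one sample, one set.

    Ranks are average ranks of expression ascending (top gene ~ N);
    the walk is by decreasing expression with ties broken by gene id.
    """
    values = list(expr_col_values)
    n = len(values)
    # average ranks, ascending
    order_asc = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order_asc[t]] = avg
        i = j + 1
    walk = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in gene_set for i in walk]
    m = sum(in_set)
    denom = sum(abs(ranks[walk[i]]) ** alpha for i in range(n) if in_set[i])
    running = 0.0
    total = 0.0
    for i in range(n):
        if in_set[i]:
            running += abs(ranks[walk[i]]) ** alpha / denom
        else:
            running -= 1.0 / (n - m)
        total += running
    return total


def pam_brute_cost(d, k):
    """Minimum total nearest-medoid cost over all medoid subsets."""
    n = d.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = sum(min(d[i, m] for m in medoids) for i in range(n))
        best = min(best, cost)
    return best


def distance_correlation_brute(x, y):
    """Textbook double-centered distance correlation, loop version."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvarx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvary = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvarx * dvary) ** 0.5) ** 0.5


def km_brute(times, events):
    """Product-limit estimator evaluated at the distinct observed times."""
    times = list(times)
    events = list(events)
    distinct = sorted(set(times))
    s = 1.0
    out = []
    for u in distinct:
        at_risk = sum(1 for t in times if t >= u)
        deaths = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        out.append((u, s))
    return out
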