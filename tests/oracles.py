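"""Independent reference implementations used as test oracles.

These are deliberately naive (direct summation, O(n^3) agglomeration) and
share no code with the package implementation they check.
"""

import numpy as np


def brute_force_average_linkage(x):
    """O(n^3) average-linkage agglomeration under Manhattan distance.

    Returns merges as (cluster_a, cluster_b, height, size) following the
    scipy id convention (new clusters numbered n, n+1, ...).
    """
    n = len(x)
    dist = {(i, j): float(np.abs(x[i] - x[j]).sum())
            for i in range(n) for j in range(i + 1, n)}
    active = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                d = np.mean([dist[tuple(sorted((p, q)))]
                             for p in active[a] for q in active[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(active[a]) + len(active[b])))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return merges


def cophenetic_from_merges(merges, n):
    """Pairwise cophenetic heights implied by a merge list."""
    members = {i: [i] for i in range(n)}
    heights = np.zeros((n, n))
    next_id = n
    for a, b, d, _ in merges:
        for p in members[a]:
            for q in members[b]:
                heights[p, q] = heights[q, p] = d
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return heights


def ammi_partition_by_double_loop(matrix, r):
    """SS partition for G, E and G x E from the definitions, by double loops."""
    y = np.asarray(matrix, float)
    n, m = y.shape
    mu = y.mean()
    g = y.mean(axis=1) - mu
    e = y.mean(axis=0) - mu
    ss_g = sum(r * m * g[i] ** 2 for i in range(n))
    ss_e = sum(r * n * e[j] ** 2 for j in range(m))
    ss_gei = 0.0
    for i in range(n):
        for j in range(m):
            z = y[i, j] - mu - g[i] - e[j]
            ss_gei += r * z * z
    return ss_g, ss_e, ss_gei
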