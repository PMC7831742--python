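"""Independent brute-force oracles used by unit, property and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or by evaluating the
defining formula, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def _average_ranks(values) -> list[float]:
    """Average ranks computed by pairwise counting (no scipy)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def wilcoxon_exact_p(x, y) -> tuple[float, float]:
    """(W+, two-sided p) by enumerating all 2^n sign assignments.

    Zero differences dropped; tied |d| get average ranks; two-sided p is
    twice the smaller tail, capped at 1.
    """
    diffs = [float(a) - float(b) for a, b in zip(x, y)]
    diffs = [d for d in diffs if d != 0]
    if not diffs:
        return 0.0, 1.0
    ranks = _average_ranks([abs(d) for d in diffs])
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    n = len(diffs)
    ws = [sum(r for s, r in zip(signs, ranks) if s) for signs in product([0, 1], repeat=n)]
    total = len(ws)
    eps = 1e-9
    p_ge = sum(1 for w in ws if w >= w_obs - eps) / total
    p_le = sum(1 for w in ws if w <= w_obs + eps) / total
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def mannwhitney_exact_p(a, b) -> tuple[float, float]:
    """(U of a, two-sided p) by enumerating every assignment of the pooled
    values to a group of size len(a).

    U is computed from pairwise comparisons (wins + half-ties), not rank
    sums, so the route differs from the implementation.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    pooled = a + b
    n, n_a = len(pooled), len(a)

    def u_of(group_a, group_b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in group_a for y in group_b
        )

    u_obs = u_of(a, b)
    us = []
    for idx in combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_of(ga, gb))
    total = len(us)
    eps = 1e-9
    p_ge = sum(1 for u in us if u >= u_obs - eps) / total
    p_le = sum(1 for u in us if u <= u_obs + eps) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bh_direct(p) -> np.ndarray:
    """q_(i) = min_{j >= i} p_(j) * m / j, evaluated literally."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def interval_gap(s1, e1, s2, e2):
    """Bases strictly between two 1-based inclusive intervals; 0 on overlap."""
    if s1 <= e2 and s2 <= e1:
        return 0
    return (s2 - e1 - 1) if e1 < s2 else (s1 - e2 - 1)


def neighbor_pairs_bruteforce(genes, max_gap: int) -> set[tuple[str, str]]:
    """All-pairs scan over (lncRNA, protein_coding) gene tuples."""
    out = set()
    for a in genes:
        if a.biotype != "lncRNA":
            continue
        for b in genes:
            if b.biotype != "protein_coding" or a.chrom != b.chrom:
                continue
            if interval_gap(a.start, a.end, b.start, b.end) <= max_gap:
                out.add((a.gene_id, b.gene_id))
    return out
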