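"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, repeated absorption,
direct summation) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, hypergeom

TIE = 1.0 + 1e-7   # relative tie tolerance for "no more likely" rules


def binomial_exact_p(sum_a: int, sum_b: int, n_a: int, n_b: int) -> float:
    """Conditional binomial two-sided exact test (the phi=0 null)."""
    T = sum_a + sum_b
    if T == 0:
        return 1.0
    k = np.arange(T + 1)
    pmf = binom.pmf(k, T, n_a / (n_a + n_b))
    return float(min(pmf[pmf <= pmf[sum_a] * TIE].sum(), 1.0))


def fisher_exact_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        return 1.0
    lo, hi = max(0, n - (N - K)), min(K, n)
    k = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(k, N, K, n)
    return float(min(pmf[pmf <= hypergeom.pmf(a, N, K, n) * TIE].sum(), 1.0))


def bh_hand(p: list[float]) -> list[float]:
    """Textbook step-up BH: sort, q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def tom_direct(a: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit double loop over shared neighbours."""
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


def dmr_spans_oracle(starts, ends, pvals, seed_p, extend_p, max_gap):
    """Fixed point of exhaustive repeated absorption, then merge.

    Operates on one chromosome; returns sorted (start, end) DMR spans.
    """
    starts = list(map(int, starts))
    ends = list(map(int, ends))
    n = len(starts)
    ext = [i for i in range(n) if pvals[i] < extend_p]
    spans = [[starts[i], ends[i]] for i in range(n) if pvals[i] < seed_p]
    changed = True
    while changed:
        changed = False
        for sp in spans:
            for i in ext:
                gap = max(starts[i] - sp[1], sp[0] - ends[i], 0)
                if gap <= max_gap and not (starts[i] >= sp[0] and ends[i] <= sp[1]):
                    sp[0] = min(sp[0], starts[i])
                    sp[1] = max(sp[1], ends[i])
                    changed = True
        # merge touching or overlapping spans
        spans.sort()
        merged = []
        for sp in spans:
            if merged and sp[0] <= merged[-1][1]:
                if sp[1] > merged[-1][1]:
                    merged[-1][1] = sp[1]
                    changed = True
                elif sp != merged[-1]:
                    changed = True
            else:
                merged.append(sp)
        if len(merged) != len(spans):
            changed = True
        spans = merged
    return [tuple(sp) for sp in spans]


def gene_assoc_oracle(intervals, genes, max_distance):
    """All-pairs interval-gene association: set of (interval idx, gene idx)."""
    out = set()
    for ii, (ichrom, istart, iend) in enumerate(intervals):
        for gi, (gchrom, gstart, gend) in enumerate(genes):
            if ichrom != gchrom:
                continue
            if istart < gend and gstart < iend:
                d = 0
            elif gstart >= iend:
                d = gstart - iend
            else:
                d = istart - gend
            if d <= max_distance:
                out.add((ii, gi))
    return out


def venn_components_oracle(interval_lists):
    """Connected components of the all-pairs intersection graph.

    ``interval_lists`` is {label: [(chrom, start, end), ...]}; returns
    {frozenset(labels): locus count}.
    """
    nodes = [(lab, iv) for lab, ivs in interval_lists.items() for iv in ivs]
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            (la, (ca, sa, ea)), (lb, (cb, sb, eb)) = nodes[i], nodes[j]
            adj[i][j] = ca == cb and sa < eb and sb < ea
    seen = [False] * n
    counts: dict[frozenset, int] = {}
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        key = frozenset(nodes[u][0] for u in comp)
        counts[key] = counts.get(key, 0) + 1
    return counts
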