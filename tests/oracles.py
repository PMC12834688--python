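"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (exhaustive enumeration, O(n^2)
scans, recompute-from-scratch loops) and shares no code with the package's
optimised implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_modified_cosine(a, b, tol):
    """Exhaustive one-to-one assignment search over candidate peak pairs.

    Returns (score, n_matched) of the maximum-total-weight assignment.
    Feasible for small spectra (<= ~8 peaks with sparse candidates).
    """
    delta = b.precursor_mz - a.precursor_mz
    wa = np.sqrt(a.intensity)
    wa = wa / np.linalg.norm(wa) if wa.size else wa
    wb = np.sqrt(b.intensity)
    wb = wb / np.linalg.norm(wb) if wb.size else wb

    cand = {}
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            if abs(a.mz[i] - b.mz[j]) <= tol or abs(a.mz[i] + delta - b.mz[j]) <= tol:
                cand.setdefault(i, []).append(j)

    a_idx = sorted(cand)
    best = (0.0, 0)

    def rec(pos, used_b, score, count):
        nonlocal best
        if score > best[0] + 1e-15:
            best = (score, count)
        if pos == len(a_idx):
            return
        i = a_idx[pos]
        rec(pos + 1, used_b, score, count)  # leave peak i unmatched
        for j in cand[i]:
            if j not in used_b:
                rec(pos + 1, used_b | {j}, score + wa[i] * wb[j], count + 1)

    rec(0, frozenset(), 0.0, 0)
    return best


def brute_window_filter(mz, intensity, k, width):
    """Indices kept by an explicit per-peak neighbourhood rank filter."""
    n = len(mz)
    keep = []
    for i in range(n):
        nbhd = [j for j in range(n) if abs(mz[j] - mz[i]) <= width]
        ranked = sorted(nbhd, key=lambda j: (-intensity[j], mz[j]))
        if i in ranked[:k]:
            keep.append(i)
    return keep


def brute_tolerance_groups(values, tol):
    """Naive O(n^2) single-linkage grouping of scalars within tol.

    Returns groups as sorted tuples of indices.
    """
    n = len(values)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(values[i] - values[j]) <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


def brute_single_linkage_clusters(spectra, precursor_tol, min_cosine, cosine_fn):
    """All-pairs single-linkage clustering oracle.

    Joinable iff |Δprecursor| <= precursor_tol and cosine >= min_cosine;
    clusters are connected components of the joinable graph. Returns the
    partition as a sorted list of frozensets of spectrum_ids.
    """
    n = len(spectra)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(spectra[i].precursor_mz - spectra[j].precursor_mz) > precursor_tol:
                continue
            score, _ = cosine_fn(spectra[i], spectra[j])
            if score >= min_cosine:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(spectra[i].spectrum_id)
    return sorted(frozenset(c) for c in clusters.values())


def brute_mutual_topk(edges, k):
    """Rank-enumeration mutual top-k filter over (a, b, cosine) triples."""
    nbrs = {}
    for a, b, cos in edges:
        nbrs.setdefault(a, []).append((b, cos))
        nbrs.setdefault(b, []).append((a, cos))
    kept = []
    for a, b, cos in edges:
        ra = sorted(nbrs[a], key=lambda t: (-t[1], t[0]))
        rb = sorted(nbrs[b], key=lambda t: (-t[1], t[0]))
        if b in [x for x, _ in ra[:k]] and a in [x for x, _ in rb[:k]]:
            kept.append((a, b, cos))
    return kept


def brute_size_cap(nodes, edges, cap):
    """Step-by-step family-size capping with BFS component recomputation.

    ``edges``: dict {(a, b): cosine} with a < b. Returns the surviving
    edge keys as a set.
    """
    edges = dict(edges)

    def components():
        adj = {n: set() for n in nodes}
        for (a, b) in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen, comps = set(), []
        for n in sorted(nodes):
            if n in seen:
                continue
            comp, stack = {n}, [n]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    while True:
        oversized = [c for c in components() if len(c) > cap]
        if not oversized:
            return set(edges)
        comp = min(oversized, key=lambda c: min(c))
        in_comp = [(cos, key) for key, cos in edges.items() if key[0] in comp]
        _, worst = min(in_comp, key=lambda t: (t[0], t[1]))
        del edges[worst]


def brute_rarefaction_all_orderings(incidence):
    """Mean accumulation curve over every permutation of the units."""
    inc = np.asarray(incidence, dtype=bool)
    n_items, n_units = inc.shape
    totals = np.zeros(n_units)
    n_perm = 0
    for perm in itertools.permutations(range(n_units)):
        seen = np.zeros(n_items, dtype=bool)
        for pos, u in enumerate(perm):
            seen |= inc[:, u]
            totals[pos] += seen.sum()
        n_perm += 1
    return totals / n_perm
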