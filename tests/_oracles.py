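"""Independent brute-force oracles used to validate the implementation.

Each function recomputes a quantity by direct enumeration or by the
defining formula, deliberately avoiding the code paths under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

# --------------------------------------------------------------- BH step-up

def bh_stepup(p_values):
    """Textbook Benjamini-Hochberg: sort, p_(i)*m/i, monotone from the top."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        adj[i] = val
        prev = val
    return adj


# ------------------------------------------------------ betweenness (exact)

def betweenness_exhaustive(graph):
    """Unnormalized betweenness by explicit enumeration of all geodesics,
    each unordered pair counted once (hand-rolled BFS, no library calls)."""
    adj = {v: sorted(graph.neighbors(v)) for v in graph.nodes}
    bc = {v: 0.0 for v in adj}
    nodes = sorted(adj)
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s: distances and predecessor lists
        dist = {s: 0}
        preds: dict = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    preds[w] = [u]
                    q.append(w)
                elif dist[w] == dist[u] + 1:
                    preds[w].append(u)
        if t not in dist:
            continue
        # enumerate every shortest path by backtracking
        paths = []

        def backtrack(v, acc):
            if v == s:
                paths.append(acc)
                return
            for p in preds[v]:
                backtrack(p, [p] + acc)

        backtrack(t, [t])
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


# ------------------------------------------------- hypergeometric upper tail

def hypergeom_upper_tail(k, n_bg, big_k, n_study):
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(n_bg, n_study)
    acc = 0
    for j in range(k, min(big_k, n_study) + 1):
        acc += math.comb(big_k, j) * math.comb(n_bg - big_k, n_study - j)
    return acc / total


# -------------------------------------------------------- seed-site scanner

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def seed_sites_bruteforce(mirna_seq, transcript_seq):
    """All-substring check of every canonical site pattern.

    Returns {(site_start, site_end, site_type)} with 1-based closed
    coordinates, keeping only the strongest class per seed-core locus.
    """
    m = mirna_seq.upper().replace("T", "U")
    t = transcript_seq.upper().replace("T", "U")
    pat8 = _rc(m[1:8]) + "A"
    pat7m8 = _rc(m[1:8])
    pat7a1 = _rc(m[1:7]) + "A"
    pat6 = _rc(m[1:7])
    # core locus -> (rank, span); core start inside each pattern:
    # pat8/pat7m8 start one base 5' of the core, pat7a1/pat6 start at it
    found = {}

    def record(core0, rank, start0, span):
        if core0 not in found or found[core0][0] < rank:
            found[core0] = (rank, (start0 + 1, start0 + span))

    for i in range(len(t)):
        if t[i : i + 8] == pat8:
            record(i + 1, 3, i, 8)
        if t[i : i + 7] == pat7m8:
            record(i + 1, 2, i, 7)
        if t[i : i + 7] == pat7a1:
            record(i, 1, i, 7)
        if t[i : i + 6] == pat6:
            record(i, 0, i, 6)
    names = {0: "6mer", 1: "7mer-A1", 2: "7mer-m8", 3: "8mer"}
    return {(span[0], span[1], names[rank]) for rank, span in found.values()}


# ----------------------------------------------------- triplet triple loop

def triplets_bruteforce(lnc_ids, mi_ids, mrna_ids, lnc_edges, mrna_edges, calls):
    """Direction-filtered triple loop over every (lncRNA, miRNA, mRNA)."""
    lnc_r = {(e.source_id, e.target_id): e.pearson_r for e in lnc_edges}
    mrna_r = {(e.source_id, e.target_id): e.pearson_r for e in mrna_edges}
    out = set()
    for lnc in lnc_ids:
        for mi in mi_ids:
            if (mi, lnc) not in lnc_r:
                continue
            for mrna in mrna_ids:
                if (mi, mrna) not in mrna_r:
                    continue
                dl, dm, dg = calls[lnc], calls[mi], calls[mrna]
                if dl == dg and {dl, dm} == {"up", "down"}:
                    out.add((lnc, mi, mrna))
    return out


# ------------------------------------- conditional NB split (full support)

def conditional_nb_pvalue_enum(sa, s, r_a, r_b):
    """Two-sided p-value over the full split support 0..s; the NB success
    probability cancels after conditioning, so any value works."""
    from scipy.stats import nbinom

    a = np.arange(0, s + 1)
    # success probability cancels after conditioning; pick one that keeps
    # the pmf in floating range (group means near the observed totals)
    p = (r_a + r_b) / (r_a + r_b + s)
    logw = nbinom.logpmf(a, r_a, p) + nbinom.logpmf(s - a, r_b, p)
    w = np.exp(logw - logw.max())
    w = w / w.sum()
    return float(w[w <= w[sa] * (1 + 1e-9)].sum())
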