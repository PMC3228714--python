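"""Independent reference implementations used as test oracles.

These are deliberately naive (exhaustive enumeration, from-scratch
recomputation) and share no code with the package paths they check.
"""
from __future__ import annotations

import itertools

import numpy as np


def brute_force_alignment(a: str, b: str, match: float = 1.0,
                          mismatch: float = -1.0, gap: float = -2.0):
    """Enumerate every global alignment of ``a`` and ``b`` as a lattice
    path, score it with free end gaps, and return ``(best_score, set of
    end-gap-discounted distances achieved by optimal alignments)``.

    Terminal runs of gap columns are free and excluded from the compared
    region; internal gap columns cost ``gap`` and count as differences.
    """
    la, lb = len(a), len(b)
    best = float("-inf")
    dists: set[float] = set()

    # A gap column is terminal (free, excluded from the compared region)
    # exactly when it runs along an edge of the DP lattice: a gap in b is
    # terminal iff no b base has been consumed yet (j == 0) or all have
    # (j == lb), and symmetrically for gaps in a.  Interior gap columns
    # are internal: they cost ``gap`` and count as one difference each.
    # state: (i, j, matches, mismatches, internal gap columns)
    stack = [(0, 0, 0, 0, 0)]
    while stack:
        i, j, m, x, g = stack.pop()
        if i == la and j == lb:
            score = m * match + x * mismatch + g * gap
            compared = m + x + g
            d = (x + g) / compared if compared else 0.0
            if score > best + 1e-12:
                best, dists = score, {round(d, 12)}
            elif abs(score - best) <= 1e-12:
                dists.add(round(d, 12))
            continue
        if i < la and j < lb:
            stack.append((i + 1, j + 1, m + (a[i] == b[j]), x + (a[i] != b[j]), g))
        if i < la:  # consume a[i] against a gap in b
            terminal = j == 0 or j == lb
            stack.append((i + 1, j, m, x, g + (0 if terminal else 1)))
        if j < lb:  # consume b[j] against a gap in a
            terminal = i == 0 or i == la
            stack.append((i, j + 1, m, x, g + (0 if terminal else 1)))
    return best, dists


def _linkage_criterion(d: np.ndarray, w: np.ndarray, A: list[int],
                       B: list[int], linkage: str) -> float:
    block = d[np.ix_(A, B)]
    if linkage == "single":
        crit = float(block.min())
    elif linkage == "complete":
        crit = float(block.max())
    else:
        wa, wb = w[A], w[B]
        ww = np.outer(wa, wb)
        crit = float((ww * block).sum() / ww.sum())
    # quantize like the implementation so float summation noise cannot
    # defeat the member-id tie-break on semantically equal criteria
    return round(crit, 10)


def reference_hier_partitions(d: np.ndarray, weights, linkage: str,
                              cutoffs) -> dict[float, set[frozenset[int]]]:
    """From-scratch agglomeration: at every step the criterion between
    every live cluster pair is recomputed from the original matrix; the
    minimal pair merges, ties broken by the lowest pair of smallest
    member indices.  Returns, per cutoff, the partition containing every
    merge with criterion <= cutoff, as frozensets of original indices."""
    n = d.shape[0]
    w = np.asarray(weights, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(n)]
    merges: list[tuple[float, list[int], list[int]]] = []
    while len(clusters) > 1:
        best_key, best_pair = None, None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                crit = _linkage_criterion(d, w, clusters[x], clusters[y], linkage)
                key = (crit, tuple(sorted((min(clusters[x]), min(clusters[y])))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (x, y)
        x, y = best_pair
        merges.append((best_key[0], clusters[x], clusters[y]))
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]

    out = {}
    for cutoff in cutoffs:
        parts = [[i] for i in range(n)]
        for height, A, B in merges:
            if height <= cutoff:
                pa = next(p for p in parts if A[0] in p)
                pb = next(p for p in parts if B[0] in p)
                if pa is not pb:
                    pa.extend(pb)
                    parts.remove(pb)
        out[cutoff] = {frozenset(p) for p in parts}
    return out


def exhaustive_rarefaction(counts, depth: int) -> float:
    """Mean OTU count over all C(N, depth) subsamples, enumerated."""
    reads = [otu for otu, c in enumerate(counts) for _ in range(c)]
    total = 0
    n_sub = 0
    for combo in itertools.combinations(range(len(reads)), depth):
        total += len({reads[k] for k in combo})
        n_sub += 1
    return total / n_sub
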