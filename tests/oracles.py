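"""Brute-force reference implementations, independent of the package internals.

Everything here works on plain Python strings/loops and small dense arrays so
it can serve as an oracle for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_pair_mi(col_i: str, col_j: str, weights, pseudocount: float) -> float:
    """MI of two residue columns by direct double loop over the 20x20 table."""
    counts = {(a, b): 0.0 for a in AA for b in AA}
    for x, y, w in zip(col_i, col_j, weights):
        if x in AA and y in AA:
            counts[(x, y)] += w
    total = sum(counts.values()) + 400 * pseudocount
    joint = {k: (v + pseudocount) / total for k, v in counts.items()}
    pi = {a: sum(joint[(a, b)] for b in AA) for a in AA}
    pj = {b: sum(joint[(a, b)] for a in AA) for b in AA}
    mi = 0.0
    for a in AA:
        for b in AA:
            p = joint[(a, b)]
            if p > 0:
                mi += p * math.log(p / (pi[a] * pj[b]))
    return mi


def oracle_mi_matrix(sequences, weights, pseudocount, kept_columns) -> np.ndarray:
    """MI over all kept column pairs; NaN diagonal and degenerate pairs."""
    cols = ["".join(seq[c] for seq in sequences) for c in kept_columns]
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            contributing = sum(
                1 for x, y in zip(cols[i], cols[j]) if x in AA and y in AA
            )
            if contributing >= 2:
                out[i, j] = oracle_pair_mi(cols[i], cols[j], weights, pseudocount)
    return out


def oracle_apc(mi: np.ndarray) -> np.ndarray:
    """APC by explicit loops over defined off-diagonal entries."""
    k = mi.shape[0]
    defined = [
        [(i != j and np.isfinite(mi[i, j])) for j in range(k)] for i in range(k)
    ]
    row_means = []
    for i in range(k):
        vals = [mi[i, j] for j in range(k) if defined[i][j]]
        row_means.append(sum(vals) / len(vals) if vals else math.nan)
    all_vals = [mi[i, j] for i in range(k) for j in range(k) if defined[i][j]]
    if not all_vals:
        return mi.copy()
    mean_all = sum(all_vals) / len(all_vals)
    if mean_all == 0:
        return mi.copy()
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if defined[i][j]:
                out[i, j] = mi[i, j] - row_means[i] * row_means[j] / mean_all
    return out


def oracle_kl(sequences, weights, pseudocount, background, kept_columns) -> np.ndarray:
    """Per-column KL conservation by direct loops."""
    out = []
    for c in kept_columns:
        counts = {a: 0.0 for a in AA}
        any_residue = False
        for seq, w in zip(sequences, weights):
            ch = seq[c]
            if ch in AA:
                counts[ch] += w
                any_residue = True
        if not any_residue:
            out.append(math.nan)
            continue
        total = sum(counts.values()) + 20 * pseudocount
        kl = 0.0
        for idx, a in enumerate(AA):
            p = (counts[a] + pseudocount) / total
            if p > 0:
                kl += p * math.log(p / background[idx])
        out.append(kl)
    return np.array(out)


def oracle_min_distances(residue_coords: list[np.ndarray]) -> np.ndarray:
    """Minimum inter-residue atom distance by explicit atom-pair loops."""
    n = len(residue_coords)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if len(residue_coords[i]) == 0:
            continue
        out[i, i] = 0.0
        for j in range(i + 1, n):
            if len(residue_coords[j]) == 0:
                continue
            best = math.inf
            for p in residue_coords[i]:
                for q in residue_coords[j]:
                    d = math.dist(p, q)
                    best = min(best, d)
            out[i, j] = out[j, i] = best
    return out


def oracle_single_linkage(identity: np.ndarray, threshold: float) -> list[set[int]]:
    """Transitive closure of the identity>=threshold relation, via repeated merging."""
    n = identity.shape[0]
    clusters = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(identity[i, j] >= threshold
                       for i in clusters[a] for j in clusters[b]):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return clusters
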