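"""Per-sequence redundancy weights from single-linkage identity clustering.

Highly similar sequences (e.g. orthologs sampled densely in one clade) would
otherwise dominate column frequency estimates. Sequences are clustered by
single linkage at a pairwise-identity threshold and each sequence receives
weight 1 / (size of its cluster), so every cluster contributes one effective
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from coevomap.msa_io import Alignment, GAP_CODE


@dataclass(frozen=True)
class SequenceWeights:
    """Weights and cluster assignment per sequence row."""

    weight: np.ndarray
    cluster_id: np.ndarray
    identity_threshold: float

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over positions where neither is a gap.

    Returns 0.0 when no position has residues in both sequences.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def _identity_matrix(encoded: np.ndarray) -> np.ndarray:
    """All-pairs identity over non-gap positions, vectorized in chunks."""
    n = encoded.shape[0]
    nongap = encoded != GAP_CODE
    ident = np.zeros((n, n))
    chunk = max(1, 2_000_000 // max(1, n * encoded.shape[1]))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        eq = encoded[start:stop, None, :] == encoded[None, :, :]
        valid = nongap[start:stop, None, :] & nongap[None, :, :]
        matches = (eq & valid).sum(axis=2)
        counts = valid.sum(axis=2)
        with np.errstate(invalid="ignore"):
            ident[start:stop] = np.where(counts > 0, matches / np.maximum(counts, 1), 0.0)
    return ident


def cluster_weights(alignment: Alignment, identity_threshold: float = 0.62) -> SequenceWeights:
    """Single-linkage clusters at ``identity >= identity_threshold``; weight = 1/cluster size.

    Single linkage (transitive closure of the similarity relation) makes the
    result invariant to the order of sequences in the file, unlike greedy
    Hobohm-style schemes.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    enc = alignment.encoded()
    ident = _identity_matrix(enc)
    adjacency = csr_matrix(ident >= identity_threshold)
    n_clusters, labels = connected_components(adjacency, directed=False)
    sizes = np.bincount(labels, minlength=n_clusters)
    weight = 1.0 / sizes[labels]
    return SequenceWeights(weight=weight, cluster_id=labels,
                           identity_threshold=identity_threshold)
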