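"""Mutual information between alignment columns, APC correction and permutation z-scores.

For every pair of kept columns, amino-acid pair frequencies are estimated
from sequence-weighted counts with an additive pseudocount (low-count
correction); gaps and unknown residues do not contribute. The raw MI per
pair is

    MI(i, j) = sum_{a,b} p_ij(a,b) * ln[ p_ij(a,b) / (p_i(a) p_j(b)) ]

in nats. The average product correction (APC) subtracts the background term
mean_i * mean_j / mean_all from each entry to suppress shared phylogenetic
and entropic signal. Corrected scores are standardized into z-scores against
a null ensemble obtained by independently shuffling the residues within each
column, which destroys inter-column correlation while preserving every
column's composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from coevomap.msa_io import Alignment, ColumnMask

logger = logging.getLogger(__name__)

#: fixed default seed for the permutation null, overridable everywhere
DEFAULT_SEED = 42
N_AA = 20


class DegeneratePairError(ValueError):
    """Fewer than 2 sequences contribute residues to both columns of a pair."""


@dataclass(frozen=True)
class PairFrequencyTable:
    """Weighted, pseudocounted joint amino-acid frequencies for one column pair."""

    joint: np.ndarray            # (20, 20), sums to 1
    marginal_i: np.ndarray       # (20,)
    marginal_j: np.ndarray       # (20,)
    pseudocount: float
    effective_count: float       # sum of weights over contributing sequences


@dataclass(frozen=True)
class ScoreMatrices:
    """Raw MI, APC-corrected MI and permutation z-scores over kept columns.

    All matrices are symmetric with NaN on the diagonal and at pairs where
    fewer than two sequences contribute. ``degenerate`` flags pairs whose
    null standard deviation was zero (z defined as 0 there). ``positions``
    holds the 1-based ungapped-reference position of each kept column.
    """

    mi_raw: np.ndarray
    mi_apc: np.ndarray
    z: np.ndarray
    degenerate: np.ndarray
    positions: np.ndarray
    mean_mi: float
    n_permutations: int
    seed: int
    null: str = "per-pair"


def _weight_array(weights, n: int) -> np.ndarray:
    """Accept a SequenceWeights or a bare array of per-sequence weights."""
    w = np.asarray(getattr(weights, "weight", weights), dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return w


def pair_frequencies(
    alignment: Alignment,
    mask: ColumnMask,
    weights,
    i: int,
    j: int,
    pseudocount: float = 0.05,
) -> PairFrequencyTable:
    """Joint frequency table for kept alignment columns ``i`` and ``j``.

    Each sequence whose residues at both columns are standard amino acids
    contributes its weight to the corresponding cell; the pseudocount is
    added to every one of the 400 cells before normalization.
    """
    if i == j:
        raise ValueError("pair columns must differ")
    if not (mask.keep[i] and mask.keep[j]):
        raise ValueError(f"columns {i}, {j} must both be kept by the mask")
    enc = alignment.encoded()
    w = _weight_array(weights, alignment.n_sequences)
    ci, cj = enc[:, i], enc[:, j]
    contrib = (ci < N_AA) & (cj < N_AA)
    if contrib.sum() < 2:
        raise DegeneratePairError(
            f"only {int(contrib.sum())} sequences contribute to pair ({i}, {j})"
        )
    counts = np.zeros((N_AA, N_AA))
    np.add.at(counts, (ci[contrib], cj[contrib]), w[contrib])
    effective = float(w[contrib].sum())
    joint = counts + pseudocount
    joint /= joint.sum()
    return PairFrequencyTable(
        joint=joint,
        marginal_i=joint.sum(axis=1),
        marginal_j=joint.sum(axis=0),
        pseudocount=pseudocount,
        effective_count=effective,
    )


def mutual_information(table: PairFrequencyTable) -> float:
    """MI of a pair frequency table, in nats; 0*ln(0) terms contribute 0."""
    p = table.joint
    expected = np.outer(table.marginal_i, table.marginal_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / expected), 0.0)
    return float(terms.sum())


def _encode_kept(alignment: Alignment, mask: ColumnMask) -> np.ndarray:
    return alignment.encoded()[:, mask.kept_columns]


def _mi_from_encoded(enc: np.ndarray, w: np.ndarray, pseudocount: float) -> np.ndarray:
    """Vectorized MI matrix over the columns of an encoded sub-alignment.

    Joint counts for all pairs at once via one matrix product over the
    one-hot expansion; pairs with fewer than 2 contributing sequences and
    the diagonal are NaN.
    """
    n, k = enc.shape
    valid = enc < N_AA
    onehot = np.zeros((n, k * N_AA))
    s_idx, c_idx = np.nonzero(valid)
    onehot[s_idx, c_idx * N_AA + enc[s_idx, c_idx]] = 1.0
    joint = ((onehot * w[:, None]).T @ onehot)                      # (k*20, k*20)
    joint = joint.reshape(k, N_AA, k, N_AA).transpose(0, 2, 1, 3)   # (k, k, 20, 20)
    n_contrib = valid.astype(float).T @ valid.astype(float)         # sequences per pair

    mi = np.full((k, k), np.nan)
    # block over rows to bound the memory of the (block, k, 20, 20) temporaries
    block = max(1, int(8e6 // max(1, k * N_AA * N_AA)))
    for lo in range(0, k, block):
        hi = min(k, lo + block)
        j_blk = joint[lo:hi] + pseudocount
        total = j_blk.sum(axis=(2, 3), keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = j_blk / total
            pi = p.sum(axis=3, keepdims=True)
            pj = p.sum(axis=2, keepdims=True)
            terms = np.where(p > 0, p * np.log(p / (pi * pj)), 0.0)
        mi[lo:hi] = terms.sum(axis=(2, 3))
    mi[n_contrib < 2] = np.nan
    np.fill_diagonal(mi, np.nan)
    return mi


def mi_matrix(
    alignment: Alignment,
    mask: ColumnMask,
    weights,
    pseudocount: float = 0.05,
) -> np.ndarray:
    """Symmetric raw-MI matrix over kept columns (NaN diagonal/degenerate pairs)."""
    if mask.n_kept < 2:
        raise ValueError("need at least 2 kept columns")
    w = _weight_array(weights, alignment.n_sequences)
    return _mi_from_encoded(_encode_kept(alignment, mask), w, pseudocount)


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average product correction: mi(i,j) - mean_i * mean_j / mean_all.

    Row means and the global mean are taken over defined (non-NaN)
    off-diagonal entries; missing entries stay missing. If the global mean
    is zero the matrix is returned unchanged with a warning.
    """
    mi = np.asarray(mi, dtype=float)
    defined = np.isfinite(mi)
    np.fill_diagonal(defined, False)
    if defined.sum() == 0:
        logger.warning("APC skipped: no defined off-diagonal entries")
        return mi.copy()
    with np.errstate(invalid="ignore"):
        row_mean = np.where(defined.sum(axis=1) > 0,
                            np.nansum(np.where(defined, mi, 0.0), axis=1)
                            / np.maximum(defined.sum(axis=1), 1), np.nan)
    mean_all = float(mi[defined].mean())
    if mean_all == 0.0:
        logger.warning("APC skipped: mean MI is zero")
        return mi.copy()
    corrected = mi - np.outer(row_mean, row_mean) / mean_all
    corrected[~defined] = np.nan
    return corrected


def permutation_zscores(
    alignment: Alignment,
    mask: ColumnMask,
    weights,
    pseudocount: float = 0.05,
    n_permutations: int = 100,
    seed: int = DEFAULT_SEED,
    null: str = "per-pair",
) -> ScoreMatrices:
    """Standardize APC-corrected MI against a column-shuffled null ensemble.

    Each replicate independently permutes the residues (gaps included) within
    every kept column and recomputes the full APC-corrected MI matrix. With
    ``null="per-pair"`` every pair is standardized by its own null moments,
    so conserved columns with intrinsically small null scales are not drowned
    out; ``null="pooled"`` uses one mean/SD over all pairs and replicates.
    Pairs whose null SD is zero get z = 0 and are flagged degenerate.
    Deterministic for a fixed seed.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutation replicates")
    if null not in ("per-pair", "pooled"):
        raise ValueError(f"unknown null mode {null!r}")
    w = _weight_array(weights, alignment.n_sequences)
    enc = _encode_kept(alignment, mask)
    k = enc.shape[1]

    mi_raw = _mi_from_encoded(enc, w, pseudocount)
    mi_apc = apc_correct(mi_raw)

    rng = np.random.default_rng(seed)
    null_apc = np.empty((n_permutations, k, k))
    for r in range(n_permutations):
        shuffled = rng.permuted(enc, axis=0)  # independent shuffle per column
        null_apc[r] = apc_correct(_mi_from_encoded(shuffled, w, pseudocount))

    if null == "per-pair":
        finite = np.isfinite(null_apc)
        n_fin = finite.sum(axis=0)
        vals = np.where(finite, null_apc, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_mean = np.where(n_fin > 0, vals.sum(axis=0) / np.maximum(n_fin, 1), np.nan)
            dev2 = np.where(finite, (null_apc - null_mean) ** 2, 0.0).sum(axis=0)
            null_sd = np.where(n_fin > 1, np.sqrt(dev2 / np.maximum(n_fin - 1, 1)), np.nan)
    else:
        finite = null_apc[np.isfinite(null_apc)]
        null_mean = np.full((k, k), finite.mean())
        null_sd = np.full((k, k), finite.std(ddof=1))

    defined = np.isfinite(mi_apc)
    degenerate = defined & ~(null_sd > 0)
    z = np.full((k, k), np.nan)
    ok = defined & (null_sd > 0)
    z[ok] = (mi_apc[ok] - null_mean[ok]) / null_sd[ok]
    z[degenerate] = 0.0

    off = np.isfinite(mi_raw)
    mean_mi = float(mi_raw[off].mean()) if off.any() else float("nan")
    return ScoreMatrices(
        mi_raw=mi_raw,
        mi_apc=mi_apc,
        z=z,
        degenerate=degenerate,
        positions=mask.ref_position.copy(),
        mean_mi=mean_mi,
        n_permutations=n_permutations,
        seed=seed,
        null=null,
    )
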