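"""Per-column Kullback-Leibler conservation and enrichment/depletion logo data.

Conservation of a column is the KL divergence of its weighted amino-acid
distribution from a background distribution (BLOSUM62-derived by default):

    KL(c) = sum_a p_c(a) * ln( p_c(a) / q(a) )   [nats]

The signed per-amino-acid terms p_c(a) * ln(p_c(a)/q(a)) decompose each
column's score into enriched (positive) and depleted (negative)
contributions, which is what a KL sequence logo displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from coevomap.msa_io import Alignment, ColumnMask, STANDARD_AA
from coevomap.mi_engine import N_AA, _weight_array

# BLOSUM62 marginal amino-acid frequencies (Henikoff & Henikoff target
# distribution), normalized to sum to 1 at import.
BLOSUM62_FREQUENCIES = {
    "A": 0.0742, "C": 0.0246, "D": 0.0536, "E": 0.0543, "F": 0.0474,
    "G": 0.0741, "H": 0.0262, "I": 0.0679, "K": 0.0582, "L": 0.0989,
    "M": 0.0221, "N": 0.0446, "P": 0.0390, "Q": 0.0342, "R": 0.0516,
    "S": 0.0572, "T": 0.0510, "V": 0.0730, "W": 0.0131, "Y": 0.0321,
}

_BLOSUM62 = np.array([BLOSUM62_FREQUENCIES[aa] for aa in STANDARD_AA])
_BLOSUM62 /= _BLOSUM62.sum()


def blosum62_background() -> np.ndarray:
    """BLOSUM62-derived background frequencies in standard amino-acid order."""
    return _BLOSUM62.copy()


def uniform_background() -> np.ndarray:
    """Uniform background (1/20 per amino acid)."""
    return np.full(N_AA, 1.0 / N_AA)


@dataclass(frozen=True)
class ConservationProfile:
    """KL conservation per kept column (NaN where no standard residue occurs)."""

    kl: np.ndarray          # per kept column, nats
    positions: np.ndarray   # 1-based ungapped-reference positions
    background: np.ndarray  # the 20 background frequencies used


def _check_background(background: np.ndarray) -> np.ndarray:
    q = np.asarray(background, dtype=float)
    if q.shape != (N_AA,):
        raise ValueError("background must have 20 entries")
    if not np.all(q > 0):
        raise ValueError("background frequencies must be strictly positive")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    return q


def _column_frequencies(
    alignment: Alignment, mask: ColumnMask, weights, pseudocount: float
) -> np.ndarray:
    """Weighted, pseudocounted frequencies (n_kept, 20); NaN rows for empty columns."""
    enc = alignment.encoded()[:, mask.kept_columns]
    w = _weight_array(weights, alignment.n_sequences)
    n, k = enc.shape
    counts = np.zeros((k, N_AA))
    valid = enc < N_AA
    for c in range(k):
        rows = valid[:, c]
        np.add.at(counts[c], enc[rows, c], w[rows])
    freqs = counts + pseudocount
    totals = freqs.sum(axis=1)
    has_residue = valid.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = freqs / totals[:, None]
    freqs[~has_residue] = np.nan
    return freqs


def kl_conservation(
    alignment: Alignment,
    mask: ColumnMask,
    weights,
    background: np.ndarray | None = None,
    pseudocount: float = 0.05,
) -> ConservationProfile:
    """KL divergence of each kept column's residue distribution from the background."""
    q = _check_background(blosum62_background() if background is None else background)
    freqs = _column_frequencies(alignment, mask, weights, pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs / q), 0.0)
        terms[~np.isfinite(freqs)] = np.nan
    kl = terms.sum(axis=1)
    return ConservationProfile(kl=kl, positions=mask.ref_position.copy(), background=q)


def logo_data(
    alignment: Alignment,
    mask: ColumnMask,
    weights,
    columns: Iterable[int],
    background: np.ndarray | None = None,
    pseudocount: float = 0.05,
) -> pd.DataFrame:
    """Signed KL contributions per selected column and amino acid.

    ``columns`` are 0-based alignment column indices that must be kept by the
    mask. Rows are indexed by reference position in selection order; columns
    are the 20 amino acids. A ``freq_<aa>`` block with the raw frequencies is
    attached via ``DataFrame.attrs["frequencies"]`` (used when a single
    position is inspected).
    """
    cols = list(columns)
    if not cols:
        raise ValueError("empty column selection")
    kept = mask.kept_columns
    col_to_row = {int(c): r for r, c in enumerate(kept)}
    missing = [c for c in cols if c not in col_to_row]
    if missing:
        raise ValueError(f"columns not kept by the mask: {missing}")
    q = _check_background(blosum62_background() if background is None else background)
    freqs = _column_frequencies(alignment, mask, weights, pseudocount)
    rows = [col_to_row[c] for c in cols]
    sel = freqs[rows]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sel > 0, sel * np.log(sel / q), 0.0)
    positions = mask.ref_position[rows]
    aa_list = list(STANDARD_AA)
    df = pd.DataFrame(terms, index=pd.Index(positions, name="position"), columns=aa_list)
    df.attrs["frequencies"] = pd.DataFrame(
        sel, index=pd.Index(positions, name="position"), columns=aa_list
    )
    return df
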