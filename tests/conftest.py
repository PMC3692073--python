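import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from coevomap.msa_io import Alignment, mask_columns
from coevomap.structure_map import Residue, StructureModel


def make_alignment(seqs, ids=None, reference_row=0) -> Alignment:
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    return Alignment(identifiers=tuple(ids), sequences=tuple(seqs),
                     reference_row=reference_row)


def make_structure(sequence: str, coords=None, spacing: float = 3.8,
                   secondary=None) -> StructureModel:
    """CA-only chain built in memory; collinear CAs unless coords given."""
    n = len(sequence)
    if coords is None:
        coords = np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])
    residues = tuple(
        Residue(author_number=str(i + 1), amino_acid=aa,
                coords=np.atleast_2d(np.asarray(coords[i], dtype=float)),
                is_hydrogen=np.zeros(len(np.atleast_2d(coords[i])), dtype=bool))
        for i, aa in enumerate(sequence)
    )
    return StructureModel(chain_id="A", residues=residues,
                          secondary=tuple(secondary or ["coil"] * n))


def random_alignment(rng, n_seq, n_col, gap_rate=0.0):
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    chars = aa[rng.integers(0, 20, size=(n_seq, n_col))]
    if gap_rate > 0:
        gaps = rng.random((n_seq, n_col)) < gap_rate
        gaps[0] = False  # keep the reference gap-free so every column survives masking
        chars[gaps] = "-"
    return make_alignment(["".join(r) for r in chars])


@pytest.fixture
def tiny_alignment():
    return make_alignment(["ACDE", "ACDF", "ACDE", "GHKL"])


@pytest.fixture
def full_mask():
    def _mask(alignment):
        return mask_columns(alignment, max_gap_fraction=1.0)
    return _mask
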