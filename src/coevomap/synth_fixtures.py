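"""Synthetic alignments with planted covariation and toy PDB files.

The generator draws independent columns from a background amino-acid
distribution and plants covarying column pairs under a two-state coupled
model: with probability equal to the coupling strength, a sequence carries
one of the two state pairs (A,D) or (C,E) chosen uniformly; otherwise the
two columns are drawn independently from the same two-letter marginals. At
coupling 1 the pair's MI has the closed form ln 2, which makes the planted
signal analytically checkable. Gaps are injected uniformly at random; the
generator does not model phylogenetic relatedness or structured gap blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from coevomap.msa_io import Alignment, STANDARD_AA
from coevomap.conservation import blosum62_background


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic alignment."""

    n_sequences: int = 200
    n_columns: int = 30
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    conservation_columns: tuple[tuple[int, str, float], ...] = ()
    background: np.ndarray | None = None
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        used: set[int] = set()
        for i, j, coupling in self.planted_pairs:
            if not (0 <= i < self.n_columns and 0 <= j < self.n_columns) or i == j:
                raise ValueError(f"planted pair ({i}, {j}) out of range or degenerate")
            if i in used or j in used:
                raise ValueError("planted pairs must use disjoint columns")
            if not 0 <= coupling <= 1:
                raise ValueError("coupling must be in [0, 1]")
            used.update((i, j))
        for c, aa, freq in self.conservation_columns:
            if not 0 <= c < self.n_columns:
                raise ValueError(f"conservation column {c} out of range")
            if aa not in STANDARD_AA or not 0 <= freq <= 1:
                raise ValueError(f"bad conservation spec ({c}, {aa}, {freq})")


def generate_msa(spec: SynthSpec) -> tuple[Alignment, list[tuple[int, int, float]]]:
    """Generate a synthetic alignment; returns it with the planted-pair ground truth.

    Deterministic per ``spec.seed``. The first sequence is the reference row.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.background if spec.background is not None else blosum62_background()
    q = np.asarray(q, dtype=float)
    q = q / q.sum()
    n, k = spec.n_sequences, spec.n_columns
    aa = np.array(list(STANDARD_AA))
    chars = aa[rng.choice(len(aa), size=(n, k), p=q)]

    for c, dominant, freq in spec.conservation_columns:
        hit = rng.random(n) < freq
        chars[hit, c] = dominant

    for i, j, coupling in spec.planted_pairs:
        # state 0 -> (A, D); state 1 -> (C, E); uncoupled draws keep the marginals
        coupled = rng.random(n) < coupling
        state_i = rng.integers(0, 2, size=n)
        state_j = np.where(coupled, state_i, rng.integers(0, 2, size=n))
        chars[:, i] = np.where(state_i == 0, "A", "C")
        chars[:, j] = np.where(state_j == 0, "D", "E")

    if spec.gap_rate > 0:
        gaps = rng.random((n, k)) < spec.gap_rate
        chars[gaps] = "-"

    width = len(str(n))
    identifiers = tuple(f"seq{idx + 1:0{width}d}" for idx in range(n))
    sequences = tuple("".join(row) for row in chars)
    alignment = Alignment(identifiers=identifiers, sequences=sequences)
    return alignment, list(spec.planted_pairs)


def write_ground_truth(pairs: list[tuple[int, int, float]], path: str | Path) -> None:
    """Write planted pairs as a small TSV (column_i, column_j, coupling)."""
    with open(path, "w") as fh:
        fh.write("column_i\tcolumn_j\tcoupling\n")
        for i, j, coupling in pairs:
            fh.write(f"{i}\t{j}\t{coupling:g}\n")


def helix_ca_coordinates(n_residues: int, rise: float = 1.5,
                         radius: float = 2.3, turn_deg: float = 100.0) -> np.ndarray:
    """CA coordinates of an ideal alpha helix (1.5 A rise, 100 deg per residue)."""
    t = np.arange(n_residues)
    theta = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * t])


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def generate_toy_pdb(
    n_residues: int,
    geometry: str = "line",
    spacing: float = 3.8,
    path: str | Path = "toy.pdb",
    sequence: str | None = None,
) -> Path:
    """Write a CA-only single-chain PDB with exact coordinates.

    ``geometry="line"`` places CAs collinearly at ``spacing`` Angstrom;
    ``geometry="helix"`` uses ideal alpha-helix parameters (spacing ignored).
    Residues are poly-alanine unless ``sequence`` (one-letter codes, length
    ``n_residues``) is given.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    if geometry == "line":
        coords = np.column_stack([
            spacing * np.arange(n_residues),
            np.zeros(n_residues),
            np.zeros(n_residues),
        ])
    elif geometry == "helix":
        coords = helix_ca_coordinates(n_residues)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for idx, (x, y, z) in enumerate(coords, start=1):
            res3 = _AA3.get(sequence[idx - 1], "UNK") if sequence else "ALA"
            fh.write(
                f"ATOM  {idx:5d}  CA  {res3} A{idx:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
    return path
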