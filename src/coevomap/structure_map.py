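"""PDB chain parsing, heavy-atom distances and alignment-to-structure mapping.

Inter-residue distance is defined as the shortest distance between any two
atoms of the residues, excluding hydrogens. The reference sequence of the
alignment is mapped onto the chain sequence with Smith-Waterman local
alignment (BLOSUM62, affine gaps), and reported positions then follow the
PDB author numbering of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import logging
import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from coevomap.msa_io import Alignment, ColumnMask, STANDARD_AA

logger = logging.getLogger(__name__)


class ChainLookupError(KeyError):
    """Requested chain is not present in the structure."""


class StructureParseError(ValueError):
    """The file has no usable ATOM records."""


class MappingError(ValueError):
    """Smith-Waterman produced no aligned residue pairs."""


@dataclass(frozen=True)
class Residue:
    """One chain residue: author numbering (with insertion code), code and atoms."""

    author_number: str              # e.g. "52" or "52A"
    amino_acid: str                 # one-letter code, 'X' if non-standard
    coords: np.ndarray              # (n_atoms, 3) in Angstrom, all atoms
    is_hydrogen: np.ndarray         # per atom

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[~self.is_hydrogen]


@dataclass(frozen=True)
class StructureModel:
    """First model of one chain: ordered residues plus secondary labels."""

    chain_id: str
    residues: tuple[Residue, ...]
    secondary: tuple[str, ...]      # per residue: helix | sheet | coil

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SeqStructMap:
    """One-to-one, order-preserving map between kept columns and chain residues.

    ``column_to_residue`` maps 0-based kept-column index -> structure residue
    index; ``coverage`` is the fraction of reference residues that mapped.
    """

    column_to_residue: dict[int, int]
    coverage: float
    author_numbers: dict[int, str] = field(default_factory=dict)


def _residue_from_gemmi(res: gemmi.Residue) -> Residue | None:
    # keep the highest-occupancy conformer among altlocs of the same atom name
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    if not best:
        return None
    atoms = list(best.values())
    coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    is_h = np.array([a.element.is_hydrogen for a in atoms], dtype=bool)
    info = gemmi.find_tabulated_residue(res.name)
    one = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
    if one not in STANDARD_AA:
        one = "X"
    icode = res.seqid.icode.strip()
    return Residue(
        author_number=f"{res.seqid.num}{icode}",
        amino_acid=one,
        coords=coords,
        is_hydrogen=is_h,
    )


def _secondary_labels(structure: gemmi.Structure, chain_name: str,
                      residues: list[gemmi.Residue]) -> list[str]:
    labels = ["coil"] * len(residues)

    def mark(start, end, label):
        if start.chain_name != chain_name:
            return
        lo, hi = start.res_id.seqid.num, end.res_id.seqid.num
        for idx, res in enumerate(residues):
            if lo <= res.seqid.num <= hi:
                labels[idx] = label

    for helix in structure.helices:
        mark(helix.start, helix.end, "helix")
    for sheet in structure.sheets:
        for strand in sheet.strands:
            mark(strand.start, strand.end, "sheet")
    return labels


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse a PDB file; first model only, one chain.

    ``chain=None`` selects the first chain. HELIX/SHEET header records, when
    present, populate per-residue secondary labels; everything else is coil.
    Hydrogens are retained in storage but excluded from distance computation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise StructureParseError(f"{path} contains no models")
    model = structure[0]
    names = [ch.name for ch in model]
    if not names:
        raise StructureParseError(f"{path} contains no chains with ATOM records")
    if chain is None:
        chain_obj = model[0]
    else:
        found = [ch for ch in model if ch.name == chain]
        if not found:
            raise ChainLookupError(
                f"chain {chain!r} not in {path.name}; available chains: {names}"
            )
        chain_obj = found[0]
    gemmi_residues = [r for r in chain_obj if any(True for _ in r)]
    residues = [_residue_from_gemmi(r) for r in gemmi_residues]
    keep = [(g, r) for g, r in zip(gemmi_residues, residues) if r is not None]
    if not keep:
        raise StructureParseError(f"chain {chain_obj.name} of {path} has no atoms")
    secondary = _secondary_labels(structure, chain_obj.name, [g for g, _ in keep])
    return StructureModel(
        chain_id=chain_obj.name,
        residues=tuple(r for _, r in keep),
        secondary=tuple(secondary),
    )


def min_distances(structure: StructureModel) -> np.ndarray:
    """Symmetric matrix of minimum heavy-atom inter-residue distances (Angstrom).

    A residue with only hydrogen atoms has NaN in its row and column.
    """
    if structure.n_residues < 2:
        raise ValueError("need at least 2 residues")
    heavy = [r.heavy_coords for r in structure.residues]
    n = structure.n_residues
    dist = np.full((n, n), np.nan)
    has_heavy = [len(h) > 0 for h in heavy]
    for i in range(n):
        if not has_heavy[i]:
            continue
        dist[i, i] = 0.0
        for j in range(i + 1, n):
            if not has_heavy[j]:
                continue
            d = cdist(heavy[i], heavy[j]).min()
            dist[i, j] = dist[j, i] = d
    return dist


def map_alignment_to_structure(
    alignment: Alignment,
    mask: ColumnMask,
    structure: StructureModel,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SeqStructMap:
    """Smith-Waterman map of the ungapped reference sequence onto the chain.

    Matched positions define a monotone one-to-one map from kept alignment
    columns to structure residue indices; mapped positions are later reported
    with the chain's author numbering. Coverage below 30% triggers a warning.
    """
    ref_ungapped = alignment.reference_sequence.replace("-", "")
    chain_seq = structure.sequence
    if not ref_ungapped or not chain_seq:
        raise MappingError("reference or chain sequence is empty")
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(substitution_matrix),
        open_gap_score=-abs(gap_open),
        extend_gap_score=-abs(gap_extend),
    )
    alignments = aligner.align(ref_ungapped, chain_seq)
    if len(alignments) == 0:
        raise MappingError("Smith-Waterman found no local alignment")
    best = alignments[0]
    # ref_pos (1-based ungapped reference) -> structure residue index
    ref_to_res: dict[int, int] = {}
    for (r0, r1), (s0, s1) in zip(*best.aligned):
        for offset in range(r1 - r0):
            ref_to_res[r0 + offset + 1] = s0 + offset
    if not ref_to_res:
        raise MappingError("Smith-Waterman alignment maps no residue pairs")
    column_to_residue = {
        k: ref_to_res[int(pos)]
        for k, pos in enumerate(mask.ref_position)
        if int(pos) in ref_to_res
    }
    coverage = len(ref_to_res) / len(ref_ungapped)
    if coverage < 0.30:
        logger.warning(
            "structure mapping covers only %.0f%% of the reference", 100 * coverage
        )
    author = {
        k: structure.residues[ri].author_number
        for k, ri in column_to_residue.items()
    }
    return SeqStructMap(
        column_to_residue=column_to_residue,
        coverage=coverage,
        author_numbers=author,
    )


def distance_network(dist: np.ndarray, cutoff: float = 5.0) -> nx.Graph:
    """Graph with an edge between residues closer than ``cutoff`` (strict <)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = np.asarray(dist)
    n = dist.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(dist < cutoff, k=1))
    graph.add_edges_from(
        (int(i), int(j), {"distance": float(dist[i, j])}) for i, j in zip(ii, jj)
    )
    return graph
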