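"""Reading, validation and column masking of protein multiple sequence alignments.

Supported on-disk formats are FASTA, ClustalW, Phylip, Nexus and PIR, parsed
through Biopython. Internally an alignment is a list of (identifier, residues)
records over the 20 standard amino acids plus gap ``-`` and unknown ``X``,
with one row designated as the reference sequence. All downstream reporting
is indexed by 1-based positions in the ungapped reference sequence.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = STANDARD_AA + GAP + UNKNOWN

#: integer codes: 0..19 amino acids, 20 gap, 21 unknown
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
GAP_CODE = 20
UNKNOWN_CODE = 21

_BIOPYTHON_FORMAT = {
    "fasta": "fasta",
    "clustal": "clustal",
    "phylip": "phylip-relaxed",
    "nexus": "nexus",
    "pir": "pir",
}


class MsaFormatError(ValueError):
    """The file could not be parsed in the requested (or sniffed) format."""


class MsaValidationError(ValueError):
    """The parsed content violates alignment invariants."""


class ReferenceLookupError(KeyError):
    """No record matches the requested reference identifier."""


class AmbiguousReferenceError(KeyError):
    """A reference prefix matches more than one record."""


@dataclass(frozen=True)
class Alignment:
    """A validated protein alignment with a designated reference row.

    ``identifiers`` and ``sequences`` are parallel; every sequence has the
    same length and uses only the 20 standard amino acids, ``-`` and ``X``.
    """

    identifiers: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_row: int = 0

    def __post_init__(self) -> None:
        if len(self.identifiers) != len(self.sequences):
            raise MsaValidationError("identifiers and sequences differ in length")
        if len(self.sequences) < 2:
            raise MsaValidationError("an alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            bad = [i for i, s in zip(self.identifiers, self.sequences)
                   if len(s) != len(self.sequences[0])]
            raise MsaValidationError(
                f"ragged alignment: sequences {bad} differ in length from the first"
            )
        if len(self.sequences[0]) < 2:
            raise MsaValidationError("alignment must have at least 2 columns")
        if not (0 <= self.reference_row < len(self.sequences)):
            raise MsaValidationError(f"reference_row {self.reference_row} out of range")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_id(self) -> str:
        return self.identifiers[self.reference_row]

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.reference_row]

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_sequences, n_columns); 0-19 aa, 20 gap, 21 unknown."""
        lut = np.full(128, UNKNOWN_CODE, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
        lut[ord(GAP)] = GAP_CODE
        raw = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return lut[raw].reshape(self.n_sequences, self.n_columns)


@dataclass(frozen=True)
class ColumnMask:
    """Kept-column mask with per-column gap fractions and reference numbering.

    ``ref_position[k]`` is the 1-based index in the ungapped reference
    sequence of the k-th kept column; columns where the reference sequence
    has a gap are never kept.
    """

    keep: np.ndarray
    gap_fraction: np.ndarray
    ref_position: np.ndarray = field(repr=False)

    @property
    def kept_columns(self) -> np.ndarray:
        """0-based alignment column indices of kept columns, in order."""
        return np.flatnonzero(self.keep)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def _normalize_residues(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        if ch in AA_INDEX or ch == GAP:
            out.append(ch)
        else:
            out.append(UNKNOWN)
    return "".join(out)


def _dedupe_identifiers(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate identifier %r renamed to %r", name, new)
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


def sniff_format(path: str | Path) -> str:
    """Guess the alignment format from the leading bytes of the file."""
    with open(path, "rb") as fh:
        head = fh.read(4096).lstrip()
    if head.startswith(b">P1;"):
        return "pir"
    if head.startswith(b">"):
        return "fasta"
    if head.upper().startswith(b"CLUSTAL"):
        return "clustal"
    if head.startswith(b"#NEXUS"):
        return "nexus"
    first = head.split(b"\n", 1)[0].split()
    if len(first) == 2 and all(tok.isdigit() for tok in first):
        return "phylip"
    raise MsaFormatError(f"could not sniff alignment format of {path}")


def read_msa(path: str | Path, format: str = "auto") -> Alignment:
    """Read and validate an alignment file.

    Residues are uppercased, ``.`` is normalized to ``-`` and non-standard
    amino-acid codes are mapped to ``X``. The first record becomes the
    reference row (see :func:`set_reference`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = sniff_format(path)
    if format not in _BIOPYTHON_FORMAT:
        raise MsaFormatError(f"unsupported format {format!r}")
    bp_format = _BIOPYTHON_FORMAT[format]
    try:
        if format in ("pir", "fasta"):
            # SeqIO tolerates ragged records, so length validation (with the
            # offending identifiers) happens in the Alignment constructor
            records = list(SeqIO.parse(str(path), bp_format))
        else:
            records = list(AlignIO.read(str(path), bp_format))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        first_line = path.read_text().splitlines()[0] if path.read_text() else ""
        raise MsaFormatError(
            f"could not parse {path} as {format}: {exc} (first line: {first_line!r})"
        ) from exc
    if not records:
        raise MsaFormatError(f"{path} contains no sequences")
    ids = _dedupe_identifiers([r.id for r in records])
    seqs = [_normalize_residues(str(r.seq)) for r in records]
    return Alignment(identifiers=tuple(ids), sequences=tuple(seqs))


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA (the processed-MSA artifact of a run)."""
    with open(path, "w") as fh:
        for name, seq in zip(alignment.identifiers, alignment.sequences):
            fh.write(f">{name}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start:start + 60] + "\n")


def set_reference(alignment: Alignment, identifier: str | None = None) -> Alignment:
    """Return a copy of the alignment with the reference row selected.

    With no identifier the first sequence is the reference. Otherwise an
    exact identifier match is tried first, then a unique prefix match.
    """
    if identifier is None:
        return replace(alignment, reference_row=0)
    exact = [i for i, name in enumerate(alignment.identifiers) if name == identifier]
    if len(exact) == 1:
        return replace(alignment, reference_row=exact[0])
    prefix = [i for i, name in enumerate(alignment.identifiers)
              if name.startswith(identifier)]
    if len(prefix) == 1:
        return replace(alignment, reference_row=prefix[0])
    if len(prefix) > 1:
        names = [alignment.identifiers[i] for i in prefix]
        raise AmbiguousReferenceError(
            f"reference {identifier!r} matches several records: {names}"
        )
    raise ReferenceLookupError(f"no record matches reference {identifier!r}")


def mask_columns(alignment: Alignment, max_gap_fraction: float = 0.5) -> ColumnMask:
    """Mask alignment columns by gap content and reference coverage.

    A column is kept iff its gap fraction is at most ``max_gap_fraction``
    and the reference row carries a residue there. Kept columns are numbered
    by their 1-based position in the ungapped reference sequence.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    enc = alignment.encoded()
    gap_fraction = (enc == GAP_CODE).mean(axis=0)
    ref_is_residue = enc[alignment.reference_row] != GAP_CODE
    keep = (gap_fraction <= max_gap_fraction) & ref_is_residue
    if keep.sum() < 2:
        raise MsaValidationError(
            f"degenerate alignment: only {int(keep.sum())} columns survive masking"
        )
    # 1-based ungapped reference numbering of every reference residue
    ref_numbering = np.cumsum(ref_is_residue)
    ref_position = ref_numbering[keep].astype(int)
    return ColumnMask(keep=keep, gap_fraction=gap_fraction, ref_position=ref_position)
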