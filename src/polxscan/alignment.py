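"""Aligned-FASTA handling and reference-residue-to-column anchoring.

The central coordinate problem solved here: analyses are phrased in the
residue numbering of a reference protein (e.g. "residues 178-279"), while
the data live in alignment columns.  :class:`ReferenceAnchor` maps reference
residue numbers onto 0-based alignment columns so that windows and single
sites can be extracted from every row of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import AlignmentShapeError, AlphabetError, AnchorRangeError

GAP = "-"

#: the 20 standard amino acids
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: ambiguity / non-standard codes normalized to 'X' on input
AMBIGUOUS_AA = set("BZJUOX*")

#: characters allowed in a normalized aligned sequence
ALPHABET = STANDARD_AA | {"X", GAP}


def normalize_aligned_seq(seq: str, *, seq_id: str = "?") -> str:
    """Upper-case, convert '.' gaps to '-', collapse ambiguity codes to 'X'.

    Raises
    ------
    AlphabetError
        If a character outside the amino-acid alphabet remains, naming the
        record and 1-based position.
    """
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch == ".":
            ch = GAP
        elif ch in AMBIGUOUS_AA:
            ch = "X"
        if ch not in ALPHABET:
            raise AlphabetError(
                f"illegal character {ch!r} in record {seq_id!r} at position {i + 1}"
            )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class Msa:
    """An immutable protein multiple sequence alignment.

    ``records`` preserves input order; all aligned sequences have identical
    length ``n_columns`` and seq_ids are unique.
    """

    records: tuple[tuple[str, str], ...]
    n_columns: int
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        index = {}
        for seq_id, seq in self.records:
            if seq_id in index:
                raise ValueError(f"duplicate seq_id {seq_id!r}")
            if len(seq) != self.n_columns:
                raise AlignmentShapeError(
                    f"record {seq_id!r} has length {len(seq)}, "
                    f"expected {self.n_columns}"
                )
            index[seq_id] = seq
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> str:
        return self._index[seq_id]

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Msa":
        """Build an Msa from (seq_id, aligned_seq) pairs, normalizing each row."""
        normalized = []
        n_columns = None
        for seq_id, seq in pairs:
            seq = normalize_aligned_seq(seq, seq_id=seq_id)
            if n_columns is None:
                n_columns = len(seq)
            elif len(seq) != n_columns:
                raise AlignmentShapeError(
                    f"record {seq_id!r} has length {len(seq)}, expected {n_columns}"
                )
            normalized.append((seq_id, seq))
        if not normalized:
            raise ValueError("alignment contains no records")
        if n_columns == 0:
            raise AlignmentShapeError("alignment has zero columns")
        return cls(records=tuple(normalized), n_columns=n_columns)


def read_fasta_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Letters are upper-cased, '.' gaps converted to '-', ambiguity codes
    (B, Z, J, U, O) normalized to 'X'.  Ragged rows raise
    :class:`AlignmentShapeError`; unknown characters raise
    :class:`AlphabetError`.
    """
    path = Path(path)
    records = SeqIO.parse(str(path), "fasta")
    pairs = [(rec.id, str(rec.seq)) for rec in records]
    if not pairs:
        raise ValueError(f"no FASTA records found in {path}")
    return Msa.from_pairs(pairs)


def write_fasta_alignment(msa: Msa, path: str | Path, *, wrap: int = 60) -> None:
    """Write the alignment as FASTA with ``wrap``-column line wrapping."""
    with open(path, "w") as fh:
        for seq_id, seq in msa.records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def ungapped_length(aligned_seq: str) -> int:
    """Number of non-gap characters in an aligned sequence."""
    return len(aligned_seq) - aligned_seq.count(GAP)


@dataclass(frozen=True)
class ReferenceAnchor:
    """Map from reference residue numbers to 0-based alignment columns."""

    ref_id: str
    first_residue_number: int
    residue_to_column: dict[int, int]

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residue_to_column) - 1

    def column(self, residue_number: int) -> int:
        """Alignment column of a single reference residue."""
        try:
            return self.residue_to_column[residue_number]
        except KeyError:
            raise AnchorRangeError(
                f"residue {residue_number} is outside the mapped span "
                f"{self.first_residue_number}..{self.last_residue_number} "
                f"of reference {self.ref_id!r}"
            ) from None


def build_anchor(msa: Msa, ref_id: str, first_residue_number: int = 1) -> ReferenceAnchor:
    """Construct the residue-number → column map from the reference row.

    Residue ``k`` maps to the column of the reference's
    ``(k - first_residue_number + 1)``-th non-gap character.
    """
    if ref_id not in msa:
        raise KeyError(f"reference {ref_id!r} not present in the alignment")
    row = msa[ref_id]
    mapping = {}
    residue = first_residue_number
    for col, ch in enumerate(row):
        if ch != GAP:
            mapping[residue] = col
            residue += 1
    return ReferenceAnchor(
        ref_id=ref_id,
        first_residue_number=first_residue_number,
        residue_to_column=mapping,
    )


def columns_for_range(
    anchor: ReferenceAnchor, start_res: int, end_res: int
) -> tuple[int, int]:
    """Inclusive column interval spanning reference residues start..end.

    Insertion columns (where the reference is gapped) that fall between the
    two boundary residues are inside the returned interval.
    """
    if start_res > end_res:
        raise ValueError(f"start residue {start_res} > end residue {end_res}")
    return anchor.column(start_res), anchor.column(end_res)
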