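"""Reference-numbered coordinate mapping through gapped alignments.

Signature residues are named in the ungapped 1-based numbering of a
reference protein (e.g. position 605 of *B. cereus* RC607 MerA). To look
a residue up in another aligned sequence, that number must be translated
to the alignment column where the reference carries its 605th residue.
:class:`AlignmentMap` holds that bijection between non-gap reference
columns and reference residue numbers.

Columns are 0-based internally; reference numbering is 1-based, matching
the literature convention. ``'.'`` gaps are normalised to ``'-'`` and
residues are upper-cased on input.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GAP",
    "MISSING",
    "Alignment",
    "AlignmentMap",
    "AlignmentError",
    "build_map",
    "residue_at",
    "trim_nterminal",
    "read_alignment",
    "write_alignment",
]

#: Marker returned when the queried row has a gap under the reference column.
GAP = "-"

#: Marker returned when the requested reference position exceeds the
#: reference length (e.g. a numbering beyond a truncated reference row).
MISSING = "?"


class AlignmentError(ValueError):
    """Alignment or mapping request is invalid."""


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple sequence alignment: ordered (id, row) pairs."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        norm = tuple((sid, _normalise(seq)) for sid, seq in self.rows)
        object.__setattr__(self, "rows", norm)
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise AlignmentError("duplicate sequence ids in alignment")
        object.__setattr__(self, "_index", {sid: seq for sid, seq in self.rows})

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.rows)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def row(self, seq_id: str) -> str:
        try:
            return self._index[seq_id]
        except KeyError:
            raise AlignmentError(f"sequence {seq_id!r} not in alignment") from None


@dataclass(frozen=True)
class AlignmentMap:
    """Bijection between reference residue numbers and alignment columns.

    ``ref_to_col[k]`` is the 0-based column holding the k-th (1-based)
    non-gap residue of the reference row; ``col_to_ref`` is its inverse,
    defined only on non-gap reference columns.
    """

    reference_id: str
    ref_to_col: dict[int, int]
    col_to_ref: dict[int, int]

    @property
    def ref_length(self) -> int:
        return len(self.ref_to_col)


def build_map(aln: Alignment, reference_id: str) -> AlignmentMap:
    """Number the non-gap columns of the reference row 1..L_ref."""
    ref_row = aln.row(reference_id)
    ref_to_col: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            k += 1
            ref_to_col[k] = col
    if k == 0:
        raise AlignmentError(f"reference row {reference_id!r} is all gaps")
    col_to_ref = {col: ref for ref, col in ref_to_col.items()}
    return AlignmentMap(reference_id, ref_to_col, col_to_ref)


def residue_at(
    aln: Alignment, amap: AlignmentMap, seq_id: str, ref_position: int
) -> str:
    """Residue of ``seq_id`` under reference position ``ref_position``.

    Returns :data:`GAP` if the row is gapped there and :data:`MISSING` if
    the reference numbering does not extend to ``ref_position``.
    """
    row = aln.row(seq_id)
    if ref_position < 1:
        raise AlignmentError(f"ref_position must be >= 1, got {ref_position}")
    col = amap.ref_to_col.get(ref_position)
    if col is None:
        return MISSING
    return row[col]


def trim_nterminal(
    aln: Alignment, amap: AlignmentMap, first_kept_ref_position: int
) -> Alignment:
    """Drop all columns left of a reference position.

    Used to remove the N-terminal metal-binding (NmerA) region before
    exporting a tree-ready alignment block. Row order and ids are kept;
    rebuilding the map on the result places ``first_kept_ref_position``
    at column 0.
    """
    if first_kept_ref_position not in amap.ref_to_col:
        raise AlignmentError(
            f"reference position {first_kept_ref_position} out of range "
            f"1..{amap.ref_length}"
        )
    start = amap.ref_to_col[first_kept_ref_position]
    return Alignment(tuple((sid, seq[start:]) for sid, seq in aln.rows))


def read_alignment(path_or_handle) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    if not records:
        raise AlignmentError("no sequences found in aligned FASTA input")
    return Alignment(tuple((r.id, str(r.seq)) for r in records))


def write_alignment(aln: Alignment, path_or_handle) -> None:
    """Write an :class:`Alignment` as aligned FASTA ('-' gaps only)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.rows
    ]
    SeqIO.write(records, path_or_handle, "fasta")
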