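"""Protein sequence records and FASTA I/O.

Sequences are uppercased on ingest. The canonical amino-acid alphabet is
the 20 standard letters; ``X`` is tolerated as an ambiguity code in subject
sequences (its handling in motif matching and alignment is decided by the
consumer modules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity code tolerated in subject sequences.
AMBIGUOUS = "X"

#: Marker used for reference positions not covered by an alignment.
GAP = "-"


class SequenceError(ValueError):
    """A sequence contains a character outside the accepted alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id :
        Unique sequence identifier (FASTA header token).
    seq :
        Amino-acid sequence; uppercased on construction.
    description :
        Free-text description (remainder of the FASTA header).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self, allow_x: bool = True) -> None:
        """Raise :class:`SequenceError` naming the first offending position."""
        allowed = AA_SET | {AMBIGUOUS} if allow_x else AA_SET
        for i, ch in enumerate(self.seq, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"{self.id}: non-amino-acid character {ch!r} at position {i}"
                )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq), rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path_or_handle) -> None:
    """Write protein records to FASTA (60-column wrapped).

    Accepts a path or an open text handle.
    """
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    if isinstance(path_or_handle, (str, Path)):
        SeqIO.write(seqs, str(path_or_handle), "fasta")
    else:
        SeqIO.write(seqs, path_or_handle, "fasta")
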