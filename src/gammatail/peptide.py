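"""Peptide container and FASTA I/O.

A :class:`Peptide` is an identified amino-acid sequence over the 20
canonical one-letter codes — the unit every sequence metric in this
package operates on.  Gaps and ambiguity codes are rejected here so that
downstream scoring never has to special-case them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class Peptide:
    """An identified peptide sequence.

    Parameters
    ----------
    id
        Free-text label (FASTA description line).
    sequence
        Uppercase string over the 20 canonical amino-acid letters;
        must be nonempty, with no gaps or ambiguity codes.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("peptide sequence must be nonempty")
        if not self.sequence.isupper():
            raise InvalidInputError(
                f"peptide sequence must be uppercase: {self.sequence!r}"
            )
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise InvalidInputError(
                f"non-canonical residue(s) {sorted(bad)} in peptide {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str, id: Union[str, None] = None) -> "Peptide":
        """Return a copy carrying ``sequence`` (and optionally a new id)."""
        return Peptide(self.id if id is None else id, sequence)


def read_fasta(path: Union[str, Path]) -> list[Peptide]:
    """Read peptides from a FASTA file (description line becomes the id)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return [Peptide(rec.description, str(rec.seq).upper()) for rec in records]


def write_fasta(peptides: Iterable[Peptide], path: Union[str, Path]) -> None:
    """Write peptides to a FASTA file, one record each."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id.split()[0], description=p.id)
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")
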