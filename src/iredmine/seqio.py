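"""FASTA input/output, sequence validation and redundancy removal.

The discovery pipeline starts from a pool of candidate protein sequences.
Because the same protein is typically found by more than one template search,
and because databases carry distinct accessions for identical sequences, the
pool is first reduced to unique entries: duplicate identifiers are dropped,
and sequences that are residue-for-residue identical under different
identifiers are collapsed onto the first occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: The 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Letters accepted in input sequences. ``X`` (unknown residue) is tolerated
#: on input; records containing it fail motif/residue criteria downstream.
ALLOWED_LETTERS = AMINO_ACIDS | {"X"}


class SequenceError(ValueError):
    """Raised for malformed sequence records (empty or illegal residues)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an accession-like identifier.

    Parameters
    ----------
    id : str
        Non-empty identifier (e.g. a UniProt accession).
    residues : str
        Upper-case amino-acid string over the 20-letter alphabet plus
        optional ``X``.
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record has an empty id")
        if not self.residues:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        for offset, letter in enumerate(self.residues):
            if letter not in ALLOWED_LETTERS:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {letter!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def contains_x(self) -> bool:
        return "X" in self.residues


@dataclass
class DedupReport:
    """Accounting of the duplicate/redundancy removal step."""

    n_input: int
    n_removed_duplicate_ids: int
    n_removed_redundant_sequences: int
    n_output: int
    removed_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_removed_duplicate_ids": self.n_removed_duplicate_ids,
                "n_removed_redundant_sequences": self.n_removed_redundant_sequences,
                "n_output": self.n_output,
                "removed_pairs": [list(p) for p in self.removed_pairs],
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["kept_id\tremoved_id"]
        lines += [f"{kept}\t{removed}" for kept, removed in self.removed_pairs]
        return "\n".join(lines) + "\n"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Line wrapping inside sequences is ignored; residues are upper-cased.
    Raises :class:`SequenceError` for empty sequences or illegal letters,
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width``."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=_description_tail(r))
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


def _description_tail(record: SequenceRecord) -> str:
    # Biopython prints "id description"; strip a leading repeat of the id.
    desc = record.description
    if desc.startswith(record.id):
        desc = desc[len(record.id):].strip()
    return desc


def deduplicate(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], DedupReport]:
    """Remove duplicate ids and redundant (identical-residue) sequences.

    The first occurrence in input order is kept in both cases; output order
    is a stable subsequence of the input order. "Redundant" means exact
    residue-string equality only.
    """
    kept: list[SequenceRecord] = []
    seen_ids: dict[str, SequenceRecord] = {}
    seen_seqs: dict[str, SequenceRecord] = {}
    n_dup_ids = 0
    n_redundant = 0
    removed_pairs: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen_ids:
            n_dup_ids += 1
            removed_pairs.append((seen_ids[rec.id].id, rec.id))
            continue
        if rec.residues in seen_seqs:
            n_redundant += 1
            removed_pairs.append((seen_seqs[rec.residues].id, rec.id))
            seen_ids[rec.id] = seen_seqs[rec.residues]
            continue
        seen_ids[rec.id] = rec
        seen_seqs[rec.residues] = rec
        kept.append(rec)
    report = DedupReport(
        n_input=len(records),
        n_removed_duplicate_ids=n_dup_ids,
        n_removed_redundant_sequences=n_redundant,
        n_output=len(kept),
        removed_pairs=removed_pairs,
    )
    return kept, report
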