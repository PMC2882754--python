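"""Single-pass membrane-protein records and topology-aware tail extraction.

A single-pass (bitopic) membrane protein exposes one of its two termini
to the cytosol, depending on its topology:

* **type I** — N-terminus out, C-terminus in: the cytoplasmic tail is
  everything C-terminal of the transmembrane domain (TMD);
* **type II** — N-terminus in: the tail is everything N-terminal of the
  TMD.

Tails are always stored N→C as they appear in the full-length protein.
TMD coordinates in the input schema are 1-based and inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MembraneProteinRecord",
    "CytoplasmicTail",
    "TailTableError",
    "read_protein_table",
    "extract_tail",
    "extract_tails",
    "write_tail_fasta",
    "read_tail_fasta",
]

TOPOLOGIES = ("I", "II")


class TailTableError(ValueError):
    """Raised when a protein table fails validation; carries all diagnostics."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class MembraneProteinRecord:
    """A protein with exactly one transmembrane domain.

    ``tmd_start``/``tmd_end`` are 1-based inclusive positions of the TMD
    within ``sequence``; ``topology`` is ``"I"`` or ``"II"``.
    """

    id: str
    sequence: str
    tmd_start: int
    tmd_end: int
    topology: str
    source_note: str = ""

    def validate(self) -> list:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems = []
        if not self.id:
            problems.append("empty id")
        if not self.sequence:
            problems.append(f"{self.id}: empty sequence")
        if self.topology not in TOPOLOGIES:
            problems.append(f"{self.id}: topology {self.topology!r} not in {{I, II}}")
        if not (1 <= self.tmd_start <= self.tmd_end <= len(self.sequence)):
            problems.append(
                f"{self.id}: TMD coordinates {self.tmd_start}..{self.tmd_end} "
                f"violate 1 <= start <= end <= {len(self.sequence)}"
            )
        return problems


@dataclass(frozen=True)
class CytoplasmicTail:
    """The cytosol-exposed segment of a single-pass protein, stored N→C."""

    protein_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_empty(self) -> bool:
        """Degenerate tails (TMD flush with the cytosolic terminus)."""
        return not self.sequence


def read_protein_table(path) -> list:
    """Read and validate a protein table.

    The TSV must carry a header with columns ``id``, ``topology``,
    ``tmd_start``, ``tmd_end``, ``sequence`` (extra columns, e.g.
    ``source_note``, are kept). Every invalid row is reported with its
    line number; duplicate ids are rejected.
    """
    records = []
    problems = []
    seen = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "topology", "tmd_start", "tmd_end", "sequence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise TailTableError([f"{path}: missing columns {missing}"])
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = MembraneProteinRecord(
                    id=(row["id"] or "").strip(),
                    sequence=(row["sequence"] or "").strip().upper(),
                    tmd_start=int(row["tmd_start"]),
                    tmd_end=int(row["tmd_end"]),
                    topology=(row["topology"] or "").strip().upper(),
                    source_note=(row.get("source_note") or "").strip(),
                )
            except (TypeError, ValueError):
                problems.append(f"line {lineno}: non-integer TMD coordinates")
                continue
            row_problems = rec.validate()
            if row_problems:
                problems.extend(f"line {lineno}: {p}" for p in row_problems)
                continue
            if rec.id in seen:
                problems.append(
                    f"line {lineno}: duplicate id {rec.id!r} (first seen on line {seen[rec.id]})"
                )
                continue
            seen[rec.id] = lineno
            records.append(rec)
    if problems:
        raise TailTableError(problems)
    return records


def extract_tail(record: MembraneProteinRecord) -> CytoplasmicTail:
    """Derive the cytoplasmic tail of a record by its topology.

    Type I: residues ``tmd_end+1 .. L`` (cytoplasmic C-terminus).
    Type II: residues ``1 .. tmd_start-1`` (cytoplasmic N-terminus),
    returned N→C exactly as stored in the protein. A TMD flush with the
    cytosolic terminus yields an (inspectable) empty tail.
    """
    if record.topology == "I":
        seq = record.sequence[record.tmd_end :]
    elif record.topology == "II":
        seq = record.sequence[: record.tmd_start - 1]
    else:
        raise ValueError(f"unknown topology {record.topology!r}")
    return CytoplasmicTail(protein_id=record.id, sequence=seq)


def extract_tails(
    records: Iterable[MembraneProteinRecord],
    topology: str = "both",
    drop_empty: bool = False,
) -> list:
    """Extract tails for all records, optionally restricted by topology."""
    if topology not in ("I", "II", "both"):
        raise ValueError("topology must be 'I', 'II' or 'both'")
    tails = []
    for rec in records:
        if topology != "both" and rec.topology != topology:
            continue
        tail = extract_tail(rec)
        if drop_empty and tail.is_empty:
            continue
        tails.append(tail)
    return tails


def write_tail_fasta(tails: Iterable[CytoplasmicTail], path) -> None:
    """Write tails as FASTA; the header carries the id and tail length."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.protein_id, description=f"length={t.length}")
        for t in tails
    ]
    SeqIO.write(records, path, "fasta")


def read_tail_fasta(path) -> list:
    """Read tails back from FASTA (inverse of :func:`write_tail_fasta`)."""
    return [
        CytoplasmicTail(protein_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
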