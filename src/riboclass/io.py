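"""Labeled RNA sequence I/O.

Sequences travel as FASTA; the family label of each record is either the
second whitespace-separated token of its header (default) or looked up in a
sidecar TSV with columns ``id<TAB>family``. Input may be DNA-alphabet or
lowercase: everything is canonicalized to uppercase RNA (T -> U). The
ambiguity code N is retained; downstream k-mer counting skips windows that
contain it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")
_VALID_RESIDUES = frozenset("ACGUN")


def canonicalize(seq: str) -> str:
    """Uppercase and map the DNA alphabet onto RNA (T -> U). Idempotent."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled sequence: unique id, family label, canonical RNA residues."""

    id: str
    family: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if not self.family:
            raise ValueError(f"record {self.id!r} has an empty family label")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid residues {sorted(bad)!r}; "
                "expected characters from {A,C,G,U,N} after canonicalization"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a sidecar label table with header ``id<TAB>family``."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[:2] != ["id", "family"]:
            raise ValueError(
                f"{path}: label sidecar must start with header 'id\\tfamily', "
                f"got {reader.fieldnames!r}"
            )
        labels: dict[str, str] = {}
        for row in reader:
            rid = row["id"]
            if rid in labels:
                raise ValueError(f"{path}: duplicate id {rid!r} in label sidecar")
            labels[rid] = row["family"]
    return labels


def write_labels_tsv(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "family"])
        for rec in records:
            writer.writerow([rec.id, rec.family])


def read_fasta(
    path: str | Path,
    labels: str | Path | dict[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read labeled sequences from FASTA, in file order.

    Parameters
    ----------
    path
        FASTA file. Sequences are canonicalized (uppercase, T -> U); residues
        outside {A,C,G,U,N} are rejected with the offending record named.
    labels
        ``None`` takes the family label from the second whitespace token of
        each header; a path or mapping supplies a sidecar ``id -> family``
        table that overrides headers.
    """
    path = Path(path)
    if labels is not None and not isinstance(labels, dict):
        labels = read_labels_tsv(labels)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for raw in SeqIO.parse(str(path), "fasta"):
        rid = raw.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if labels is not None:
            try:
                family = labels[rid]
            except KeyError:
                raise ValueError(
                    f"{path}: record {rid!r} has no entry in the label sidecar"
                ) from None
        else:
            tokens = raw.description.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: record {rid!r} has no family label in its header "
                    "(expected '>id family')"
                )
            family = tokens[1]
        residues = canonicalize(str(raw.seq))
        if not residues:
            raise ValueError(f"{path}: record {rid!r} has an empty sequence")
        try:
            records.append(SequenceRecord(id=rid, family=family, residues=residues))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as ``>id family`` FASTA with sequence lines wrapped."""
    with Path(path).open("w") as fh:
        for rec in records:
            if not isinstance(rec, SequenceRecord):  # re-validate foreign input
                rec = SequenceRecord(rec.id, rec.family, rec.residues)
            fh.write(f">{rec.id} {rec.family}\n")
            for start in range(0, rec.length, width):
                fh.write(rec.residues[start : start + width] + "\n")
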