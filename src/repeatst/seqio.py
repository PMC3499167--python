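"""Sequence input/output.

Reads and writes FASTA, performs six-frame translation of nucleotide
input, and serializes per-protein feature annotations as GFF3 or TSV.

Coordinate convention: 0-based half-open internally, 1-based inclusive
in every file written (GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = set("ACGTUN")

GFF_SOURCE = "repeatst"

FEATURE_KINDS = (
    "signal_peptide",
    "nterm_region",
    "repeat",
    "truncated_repeat",
    "glyco_site",
    "duf_like_domain",
)


@dataclass
class SequenceRecord:
    """One protein or nucleotide sequence with identifier and provenance."""

    id: str
    residues: str
    description: str = ""
    kind: Literal["protein", "nucleotide"] = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        self.residues = self.residues.upper()
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else NUCLEOTIDE_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(f"{self.id}: residues {sorted(bad)} not valid for kind={self.kind}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FeatureRow:
    """One annotated feature interval, 1-based inclusive coordinates."""

    seq_id: str
    feature_kind: str
    start: int
    end: int
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.seq_id}: bad interval {self.start}..{self.end}")


def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Stop characters ('*') are stripped with a warning; case is normalized
    to upper. Raises on an empty file or duplicate identifiers.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"{rec.id}: stripping '*' stop characters")
            seq = seq.replace("*", "")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc, kind=kind))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips with :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


_FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def six_frame_translate(record: SequenceRecord) -> list[SequenceRecord]:
    """Translate a nucleotide record in all six reading frames.

    Standard genetic code, stops rendered '*', trailing partial codons
    dropped, ambiguous nucleotides (N) translated to 'X'. Minus frames
    are read on the reverse complement.
    """
    if record.kind != "nucleotide":
        raise ValueError(f"{record.id}: six-frame translation requires nucleotide input")
    fwd = Seq(record.residues.replace("U", "T"))
    rev = fwd.reverse_complement()
    out = []
    for frame in _FRAMES:
        strand = fwd if frame.startswith("+") else rev
        off = int(frame[1]) - 1
        sub = strand[off:len(strand) - (len(strand) - off) % 3]
        aa = str(sub.translate()) if len(sub) else ""
        if not aa:
            continue
        out.append(
            SequenceRecord(
                id=f"{record.id}|{frame}",
                residues=aa,
                description=f"frame {frame} of {record.id}",
                kind="protein",
            )
        )
    return out


def write_feature_table(rows: Iterable[FeatureRow], path: str | Path, fmt: str = "gff3") -> None:
    """Serialize feature rows as GFF3 or TSV (1-based inclusive coordinates)."""
    rows = list(rows)
    if fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in rows:
                attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items()) or "."
                fh.write(
                    "\t".join(
                        [r.seq_id, GFF_SOURCE, r.feature_kind, str(r.start), str(r.end),
                         ".", ".", ".", attrs]
                    )
                    + "\n"
                )
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("seq_id\tfeature_kind\tstart\tend\tattributes\n")
            for r in rows:
                attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items())
                fh.write(f"{r.seq_id}\t{r.feature_kind}\t{r.start}\t{r.end}\t{attrs}\n")
    else:
        raise ValueError(f"unknown feature table format {fmt!r}")
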