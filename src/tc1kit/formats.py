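"""Readers and writers for the standard formats the pipeline touches.

Internally every coordinate is 0-based half-open on the forward strand;
conversion to the 1-based inclusive GFF3 convention happens only here,
at the format boundary.  FASTA goes through Biopython's SeqIO (wrapped
at 60 columns on write) after a light structural pre-check so malformed
files fail with a line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastaParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    seq: str


def read_fasta(path) -> List[FastaRecord]:
    """Read FASTA records; description lines are preserved verbatim.

    CRLF and LF inputs parse identically.  A sequence line appearing
    before any header raises :class:`FastaParseError` with its line
    number.
    """
    with open(path) as fh:
        seen_header = False
        for ln, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FastaParseError("empty FASTA header", ln)
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    "sequence data before any '>' header", ln)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(FastaRecord(rec.id, desc, str(rec.seq)))
    return records


def write_fasta(records: Iterable[Union[FastaRecord, Tuple]], path) -> None:
    """Write records wrapped at 60 columns (round-trips read_fasta)."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            rid, desc, seq = rec.id, rec.description, rec.seq
        else:
            rid, desc, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(seqrecords, str(path), "fasta")


@dataclass(frozen=True)
class Feature:
    """A genomic feature in internal (0-based half-open) coordinates."""

    contig: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    ftype: str = "region"
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")


def write_bed(features: Sequence[Feature], path) -> None:
    """BED6: 0-based half-open, as stored internally."""
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda x: (x.contig, x.start, x.end)):
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.name}\t"
                     f"{int(round(f.score))}\t{f.strand}\n")


def read_bed(path) -> List[Feature]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append(Feature(contig, start, end, name, score, strand))
    return out


def write_gff3(features: Sequence[Feature], path,
               source: str = "tc1kit") -> None:
    """GFF3: converts to 1-based inclusive coordinates on output."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.contig, x.start, x.end)):
            attrs = ";".join(f"{k}={v}" for k, v in
                             [("Name", f.name)] + sorted(f.attributes.items()))
            fh.write(f"{f.contig}\t{source}\t{f.ftype}\t{f.start + 1}\t"
                     f"{f.end}\t{f.score:.6g}\t{f.strand}\t.\t{attrs}\n")


def read_gff3(path) -> List[Feature]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if kv)
            name = attrs.pop("Name", ".")
            out.append(Feature(parts[0], int(parts[3]) - 1, int(parts[4]),
                               name, float(parts[5]), parts[6], parts[2],
                               attrs))
    return out
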