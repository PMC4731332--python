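"""Sequence records, genomic features, and readers/writers for FASTA/FASTQ/GFF3/BED.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based closed)
and BED (0-based half-open) conventions are applied only at the file boundary.
Sequences are handled in DNA alphabet internally: readers can normalize U -> T,
and RNA display is a presentation concern of the reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Strict nucleotide alphabet accepted in SeqRecord sequences.
SEQ_ALPHABET = frozenset("ACGTUN")
#: Full IUPAC degenerate alphabet (patterns, revcomp).
IUPAC_ALPHABET = frozenset(IUPAC_COMPLEMENT)


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "SeqRecord":
        """Subrecord over [start, end), carrying qualities along."""
        qual = self.qual[start:end] if self.qual is not None else None
        return SeqRecord(self.id, self.seq[start:end], qual)


@dataclass
class Feature:
    """A located annotation on a sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "region"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (involution)."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def _check_alphabet(seq: str, line_no: int) -> None:
    bad = set(seq) - SEQ_ALPHABET
    if bad:
        raise FormatError(
            f"line {line_no}: non-IUPAC nucleotide character(s) {sorted(bad)}"
        )


def read_fasta(path, u_to_t: bool = True) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased; U normalized to T by default)."""
    records: list[SeqRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        records.append(SeqRecord(header, seq))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if line[1:].strip() else None
                if header is None:
                    raise FormatError(f"line {line_no}: empty FASTA header")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"line {line_no}: sequence data before any '>' header"
                    )
                seq = line.strip().upper()
                if u_to_t:
                    seq = seq.replace("U", "T")
                _check_alphabet(seq, line_no)
                chunks.append(seq)
        _flush()
    del header_line
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path, u_to_t: bool = True) -> list[SeqRecord]:
    """Read 4-line FASTQ records (Phred+33)."""
    records: list[SeqRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("@"):
            raise FormatError(f"line {i + 1}: expected '@' FASTQ header")
        if i + 3 >= len(lines):
            raise FormatError(f"line {i + 1}: truncated FASTQ record")
        rid = lines[i][1:].split()[0]
        seq = lines[i + 1].strip().upper()
        if u_to_t:
            seq = seq.replace("U", "T")
        _check_alphabet(seq, i + 2)
        if not lines[i + 2].startswith("+"):
            raise FormatError(f"line {i + 3}: expected '+' separator")
        qline = lines[i + 3].strip()
        if len(qline) != len(seq):
            raise FormatError(
                f"line {i + 4}: quality length {len(qline)} != sequence length {len(seq)}"
            )
        qual = [ord(c) - 33 for c in qline]
        if any(q < 0 for q in qual):
            raise FormatError(f"line {i + 4}: quality character below Phred+33 range")
        records.append(SeqRecord(rid, seq, qual))
        i += 4
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qline = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


def write_gff(features: Iterable[Feature], path, source: str = "permacirc") -> None:
    """GFF3 writer: columns 4/5 are 1-based closed (start+1, end)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        source,
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(features: Iterable[Feature], path) -> None:
    """BED6 writer: 0-based half-open, name from kind."""
    with open(path, "w") as fh:
        fh.write('track name="permacirc"\n')
        for f in features:
            name = f.attrs.get("name", f.kind)
            fh.write(
                "\t".join(
                    [f.seq_id, str(f.start), str(f.end), str(name), "0", f.strand]
                )
                + "\n"
            )


def parse_gff_intervals(path) -> list[Feature]:
    """Minimal GFF3 reader used by round-trip tests: recovers intervals/strand/kind."""
    out: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                Feature(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    kind=cols[2],
                )
            )
    return out


def parse_bed_intervals(path) -> list[Feature]:
    out: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                Feature(
                    seq_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5] if len(cols) > 5 else "+",
                    kind=cols[3] if len(cols) > 3 else "region",
                )
            )
    return out
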