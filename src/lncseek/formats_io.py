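"""Genomic interval/transcript containers and the file formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)``.  On disk,
GTF is 1-based inclusive and BED is 0-based half-open; the readers and
writers below convert at the boundary so no other module thinks about
dialects.

Sequences are uppercase DNA over ``{A, C, G, T, N}``.  ``N`` is preserved;
downstream scanners treat it as matching nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import BoundsError, FormatError, InputError

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "SequenceStore",
    "reverse_complement",
    "read_gtf",
    "write_gtf",
    "transcripts_by_gene",
    "spliced_sequence",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "read_expression_table",
    "write_expression_table",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A stranded, multi-exon transcript with expression and provenance attributes.

    ``exons`` must be non-overlapping, sorted by start, and share one
    chromosome and strand.  ``expression`` maps sample id to FPKM.
    """

    transcript_id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    biotype: str = "candidate"
    n_experiments_detected: int = 1
    coverage: float = 0.0
    expression: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise InputError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise InputError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise InputError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e.end
        if self.n_experiments_detected < 0 or self.coverage < 0:
            raise InputError(f"{self.transcript_id}: negative provenance attribute")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> List[GenomicInterval]:
        """Gaps between consecutive exons (empty for mono-exonic transcripts)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def mean_fpkm(self) -> float:
        if not self.expression:
            return 0.0
        vals = list(self.expression.values())
        return float(sum(vals) / len(vals))

    def with_expression(self, expression: Mapping[str, float]) -> "TranscriptModel":
        return replace(self, expression=dict(expression))


class SequenceStore:
    """Chromosome name -> uppercase DNA string, with bounds-checked lookups."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise InputError(f"{name}: non-DNA characters {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        return cls(read_fasta(path))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring ``[start, end)``; out-of-bounds is an error, never truncation."""
        n = self.length(chrom)
        if not (0 <= start < end <= n):
            raise BoundsError(
                f"{chrom}:{start}-{end} out of bounds (length {n})"
            )
        return self._seqs[chrom][start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)

    def as_dict(self) -> Dict[str, str]:
        return dict(self._seqs)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(path) -> List[TranscriptModel]:
    """Read exon features from a GTF into TranscriptModels (one per transcript_id).

    1-based inclusive coordinates on disk become 0-based half-open in memory.
    Optional attributes are picked up when present: ``cov`` -> coverage,
    ``exp_count`` -> n_experiments_detected, ``FPKM`` -> expression["FPKM"],
    ``biotype`` -> biotype.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise FormatError(
                    f"{path}: line {lineno}: end ({end1}) precedes start ({start1})"
                )
            if strand not in STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(
                    f"{path}: line {lineno}: exon lacks gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tid in exons:
                prev = exons[tid][0]
                if prev.strand != strand or prev.chrom != chrom:
                    raise FormatError(
                        f"{path}: line {lineno}: transcript {tid} exons disagree "
                        "on chromosome/strand"
                    )
            else:
                order.append(tid)
                meta[tid] = attrs
            exons.setdefault(tid, []).append(iv)

    out = []
    for tid in order:
        attrs = meta[tid]
        expression = {}
        if "FPKM" in attrs:
            expression["FPKM"] = float(attrs["FPKM"])
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs["gene_id"],
                exons=tuple(sorted(exons[tid], key=lambda e: e.start)),
                biotype=attrs.get("biotype", "candidate"),
                n_experiments_detected=int(attrs.get("exp_count", 1)),
                coverage=float(attrs.get("cov", 0.0)),
                expression=expression,
            )
        )
    return out


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path,
    source: str = "lncseek",
    extra_attrs: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> None:
    """Write exon features, 1-based inclusive; round-trips with read_gtf.

    ``extra_attrs`` maps transcript_id -> {attribute: value} for additional
    per-transcript annotations (e.g. positional class).
    """
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "biotype": t.biotype,
                "exp_count": str(t.n_experiments_detected),
                "cov": repr(float(t.coverage)),
            }
            attrs.update(extra_attrs.get(t.transcript_id, {}))
            attr_s = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attr_s,
                        ]
                    )
                    + "\n"
                )


def transcripts_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> Dict[str, List[TranscriptModel]]:
    genes: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return genes


def spliced_sequence(t: TranscriptModel, genome: SequenceStore) -> str:
    """Spliced transcript sequence in sense (5'->3') orientation.

    Plus strand: exon substrings concatenated in start order.  Minus strand:
    reverse complement of that concatenation.
    """
    concat = "".join(genome.fetch(e.chrom, e.start, e.end) for e in t.exons)
    if t.strand == "-":
        return reverse_complement(concat)
    return concat


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6


def write_bed(transcripts: Iterable[TranscriptModel], path) -> None:
    """BED6 over transcript spans; score = round(min(1000, mean FPKM))."""
    with open(path, "w") as fh:
        for t in transcripts:
            score = int(round(min(1000.0, t.mean_fpkm())))
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        str(score),
                        t.strand,
                    ]
                )
                + "\n"
            )


def read_bed(path) -> List[Tuple[GenomicInterval, str, int]]:
    """Read BED (>=3 columns) into (interval, name, score) triples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            score = int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 0
            strand = fields[5] if len(fields) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path) -> pd.DataFrame:
    """TSV with transcript ids in the first column and sample ids as header.

    Returns a float DataFrame indexed by transcript id.  A non-numeric cell
    raises a FormatError naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[numeric.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
    result = pd.DataFrame(out, index=df.index)
    result.index.name = df.index.name or "transcript_id"
    return result


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="transcript_id")
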