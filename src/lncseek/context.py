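"""Positional classification of lncRNAs, cis target assignment, promoter extraction.

Classification relative to protein-coding annotation uses three labels with
fixed precedence (antisense > intronic > lincRNA):

* **antisense** — at least 1 bp of exonic overlap with a coding transcript on
  the opposite strand;
* **intronic** — the whole transcript span lies inside a single intron of some
  coding transcript (either strand), with no exonic overlap;
* **lincRNA** — no basepair overlap with any coding gene span (union of
  isoform spans).

A transcript with same-strand exonic overlap with coding annotation — or any
other unresolvable overlap — is flagged ``ambiguous`` and excluded from the
lncRNA set, so the three labels partition the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .errors import InputError
from .formats_io import (
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    reverse_complement,
    transcripts_by_gene,
)
from .identify import OrfResult

CLASSES = ("lincRNA", "antisense", "intronic")
AMBIGUOUS = "ambiguous"

__all__ = [
    "LncRNARecord",
    "CodingAnnotation",
    "classify_lncrna",
    "gene_spans",
    "assign_cis_targets",
    "extract_promoter",
    "CLASSES",
    "AMBIGUOUS",
]


@dataclass
class LncRNARecord:
    """A surviving lncRNA candidate with its genomic-context annotations."""

    transcript: TranscriptModel
    positional_class: str
    longest_orf: Optional[OrfResult] = None
    #: window size (nt) -> [(gene_id, signed distance nt), ...]
    cis_targets: Dict[int, List[Tuple[str, int]]] = field(default_factory=dict)
    promoter: Optional[GenomicInterval] = None
    promoter_seq: Optional[str] = None
    motif_hits: List = field(default_factory=list)
    seed_hits: List = field(default_factory=list)

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id

    @property
    def gene_id(self) -> str:
        return self.transcript.gene_id


class CodingAnnotation:
    """Indexed protein-coding annotation for repeated classification queries."""

    def __init__(self, coding: Sequence[TranscriptModel]):
        self.transcripts = list(coding)
        self.exon_trees: Dict[str, IntervalTree] = {}
        self.intron_trees: Dict[str, IntervalTree] = {}
        self.span_trees: Dict[str, IntervalTree] = {}
        for t in self.transcripts:
            et = self.exon_trees.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                et.addi(e.start, e.end, t.strand)
            it = self.intron_trees.setdefault(t.chrom, IntervalTree())
            for intron in t.introns():
                it.addi(intron.start, intron.end, t.transcript_id)
        for gid, span in gene_spans(self.transcripts).items():
            self.span_trees.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, gid
            )

    def classify(self, t: TranscriptModel) -> str:
        et = self.exon_trees.get(t.chrom, IntervalTree())
        opposite = same = False
        for e in t.exons:
            for hit in et.overlap(e.start, e.end):
                if hit.data == t.strand:
                    same = True
                else:
                    opposite = True
        if opposite:
            return "antisense"
        if same:
            return AMBIGUOUS
        it = self.intron_trees.get(t.chrom, IntervalTree())
        for hit in it.overlap(t.start, t.end):
            if hit.begin <= t.start and t.end <= hit.end:
                return "intronic"
        st = self.span_trees.get(t.chrom, IntervalTree())
        if not st.overlap(t.start, t.end):
            return "lincRNA"
        return AMBIGUOUS


def classify_lncrna(t: TranscriptModel, coding: Sequence[TranscriptModel]) -> str:
    """Positional class of one transcript against coding annotation.

    Convenience wrapper; build a :class:`CodingAnnotation` once for batches.
    """
    return CodingAnnotation(coding).classify(t)


def gene_spans(coding: Iterable[TranscriptModel]) -> Dict[str, GenomicInterval]:
    """Union span (5'-most start to 3'-most end over isoforms) per gene."""
    spans: Dict[str, GenomicInterval] = {}
    for gid, txs in transcripts_by_gene(coding).items():
        chroms = {t.chrom for t in txs}
        if len(chroms) > 1:
            raise InputError(f"gene {gid}: isoforms on multiple chromosomes")
        start = min(t.start for t in txs)
        end = max(t.end for t in txs)
        strands = {t.strand for t in txs}
        strand = strands.pop() if len(strands) == 1 else "."
        spans[gid] = GenomicInterval(txs[0].chrom, start, end, strand)
    return spans


def assign_cis_targets(
    lnc: TranscriptModel,
    genes: Mapping[str, GenomicInterval],
    windows: Sequence[int] = (10_000, 100_000),
) -> Dict[int, List[Tuple[str, int]]]:
    """Coding genes within each distance window of the lncRNA span.

    Distance is the gap between spans (0 when they overlap); the sign is
    negative when the gene lies 5' of the lncRNA in genomic coordinates.
    Windows must be positive and ascending, so the smaller window's target
    set nests inside the larger one.
    """
    windows = list(windows)
    if any(w <= 0 for w in windows) or windows != sorted(windows):
        raise InputError("windows must be positive and sorted ascending")
    out: Dict[int, List[Tuple[str, int]]] = {w: [] for w in windows}
    for gid in sorted(genes):
        g = genes[gid]
        if g.chrom != lnc.chrom:
            continue
        if g.start < lnc.end and lnc.start < g.end:
            dist = 0
        elif g.end <= lnc.start:
            dist = -(lnc.start - g.end)
        else:
            dist = g.start - lnc.end
        for w in windows:
            if abs(dist) <= w:
                out[w].append((gid, dist))
    for w in windows:
        out[w].sort(key=lambda pair: (abs(pair[1]), pair[0]))
    return out


def extract_promoter(
    t: TranscriptModel, genome: SequenceStore, upstream_nt: int = 2_000
) -> Tuple[GenomicInterval, str]:
    """The upstream promoter window of a transcript, read 5'->3' toward the TSS.

    Plus strand: ``[TSS - upstream_nt, TSS)`` on the genome.  Minus strand:
    ``[TES, TES + upstream_nt)``, reverse-complemented.  The window is clipped
    at chromosome edges (never an error); the returned interval records the
    actual extent.
    """
    if t.strand == ".":
        raise InputError(f"{t.transcript_id}: promoter undefined for strand '.'")
    if upstream_nt <= 0:
        raise InputError("upstream_nt must be positive")
    chrom_len = genome.length(t.chrom)
    if t.strand == "+":
        start = max(0, t.start - upstream_nt)
        end = t.start
    else:
        start = t.end
        end = min(chrom_len, t.end + upstream_nt)
    if start >= end:
        raise InputError(
            f"{t.transcript_id}: promoter fully clipped at chromosome edge"
        )
    iv = GenomicInterval(t.chrom, start, end, t.strand)
    seq = genome.fetch_interval(iv)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return iv, seq
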