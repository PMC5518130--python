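"""The five-step lncRNA candidate filter cascade and the ORF coding-potential surrogate.

The cascade mirrors the standard assembled-transcriptome triage for long
non-coding RNA discovery, applied in fixed order:

1. drop transcripts detected in fewer than ``min_experiments`` libraries;
2. drop mono-exonic transcripts and transcripts shorter than 200 nt
   (two independent conditions — either one triggers removal);
3. drop transcripts with assembler coverage below 3;
4. drop transcripts with any exonic overlap with a known small-RNA locus
   (strand-agnostic genomic overlap against a BED blacklist);
5. drop transcripts judged protein-coding.

Step 5's built-in surrogate calls a transcript coding when its longest
ATG-initiated open reading frame reaches ``coding_orf_threshold_nt``
(default 300 nt, ~100 aa — the conventional lncRNA cutoff).  External
predictor labels (e.g. from CPC/CNCI/Pfam runs) can be supplied; a
transcript is kept as noncoding only when *every* predictor, built-in rule
included, labels it noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .errors import InputError
from .formats_io import GenomicInterval, SequenceStore, TranscriptModel, spliced_sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: cascade step names, in application order
CASCADE_STEPS = (
    "detected_experiments",
    "size_and_exon_count",
    "coverage",
    "small_rna_overlap",
    "coding_potential",
)

#: rejection reasons, keyed by the step that can emit them
REJECTION_REASONS = (
    "few_experiments",
    "mono_exonic",
    "too_short",
    "low_coverage",
    "small_rna_overlap",
    "coding",
)

__all__ = [
    "OrfResult",
    "FilterParams",
    "FilterReport",
    "find_longest_orf",
    "score_coding_potential",
    "run_filter_cascade",
    "CASCADE_STEPS",
    "REJECTION_REASONS",
]


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame of a transcript, in transcript coordinates.

    ``length_nt`` includes the stop codon when one is present (stop-inclusive
    convention, stated here because conventions differ).  When no in-frame
    stop exists, the reading runs to the last complete codon and
    ``has_stop`` is False.
    """

    frame: int
    start: int
    end: int  # 0-based half-open, end exclusive
    length_nt: int
    has_stop: bool


def find_longest_orf(seq: str) -> Optional[OrfResult]:
    """Longest ATG-initiated reading frame, sense orientation, all three frames.

    The ORF ends at the first in-frame stop (TAA/TAG/TGA, included in the
    length); with no in-frame stop the open reading to the 3' end qualifies,
    truncated to whole codons.  Ties break to the smaller start offset, then
    the smaller frame index.  Codons containing N never match ATG or a stop.
    Returns None when no ATG opens a frame.
    """
    seq = seq.upper()
    n = len(seq)
    best: Optional[OrfResult] = None

    def better(cand: OrfResult) -> bool:
        if best is None:
            return True
        return (cand.length_nt, -cand.start, -cand.frame) > (
            best.length_nt,
            -best.start,
            -best.frame,
        )

    for frame in range(3):
        open_start: Optional[int] = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    cand = OrfResult(
                        frame, open_start, pos + 3, pos + 3 - open_start, True
                    )
                    if better(cand):
                        best = cand
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
            pos += 3
        if open_start is not None:
            end = open_start + 3 * ((n - open_start) // 3)
            cand = OrfResult(frame, open_start, end, end - open_start, False)
            if better(cand):
                best = cand
    return best


@dataclass
class FilterParams:
    """Thresholds for the filter cascade (defaults follow convention)."""

    min_experiments: int = 2
    min_length_nt: int = 200
    require_multi_exon: bool = True
    min_coverage: float = 3.0
    coding_orf_threshold_nt: int = 300
    #: predictor name -> {transcript_id -> "coding"/"noncoding"}
    external_coding_labels: Optional[Mapping[str, Mapping[str, str]]] = None

    def __post_init__(self) -> None:
        if (
            self.min_experiments < 0
            or self.min_length_nt < 0
            or self.min_coverage < 0
            or self.coding_orf_threshold_nt < 0
        ):
            raise InputError("filter thresholds must be >= 0")


def score_coding_potential(
    t: TranscriptModel, seq: str, params: FilterParams
) -> str:
    """Label a transcript "coding" or "noncoding".

    Built-in rule: coding iff the longest ORF reaches the threshold.  With
    external predictor labels the transcript is noncoding only if every
    predictor that labels it agrees (the built-in rule counts as one
    predictor); any "coding" vote flags it coding.
    """
    orf = find_longest_orf(seq)
    votes = ["coding" if orf and orf.length_nt >= params.coding_orf_threshold_nt
             else "noncoding"]
    if params.external_coding_labels:
        for predictor, labels in params.external_coding_labels.items():
            if t.transcript_id in labels:
                label = labels[t.transcript_id]
                if label not in ("coding", "noncoding"):
                    raise InputError(
                        f"{predictor}: bad label {label!r} for {t.transcript_id}"
                    )
                votes.append(label)
    return "coding" if "coding" in votes else "noncoding"


@dataclass
class FilterReport:
    """Per-step survivor counts plus a rejection reason for every removed transcript."""

    n_input: int
    steps: List[Tuple[str, int]] = field(default_factory=list)
    rejected: Dict[str, str] = field(default_factory=dict)

    @property
    def n_survivors(self) -> int:
        return self.steps[-1][1] if self.steps else self.n_input

    def validate(self) -> None:
        counts = [self.n_input] + [n for _, n in self.steps]
        for a, b in zip(counts, counts[1:]):
            if b > a:
                raise AssertionError("survivor counts must be non-increasing")
        if self.n_survivors + len(self.rejected) != self.n_input:
            raise AssertionError("survivors + rejected must equal input count")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.steps, columns=["step", "survivors"])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# input\t{self.n_input}\n")
            for name, n in self.steps:
                fh.write(f"# after {name}\t{n}\n")
            fh.write("transcript_id\treason\n")
            for tid in sorted(self.rejected):
                fh.write(f"{tid}\t{self.rejected[tid]}\n")


def _smallrna_trees(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def run_filter_cascade(
    candidates: Sequence[TranscriptModel],
    smallrna: Iterable[GenomicInterval],
    params: Optional[FilterParams] = None,
    genome: Optional[SequenceStore] = None,
    sequences: Optional[Mapping[str, str]] = None,
) -> Tuple[List[TranscriptModel], FilterReport]:
    """Run the five filters in order; return survivors and the audit report.

    Step 5 needs spliced sequences: pass ``genome`` (sequences extracted on
    the fly) or a precomputed ``sequences`` map.  The report records the
    survivor count after each step and, for every rejected transcript, the
    first reason that triggered.
    """
    params = params or FilterParams()
    if genome is None and sequences is None:
        raise InputError("run_filter_cascade needs a genome or a sequences map")
    if params.external_coding_labels:
        known = {t.transcript_id for t in candidates}
        for predictor, labels in params.external_coding_labels.items():
            unknown = set(labels) - known
            if unknown:
                raise KeyError(
                    f"{predictor}: external labels for unknown transcript ids "
                    f"{sorted(unknown)[:5]}"
                )

    def get_seq(t: TranscriptModel) -> str:
        if sequences is not None and t.transcript_id in sequences:
            return sequences[t.transcript_id]
        assert genome is not None
        return spliced_sequence(t, genome)

    report = FilterReport(n_input=len(candidates))
    survivors = list(candidates)

    def apply(step_name, reject_reason_fn):
        nonlocal survivors
        kept = []
        for t in survivors:
            reason = reject_reason_fn(t)
            if reason is None:
                kept.append(t)
            else:
                report.rejected[t.transcript_id] = reason
        survivors = kept
        report.steps.append((step_name, len(survivors)))

    # 1: detection breadth
    apply(
        CASCADE_STEPS[0],
        lambda t: "few_experiments"
        if t.n_experiments_detected < params.min_experiments
        else None,
    )

    # 2: exon count and spliced length (independent conditions)
    def step2(t):
        if params.require_multi_exon and t.n_exons < 2:
            return "mono_exonic"
        if t.spliced_length < params.min_length_nt:
            return "too_short"
        return None

    apply(CASCADE_STEPS[1], step2)

    # 3: assembler coverage
    apply(
        CASCADE_STEPS[2],
        lambda t: "low_coverage" if t.coverage < params.min_coverage else None,
    )

    # 4: small-RNA blacklist overlap (strand-agnostic, exonic)
    trees = _smallrna_trees(smallrna)

    def step4(t):
        tree = trees.get(t.chrom)
        if tree is None:
            return None
        for e in t.exons:
            if tree.overlap(e.start, e.end):
                return "small_rna_overlap"
        return None

    apply(CASCADE_STEPS[3], step4)

    # 5: coding potential
    apply(
        CASCADE_STEPS[4],
        lambda t: "coding"
        if score_coding_potential(t, get_seq(t), params) == "coding"
        else None,
    )

    report.validate()
    return survivors, report
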