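"""Summary statistics over annotated lncRNA records.

Aggregation conventions (the two bookkeeping levels are both kept):

* length, exon-count and ORF statistics are **per transcript**;
* positional class, cis-target coverage and motif-site counts are **per
  locus** (gene): class by precedence over isoforms, targets as the union,
  motif sites as the max over isoform promoters.

Ratios are carried at full precision; :func:`display_round` applies the
one-decimal, half-up presentation rounding used in printed summaries
(e.g. 402 transcripts / 343 loci -> 1.17... -> "1.2").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence

from .context import AMBIGUOUS, CLASSES, LncRNARecord
from .errors import InputError

__all__ = ["SummaryStats", "summarize", "display_round"]

_CLASS_PRECEDENCE = {"antisense": 0, "intronic": 1, "lincRNA": 2, AMBIGUOUS: 3}


def display_round(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, applied only at presentation time."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryStats:
    """Cohort-level description of an identified lncRNA set."""

    n_transcripts: int
    n_loci: int
    mean_isoforms_per_locus: float
    class_counts: Dict[str, int]
    length_mean: float
    length_min: int
    length_max: int
    exon_histogram: Dict[int, int]
    mean_exons: float
    fraction_two_exons: float
    mean_orf_length: float
    n_orf_bearing: int
    fpkm_threshold: float
    fraction_fpkm_below: float
    mean_fpkm: float
    fraction_with_cis_target: float
    motif_sites_total: int
    promoters_with_site: int
    mean_sites_per_lncrna: float
    per_chromosome: Dict[str, int]

    def validate(self) -> None:
        fractions = (
            self.fraction_two_exons,
            self.fraction_fpkm_below,
            self.fraction_with_cis_target,
        )
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise AssertionError("fractions must lie in [0, 1]")
        if sum(self.exon_histogram.values()) != self.n_transcripts:
            raise AssertionError("exon histogram must sum to the transcript count")
        if sum(self.per_chromosome.values()) != self.n_transcripts:
            raise AssertionError("per-chromosome counts must sum to the total")
        if self.n_loci:
            expected = self.n_transcripts / self.n_loci
            if abs(self.mean_isoforms_per_locus - expected) > 1e-9:
                raise AssertionError("mean isoforms must equal transcripts/loci")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["exon_histogram"] = {str(k): v for k, v in sorted(self.exon_histogram.items())}
        d["per_chromosome"] = dict(sorted(self.per_chromosome.items()))
        d["class_counts"] = dict(sorted(self.class_counts.items()))
        return d

    def display(self) -> Dict[str, float]:
        """One-decimal presentation of the headline ratios."""
        return {
            "mean_isoforms_per_locus": display_round(self.mean_isoforms_per_locus),
            "mean_length": display_round(self.length_mean),
            "mean_exons": display_round(self.mean_exons),
            "mean_orf_length": display_round(self.mean_orf_length),
            "pct_two_exons": display_round(100 * self.fraction_two_exons),
            "pct_fpkm_below_threshold": display_round(100 * self.fraction_fpkm_below),
            "pct_with_cis_target": display_round(100 * self.fraction_with_cis_target),
            "mean_sites_per_lncrna": display_round(self.mean_sites_per_lncrna),
        }


def summarize(
    records: Sequence[LncRNARecord], fpkm_threshold: float = 15.0
) -> SummaryStats:
    """Compute cohort statistics from annotated records alone."""
    records = [r for r in records if r.positional_class != AMBIGUOUS]
    if not records:
        raise InputError("summarize needs at least one classified record")

    by_locus: Dict[str, List[LncRNARecord]] = {}
    for r in records:
        by_locus.setdefault(r.gene_id, []).append(r)

    n_tx = len(records)
    n_loci = len(by_locus)

    class_counts = {c: 0 for c in CLASSES}
    fraction_target = 0
    sites_total = 0
    promoters_with_site = 0
    for recs in by_locus.values():
        cls = min((r.positional_class for r in recs), key=_CLASS_PRECEDENCE.get)
        class_counts[cls] += 1
        if any(hits for r in recs for hits in r.cis_targets.values()):
            fraction_target += 1
        locus_sites = max((len(r.motif_hits) for r in recs), default=0)
        sites_total += locus_sites
        if locus_sites:
            promoters_with_site += 1

    lengths = [r.transcript.spliced_length for r in records]
    exon_counts = [r.transcript.n_exons for r in records]
    hist: Dict[int, int] = {}
    for n in exon_counts:
        hist[n] = hist.get(n, 0) + 1
    orf_lengths = [r.longest_orf.length_nt for r in records if r.longest_orf]
    fpkms = [r.transcript.mean_fpkm() for r in records]

    per_chrom: Dict[str, int] = {}
    for r in records:
        per_chrom[r.transcript.chrom] = per_chrom.get(r.transcript.chrom, 0) + 1

    stats = SummaryStats(
        n_transcripts=n_tx,
        n_loci=n_loci,
        mean_isoforms_per_locus=n_tx / n_loci,
        class_counts=class_counts,
        length_mean=sum(lengths) / n_tx,
        length_min=min(lengths),
        length_max=max(lengths),
        exon_histogram=hist,
        mean_exons=sum(exon_counts) / n_tx,
        fraction_two_exons=hist.get(2, 0) / n_tx,
        mean_orf_length=(sum(orf_lengths) / len(orf_lengths)) if orf_lengths else 0.0,
        n_orf_bearing=len(orf_lengths),
        fpkm_threshold=fpkm_threshold,
        fraction_fpkm_below=sum(1 for f in fpkms if f < fpkm_threshold) / n_tx,
        mean_fpkm=sum(fpkms) / n_tx,
        fraction_with_cis_target=fraction_target / n_loci,
        motif_sites_total=sites_total,
        promoters_with_site=promoters_with_site,
        mean_sites_per_lncrna=(
            sites_total / promoters_with_site if promoters_with_site else 0.0
        ),
        per_chromosome=per_chrom,
    )
    stats.validate()
    return stats
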