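"""Seed-reproducible synthetic study: genome, annotation, candidates, expression, qPCR.

The generator emits a complete toy study in the exact formats the pipeline
consumes, with machine-readable truth tables, so every stage is testable
without downloads.  It emulates a castrated-vs-intact full-sib pig design:

* a multi-chromosome random genome with protein-coding genes;
* planted lncRNAs of the three positional classes (intergenic, antisense,
  intronic), each satisfying its class definition by construction;
* decoy transcripts that each violate exactly one filter of the
  identification cascade (mono-exonic, <200 nt, coverage <3, detected in one
  experiment, small-RNA overlap, long coding ORF);
* 3-vs-3 two-group negative-binomial counts with planted 4-fold (|log2FC|=2)
  up- and down-regulation and a shared per-pair random intercept on the
  log-mean emulating the full-sib pairing;
* low lncRNA expression: ~91% of planted lncRNAs are assigned mean FPKM
  targets below 15 by construction;
* C/EBPalpha-like consensus motifs planted at recorded promoter offsets;
* miRNA seed sites planted at recorded transcript offsets;
* qPCR plates with Ct = intercept - log2(expression) + Gaussian noise.

Planted lncRNA sequences are ORF-repaired (in-frame TAA insertion at
unprotected codons) so every keep is noncoding under the 300-nt ORF
surrogate; the coding decoy carries an explicit 366-nt ORF.

All randomness flows from ``SimulationConfig.seed``; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .formats_io import (
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_expression_table,
    write_fasta,
    write_gtf,
)
from .identify import find_longest_orf
from .motifs import MiRNA, cebpa_example_pwm, write_mirnas, write_pwm

DECOY_REASONS = (
    "few_experiments",
    "mono_exonic",
    "too_short",
    "low_coverage",
    "small_rna_overlap",
    "coding",
)

#: illustrative mature sequences for the adipogenesis-related miRNA panel
#: (13 promoting + 5 depressing); synthetic stand-ins bundled for fixtures,
#: not curated database entries.
DEFAULT_MIRNAS: Tuple[Tuple[str, str], ...] = (
    ("let-7", "UGAGGUAGUAGGUUGUAUAGUU"),
    ("miR-9", "UCUUUGGUUAUCUAGCUGUAUGA"),
    ("miR-15a", "UAGCAGCACAUAAUGGUUUGUG"),
    ("miR-17", "CAAAGUGCUUACAGUGCAGGUAG"),
    ("miR-21", "UAGCUUAUCAGACUGAUGUUGA"),
    ("miR-24", "UGGCUCAGUUCAGCAGGAACAG"),
    ("miR-30", "UGUAAACAUCCUCGACUGGAAG"),
    ("miR-103", "AGCAGCAUUGUACAGGGCUAUGA"),
    ("miR-107", "AGCAGCAUUGUACAGGGCUAUCA"),
    ("miR-125b", "UCCCUGAGACCCUAACUUGUGA"),
    ("miR-204", "UUCCCUUUGUCAUCCUAUGCCU"),
    ("miR-210", "CUGUGCGUGUGACAGCGGCUGA"),
    ("miR-378", "ACUGGACUUGGAGUCAGAAGGC"),
    ("miR-27", "UUCACAGUGGCUAAGUUCCGC"),
    ("miR-150", "UCUCCCAACCCUUGUACCAGUG"),
    ("miR-221", "AGCUACAUUGUCUGCUGGGUUUC"),
    ("miR-222", "AGCUACAUCUGGCUACUGGGU"),
    ("miR-326", "CCUCUGGGCCCUUCCUCCAG"),
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

__all__ = [
    "SimulationConfig",
    "simulate_study",
    "simulate_null_counts",
    "simulate_two_group_counts",
    "DECOY_REASONS",
    "DEFAULT_MIRNAS",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the standard conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_coding_genes: int = 40
    n_lincrna: int = 16
    n_antisense: int = 8
    n_intronic: int = 6
    decoys_per_reason: Dict[str, int] = field(
        default_factory=lambda: {r: 4 for r in DECOY_REASONS}
    )
    samples_per_group: int = 3
    dispersion: float = 0.1
    pair_sd: float = 0.25  # log2-scale shared full-sib intercept
    n_de_up: int = 9
    n_de_down: int = 9
    de_log2fc: float = 2.0
    fraction_low_expression: float = 0.912  # keeps assigned FPKM target < 15
    library_size: float = 2e7  # nominal fragments per library
    coding_orf_threshold_nt: int = 300
    motif_rate: float = 1.9  # expected planted sites per designated promoter
    n_motif_promoters: int = 10
    n_seed_transcripts: int = 10
    seed_sites_per_transcript: int = 2
    promoter_length: int = 2_000
    ct_noise_sd: float = 0.15  # cycles
    qpcr_replicates: int = 3
    n_qpcr_up: int = 4
    n_qpcr_down: int = 4

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigurationError("seed must be >= 0")
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
            "n_coding_genes": self.n_coding_genes,
            "samples_per_group": self.samples_per_group,
            "dispersion": self.dispersion,
            "library_size": self.library_size,
            "promoter_length": self.promoter_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")
        nonneg = {
            "n_lincrna": self.n_lincrna,
            "n_antisense": self.n_antisense,
            "n_intronic": self.n_intronic,
            "n_de_up": self.n_de_up,
            "n_de_down": self.n_de_down,
            "pair_sd": self.pair_sd,
            "motif_rate": self.motif_rate,
            "ct_noise_sd": self.ct_noise_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        unknown = set(self.decoys_per_reason) - set(DECOY_REASONS)
        if unknown:
            raise ConfigurationError(f"unknown decoy reasons {sorted(unknown)}")
        if any(v < 0 for v in self.decoys_per_reason.values()):
            raise ConfigurationError("decoy counts must be >= 0")
        if not math.isfinite(self.de_log2fc):
            raise ConfigurationError("de_log2fc must be finite")
        n_keep = self.n_lincrna + self.n_antisense + self.n_intronic
        if self.n_de_up + self.n_de_down > n_keep:
            raise ConfigurationError("more planted DE transcripts than lncRNAs")
        if self.n_intronic + self.n_antisense > self.n_coding_genes:
            raise ConfigurationError(
                "need one distinct coding gene per intronic/antisense lncRNA"
            )

    @property
    def n_keep(self) -> int:
        return self.n_lincrna + self.n_antisense + self.n_intronic

    @property
    def sample_ids(self) -> Tuple[List[str], List[str]]:
        cas = [f"cas_{i + 1}" for i in range(self.samples_per_group)]
        intact = [f"int_{i + 1}" for i in range(self.samples_per_group)]
        return cas, intact


# ---------------------------------------------------------------------------
# low-level helpers


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB with var = m + dispersion * m^2 (shape r = 1/dispersion)."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _repair_orfs(
    seq: List[str],
    protected: np.ndarray,
    threshold: int,
    max_iter: int = 500,
) -> None:
    """Insert in-frame TAA stops (at unprotected codons) until no ORF reaches
    ``threshold``.  Mutates ``seq`` in place."""
    for _ in range(max_iter):
        orf = find_longest_orf("".join(seq))
        if orf is None or orf.length_nt < threshold:
            return
        candidates = [
            p
            for p in range(orf.start + 3, min(orf.end, len(seq)) - 2, 3)
            if not protected[p : p + 3].any()
        ]
        if candidates:
            p = candidates[len(candidates) // 2]
            seq[p : p + 3] = list("TAA")
        elif not protected[orf.start : orf.start + 3].any():
            seq[orf.start + 2] = "A"  # ATG -> ATA kills the start codon
        else:
            raise ConfigurationError(
                "cannot break a long ORF without touching planted features"
            )
    raise ConfigurationError("ORF repair did not converge")


def _split_length(
    rng: np.random.Generator, total: int, n_parts: int, minimum: int = 60
) -> List[int]:
    """Split ``total`` into n_parts pieces, each >= minimum."""
    if total < n_parts * minimum:
        raise ConfigurationError("transcript too short for its exon count")
    free = total - n_parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=n_parts - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]])) + minimum
    return [int(x) for x in parts]


def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
) -> Tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


# ---------------------------------------------------------------------------
# study generation


@dataclass
class _Planted:
    transcript: TranscriptModel
    role: str  # keep / decoy / coding
    label: str  # positional class, rejection reason, or "."
    seed_targets: List[Tuple[str, int, str]] = field(default_factory=list)


def simulate_study(cfg: SimulationConfig, outdir) -> Dict[str, Path]:
    """Generate the full study under ``outdir``; returns a name -> path map.

    Files written: genome.fa, annotation.gtf, candidates.gtf, expression.tsv,
    smallrna.bed, mirnas.tsv, pwm.txt, qpcr.tsv, pathways.gmt, truth.tsv,
    truth_motifs.tsv, truth_seeds.tsv, config.json.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_len = cfg.chromosome_length

    # ---- plan loci -------------------------------------------------------
    # gene i hosts an intronic lncRNA for i < n_intronic, carries an
    # antisense lncRNA for n_intronic <= i < n_intronic + n_antisense
    gene_items = [("gene", i) for i in range(cfg.n_coding_genes)]
    intergenic_items: List[Tuple[str, object]] = [
        ("lincRNA", i) for i in range(cfg.n_lincrna)
    ]
    for reason in DECOY_REASONS:
        for k in range(cfg.decoys_per_reason.get(reason, 0)):
            intergenic_items.append(("decoy", (reason, k)))
    items = gene_items + intergenic_items
    order = rng.permutation(len(items))
    per_chrom: Dict[str, List] = {c: [] for c in chrom_names}
    for rank, idx in enumerate(order):
        per_chrom[chrom_names[rank % cfg.n_chromosomes]].append(items[idx])

    coding: List[TranscriptModel] = []
    keeps: List[_Planted] = []
    decoys: List[_Planted] = []
    smallrna: List[Tuple[GenomicInterval, str]] = []

    def make_lnc_like(
        chrom: str, start: int, tid: str, gid: str, *, n_exons: int,
        spliced: int, nexp: int, cov: float
    ) -> TranscriptModel:
        strand = str(rng.choice(["+", "-"]))
        exon_lens = _split_length(rng, spliced, n_exons) if n_exons > 1 else [spliced]
        intron_lens = [int(rng.integers(300, 701)) for _ in range(n_exons - 1)]
        exons = _make_exons(rng, chrom, start, strand, exon_lens, intron_lens)
        return TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            exons=exons,
            biotype="candidate",
            n_experiments_detected=nexp,
            coverage=cov,
        )

    tail_margin = cfg.promoter_length + 500
    for chrom in chrom_names:
        cursor = cfg.promoter_length + 2_000
        for kind, payload in per_chrom[chrom]:
            gap = int(rng.integers(2_500, 3_201))
            start = cursor
            if kind == "gene":
                gidx = payload
                hosts_intronic = gidx < cfg.n_intronic
                carries_antisense = (
                    cfg.n_intronic <= gidx < cfg.n_intronic + cfg.n_antisense
                )
                strand = str(rng.choice(["+", "-"]))
                n_ex = int(rng.integers(3, 6))
                exon_lens = [int(rng.integers(150, 251)) for _ in range(n_ex)]
                intron_lens = [int(rng.integers(400, 701)) for _ in range(n_ex - 1)]
                host_intron_idx = None
                if hosts_intronic:
                    host_intron_idx = (n_ex - 1) // 2
                    intron_lens[host_intron_idx] = int(rng.integers(3_500, 4_201))
                exons = _make_exons(rng, chrom, start, strand, exon_lens, intron_lens)
                gid = f"PCG_{gidx:04d}"
                gene = TranscriptModel(
                    transcript_id=f"PCT_{gidx:04d}",
                    gene_id=gid,
                    exons=exons,
                    biotype="protein_coding",
                    n_experiments_detected=3,
                    coverage=20.0,
                )
                coding.append(gene)
                footprint_end = gene.end

                if hosts_intronic:
                    intron = gene.introns()[host_intron_idx]
                    e1 = int(rng.integers(120, 251))
                    gap_i = int(rng.integers(150, 401))
                    e2 = int(rng.integers(120, 251))
                    lstart = intron.start + 100
                    assert lstart + e1 + gap_i + e2 <= intron.end - 100
                    lstrand = str(rng.choice(["+", "-"]))
                    lnc_exons = _make_exons(
                        rng, chrom, lstart, lstrand, [e1, e2], [gap_i]
                    )
                    i = len([p for p in keeps if p.label == "intronic"])
                    keeps.append(
                        _Planted(
                            TranscriptModel(
                                transcript_id=f"LNCT_INT_{i:03d}",
                                gene_id=f"LNCG_INT_{i:03d}",
                                exons=lnc_exons,
                                biotype="candidate",
                                n_experiments_detected=int(rng.integers(2, 5)),
                                coverage=float(rng.uniform(5, 50)),
                            ),
                            "keep",
                            "intronic",
                        )
                    )

                if carries_antisense:
                    last = gene.exons[-1]
                    a_strand = "-" if strand == "+" else "+"
                    e1 = GenomicInterval(chrom, last.end - 80, last.end + 120, a_strand)
                    b_start = gene.end + 400
                    b_len = int(rng.integers(150, 301))
                    e2 = GenomicInterval(chrom, b_start, b_start + b_len, a_strand)
                    i = len([p for p in keeps if p.label == "antisense"])
                    keeps.append(
                        _Planted(
                            TranscriptModel(
                                transcript_id=f"LNCT_AS_{i:03d}",
                                gene_id=f"LNCG_AS_{i:03d}",
                                exons=(e1, e2),
                                biotype="candidate",
                                n_experiments_detected=int(rng.integers(2, 5)),
                                coverage=float(rng.uniform(5, 50)),
                            ),
                            "keep",
                            "antisense",
                        )
                    )
                    footprint_end = max(footprint_end, e2.end)
            elif kind == "lincRNA":
                i = payload
                n_ex = 2 if rng.random() < 0.9 else 3
                spliced = int(np.exp(rng.uniform(np.log(250), np.log(2_200))))
                t = make_lnc_like(
                    chrom, start, f"LNCT_LINC_{i:03d}", f"LNCG_LINC_{i:03d}",
                    n_exons=n_ex, spliced=spliced,
                    nexp=int(rng.integers(2, 5)), cov=float(rng.uniform(5, 50)),
                )
                keeps.append(_Planted(t, "keep", "lincRNA"))
                footprint_end = t.end
            else:  # decoy
                reason, k = payload
                tid = f"DECOY_{reason}_{k:02d}"
                gid = f"DECOYG_{reason}_{k:02d}"
                nexp, cov, n_ex, spliced = 3, 10.0, 2, 600
                if reason == "few_experiments":
                    nexp = 1
                elif reason == "mono_exonic":
                    n_ex = 1
                elif reason == "too_short":
                    spliced = 150
                elif reason == "low_coverage":
                    cov = float(rng.uniform(0.3, 2.5))
                t = make_lnc_like(
                    chrom, start, tid, gid,
                    n_exons=n_ex, spliced=spliced, nexp=nexp, cov=cov,
                )
                decoys.append(_Planted(t, "decoy", reason))
                if reason == "small_rna_overlap":
                    e = t.exons[0]
                    mid = (e.start + e.end) // 2
                    smallrna.append(
                        (
                            GenomicInterval(chrom, mid - 15, mid + 15, "+"),
                            f"SRNA_{len(smallrna):02d}",
                        )
                    )
                footprint_end = t.end
            cursor = footprint_end + gap
            if cursor > chrom_len - tail_margin:
                raise ConfigurationError(
                    f"{chrom}: planted features do not fit in "
                    f"{chrom_len} bp (cursor reached {cursor})"
                )

    # ---- genome ----------------------------------------------------------
    genome_arr: Dict[str, np.ndarray] = {
        c: rng.integers(0, 4, size=chrom_len).astype(np.uint8) for c in chrom_names
    }
    reserved: Dict[str, np.ndarray] = {
        c: np.zeros(chrom_len, dtype=bool) for c in chrom_names
    }

    def write_genome(chrom: str, start: int, seq: str, protect: bool = True) -> None:
        idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for j, b in enumerate("ACGT"):
            lut[ord(b)] = j
        genome_arr[chrom][start : start + len(seq)] = lut[idx]
        if protect:
            reserved[chrom][start : start + len(seq)] = True

    def read_genome(chrom: str, start: int, end: int) -> str:
        return _BASE_BYTES[genome_arr[chrom][start:end]].tobytes().decode("ascii")

    # ---- plant candidate sequences --------------------------------------
    mirna_panel = [MiRNA(name, seq) for name, seq in DEFAULT_MIRNAS]
    seed_truth: List[Tuple[str, str, int, str]] = []
    seed_designated = {
        p.transcript.transcript_id
        for p in keeps[: cfg.n_seed_transcripts]
        if p.transcript.spliced_length >= 80
    }

    for planted in keeps + decoys:
        t = planted.transcript
        L = t.spliced_length
        seq = list(_rand_dna(rng, L))
        protected = np.zeros(L, dtype=bool)

        if t.transcript_id in seed_designated:
            taken: List[Tuple[int, int]] = []
            for _ in range(cfg.seed_sites_per_transcript):
                mir = mirna_panel[int(rng.integers(0, len(mirna_panel)))]
                stype = str(rng.choice(["8mer", "7mer-m8"]))
                site = mir.site_strings()[stype]
                placed = False
                for _attempt in range(50):
                    off = int(rng.integers(5, L - len(site) - 6))
                    if all(
                        off + len(site) + 1 <= a or off >= b + 1 for a, b in taken
                    ):
                        placed = True
                        break
                if not placed:
                    continue
                seq[off : off + len(site)] = list(site)
                protected[off : off + len(site)] = True
                if stype == "7mer-m8" and seq[off + 7] == "A":
                    seq[off + 7] = "C"  # keep the planted type from upgrading to 8mer
                    protected[off + 7] = True
                taken.append((off, off + len(site)))
                seed_truth.append((t.transcript_id, mir.name, off, stype))

        if planted.label == "coding":
            orf_start = 30
            codons = [
                _NONSTOP_CODONS[int(rng.integers(0, len(_NONSTOP_CODONS)))]
                for _ in range(120)
            ]
            orf = "ATG" + "".join(codons) + "TAA"
            seq[orf_start : orf_start + len(orf)] = list(orf)
            protected[orf_start : orf_start + len(orf)] = True
        else:
            _repair_orfs(seq, protected, cfg.coding_orf_threshold_nt)

        spliced = "".join(seq)
        genomic = spliced if t.strand == "+" else reverse_complement(spliced)
        pos = 0
        for e in t.exons:
            write_genome(t.chrom, e.start, genomic[pos : pos + len(e)])
            pos += len(e)

    # ---- plant promoter motifs ------------------------------------------
    pwm = cebpa_example_pwm()
    consensus = pwm.consensus()
    rc_consensus = reverse_complement(consensus)
    motif_truth: List[Tuple[str, int, str]] = []
    linc_keeps = [p for p in keeps if p.label == "lincRNA"]
    for planted in linc_keeps[: cfg.n_motif_promoters]:
        t = planted.transcript
        if t.strand == "+":
            pstart, pend = t.start - cfg.promoter_length, t.start
        else:
            pstart, pend = t.end, t.end + cfg.promoter_length
        # scrub chance occurrences of the consensus from the promoter window
        for _ in range(50):
            window = read_genome(t.chrom, pstart, pend)
            hit = -1
            for pat in (consensus, rc_consensus):
                j = window.find(pat)
                if j >= 0 and not reserved[t.chrom][pstart + j : pstart + j + 8].any():
                    hit = j
                    break
            if hit < 0:
                break
            g = pstart + hit + 4
            genome_arr[t.chrom][g] = (genome_arr[t.chrom][g] + 2) % 4
        k = min(int(rng.poisson(cfg.motif_rate)), 12)
        chosen: List[int] = []
        for _ in range(k):
            for _attempt in range(100):
                off = int(rng.integers(0, cfg.promoter_length - len(consensus) + 1))
                if all(abs(off - c) >= len(consensus) for c in chosen):
                    chosen.append(off)
                    break
        for off in sorted(chosen):
            if t.strand == "+":
                gstart = pstart + off
                write_genome(t.chrom, gstart, consensus)
            else:
                gstart = pend - off - len(consensus)
                write_genome(t.chrom, gstart, rc_consensus)
            motif_truth.append((t.transcript_id, off, "+"))

    # ---- expression ------------------------------------------------------
    all_tx = [p.transcript for p in keeps + decoys] + coding
    tx_ids = [t.transcript_id for t in all_tx]
    lengths = pd.Series(
        [t.spliced_length for t in all_tx], index=tx_ids, dtype=float
    )

    n_keep = len(keeps)
    targets = np.empty(len(all_tx))
    n_low = math.ceil(cfg.fraction_low_expression * n_keep)
    keep_order = rng.permutation(n_keep)
    for rank, i in enumerate(keep_order):
        if rank < n_low:
            targets[i] = float(np.exp(rng.uniform(np.log(0.5), np.log(12.0))))
        else:
            targets[i] = float(rng.uniform(18.0, 60.0))
    for j in range(len(decoys)):
        targets[n_keep + j] = float(np.exp(rng.uniform(np.log(0.5), np.log(20.0))))
    for j in range(len(coding)):
        targets[n_keep + len(decoys) + j] = float(
            np.exp(rng.uniform(np.log(1.0), np.log(100.0)))
        )

    lfc = np.zeros(len(all_tx))
    de_idx = rng.choice(n_keep, size=cfg.n_de_up + cfg.n_de_down, replace=False)
    lfc[de_idx[: cfg.n_de_up]] = cfg.de_log2fc
    lfc[de_idx[cfg.n_de_up :]] = -cfg.de_log2fc

    cas_ids, int_ids = cfg.sample_ids
    n_pairs = cfg.samples_per_group
    pair_eps = rng.normal(0.0, cfg.pair_sd, size=(len(all_tx), n_pairs))
    counts = {}
    for j in range(n_pairs):
        for group, sid in (("cas", cas_ids[j]), ("int", int_ids[j])):
            fpkm_mean = targets * (2.0 ** lfc if group == "cas" else 1.0)
            mean_counts = (
                fpkm_mean
                * lengths.to_numpy()
                * cfg.library_size
                / 1e9
                * 2.0 ** pair_eps[:, j]
            )
            counts[sid] = _nb_draw(rng, mean_counts, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=tx_ids)[cas_ids + int_ids]
    # FPKM against the nominal library size: the toy transcriptome is a tiny
    # subsample of a full library, so realized column sums are not depths
    fpkm_df = (
        counts_df.mul(1e9).div(lengths, axis=0).div(cfg.library_size, axis=1)
    )

    # ---- qPCR ------------------------------------------------------------
    keep_ids = [p.transcript.transcript_id for p in keeps]
    up_ids = sorted(keep_ids[i] for i in de_idx[: cfg.n_de_up])
    down_ids = sorted(keep_ids[i] for i in de_idx[cfg.n_de_up :])
    qpcr_genes = up_ids[: cfg.n_qpcr_up] + down_ids[: cfg.n_qpcr_down]
    qpcr_rows = []
    for gene in qpcr_genes:
        eff = float(np.clip(rng.normal(0.93, 0.03), 0.80, 1.00))
        for j in range(n_pairs):
            for group, sid in (("castrated", cas_ids[j]), ("intact", int_ids[j])):
                val = float(fpkm_df.at[gene, sid])
                for rep in range(1, cfg.qpcr_replicates + 1):
                    ct = 22.0 - math.log2(val + 0.25) + rng.normal(0, cfg.ct_noise_sd)
                    ref = 15.0 + rng.normal(0, cfg.ct_noise_sd)
                    qpcr_rows.append(
                        {
                            "gene": gene,
                            "sample": sid,
                            "group": group,
                            "pair": j + 1,
                            "replicate": rep,
                            "ct": round(ct, 4),
                            "ref_ct": round(ref, 4),
                            "efficiency": round(eff, 3),
                        }
                    )
    qpcr_df = pd.DataFrame(qpcr_rows)

    # ---- pathways --------------------------------------------------------
    gene_ids = sorted({t.gene_id for t in coding})
    shuffled = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    pathway_size = 8
    pathways = {
        f"PATHWAY_{i // pathway_size + 1:02d}": shuffled[i : i + pathway_size]
        for i in range(0, len(shuffled) - pathway_size + 1, pathway_size)
    }

    # ---- write files -----------------------------------------------------
    paths: Dict[str, Path] = {}

    def out(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(
        {c: read_genome(c, 0, chrom_len) for c in chrom_names}, out("genome.fa")
    )
    write_gtf(coding, out("annotation.gtf"), source="lncseek_sim")
    write_gtf(
        [p.transcript for p in keeps + decoys],
        out("candidates.gtf"),
        source="lncseek_sim",
    )
    write_expression_table(fpkm_df, out("expression.tsv"))
    with open(out("smallrna.bed"), "w") as fh:
        for iv, name in smallrna:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
    write_mirnas(mirna_panel, out("mirnas.tsv"))
    write_pwm(pwm, out("pwm.txt"))
    qpcr_df.to_csv(out("qpcr.tsv"), sep="\t", index=False)
    with open(out("pathways.gmt"), "w") as fh:
        for name in sorted(pathways):
            fh.write("\t".join([name, "synthetic"] + pathways[name]) + "\n")

    de_status = {}
    for rank, i in enumerate(de_idx):
        de_status[keep_ids[i]] = "up" if rank < cfg.n_de_up else "down"
    with open(out("truth.tsv"), "w") as fh:
        fh.write(
            "transcript_id\tgene_id\trole\tlabel\tde\tlog2_effect\ttarget_fpkm\n"
        )
        for i, planted in enumerate(keeps + decoys):
            t = planted.transcript
            de = de_status.get(t.transcript_id, "ns")
            effect = lfc[i]
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\t{planted.role}\t{planted.label}"
                f"\t{de}\t{effect:g}\t{targets[i]:.6g}\n"
            )
        for j, t in enumerate(coding):
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\tcoding\t.\tns\t0"
                f"\t{targets[n_keep + len(decoys) + j]:.6g}\n"
            )
    with open(out("truth_motifs.tsv"), "w") as fh:
        fh.write("transcript_id\tpromoter_offset\tstrand\n")
        for tid, off, strand in motif_truth:
            fh.write(f"{tid}\t{off}\t{strand}\n")
    with open(out("truth_seeds.tsv"), "w") as fh:
        fh.write("transcript_id\tmirna\toffset\tsite_type\n")
        for tid, mir, off, stype in seed_truth:
            fh.write(f"{tid}\t{mir}\t{off}\t{stype}\n")
    with open(out("config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# standalone count simulators (for calibration and power studies)


def simulate_null_counts(
    n_transcripts: int,
    n_per_group: int,
    dispersion: float,
    seed: int,
    mean: float = 100.0,
) -> pd.DataFrame:
    """Two-group NB count matrix with no group effect (both groups one law)."""
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    if n_per_group < 2:
        raise ConfigurationError("need at least 2 samples per group")
    if n_transcripts < 0:
        raise ConfigurationError("n_transcripts must be >= 0")
    rng = np.random.default_rng(seed)
    cols = [f"case_{i + 1}" for i in range(n_per_group)] + [
        f"ctrl_{i + 1}" for i in range(n_per_group)
    ]
    if n_transcripts == 0:
        return pd.DataFrame({c: pd.Series(dtype=int) for c in cols})
    data = {
        c: _nb_draw(rng, np.full(n_transcripts, float(mean)), dispersion)
        for c in cols
    }
    index = [f"tx_{i + 1}" for i in range(n_transcripts)]
    return pd.DataFrame(data, index=index)


def simulate_two_group_counts(
    means: Sequence[float],
    log2fc: Sequence[float],
    n_per_group: int,
    dispersion: float,
    seed: int,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """NB counts with per-transcript control means and planted case log2FCs.

    Returns (counts, case_sample_ids, control_sample_ids).
    """
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    if n_per_group < 2:
        raise ConfigurationError("need at least 2 samples per group")
    means = np.asarray(means, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if means.shape != log2fc.shape or np.any(means <= 0):
        raise ConfigurationError("means must be positive and match log2fc in shape")
    rng = np.random.default_rng(seed)
    case_cols = [f"case_{i + 1}" for i in range(n_per_group)]
    ctrl_cols = [f"ctrl_{i + 1}" for i in range(n_per_group)]
    data = {}
    for c in case_cols:
        data[c] = _nb_draw(rng, means * 2.0 ** log2fc, dispersion)
    for c in ctrl_cols:
        data[c] = _nb_draw(rng, means, dispersion)
    index = [f"tx_{i + 1}" for i in range(len(means))]
    return pd.DataFrame(data, index=index), case_cols, ctrl_cols
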