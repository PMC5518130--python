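# Methods

This note documents the models and procedures implemented in `lncseek`, the
parameters that matter, what the synthetic study does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Identification cascade

Candidates are triaged by five filters in fixed order (detection breadth,
size/exon count, coverage, small-RNA overlap, coding potential). Design
choices:

* **Step 2 is a disjunction.** Mono-exonic transcripts and transcripts
  shorter than 200 nt are removed independently; either condition triggers
  removal. This is the reading consistent with discovery sets whose shortest
  member is just above 200 nt and whose members are overwhelmingly
  multi-exonic. A strict conjunction is available via
  `FilterParams(require_multi_exon=False)`.
* **Detection breadth** counts libraries over the whole experiment (not per
  condition); the attribute travels on the GTF as `exp_count`.
* **Coverage** is mean per-base read depth as emitted by the assembler's
  `cov` attribute (the conventional Cufflinks meaning).
* **Small-RNA similarity** is implemented as strand-agnostic genomic overlap
  (≥ 1 bp, exonic) with a BED blacklist rather than sequence alignment: no
  aligner or identity cutoff is part of the contract, and genomic overlap is
  reproducible and auditable.
* **Coding potential** uses a transparent ORF-length surrogate: coding iff
  the longest ATG-initiated ORF ≥ 300 nt (~100 aa, the conventional lncRNA
  cutoff). The interface is pluggable: external predictor labels
  (CPC/CNCI/Pfam or anything else) are combined by the strictest rule — a
  transcript is noncoding only when every predictor that labels it agrees,
  the built-in rule counting as one predictor.
* **ORF convention.** Lengths are stop-codon-inclusive; with no in-frame stop
  the open reading runs to the last complete codon and is flagged
  `has_stop=False`. Ties break to the smaller start offset, then the smaller
  frame. Codons containing `N` never match ATG or a stop. Scanning is
  sense-strand only, all three frames.

The cascade records survivors after each step and the *first* triggering
rejection reason per transcript, so `survivors + rejected = input` always
holds and reapplying the cascade to its own survivors is the identity.

## Positional classification

Precedence antisense > intronic > lincRNA, with the three labels defined so
they partition the survivor set: antisense needs exonic overlap on the
opposite strand; intronic needs the whole span inside a single intron of some
coding transcript on either strand (sense- and antisense-intronic are not
distinguished, since the taxonomy has exactly three classes); lincRNA needs
zero overlap with any coding gene span (union of isoform spans — intergenic
is a gene-level notion). Anything else — in particular same-strand exonic
overlap, which would make the transcript a coding-gene isoform candidate
rather than a lncRNA — is flagged `ambiguous` and excluded.

Cis targets use gap distance between the lncRNA span and the gene union span
(0 when overlapping), signed negative when the gene lies 5′ of the lncRNA in
genomic coordinates; windows default to 10 kb and 100 kb and nest by
construction. Promoters are the 2,000 bp upstream of the TSS, strand-aware
(minus-strand promoters are reverse-complemented so the string reads 5′→3′
toward the TSS) and clipped at chromosome edges rather than erroring.

## Motif and seed scanning

The PWM scorer replaces proprietary matrix-similarity scores with min-max
normalized log-odds: S = Σⱼ log(p(bⱼ,j)/q(bⱼ)) mapped to
(S − S_min)/(S_max − S_min), where S_min/S_max are the per-matrix attainable
extremes. The consensus therefore scores exactly 1, hit count is
non-increasing in the threshold, and scanning a sequence and its reverse
complement yields the same score multiset. Default threshold 0.85; windows
containing `N` score −∞. The bundled C/EBPα-like matrix is built from an
illustrative alignment of TTGCGCAA-family sites (pseudocount 0.5, uniform
background) — it is a fixture for demonstrations and tests, not a curated
database matrix. Note the consensus is palindromic, so a planted site is
reported on both strands at the same offset.

Seed matching is the canonical hierarchy on the transcript's spliced sense
sequence (8mer > 7mer-m8 > 7mer-A1 > 6mer, strongest type per offset, miRNA
positions numbered from the 5′ end, U→T applied on the miRNA side). Scanning
operates on transcript sequence by default — the field's convention for
miRNA–lncRNA targeting — but the scanner is sequence-agnostic, so promoter
sequences can be passed instead where that reading is wanted.
Thermodynamic duplex scoring and conservation filters are out of scope.

## Differential expression and enrichment

The DE test is deliberately transparent rather than a reimplementation of any
specific tool: per transcript, a two-sided Welch t-test on log2(FPKM + 1),
BH-adjusted across all tested transcripts, with calls requiring both
|log2FC| ≥ 1 and q < 0.05. Fold changes are computed on pseudocounted group
means (castrated over intact). The pseudocount (default 1) avoids −∞ at zero
and intentionally shrinks fold changes of lowly expressed transcripts, which
is why detection sensitivity rises with expression level. Constant
transcripts with equal group means get p = 1 by convention. The full-sib
pairing of the motivating design is ignored by the default (unpaired) test;
the generator nevertheless simulates the pairing so paired analyses can be
explored.

Enrichment is the hypergeometric upper tail P(X ≥ k) over a
user-chosen universe, defaulting in the pipeline to all expressed
protein-coding genes, with BH across pathways.

qPCR arithmetic: replicate Ct values are averaged first; relative expression
is 2^−ΔΔCt; primer efficiency is E = 10^(−1/slope) − 1 from the standard
curve slope (slope −1/log₁₀2 ≈ −3.3219 ⇔ perfect doubling, E = 1);
concordance is the Pearson correlation of qPCR and RNA-seq log2 fold changes.

## Synthetic study

The generator emulates the 3-vs-3 castrated/intact full-sib design at toy
scale and writes machine-readable truth tables. Defaults (chosen once as the
standard study conditions): 2 chromosomes × 500 kb, 40 protein-coding genes,
30 planted lncRNAs (16 lincRNA / 8 antisense / 6 intronic), 4 decoys per
rejection reason (24 total), NB counts with dispersion 0.1, a shared per-pair
N(0, 0.25²) intercept on the log2 mean emulating full-sib correlation, 9 up-
and 9 down-regulated lncRNAs planted at |log2FC| = 2, 91.2% of planted
lncRNAs assigned mean-FPKM targets below 15 (low lncRNA expression is a
design feature, enforced by construction on the assigned targets), Poisson(1.9)
consensus motifs planted in 10 lincRNA promoters, two seed sites planted in
each of 10 transcripts, and qPCR plates with Ct = 22 − log2(FPKM + 0.25) +
N(0, 0.15²) per well (0.15 cycles is typical replicate spread; a free
simulation parameter). FPKM is computed against the nominal library size
(2×10⁷ fragments) because the toy transcriptome is a tiny subsample of a
full library — realized column sums are not sequencing depths.

Construction guarantees: every planted lincRNA/antisense/intronic satisfies
its class definition geometrically; every decoy violates exactly one filter;
planted lncRNA sequences are ORF-repaired (in-frame TAA insertions at
positions not occupied by planted features) so no keep reaches the 300-nt
coding cutoff, while the coding decoy carries an explicit 366-nt ORF; planted
motif and seed sites are recorded with their offsets, and chance consensus
occurrences are scrubbed from designated promoters before planting. A fixed
seed yields byte-identical files.

What the generator does **not** emulate: read-level data (FASTQ, mapping
ambiguity, positional bias), assembly artifacts (fragmented or chimeric
models), realistic genome composition (GC structure, repeats), isoform
complexity (one transcript per locus by default) and between-transcript
correlation beyond the pair intercept. Passing the planted-truth suites
therefore demonstrates that the implementation computes its contracts
exactly, not that the cascade's thresholds are optimal on real tissue.

Expected statistical behavior at the default scale, measured by the
acceptance script rather than asserted as constants: the Welch/BH test is
slightly conservative under the NB null at n = 3 (raw p < 0.05 rate ≈ 0.035,
inside the 0.03–0.08 calibration band), sensitivity at |log2FC| = 2 rises
monotonically across expression tiers and is low for the faintest
transcripts (so only a minority of the 18 planted DE lncRNAs reach q < 0.05
— expected, not a defect), no significant call flips sign, and qPCR/RNA-seq
concordance on the 8 assayed genes is R > 0.9.

## Problem sizes

The bundled tests and the acceptance script run at the default toy scale
(seconds on one CPU): the 54-candidate study end to end, 200 null replicates
of 2,000 transcripts for calibration, 1,200 transcripts for the power tiers,
and 100 random sequences per scanner for the brute-force oracle comparisons.

## Known limitations

* The ORF surrogate and the external-label intersection rule approximate,
  but do not reproduce, CPC/CNCI/Pfam decisions; the PWM scanner is not
  numerically comparable to commercial matrix-similarity scores (only the
  [0, 1] interface and monotonicity are shared); seed matching ignores
  binding energetics.
* The DE test is a generic two-group test; it does not emulate Cuffdiff or
  negative-binomial GLMs, and with n = 3 it has limited power at low
  expression.
* Mean ORF length in summaries averages over ORF-bearing transcripts only
  (the count of ORF-less transcripts is reported alongside).
* Multi-isoform lncRNA loci aggregate as: length/exon/ORF statistics per
  transcript; class, cis-target and motif-site accounting per locus (class by
  precedence, targets as union, motif sites as the max over isoform
  promoters). Both raw tables are emitted so either accounting can be redone.
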