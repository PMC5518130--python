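"""ORF finding against a brute-force oracle, coding-potential votes, filter cascade."""

import numpy as np
import pytest

from lncseek import (
    FilterParams,
    GenomicInterval,
    SequenceStore,
    SimulationConfig,
    TranscriptModel,
    find_longest_orf,
    run_filter_cascade,
    score_coding_potential,
    simulate_study,
)
from lncseek.formats_io import read_gtf

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq):
    """Enumerate every ATG...stop span in all frames; same tie/tail convention."""
    seq = seq.upper()
    n = len(seq)
    spans = []
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        has_stop = False
        for pos in range(start, n - 2, 3):
            if seq[pos : pos + 3] in STOPS:
                end = pos + 3
                has_stop = True
                break
        if end is None:
            end = start + 3 * ((n - start) // 3)
        spans.append((end - start, -start, -(start % 3), start, end, has_stop))
    if not spans:
        return None
    length, _ns, _nf, start, end, has_stop = max(spans)
    return (start, end, length, has_stop)


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAG", (0, 9, 9, True)),
            ("ATGATGTGA", (0, 9, 9, True)),  # outer ATG outranks nested start
            ("ATGAAA", (0, 6, 6, False)),  # open to the 3' end
            ("ATGAAAT", (0, 6, 6, False)),  # tail truncated to whole codons
        ],
    )
    def test_known_orfs(self, seq, expected):
        orf = find_longest_orf(seq)
        assert (orf.start, orf.end, orf.length_nt, orf.has_stop) == expected

    def test_no_start_codon_or_empty(self):
        assert find_longest_orf("CCCCCCCC") is None
        assert find_longest_orf("") is None

    def test_stop_inclusive_and_multiple_of_three(self):
        orf = find_longest_orf("CCATGAAATTTTAGCC")
        assert orf.has_stop and orf.length_nt % 3 == 0

    def test_n_never_matches_start_or_stop(self):
        assert find_longest_orf("ATN" * 20) is None
        orf = find_longest_orf("ATGAANTAA")
        assert orf.length_nt == 9  # TAA still terminates; AAN is a plain codon

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(0, 240))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            got = find_longest_orf(seq)
            want = brute_force_longest_orf(seq)
            if want is None:
                assert got is None
            else:
                assert (got.start, got.end, got.length_nt, got.has_stop) == want


def _cand(tid, spliced, n_exons=2, nexp=3, cov=10.0, chrom="chr1", start=0,
          strand="+"):
    if n_exons == 1:
        exons = (GenomicInterval(chrom, start, start + spliced, strand),)
    else:
        half = spliced // 2
        exons = (
            GenomicInterval(chrom, start, start + half, strand),
            GenomicInterval(chrom, start + half + 100,
                            start + half + 100 + (spliced - half), strand),
        )
    return TranscriptModel(tid, f"G_{tid}", exons, n_experiments_detected=nexp,
                           coverage=cov)


NONCODING = "".join(
    c for c in ("CCC" * 400)
)  # no ATG anywhere -> no ORF


class TestCodingPotential:
    def test_builtin_threshold(self):
        params = FilterParams()
        short_orf = "C" * 100 + "ATG" + "GGA" * 29 + "TAA" + "C" * 50  # 93-nt ORF
        long_orf = "ATG" + "GGA" * 149 + "TAA"  # 453-nt ORF
        t = _cand("t", 300)
        assert score_coding_potential(t, short_orf, params) == "noncoding"
        assert score_coding_potential(t, long_orf, params) == "coding"

    def test_external_labels_require_unanimous_noncoding(self):
        t = _cand("t1", 300)
        seq = "C" * 300  # built-in votes noncoding
        params = FilterParams(
            external_coding_labels={
                "CPC": {"t1": "noncoding"},
                "CNCI": {"t1": "coding"},
            }
        )
        assert score_coding_potential(t, seq, params) == "coding"
        params_all_nc = FilterParams(
            external_coding_labels={
                "CPC": {"t1": "noncoding"},
                "CNCI": {"t1": "noncoding"},
            }
        )
        assert score_coding_potential(t, seq, params_all_nc) == "noncoding"

    def test_unknown_external_transcript_id_is_key_error(self):
        t = _cand("t1", 300)
        params = FilterParams(external_coding_labels={"CPC": {"ghost": "coding"}})
        with pytest.raises(KeyError):
            run_filter_cascade([t], [], params, sequences={"t1": "C" * 300})


class TestCascade:
    def _run(self, cands, smallrna=(), params=None):
        seqs = {t.transcript_id: NONCODING[: t.spliced_length] for t in cands}
        return run_filter_cascade(cands, smallrna, params or FilterParams(),
                                  sequences=seqs)

    def test_mono_exonic_removed_even_when_long(self):
        _surv, report = self._run([_cand("m", 1_000, n_exons=1)])
        assert report.rejected["m"] == "mono_exonic"

    def test_short_multi_exon_removed(self):
        _surv, report = self._run([_cand("s", 199)])
        assert report.rejected["s"] == "too_short"

    def test_first_triggering_reason_wins(self):
        # fails detection (step 1) and coverage (step 3): step 1 reason reported
        _surv, report = self._run([_cand("x", 600, nexp=1, cov=0.5)])
        assert report.rejected["x"] == "few_experiments"

    def test_strict_and_reading_keeps_long_mono_exonic(self):
        params = FilterParams(require_multi_exon=False)
        surv, _report = self._run([_cand("m", 1_000, n_exons=1)], params=params)
        assert [t.transcript_id for t in surv] == ["m"]

    def test_small_rna_overlap_is_strand_agnostic_and_exonic(self):
        t = _cand("t", 600, start=1_000, strand="+")
        hit = GenomicInterval("chr1", 1_010, 1_020, "-")
        intron_only = GenomicInterval("chr1", 1_305, 1_390, "-")  # in the gap
        _surv, report = self._run([t], smallrna=[hit])
        assert report.rejected["t"] == "small_rna_overlap"
        surv, _ = self._run([t], smallrna=[intron_only])
        assert len(surv) == 1

    def test_empty_input_yields_zero_count_report(self):
        surv, report = self._run([])
        assert surv == [] and report.n_survivors == 0
        report.validate()

    def test_counts_non_increasing_and_partition(self):
        cands = [
            _cand("a", 600),
            _cand("b", 150),
            _cand("c", 600, nexp=1),
            _cand("d", 600, cov=1.0),
        ]
        surv, report = self._run(cands)
        counts = [report.n_input] + [n for _s, n in report.steps]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert len(surv) + len(report.rejected) == report.n_input

    def test_cascade_is_idempotent(self):
        cands = [_cand("a", 600), _cand("b", 150), _cand("c", 600, cov=0.1)]
        surv1, _ = self._run(cands)
        surv2, report2 = self._run(surv1)
        assert [t.transcript_id for t in surv1] == [t.transcript_id for t in surv2]
        assert report2.rejected == {}

    def test_survivors_are_long_and_multi_exonic(self):
        cands = [_cand(f"t{i}", 180 + 20 * i, n_exons=1 + i % 3) for i in range(12)]
        surv, _ = self._run(cands)
        assert all(t.spliced_length >= 200 and t.n_exons >= 2 for t in surv)


def test_zero_decoy_simulation_keeps_every_candidate(tmp_path):
    cfg = SimulationConfig(
        seed=5,
        decoys_per_reason={},
        n_lincrna=6,
        n_antisense=3,
        n_intronic=2,
        n_de_up=3,
        n_de_down=3,
        n_coding_genes=20,
        n_motif_promoters=4,
        n_seed_transcripts=4,
    )
    paths = simulate_study(cfg, tmp_path)
    candidates = read_gtf(paths["candidates.gtf"])
    genome = SequenceStore.from_fasta(paths["genome.fa"])
    surv, report = run_filter_cascade(candidates, [], genome=genome)
    assert report.rejected == {}
    assert {t.transcript_id for t in surv} == {
        t.transcript_id for t in candidates
    }
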