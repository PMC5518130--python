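"""PWM construction/scanning and seed matching, checked against naive oracles."""

import math

import numpy as np
import pytest

from lncseek import (
    InputError,
    MiRNA,
    build_pwm,
    cebpa_example_pwm,
    pwm_scan,
    read_pwm,
    reverse_complement,
    seed_scan,
    write_pwm,
)

RNG = np.random.default_rng(21)


def naive_pwm_scan(seq, pwm, threshold, both_strands=True):
    """Per-offset rescoring with plain Python loops (independent of the scanner)."""
    seq = seq.upper()
    L = pwm.length
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    lo = [
        [math.log(pwm.matrix[b, j] / pwm.background[b]) for j in range(L)]
        for b in range(4)
    ]
    smin = sum(min(lo[b][j] for b in range(4)) for j in range(L))
    smax = sum(max(lo[b][j] for b in range(4)) for j in range(L))
    hits = []
    strands = ["+", "-"] if both_strands else ["+"]
    for off in range(len(seq) - L + 1):
        for strand in strands:
            window = seq[off : off + L]
            if strand == "-":
                window = reverse_complement(window)
            if any(c not in idx for c in window):
                continue
            s = sum(lo[idx[c]][j] for j, c in enumerate(window))
            norm = (s - smin) / (smax - smin)
            if norm >= threshold:
                hits.append((off, strand, norm))
    return sorted(hits)


def naive_seed_scan(seq, mirna):
    """Substring search for the four site strings, strongest type per offset."""
    seq = seq.upper().replace("U", "T")
    sites = mirna.site_strings()
    found = {}
    for stype in ("6mer", "7mer-A1", "7mer-m8", "8mer"):  # weakest to strongest
        pat = sites[stype]
        start = 0
        while True:
            j = seq.find(pat, start)
            if j < 0:
                break
            found[j] = stype  # later (stronger) types overwrite
            start = j + 1
    return sorted(found.items())


class TestBuildPwm:
    def test_pure_counts_without_pseudocount(self):
        pwm = build_pwm(["AATT", "AATT"], pseudocount=0.0)
        np.testing.assert_allclose(pwm.matrix[:, 0], [1, 0, 0, 0])
        np.testing.assert_allclose(pwm.matrix[:, 3], [0, 0, 0, 1])

    def test_pseudocount_formula_by_hand(self):
        # sites {A, C}, pseudocount 0.5:
        # p(b) = (count + 0.5) / (2 + 4*0.5), so p(A) = p(C) = 1.5/4, p(G) = p(T) = 0.5/4
        pwm = build_pwm(["A", "C"], pseudocount=0.5)
        np.testing.assert_allclose(
            pwm.matrix[:, 0], [1.5 / 4, 1.5 / 4, 0.5 / 4, 0.5 / 4], atol=1e-12
        )

    def test_single_site_and_ragged_lengths_rejected(self):
        with pytest.raises(InputError):
            build_pwm(["ACGT"])
        with pytest.raises(InputError):
            build_pwm(["ACGT", "ACG"])

    def test_columns_sum_to_one(self):
        pwm = cebpa_example_pwm()
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-12)


class TestPwmScan:
    def test_consensus_scores_exactly_one(self):
        pwm = cebpa_example_pwm()
        hits = pwm_scan(pwm.consensus(), pwm, threshold=1.0)
        assert any(h.offset == 0 and h.score == pytest.approx(1.0) for h in hits)

    def test_hit_count_non_increasing_in_threshold(self):
        pwm = cebpa_example_pwm()
        seq = "".join(RNG.choice(list("ACGT"), size=500))
        counts = [len(pwm_scan(seq, pwm, th)) for th in (0.0, 0.5, 0.8, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_zero_reports_every_offset_both_strands(self):
        pwm = cebpa_example_pwm()
        seq = "".join(RNG.choice(list("ACGT"), size=60))
        hits = pwm_scan(seq, pwm, threshold=0.0)
        assert len(hits) == 2 * (len(seq) - pwm.length + 1)

    def test_reverse_complement_scan_preserves_score_multiset(self):
        pwm = cebpa_example_pwm()
        seq = "".join(RNG.choice(list("ACGT"), size=300))
        fwd = sorted(round(h.score, 12) for h in pwm_scan(seq, pwm, 0.0))
        rev = sorted(
            round(h.score, 12)
            for h in pwm_scan(reverse_complement(seq), pwm, 0.0)
        )
        assert fwd == rev

    def test_windows_with_n_never_hit(self):
        pwm = cebpa_example_pwm()
        seq = "N" * 20
        assert pwm_scan(seq, pwm, threshold=0.0) == []

    def test_sequence_shorter_than_matrix_is_empty(self):
        pwm = cebpa_example_pwm()
        assert pwm_scan("ACG", pwm) == []

    @pytest.mark.parametrize("threshold", [0.7, 0.85, 0.95])
    def test_agrees_with_naive_rescoring(self, threshold):
        pwm = cebpa_example_pwm()
        for _ in range(20):
            n = int(RNG.integers(8, 400))
            seq = "".join(RNG.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            got = sorted((h.offset, h.strand, round(h.score, 10))
                         for h in pwm_scan(seq, pwm, threshold))
            want = [(o, s, round(sc, 10))
                    for o, s, sc in naive_pwm_scan(seq, pwm, threshold)]
            assert got == want

    def test_planted_consensus_recovered_at_threshold_one(self):
        pwm = cebpa_example_pwm()
        rng = np.random.default_rng(4)
        consensus = pwm.consensus()
        bg = list("ACG")  # no T: background can never spell the T-rich consensus
        seq = list("".join(rng.choice(bg, size=2_000)))
        planted = [100, 700, 1_500]
        for off in planted:
            seq[off : off + len(consensus)] = consensus
        hits = pwm_scan("".join(seq), pwm, threshold=1.0)
        assert sorted({h.offset for h in hits}) == planted

    def test_file_round_trip(self, tmp_path):
        pwm = cebpa_example_pwm()
        p = tmp_path / "m.pwm"
        write_pwm(pwm, p)
        back = read_pwm(p)
        np.testing.assert_array_equal(back.matrix, pwm.matrix)
        np.testing.assert_array_equal(back.background, pwm.background)


LET7 = MiRNA("let-7", "UGAGGUAGUAGGUUGUAUAGUU")


class TestSeedScan:
    def test_let7_seed_reverse_complement_site(self):
        # positions 2-8 of let-7 are GAGGUAG; transcript-side 7mer-m8 is CTACCTC
        assert LET7.site_strings()["7mer-m8"] == "CTACCTC"
        hits = seed_scan("GGGCTACCTCGGG", [LET7])
        assert any(h.offset == 3 and h.site_type in ("7mer-m8", "8mer") for h in hits)

    def test_exact_8mer_transcript(self):
        site = LET7.site_strings()["8mer"]
        (hit,) = [h for h in seed_scan(site, [LET7]) if h.site_type == "8mer"]
        assert hit.offset == 0

    def test_site_hierarchy_strongest_type_reported(self):
        s = LET7.site_strings()
        assert s["8mer"] == s["7mer-m8"] + "A"
        assert s["7mer-A1"] == s["6mer"] + "A"
        hits = {h.offset: h.site_type for h in seed_scan(s["8mer"], [LET7])}
        assert hits[0] == "8mer"  # not double-reported as 7mer-m8

    def test_mature_shorter_than_8_rejected(self):
        with pytest.raises(InputError):
            MiRNA("tiny", "UGAGGUA")

    def test_u_and_t_transcripts_equivalent(self):
        dna = seed_scan("GGCTACCTCAGG", [LET7])
        rna = seed_scan("GGCUACCUCAGG", [LET7])
        assert [(h.offset, h.site_type) for h in dna] == [
            (h.offset, h.site_type) for h in rna
        ]

    def test_agrees_with_naive_substring_search(self):
        mirnas = [LET7, MiRNA("miR-21", "UAGCUUAUCAGACUGAUGUUGA")]
        for _ in range(20):
            n = int(RNG.integers(10, 2_000))
            seq = "".join(RNG.choice(list("ACGT"), size=n))
            for mir in mirnas:
                got = sorted(
                    (h.offset, h.site_type)
                    for h in seed_scan(seq, [mir])
                )
                assert got == naive_seed_scan(seq, mir)
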