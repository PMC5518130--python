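"""FPKM normalization, DE testing, BH, enrichment, and qPCR arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from lncseek import (
    InputError,
    bh_adjust,
    concordance,
    de_test,
    delta_delta_ct,
    enrich_targets,
    normalize_fpkm,
    primer_efficiency,
)


def naive_bh(p):
    """Independent step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestNormalizeFpkm:
    def test_formula_by_hand(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["a", "b"])
        fpkm = normalize_fpkm(counts, {"a": 1_000, "b": 500},
                              {"s1": 1_000_000})
        assert fpkm.at["a", "s1"] == pytest.approx(100.0)
        assert fpkm.at["b", "s1"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [40], "s2": [40]}, index=["a"])
        fpkm = normalize_fpkm(counts, {"a": 1_000}, {"s1": 1e6, "s2": 2e6})
        assert fpkm.at["a", "s1"] == pytest.approx(2 * fpkm.at["a", "s2"])

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(InputError):
            normalize_fpkm(counts, {"a": 100}, {"s1": 0})


class TestDeTest:
    CASE = ["c1", "c2", "c3"]
    CTRL = ["k1", "k2", "k3"]

    def _frame(self, case_vals, ctrl_vals, ids=("t1",)):
        data = {}
        for j, c in enumerate(self.CASE):
            data[c] = [v[j] for v in case_vals]
        for j, c in enumerate(self.CTRL):
            data[c] = [v[j] for v in ctrl_vals]
        return pd.DataFrame(data, index=list(ids))

    def test_identical_groups_are_ns_with_zero_lfc(self):
        expr = self._frame([(5.0, 6.0, 7.0)], [(5.0, 6.0, 7.0)])
        res = de_test(expr, self.CASE, self.CTRL)
        assert res.at["t1", "log2fc"] == 0.0
        assert res.at["t1", "call"] == "ns"

    def test_fold_change_arithmetic_without_pseudocount(self):
        expr = self._frame([(10.0, 10.0, 10.0)], [(5.0, 5.0, 5.0)])
        res = de_test(expr, self.CASE, self.CTRL, pseudocount=0.0)
        assert res.at["t1", "log2fc"] == pytest.approx(1.0)

    def test_constant_equal_transcript_gets_p_one(self):
        expr = self._frame([(3.0, 3.0, 3.0)], [(3.0, 3.0, 3.0)])
        res = de_test(expr, self.CASE, self.CTRL)
        assert res.at["t1", "pvalue"] == 1.0

    def test_label_swap_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, 6)),
            columns=self.CASE + self.CTRL,
            index=[f"t{i}" for i in range(50)],
        )
        a = de_test(expr, self.CASE, self.CTRL)
        b = de_test(expr, self.CTRL, self.CASE)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], atol=1e-12)

    def test_calls_respect_both_thresholds(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(3, 0.2, size=(100, 3))
        up = np.vstack([base[:50] * 8, base[50:]])
        expr = pd.DataFrame(
            np.hstack([up, base]),
            columns=self.CASE + self.CTRL,
            index=[f"t{i}" for i in range(100)],
        )
        res = de_test(expr, self.CASE, self.CTRL)
        called = res[res["call"] != "ns"]
        assert len(called) > 0
        assert ((called["qvalue"] < 0.05)
                & (called["log2fc"].abs() >= 1.0)).all()

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["t"])
        with pytest.raises(InputError):
            de_test(expr, ["a"], ["b", "c"])


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_independent_step_up_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            np.testing.assert_allclose(bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_monotone_in_each_pvalue(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        bumped = p.copy()
        bumped[7] = min(1.0, p[7] + 0.2)
        assert (bh_adjust(bumped) >= q - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestEnrichment:
    def test_complete_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        res = enrich_targets(pathway, {"P": pathway}, universe)
        assert res.at["P", "pvalue"] == pytest.approx(1.0 / comb(20, 5, exact=True))

    def test_zero_overlap_and_degenerate_certainty(self):
        universe = {f"g{i}" for i in range(20)}
        res = enrich_targets(
            {"g10", "g11"}, {"P": {"g0", "g1"}, "ALL": universe}, universe
        )
        assert res.at["P", "pvalue"] == pytest.approx(
            1.0, abs=1e-12
        ) or res.at["P", "pvalue"] < 1.0  # P(X >= 0) when overlap 0
        assert res.at["ALL", "pvalue"] == pytest.approx(1.0)
        res0 = enrich_targets(set(), {"P": {"g0"}}, universe)
        assert res0.at["P", "pvalue"] == pytest.approx(1.0)

    def test_targets_outside_universe_rejected(self):
        with pytest.raises(InputError):
            enrich_targets({"x"}, {"P": {"a"}}, {"a", "b"})
        with pytest.raises(InputError):
            enrich_targets(set(), {}, set())


class TestQpcr:
    def test_ddct_worked_example(self):
        assert delta_delta_ct(20, 15, 22, 15) == pytest.approx(4.0)

    def test_calibrator_against_itself_is_one(self):
        assert delta_delta_ct(19.3, 15.1, 19.3, 15.1) == pytest.approx(1.0)

    def test_one_extra_cycle_halves_expression(self):
        base = delta_delta_ct(20, 15, 22, 15)
        assert delta_delta_ct(21, 15, 22, 15) == pytest.approx(base / 2)

    def test_replicates_averaged_first(self):
        assert delta_delta_ct([19.9, 20.1], [15.0, 15.0], 22, 15) == pytest.approx(4.0)

    def test_perfect_doubling_slope(self):
        assert primer_efficiency(-1 / math.log10(2)) == pytest.approx(1.0, abs=1e-3)

    def test_efficiency_closed_form(self):
        assert primer_efficiency(-3.6) == pytest.approx(10 ** (1 / 3.6) - 1)

    def test_positive_slope_rejected(self):
        with pytest.raises(InputError):
            primer_efficiency(1.0)


class TestConcordance:
    def test_perfect_agreement_and_disagreement(self):
        x = [1.0, -2.0, 0.5, 3.0]
        assert concordance(x, x) == pytest.approx(1.0)
        assert concordance(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(InputError):
            concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            concordance([1.0, 2.0], [1.0, 2.0])
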