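"""Audic-Claverie significance and stress-regulation calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_ac_pvalue
from oryzamir.config import PipelineConfig
from oryzamir.diffexpr import ac_pvalue, call_stress_regulated, log2_ratio

DEPTHS = {"control": 10_000_000, "drought": 10_000_000,
          "cold": 10_000_000, "salt": 10_000_000}


class TestAcPvalue:
    def test_zero_zero_equal_depths_is_one(self):
        assert ac_pvalue(0, 0, 10_000, 10_000) == 1.0

    def test_zero_vs_nine_equal_depths(self):
        # P(Y >= 9 | x=0) = 2^-9; doubled = 2/512
        assert ac_pvalue(0, 9, 10_000, 10_000) == pytest.approx(2 / 512,
                                                                rel=1e-12)

    def test_near_symmetry_at_equal_depths(self):
        # swapping x and y moves each inclusive tail by at most the observed
        # point's mass, so the doubled-minimal-tail p-values agree within 2x
        for x, y in [(3, 17), (40, 25), (0, 100), (7, 7)]:
            p1 = ac_pvalue(x, y, 5_000, 5_000)
            p2 = ac_pvalue(y, x, 5_000, 5_000)
            assert p2 / 2 * (1 - 1e-9) <= p1 <= 2 * p2 * (1 + 1e-9)

    def test_matches_negative_binomial_identity(self):
        # p(k|x) is NB(r=x+1, p=N1/(N1+N2)); cross-check via scipy.stats
        from scipy import stats
        for x, y, n1, n2 in [(5, 20, 10**6, 10**6), (30, 12, 10**6, 2 * 10**6)]:
            ps = n1 / (n1 + n2)
            expected = min(1.0, 2 * min(stats.nbinom.cdf(y, x + 1, ps),
                                        stats.nbinom.sf(y - 1, x + 1, ps)))
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.integers(0, 500, size=2)
            p = ac_pvalue(int(x), int(y), 1_000_000, 2_000_000)
            assert 0.0 < p <= 1.0

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.integers(0, 120), st.integers(0, 120),
           st.sampled_from([(10**6, 10**6), (10**6, 2 * 10**6)]))
    def test_matches_direct_log_space_summation(self, x, y, depths):
        n1, n2 = depths
        assert ac_pvalue(x, y, n1, n2) == \
            pytest.approx(naive_ac_pvalue(x, y, n1, n2), rel=1e-10)

    def test_large_counts_do_not_overflow(self):
        p = ac_pvalue(100_000, 120_000, 5_000_000, 5_000_000)
        assert 0.0 < p < 1e-6

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ac_pvalue(-1, 0, 100, 100)
        with pytest.raises(ValueError):
            ac_pvalue(0, 0, 0, 100)


class TestLog2Ratio:
    def test_four_fold_change_is_two(self):
        assert log2_ratio(400.0, 100.0, 10**6, 10**6) == pytest.approx(2.0)

    def test_equal_expression_is_zero(self):
        assert log2_ratio(150.0, 150.0, 10**6, 10**6) == 0.0

    def test_zero_stress_count_uses_single_read_pseudocount(self):
        # one read in 4e6 is 2.5 TPTM; log2(2.5/100) ~ -5.32
        assert log2_ratio(0.0, 100.0, 4_000_000, 4_000_000) == \
            pytest.approx(math.log2(2.5 / 100), abs=1e-6)

    def test_both_zero_is_undefined(self):
        assert math.isnan(log2_ratio(0.0, 0.0, 10**6, 10**6))


def _calls(control, drought):
    counts = pd.DataFrame({"control": control, "drought": drought,
                           "cold": control, "salt": control},
                          index=[f"m{i}" for i in range(len(control))])
    return {c.mirna: c for c in call_stress_regulated(counts, DEPTHS)
            if c.stress == "drought"}


class TestStressCalls:
    def test_all_three_criteria_met_calls_up(self):
        calls = _calls([60], [150])  # TPTM 60 vs 150, log2 ~ 1.32
        assert calls["m0"].verdict == "up"
        assert calls["m0"].p <= 0.01

    def test_log2_ratio_exactly_one_is_unchanged(self):
        calls = _calls([50], [100])  # log2 exactly 1, everything else passes
        assert calls["m0"].log2_ratio == pytest.approx(1.0)
        assert calls["m0"].verdict == "unchanged"

    def test_expression_floor_of_100_tptm_is_enforced(self):
        calls = _calls([99], [12])  # strong ratio and p, but max TPTM 99
        assert calls["m0"].verdict == "unchanged"

    def test_downregulation_called_with_negative_ratio(self):
        calls = _calls([400], [90])
        assert calls["m0"].verdict == "down"
        assert calls["m0"].log2_ratio < -1

    def test_doubling_depths_and_counts_preserves_verdicts(self):
        counts1 = pd.DataFrame({"control": [60, 400], "drought": [150, 90],
                                "cold": [60, 400], "salt": [60, 400]},
                               index=["a", "b"])
        counts2 = counts1 * 2
        d2 = {k: v * 2 for k, v in DEPTHS.items()}
        v1 = [c.verdict for c in call_stress_regulated(counts1, DEPTHS)]
        v2 = [c.verdict for c in call_stress_regulated(counts2, d2)]
        assert v1 == v2

    def test_optional_bh_correction_can_only_remove_calls(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(80, size=60)
        y = rng.poisson(80, size=60)
        y[:3] = x[:3] * 5 + 50
        counts = pd.DataFrame({"control": x, "drought": y, "cold": x,
                               "salt": x}, index=[f"m{i}" for i in range(60)])
        raw = {c.mirna for c in call_stress_regulated(counts, DEPTHS)
               if c.verdict != "unchanged"}
        cfg = PipelineConfig(de_fdr=True)
        adj = {c.mirna for c in call_stress_regulated(counts, DEPTHS, cfg)
               if c.verdict != "unchanged"}
        assert adj <= raw

    def test_stress_truth_recovered_on_synthetic_study(self, study,
                                                       study_result):
        # locus 0 was simulated 6x up in drought, locus 1 ~7x down in cold
        truth = study.truth
        by = {(c.mirna, c.stress): c for c in study_result.de_calls}
        name_of = {l.mature: l.name for l in study_result.loci}
        up = by.get((name_of[truth.loci[0].mature], "drought"))
        down = by.get((name_of[truth.loci[1].mature], "cold"))
        assert up is not None and up.verdict == "up"
        assert down is not None and down.verdict == "down"
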