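"""Effect-size derivation: genetic-model ORs, SMD, SE recovery, HWE."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from genemeta.effects import (
    EffectSize,
    GeneticModel,
    genotype_freqs_from_raf,
    hwe_test,
    or_from_counts,
    reconstruct_counts,
    se_from_ci,
    se_from_p,
    smd,
)


class TestHweReconstruction:
    @pytest.mark.parametrize(
        "f, expected",
        [
            (0.5, (0.25, 0.50, 0.25)),
            (0.0, (0.0, 0.0, 1.0)),
            (1.0, (1.0, 0.0, 0.0)),
            (0.971, (0.942841, 0.056318, 0.000841)),
        ],
    )
    def test_genotype_frequencies(self, f, expected):
        got = genotype_freqs_from_raf(f)
        assert got == pytest.approx(expected, abs=1e-12)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "f, n, expected",
        [(0.5, 100, (25, 50, 25)), (1.0, 50, (50, 0, 0)), (0.3, 1000, (90, 420, 490))],
    )
    def test_expected_counts(self, f, n, expected):
        assert reconstruct_counts(f, n) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("f", [-0.1, 1.5])
    def test_frequency_domain(self, f):
        with pytest.raises(ValueError):
            genotype_freqs_from_raf(f)

    @given(st.floats(0.01, 0.99), st.integers(10, 100000))
    def test_allele_counting_recovers_frequency(self, f, n):
        """Fractional expected counts invert exactly to f by allele counting."""
        c2, c1, c0 = reconstruct_counts(f, n)
        assert (2 * c2 + c1) / (2 * n) == pytest.approx(f, abs=1e-12)


class TestGeneticModelOr:
    def test_identical_groups_are_null(self):
        for model in GeneticModel:
            eff = or_from_counts((25, 50, 25), (25, 50, 25), model)
            assert eff.estimate == pytest.approx(0.0, abs=1e-12)

    def test_allele_model_cross_product(self):
        # case alleles 30 risk / 70 other; control 10 / 90 -> OR = 2700/700
        eff = or_from_counts((15, 0, 35), (5, 0, 45), GeneticModel.ALLELE)
        assert math.exp(eff.estimate) == pytest.approx(2700 / 700, rel=1e-12)

    def test_dominant_collapse(self):
        # carriers 90/10 in cases vs 70/30 in controls -> OR = 27/7
        eff = or_from_counts((70, 20, 10), (30, 40, 30), GeneticModel.DOMINANT)
        assert math.exp(eff.estimate) == pytest.approx(27 / 7, rel=1e-12)

    def test_recessive_collapse(self):
        eff = or_from_counts((40, 30, 30), (20, 40, 40), GeneticModel.RECESSIVE)
        assert math.exp(eff.estimate) == pytest.approx((40 * 80) / (60 * 20), rel=1e-12)

    def test_woolf_se(self):
        eff = or_from_counts((15, 0, 35), (5, 0, 45), GeneticModel.ALLELE)
        assert eff.se == pytest.approx(math.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), rel=1e-12)

    def test_zero_cell_continuity_correction(self):
        eff = or_from_counts((10, 0, 0), (0, 0, 10), GeneticModel.ALLELE)
        assert math.isfinite(eff.estimate)
        with pytest.raises(ZeroDivisionError):
            or_from_counts((10, 0, 0), (0, 0, 10), GeneticModel.ALLELE, correction=None)

    triples = st.tuples(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))

    @given(triples, triples)
    def test_allele_or_equals_2x2_cross_product(self, case, control):
        """Brute-force oracle: the allele model is the allele-count 2x2."""
        a, b = 2 * case[0] + case[1], 2 * case[2] + case[1]
        c, d = 2 * control[0] + control[1], 2 * control[2] + control[1]
        assume(min(a, b, c, d) > 0)
        eff = or_from_counts(case, control, GeneticModel.ALLELE, correction=None)
        assert math.exp(eff.estimate) == pytest.approx(a * d / (b * c), rel=1e-10)

    @given(triples, triples, st.sampled_from(list(GeneticModel)))
    def test_group_swap_inverts_or(self, case, control, model):
        assume(sum(case) > 0 and sum(control) > 0)
        try:
            fwd = or_from_counts(case, control, model)
            rev = or_from_counts(control, case, model)
        except ZeroDivisionError:
            assume(False)
        assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-10)


class TestSmd:
    def test_equal_means_give_zero(self):
        assert smd(10, 5.0, 1.2, 12, 5.0, 0.9).estimate == 0.0

    def test_cohen_hand_case(self):
        eff = smd(2, 1.0, 1.0, 2, 0.0, 1.0, flavor="cohen")
        assert eff.estimate == pytest.approx(1.0, rel=1e-12)
        assert eff.se == pytest.approx(math.sqrt(1.125), rel=1e-12)

    def test_hedges_small_sample_correction(self):
        eff = smd(2, 1.0, 1.0, 2, 0.0, 1.0, flavor="hedges")
        assert eff.estimate == pytest.approx(1.0 - 3.0 / 7.0, rel=1e-12)

    @given(
        st.integers(2, 200), st.floats(-3, 3), st.floats(0.1, 3),
        st.integers(2, 200), st.floats(-3, 3), st.floats(0.1, 3),
    )
    def test_hedges_never_exceeds_cohen(self, n1, m1, sd1, n0, m0, sd0):
        d = smd(n1, m1, sd1, n0, m0, sd0, "cohen").estimate
        g = smd(n1, m1, sd1, n0, m0, sd0, "hedges").estimate
        assert abs(g) <= abs(d) + 1e-15
        if d != 0:
            assert abs(g) < abs(d)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            smd(1, 1.0, 1.0, 5, 0.0, 1.0)


class TestSeRecovery:
    def test_unit_normal_interval(self):
        assert se_from_ci(-1.959963984540054, 1.959963984540054) == pytest.approx(1.0, rel=1e-9)

    def test_identity_scale_bounds(self):
        # published per-allele FG interval 0.070 (0.060, 0.079) mmol/l
        assert se_from_ci(0.060, 0.079) == pytest.approx(0.0190 / (2 * 1.959963984540054), rel=1e-6)

    def test_log_scale_bounds(self):
        # published OR interval 0.964 (0.947, 0.981)
        got = se_from_ci(0.947, 0.981, scale="log")
        assert got == pytest.approx((math.log(0.981) - math.log(0.947)) / (2 * 1.959963984540054), rel=1e-9)
        assert got == pytest.approx(0.00900, abs=5e-5)

    @pytest.mark.parametrize("estimate", [0.1, -0.1])
    def test_se_from_p_hand_value(self, estimate):
        assert se_from_p(estimate, 0.05) == pytest.approx(0.1 / 1.959963984540054, rel=1e-6)

    def test_se_p_round_trip(self):
        # published MAGIC slope 0.075 (SE 0.003) mmol/l per allele
        eff = EffectSize(0.075, 0.003)
        assert se_from_p(0.075, eff.p) == pytest.approx(0.003, rel=1e-9)

    @given(st.floats(-5, 5), st.floats(0.01, 2), st.floats(0.5, 0.999))
    def test_ci_construction_inverse(self, est, se, level):
        """se_from_ci inverts EffectSize.ci at the same level, both scales."""
        eff = EffectSize(est, se, "identity")
        lo, hi = eff.ci(level)
        assert se_from_ci(lo, hi, level) == pytest.approx(se, rel=1e-9)
        eff_log = EffectSize(est, se, "log")
        lo, hi = eff_log.ci(level)
        assert se_from_ci(lo, hi, level, scale="log") == pytest.approx(se, rel=1e-9)

    @pytest.mark.parametrize("bad", [(0.0, None), (1.0, None), (None, 0.0)])
    def test_domain_errors(self, bad):
        p, est = bad
        with pytest.raises(ValueError):
            se_from_p(0.1 if est is None else est, 0.5 if p is None else p)


class TestHwe:
    def test_exact_proportions(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.f_hat == 0.5

    def test_strong_departure(self):
        assert hwe_test((90, 20, 90)).chi2 == pytest.approx(128.0, rel=1e-12)

    def test_moderate_departure(self):
        res = hwe_test((30, 30, 40))
        assert res.f_hat == pytest.approx(0.45)
        # expected (20.25, 49.5, 30.25): 9.75^2/20.25 + 19.5^2/49.5 + 9.75^2/30.25
        assert res.chi2 == pytest.approx(15.5188246, rel=1e-6)
        assert not res.hwe_ok

    def test_monomorphic_flag(self):
        res = hwe_test((50, 0, 0))
        assert res.monomorphic and res.chi2 == 0.0 and res.p == 1.0

    @given(st.tuples(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)))
    def test_chi2_zero_iff_observed_equals_expected(self, counts):
        res = hwe_test(counts)
        expected = np.array(reconstruct_counts(res.f_hat, sum(counts)))
        if np.allclose(np.array(counts, dtype=float), expected, atol=1e-9):
            assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        else:
            assert res.chi2 > 0


class TestEffectSizeInvariants:
    @given(st.floats(-3, 3), st.floats(0.01, 2))
    def test_p_is_two_sided_normal_tail(self, est, se):
        from scipy import stats
        eff = EffectSize(est, se)
        assert eff.p == pytest.approx(2 * stats.norm.sf(abs(est / se)), rel=1e-12)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            EffectSize(0.1, 0.0)
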