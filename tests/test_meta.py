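"""Pooling: fixed-effect, DerSimonian-Laird, heterogeneity, subgroups, RAF."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genemeta.effects import EffectSize
from genemeta.io import load_fg_studies
from genemeta.meta import (
    MetaAnalysis,
    SubgroupSpec,
    dersimonian_laird,
    fixed_effect,
    heterogeneity,
    leave_one_out,
    pooled_raf,
    subgroup_meta,
)


def effs(ys, ses):
    return [EffectSize(y, s, label=str(i)) for i, (y, s) in enumerate(zip(ys, ses))]


class TestFixedEffect:
    def test_single_study_passthrough(self):
        r = fixed_effect([EffectSize(0.3, 0.1)])
        assert (r.estimate, r.se) == (0.3, 0.1)
        assert r.het is None

    def test_two_unit_se_studies(self):
        r = fixed_effect(effs([0.0, 2.0], [1.0, 1.0]))
        assert r.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.se == pytest.approx(1 / math.sqrt(2), rel=1e-12)

    def test_equal_weights_give_arithmetic_mean(self):
        y = [0.1, 0.5, -0.2, 0.3]
        r = fixed_effect(effs(y, [0.2] * 4))
        assert r.estimate == pytest.approx(np.mean(y), rel=1e-12)

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            fixed_effect([EffectSize(0.1, 0.1, "log"), EffectSize(0.1, 0.1, "identity")])


class TestDerSimonianLaird:
    def test_two_study_hand_case(self):
        r = dersimonian_laird(effs([0.0, 2.0], [1.0, 1.0]))
        assert r.Q == pytest.approx(2.0, abs=1e-12)
        assert r.tau2 == pytest.approx(1.0, abs=1e-12)
        assert r.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.se == pytest.approx(1.0, abs=1e-12)

    def test_truncation_at_zero_matches_fixed(self):
        r = dersimonian_laird(effs([0.0, 1.0, 2.0], [1.0] * 3))
        f = fixed_effect(effs([0.0, 1.0, 2.0], [1.0] * 3))
        assert r.Q == pytest.approx(2.0) and r.df == 2
        assert r.tau2 == 0.0
        assert r.estimate == pytest.approx(f.estimate, abs=1e-14)
        assert r.se == pytest.approx(f.se, abs=1e-14)

    def test_homogeneous_studies(self):
        r = dersimonian_laird(effs([0.4] * 4, [0.1, 0.2, 0.3, 0.4]))
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.tau2 == 0.0
        assert r.estimate == pytest.approx(0.4, rel=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            dersimonian_laird([EffectSize(0.1, 0.1)])

    def test_against_metafor(self, metafor_dataset):
        d = metafor_dataset
        r = MetaAnalysis(d["y"], d["se"]).fit(method="random")
        assert r.estimate == pytest.approx(d["dl_estimate"], abs=1e-9)
        assert r.se == pytest.approx(d["dl_se"], abs=1e-9)
        assert r.tau2 == pytest.approx(d["tau2"], abs=1e-9)
        assert r.Q == pytest.approx(d["Q"], abs=1e-9)
        assert r.i2 == pytest.approx(d["i2"], abs=1e-6)
        assert r.h2_classical == pytest.approx(d["h2_classical"], abs=1e-9)
        assert r.ci == pytest.approx(d["ci"], abs=1e-9)
        assert r.p == pytest.approx(d["p"], abs=1e-9)
        f = MetaAnalysis(d["y"], d["se"]).fit(method="fixed")
        assert f.estimate == pytest.approx(d["fe_estimate"], abs=1e-9)
        assert f.se == pytest.approx(d["fe_se"], abs=1e-9)

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)), min_size=2, max_size=12))
    def test_pooled_estimate_is_convex_combination(self, studies):
        y = [a for a, _ in studies]
        r = dersimonian_laird(effs(y, [b for _, b in studies]))
        assert min(y) - 1e-9 <= r.estimate <= max(y) + 1e-9
        assert np.all(r.weights > 0)
        assert np.sum(r.weights) == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance(self, metafor_dataset):
        d = metafor_dataset
        base = MetaAnalysis(d["y"], d["se"]).fit()
        for perm in itertools.islice(itertools.permutations(range(6)), 0, 24, 5):
            y = [d["y"][i] for i in perm]
            se = [d["se"][i] for i in perm]
            r = MetaAnalysis(y, se).fit()
            assert r.estimate == pytest.approx(base.estimate, abs=1e-12)
            assert r.tau2 == pytest.approx(base.tau2, abs=1e-12)

    def test_tau2_recovery_on_gaussian_draws(self, rng):
        """DL moment estimator is nearly unbiased at high tau/se ratios."""
        tau, se, k = 0.05, 0.005, 15
        est = [
            MetaAnalysis(0.07 + rng.normal(0, math.hypot(tau, se), k), [se] * k).fit().tau2
            for _ in range(400)
        ]
        assert np.mean(est) == pytest.approx(tau**2, rel=0.25)

    def test_ci_coverage_on_gaussian_draws(self, rng):
        tau, se, k, mu = 0.05, 0.005, 15, 0.07
        hits = 0
        reps = 300
        for _ in range(reps):
            lo, hi = MetaAnalysis(mu + rng.normal(0, math.hypot(tau, se), k), [se] * k).fit().ci
            hits += lo <= mu <= hi
        assert 92 <= 100 * hits / reps <= 98


class TestHeterogeneity:
    def test_fifty_percent_point(self):
        h = heterogeneity(2.0, 1)
        assert h.i2 == pytest.approx(50.0)
        assert h.h2_classical == pytest.approx(2.0)
        assert h.h2 == pytest.approx(1.0)

    @pytest.mark.parametrize("q, df", [(0.5, 1), (3.0, 5), (9.0, 9)])
    def test_truncation_below_df(self, q, df):
        h = heterogeneity(q, df)
        assert h.i2 == 0.0 and h.h2 == 0.0

    def test_test_based_interval_hand_case(self):
        h = heterogeneity(20.0, 9)
        assert h.i2 == pytest.approx(55.0, abs=1e-9)
        se_lnh = 0.5 * (math.log(20) - math.log(9)) / (math.sqrt(40) - math.sqrt(17))
        assert se_lnh == pytest.approx(0.18135, abs=1e-4)
        lnh = 0.5 * math.log(20 / 9)
        z = 1.959963984540054
        lo_h, hi_h = math.exp(lnh - z * se_lnh), math.exp(lnh + z * se_lnh)
        assert h.i2_ci[0] == pytest.approx(100 * (lo_h**2 - 1) / lo_h**2, abs=1e-6)
        assert h.i2_ci[1] == pytest.approx(100 * (hi_h**2 - 1) / hi_h**2, abs=1e-6)

    def test_small_q_interval_matches_published_shape(self):
        # three homogeneous studies: I2 = 0 with upper bound ~90%
        h = heterogeneity(0.5, 2)
        assert h.i2 == 0.0
        assert h.i2_ci[0] == 0.0
        assert h.i2_ci[1] == pytest.approx(89.6, abs=0.5)

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity(1.0, 0)


class TestLeaveOneOut:
    def test_identical_studies_reproduce_parent(self):
        e = effs([0.5] * 3, [0.1] * 3)
        parent = dersimonian_laird(e)
        for r in leave_one_out(e):
            assert r.estimate == pytest.approx(parent.estimate, abs=1e-12)

    def test_reduces_to_two_study_hand_case(self):
        e = effs([0.0, 1.0, 2.0], [1.0] * 3)
        fits = leave_one_out(e)
        middle_out = fits[1]
        assert middle_out.estimate == pytest.approx(1.0, abs=1e-12)
        assert middle_out.tau2 == pytest.approx(1.0, abs=1e-12)

    def test_output_length_and_minimum_k(self):
        e = effs([0.1, 0.2, 0.3, 0.4], [0.1] * 4)
        assert len(leave_one_out(e)) == 4
        with pytest.raises(ValueError):
            leave_one_out(e[:2])


class TestSubgroups:
    def test_fixture_membership_counts(self):
        table = load_fg_studies().for_snp("rs560887")
        out = {s.level: s for s in subgroup_meta(table, SubgroupSpec("ethnicity"))}
        assert out["overall"].k == 32
        assert out["Caucasian"].k == 23
        assert out["Asian"].k == 5
        assert out["African-American"].k == 3
        assert out["mixed"].k == 1

    def test_level_totals_conserve_overall(self):
        table = load_fg_studies().for_snp("rs560887")
        subs = subgroup_meta(table, SubgroupSpec("ethnicity"))
        overall = next(s for s in subs if s.level == "overall")
        assert overall.n_total == 184524
        assert sum(s.n_total for s in subs if s.level != "overall") == overall.n_total

    def test_characteristics_only_records_yield_no_pool(self):
        table = load_fg_studies().for_snp("rs560887")
        overall = next(s for s in subgroup_meta(table) if s.level == "overall")
        assert overall.result is None and overall.k_used == 0
        assert len(overall.excluded) == 32

    def test_single_level_equals_overall(self, tmp_path):
        from genemeta.io import QuantStudy, SnpRaf, StudyTable
        recs = [
            QuantStudy(f"s{i}", "Asian", (SnpRaf("rs1", "G", 0.7),), 1000,
                       beta=0.05 + 0.01 * i, beta_se=0.01)
            for i in range(4)
        ]
        table = StudyTable(recs, outcome="FG", snp_id="rs1")
        out = {s.level: s for s in subgroup_meta(table)}
        assert out["Asian"].result.estimate == pytest.approx(out["overall"].result.estimate)


class TestPooledRaf:
    def test_identical_frequencies_invariant(self):
        for method in ("mean", "inverse_variance"):
            assert pooled_raf([(0.5, 10), (0.5, 1000)], method) == pytest.approx(0.5)

    def test_asian_mean_frequency(self):
        f = pooled_raf([(0.971, 1), (0.907, 1), (0.82, 1), (0.84, 1)], method="mean")
        assert f == pytest.approx(0.8845, abs=1e-12)

    def test_inverse_variance_weighting(self):
        # w = 2n/(f(1-f)): the larger, less variable study dominates
        f = pooled_raf([(0.9, 10000), (0.5, 100)], method="inverse_variance")
        assert 0.87 < f < 0.9

    def test_monomorphic_excluded(self):
        f = pooled_raf([(1.0, 100), (0.5, 100)], method="inverse_variance")
        assert f == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_raf([])
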