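"""Endotype discovery simulator: effect-matrix structure, competing-cause
cohort generation (exponential-tilting oracle), nested case-control sampling,
score-test calibration, BH against a brute-force oracle, and the strategy
comparison engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from prevsim import endotype as et
from prevsim.errors import ConfigurationError, PrevsimError


class TestEffectMatrix:
    @pytest.mark.parametrize("m,nulls", [(50, 35), (200, 185), (15, 0)])
    def test_null_factor_count(self, m, nulls):
        em = et.build_effect_matrix(m)
        assert len(em.null_factors) == nulls
        assert (em.beta[em.null_factors] == 0).all()

    def test_structure(self):
        em = et.build_effect_matrix(50)
        b = math.log(2)
        # specific factors: exactly one nonzero column; shared: three
        for j in range(9):
            assert (em.beta[j] != 0).sum() == 1
            assert em.beta[j].max() == pytest.approx(b)
        for j in range(9, 15):
            assert np.allclose(em.beta[j], b)
        assert em.labels[0] == "specific-e1"
        assert em.labels[9] == "shared"
        assert em.labels[-1] == "null"

    def test_too_small_m(self):
        with pytest.raises(ValueError):
            et.build_effect_matrix(14)


class TestCohort:
    def test_rate_calibration_hits_target(self):
        em = et.build_effect_matrix(20)
        rate = et.calibrate_cohort_rate(em, target_cases=200, n_cohort=20_000)
        counts = [
            et.simulate_cohort(
                et.CohortSpec(20_000, rate), em, seed=s).n_cases
            for s in range(8)
        ]
        # Poisson-ish spread around 200
        assert abs(np.mean(counts) - 200) < 3 * math.sqrt(200 / 8) + 10

    def test_equal_endotype_shares_under_null_effects(self):
        em = et.EffectMatrix(m=15, beta=np.zeros((15, 3)), labels=("null",) * 15)
        cohort = et.simulate_cohort(et.CohortSpec(100_000, 1.0e-3), em, seed=1)
        cases = cohort.outcome[cohort.outcome > 0]
        shares = np.bincount(cases, minlength=4)[1:] / len(cases)
        se = math.sqrt((1 / 3) * (2 / 3) / len(cases))
        assert np.all(np.abs(shares - 1 / 3) < 3 * se)

    def test_mutually_exclusive_labels(self):
        em = et.build_effect_matrix(20)
        cohort = et.simulate_cohort(et.CohortSpec(30_000, 2e-4), em, seed=2)
        assert set(np.unique(cohort.outcome)).issubset({0, 1, 2, 3})

    def test_exponential_tilting_of_case_factors(self):
        """Rare disease: an endotype-specific factor among that endotype's
        cases is N(beta, 1)-distributed (tilt phi(x)e^{beta x} ~ phi(x-beta))."""
        em = et.build_effect_matrix(20)
        rate = et.calibrate_cohort_rate(em, target_cases=1000, n_cohort=200_000)
        cohort = et.simulate_cohort(et.CohortSpec(200_000, rate), em, seed=3)
        b = math.log(2)
        # average the 9 specific (factor, own-endotype) pairs for precision
        devs, ctrl_means = [], []
        for e in range(3):
            cases = cohort.outcome == e + 1
            for j in range(3 * e, 3 * e + 3):
                devs.append(cohort.factors[cases, j].mean() - b)
        controls = cohort.outcome == 0
        assert abs(np.mean(devs)) < 0.03
        assert abs(cohort.factors[controls, :15].mean()) < 0.01

    def test_saturated_incidence_rejected(self):
        em = et.build_effect_matrix(15)
        with pytest.raises(ConfigurationError):
            et.simulate_cohort(et.CohortSpec(500, 50.0), em, seed=4)


class TestCaseControl:
    def test_two_to_one_ratio_and_disjointness(self):
        em = et.build_effect_matrix(20)
        rate = et.calibrate_cohort_rate(em, 200, 20_000)
        cohort = et.simulate_cohort(et.CohortSpec(20_000, rate), em, seed=5)
        sample = et.sample_case_control(cohort, ratio=2, seed=6)
        n_cases = (sample.outcome > 0).sum()
        assert (sample.outcome == 0).sum() == 2 * n_cases
        assert n_cases == cohort.n_cases

    def test_no_cases_flagged_empty(self):
        cohort = et.Cohort(factors=np.zeros((10, 15)), outcome=np.zeros(10, int))
        assert et.sample_case_control(cohort, seed=0).empty

    def test_insufficient_controls_raises(self):
        cohort = et.Cohort(factors=np.zeros((10, 15)),
                           outcome=np.array([1] * 8 + [0] * 2))
        with pytest.raises(PrevsimError):
            et.sample_case_control(cohort, ratio=2, seed=0)

    def test_sampled_control_factor_means_near_zero(self):
        em = et.build_effect_matrix(30)
        rate = et.calibrate_cohort_rate(em, 300, 30_000)
        cohort = et.simulate_cohort(et.CohortSpec(30_000, rate), em, seed=7)
        sample = et.sample_case_control(cohort, seed=8)
        ctrl = sample.factors[sample.outcome == 0]
        se = 1 / math.sqrt(len(ctrl))
        assert np.abs(ctrl.mean(axis=0)).max() < 4 * se

    def test_control_columns_uncorrelated(self):
        em = et.build_effect_matrix(25)
        rate = et.calibrate_cohort_rate(em, 400, 20_000)
        cohort = et.simulate_cohort(et.CohortSpec(20_000, rate), em, seed=9)
        sample = et.sample_case_control(cohort, seed=10)
        ctrl = sample.factors[sample.outcome == 0]
        r = np.corrcoef(ctrl.T)
        np.fill_diagonal(r, 0.0)
        assert np.abs(r).max() < 4 / math.sqrt(len(ctrl))


class TestAssociationTests:
    def _sample(self, m=50, cases=200, seed=11):
        em = et.build_effect_matrix(m)
        rate = et.calibrate_cohort_rate(em, cases, 20_000)
        cohort = et.simulate_cohort(et.CohortSpec(20_000, rate), em, seed=seed)
        return et.sample_case_control(cohort, seed=seed + 1), em

    @pytest.mark.parametrize("strategy,o", [
        ("composite_only", 1), ("two_endotypes", 2), ("four_outcomes", 4)])
    def test_matrix_shape(self, strategy, o):
        sample, _ = self._sample()
        assert et.test_associations(sample, strategy).shape == (o, 50)

    def test_null_pvalues_uniform(self):
        # factors independent of outcome: p-values ~ U(0,1) across nulls
        em = et.EffectMatrix(m=2000, beta=np.zeros((2000, 3)),
                             labels=("null",) * 2000)
        sample = et.simulate_case_control_retrospective(em, 150, seed=12)
        p = et.test_associations(sample, "composite_only").ravel()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_cross_endotype_factor_is_null(self):
        # an e1-specific factor tested on outcome e2 rejects at ~alpha
        rejected, total = 0, 0
        rng = np.random.default_rng(13)
        em = et.build_effect_matrix(20)
        for _ in range(300):
            sample = et.simulate_case_control_retrospective(em, 150, seed=rng)
            p = et.test_associations(sample, "two_endotypes")
            rejected += (p[1, 0:3] < 0.05).sum()  # e1-specific factors on e2
            total += 3
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(rejected / total - 0.05) < 4 * se

    def test_strongly_associated_factor_detected(self):
        sample, _ = self._sample(cases=200)
        p = et.test_associations(sample, "composite_only")
        assert (p[0, 9:15] < 1e-4).all()  # shared factors, big shift


class TestBH:
    def test_hand_executed_step_up(self):
        p = np.array([[0.001, 0.01, 0.02, 0.04, 0.05]])
        assert et.bh_select(p, q=0.05).all()

    def test_all_ones_rejects_nothing(self):
        assert not et.bh_select(np.ones((2, 6)), q=0.05).any()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_exhaustive_cutoff_search(self, pvals):
        p = np.array(pvals)
        mine = et.bh_select(p.reshape(1, -1), q=0.05).ravel()
        # oracle: largest k with p_(k) <= k q / m, reject all p <= that cutoff
        m = len(p)
        srt = np.sort(p)
        ks = [k for k in range(1, m + 1) if srt[k - 1] <= 0.05 * k / m]
        expected = (p <= srt[max(ks) - 1]) if ks else np.zeros(m, bool)
        assert (mine == expected).all()

    def test_nan_entries_excluded(self):
        p = np.array([[0.001, np.nan, 0.5]])
        rej = et.bh_select(p, q=0.05)
        assert rej[0, 0] and not rej[0, 1] and not rej[0, 2]

    def test_all_null_fdr_controlled(self):
        em = et.EffectMatrix(m=100, beta=np.zeros((100, 3)), labels=("null",) * 100)
        rng = np.random.default_rng(14)
        fdrs = []
        for _ in range(400):
            sample = et.simulate_case_control_retrospective(em, 100, seed=rng)
            p = et.test_associations(sample, "composite_only")
            rej = et.bh_select(p, q=0.05)
            fdrs.append(1.0 if rej.any() else 0.0)
        # with all nulls, FDR = P(any rejection) and must be <= q
        assert np.mean(fdrs) <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / 400)


class TestDiscovery:
    def test_empty_rejections(self):
        em = et.build_effect_matrix(50)
        res = et.evaluate_discovery(np.zeros((1, 50), bool), em, "composite_only")
        assert res.true_positives == 0 and res.false_positives == 0
        assert res.realized_fdr == 0.0 and not res.detected_ge5

    def test_saturated_rejections(self):
        em = et.build_effect_matrix(50)
        res = et.evaluate_discovery(np.ones((4, 50), bool), em, "four_outcomes")
        assert res.true_positives == 15
        assert res.false_positives == 35
        assert res.detected_ge5

    def test_factor_counted_once_across_outcomes(self):
        em = et.build_effect_matrix(20)
        rej = np.zeros((4, 20), bool)
        rej[:, 9] = True  # one shared factor rejected on all four outcomes
        res = et.evaluate_discovery(rej, em, "four_outcomes")
        assert res.true_positives == 1


class TestStrategyComparison:
    def test_single_replicate_reproducible(self):
        kw = dict(case_counts=[100], m_values=[30], strategies=("composite_only",),
                  replicates=1, seed=77)
        a = et.run_strategy_comparison(**kw)
        b = et.run_strategy_comparison(**kw)
        assert a.equals(b)

    def test_composite_beats_two_endotypes(self):
        # analysing two of three endotypes loses power vs the composite alone
        tab = et.run_strategy_comparison(
            [75], [50], ("composite_only", "two_endotypes"),
            replicates=150, seed=15)
        comp = tab[tab.strategy == "composite_only"].iloc[0]
        two = tab[tab.strategy == "two_endotypes"].iloc[0]
        assert comp.power_ge5 >= two.power_ge5 - 2 * (comp.mc_se + two.mc_se)

    def test_power_monotone_in_case_count(self):
        tab = et.run_strategy_comparison(
            [50, 150], [50], ("composite_only",), replicates=150, seed=16)
        lo, hi = tab.power_ge5.iloc[0], tab.power_ge5.iloc[1]
        assert hi >= lo - 2 * tab.mc_se.max()

    def test_retrospective_matches_cohort_path(self):
        kw = dict(case_counts=[120], m_values=[50], strategies=("four_outcomes",),
                  replicates=120, q=0.05)
        coh = et.run_strategy_comparison(seed=17, method="cohort", **kw)
        retro = et.run_strategy_comparison(seed=18, method="retrospective", **kw)
        tol = 2 * (coh.mc_se.iloc[0] + retro.mc_se.iloc[0]) + 0.02
        assert abs(coh.power_ge5.iloc[0] - retro.power_ge5.iloc[0]) < tol
        assert abs(coh.mean_tp.iloc[0] - retro.mean_tp.iloc[0]) < 1.0
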