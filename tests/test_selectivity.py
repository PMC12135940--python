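import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from whisksel.core import AnalysisWindows
from whisksel.rates import ConditionRateSample
from whisksel.selectivity import (DPRIME_CAP, BiasSeries, UnitClass,
                                  behavioral_dprime, bias_from_baseline,
                                  classify_preference, classify_responsive,
                                  classify_touch_effect, filter_disengaged_cr,
                                  group_by_baseline_rate,
                                  population_preference_stats, stimulus_bias)

from conftest import make_trial


def samples(mus, variances, n=10):
    return [ConditionRateSample(m, v, n) for m, v in zip(mus, variances)]


class TestStimulusBias:
    def test_direct_formula_value(self):
        # (10 - 6) / sqrt((4 + 4) / 2) = 2
        out = stimulus_bias(samples([10.0], [4.0]), samples([6.0], [4.0]))
        assert out.dprime[0] == pytest.approx(2.0, abs=1e-12)

    def test_identical_zero_and_antisymmetry(self):
        a = samples([3.0, 5.0], [1.0, 2.0])
        b = samples([2.0, 7.0], [2.0, 1.0])
        assert not stimulus_bias(a, a).dprime.any()
        assert np.allclose(stimulus_bias(a, b).dprime,
                           -stimulus_bias(b, a).dprime, atol=1e-15)

    def test_degenerate_variance_rules(self):
        equal = stimulus_bias(samples([2.0], [0.0]), samples([2.0], [0.0]))
        assert equal.dprime[0] == 0.0 and not equal.degenerate_bins[0]
        diff = stimulus_bias(samples([3.0], [0.0]), samples([2.0], [0.0]))
        assert diff.dprime[0] == DPRIME_CAP and diff.degenerate_bins[0]

    def test_too_few_trials_errors(self):
        with pytest.raises(ValueError, match="condition B"):
            stimulus_bias(samples([1.0], [1.0]),
                          [ConditionRateSample(1.0, 1.0, 1)])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_independent_formula(self, seed):
        """Random moment pairs agree with a separate evaluation of
        (mu_A - mu_B) / sqrt((var_A + var_B) / 2) to 1e-12."""
        rng = np.random.default_rng(seed)
        mu_a, mu_b = rng.normal(0, 10, 5), rng.normal(0, 10, 5)
        va, vb = rng.uniform(0.1, 9, 5), rng.uniform(0.1, 9, 5)
        out = stimulus_bias(samples(mu_a, va), samples(mu_b, vb)).dprime
        expected = (mu_a - mu_b) / np.sqrt((va + vb) / 2.0)
        assert np.allclose(out, expected, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6), scale=st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, scale):
        """Common positive rescaling of both conditions' rates leaves d' fixed."""
        rng = np.random.default_rng(seed)
        mu_a, mu_b = rng.normal(5, 2, 3), rng.normal(5, 2, 3)
        va, vb = rng.uniform(0.5, 4, 3), rng.uniform(0.5, 4, 3)
        base = stimulus_bias(samples(mu_a, va), samples(mu_b, vb)).dprime
        scaled = stimulus_bias(samples(mu_a * scale, va * scale ** 2),
                               samples(mu_b * scale, vb * scale ** 2)).dprime
        assert np.allclose(base, scaled, rtol=1e-9)


class TestBiasFromBaseline:
    def test_condition_equal_baseline_is_zero(self):
        base = ConditionRateSample(4.0, 2.0, 20)
        out = bias_from_baseline(samples([4.0, 4.0], [2.0, 2.0], 20), base)
        assert np.allclose(out.dprime, 0.0)

    def test_suppressed_condition_negative(self):
        base = ConditionRateSample(10.0, 4.0, 20)
        out = bias_from_baseline(samples([2.0, 5.0], [4.0, 4.0], 20), base)
        assert (out.dprime < 0).all()

    def test_reduces_to_stimulus_bias(self):
        base = ConditionRateSample(3.0, 1.5, 12)
        cond = samples([1.0, 6.0], [0.5, 2.0], 12)
        direct = bias_from_baseline(cond, base).dprime
        via = stimulus_bias(cond, [base, base]).dprime
        assert np.array_equal(direct, via)


class TestClassifyResponsive:
    def test_identical_groups_not_responsive(self):
        g = np.ones(10)
        assert classify_responsive(g, g, g) is False

    def test_strong_response_detected(self):
        """3x baseline evoked rate, 30 trials/group: detected in > 99%."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            base = rng.poisson(3.0, 30).astype(float)
            stim = rng.poisson(9.0, 30).astype(float)
            other = rng.poisson(3.0, 30).astype(float)
            hits += classify_responsive(base, stim, other)
        assert hits / n_sim > 0.99

    def test_null_type_i_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        n_sim = 1000
        hits = sum(
            classify_responsive(rng.normal(5, 1, 20), rng.normal(5, 1, 20),
                                rng.normal(5, 1, 20))
            for _ in range(n_sim)
        )
        # Tukey corrects over 3 contrasts but only 2 are counted: rate <= alpha
        assert 0.01 < hits / n_sim < 0.07

    def test_too_few_trials_errors(self):
        with pytest.raises(ValueError, match=">= 5"):
            classify_responsive(np.ones(3), np.ones(5), np.ones(5))


class TestClassifyPreference:
    def _series(self, values):
        centers = np.arange(0.005, 0.3, 0.01)
        s = BiasSeries("u", centers, np.asarray(values, float))
        s.window_means["response"] = float(np.mean(values))
        return s

    def test_all_positive(self):
        assert classify_preference(self._series(np.ones(30))) == "positive"

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.4, 1.0, 30)
        flipped = classify_preference(self._series(-vals))
        direct = classify_preference(self._series(vals))
        assert {direct, flipped} == {"positive", "negative"}

    def test_exact_tie_is_none(self):
        assert classify_preference(self._series(np.zeros(30))) == "none"


class TestClassifyTouchEffect:
    def test_identical_windows_neither(self):
        g = np.ones(10)
        assert classify_touch_effect(g, g) == "neither"

    def test_suppression_power(self):
        """50% suppression of a 10 sp/s baseline, 40 trials: > 95% detected."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            base = rng.poisson(10.0 * 1.5, 40) / 1.5
            resp = rng.poisson(5.0 * 0.3, 40) / 0.3
            hits += classify_touch_effect(resp, base) == "suppressed"
        assert hits / n_sim > 0.95

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(2)
        n_sim = 2000
        fp = sum(
            classify_touch_effect(rng.normal(5, 1, 20), rng.normal(5, 1, 20))
            != "neither"
            for _ in range(n_sim)
        )
        assert 0.03 < fp / n_sim < 0.07


def _seq(pattern):
    """Build a trial list from a compact outcome pattern like 'H,M,M,CR'."""
    out = []
    for i, tok in enumerate(pattern.split(",")):
        stim, outcome = {"H": ("positive", "Hit"), "M": ("positive", "Miss"),
                         "CR": ("negative", "CR"), "FA": ("negative", "FA")}[tok]
        out.append(make_trial(i, stim, outcome, first_touch=2.0 + 6.0 * i))
    return out


class TestDisengagementFilter:
    def test_no_miss_runs_identity(self):
        trials = _seq("H,CR,H,CR,FA")
        assert filter_disengaged_cr(trials) == trials

    def test_five_miss_run_removes_crs(self):
        trials = _seq("H,M,M,M,M,M,CR,CR,H")
        kept = filter_disengaged_cr(trials)
        assert [t.outcome for t in kept] == ["H" and "Hit", "Miss"] + ["Miss"] * 4 + ["Hit"]
        assert all(t.outcome != "CR" for t in kept)

    def test_four_miss_run_keeps_cr(self):
        trials = _seq("H,M,M,CR,M,M,H")
        kept = filter_disengaged_cr(trials)
        assert sum(t.outcome == "CR" for t in kept) == 1

    def test_cr_inside_run_counts_as_member_not_miss(self):
        # CRs interleave but only 4 Misses: nothing removed
        trials = _seq("M,CR,M,CR,M,CR,M,H")
        kept = filter_disengaged_cr(trials)
        assert sum(t.outcome == "CR" for t in kept) == 3
        # fifth Miss tips the same structure into removal
        trials5 = _seq("M,CR,M,CR,M,CR,M,M,H")
        kept5 = filter_disengaged_cr(trials5)
        assert sum(t.outcome == "CR" for t in kept5) == 0

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_never_removes_licked_trials_or_reorders(self, seed):
        rng = np.random.default_rng(seed)
        toks = rng.choice(["H", "M", "CR", "FA"], size=30)
        trials = _seq(",".join(toks))
        kept = filter_disengaged_cr(trials)
        ids = [t.trial_id for t in kept]
        assert ids == sorted(ids)
        licked = {t.trial_id for t in trials if t.outcome in ("Hit", "FA")}
        assert licked <= set(ids)


class TestPopulationPreference:
    @staticmethod
    def _classes(n_pos, n_neg, mice=("a", "b")):
        out = []
        for i in range(n_pos + n_neg):
            pref = "positive" if i < n_pos else "negative"
            out.append(UnitClass(unit_id=str(i), responsive=True, preference=pref,
                                 mouse_id=mice[i % len(mice)]))
        return out

    def test_even_split(self):
        stats = population_preference_stats(self._classes(200, 200))
        assert stats.fraction_positive == 0.5
        assert stats.gof_p > 0.9

    def test_single_mouse_flagged(self):
        stats = population_preference_stats(self._classes(8, 2, mice=("a",)))
        assert stats.single_mouse and stats.homogeneity_p is None

    def test_chi_squared_matches_closed_form(self):
        stats = population_preference_stats(self._classes(30, 10, mice=("a",)),
                                            by_mouse=False)
        # chi2 = sum (O - E)^2 / E with E = 20
        assert stats.gof_chi2 == pytest.approx((100 / 20) * 2)
        assert stats.gof_p == pytest.approx(sstats.chi2.sf(10.0, 1))


class TestBaselineGroups:
    def _cls(self, rate):
        return UnitClass(unit_id=str(rate), responsive=True,
                         preference="positive", baseline_rate=rate)

    def test_boundary_joins_ge_group(self):
        groups = group_by_baseline_rate([self._cls(4.0)], edges=(4.0,))
        assert len(groups[0]) == 1 and not groups[1]

    def test_all_below_edges(self):
        groups = group_by_baseline_rate([self._cls(0.5), self._cls(2.0)],
                                        edges=(100.0,))
        assert not groups[0] and len(groups[1]) == 2

    def test_standard_bfr_partition(self):
        rates = [0.5, 1.0, 3.0, 5.0, 9.9, 10.0, 40.0]
        groups = group_by_baseline_rate([self._cls(r) for r in rates])
        sizes = [len(g) for g in groups]
        assert sizes == [2, 2, 2, 1]  # >=10, [5,10), [1,5), <1

    def test_edges_must_decrease(self):
        with pytest.raises(ValueError):
            group_by_baseline_rate([], edges=(1.0, 5.0))


class TestBehavioralDprime:
    def test_equal_rates_zero(self):
        assert behavioral_dprime(0.4, 0.4) == 0.0

    def test_standard_quantile_value(self):
        assert behavioral_dprime(0.9, 0.1) == pytest.approx(2.563, abs=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            behavioral_dprime(1.2, 0.1)

    @settings(max_examples=30, deadline=None)
    @given(h1=st.floats(0.05, 0.9), h2=st.floats(0.05, 0.9),
           fa=st.floats(0.05, 0.95))
    def test_monotone_in_hit_rate(self, h1, h2, fa):
        lo, hi = sorted([h1, h2])
        assert behavioral_dprime(hi, fa) >= behavioral_dprime(lo, fa)
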