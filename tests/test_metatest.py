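"""SGoF/SGoF+ metatest: exceedance counting, gamma0 selection, critical
values and the excess-of-significants rejection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sgofplus import (
    PValueSet,
    empirical_exceedance,
    gof_critical_value,
    ks_one_sided_critical,
    select_gamma0,
    sgof,
    sgof_plus,
)

pvalue_lists = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=200
)


class TestPValueSet:
    def test_validates_range(self):
        with pytest.raises(ValueError):
            PValueSet(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            PValueSet(np.array([-0.1]))
        with pytest.raises(ValueError):
            PValueSet(np.array([]))

    def test_preserves_input_order_and_does_not_mutate(self):
        raw = np.array([0.9, 0.1, 0.5])
        ps = PValueSet(raw)
        _ = ps.sorted()
        assert list(ps.values) == [0.9, 0.1, 0.5]
        assert list(raw) == [0.9, 0.1, 0.5]


class TestEmpiricalExceedance:
    @pytest.mark.parametrize(
        "p, gamma, expected",
        [
            ([0.01, 0.03, 0.2, 0.7], 0.05, 0.5),
            ([0.3, 0.9, 0.2], 1.0, 1.0),
            ([0.5, 0.6], 0.0, 0.0),
        ],
    )
    def test_direct_counts(self, p, gamma, expected):
        assert empirical_exceedance(p, gamma) == expected

    def test_closed_convention_counts_equal_values(self):
        assert empirical_exceedance([0.05, 0.05, 0.8, 0.9], 0.05) == 0.5

    @given(pvalue_lists)
    @settings(deadline=None, max_examples=50)
    def test_step_function_bounds(self, p):
        arr = np.asarray(p)
        assert empirical_exceedance(p, 1.0) == 1.0
        below = np.nextafter(arr.min(), -1)
        if below >= 0.0:
            assert empirical_exceedance(p, below) == 0.0
        assert empirical_exceedance(p, float(arr.max())) == 1.0


class TestSelectGamma0:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.9, 0.95], 0.02),  # diffs 0.24, 0.48, -0.15, 0.05
            ([0.2, 0.4, 0.6, 0.8], 0.8),  # diffs 0.05, 0.10, 0.15, 0.20
            ([0.5], 0.5),
        ],
    )
    def test_enumerated_examples(self, p, expected):
        assert select_gamma0(p) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        """argmax of K_gamma - gamma over distinct observed p-values."""
        for _ in range(300):
            S = int(rng.integers(1, 60))
            p = np.round(rng.random(S), 3)  # rounding forces ties
            p = np.clip(p, 1e-4, 1 - 1e-4)
            cands = np.unique(p)
            diffs = [(np.mean(p <= g) - g) for g in cands]
            expected = cands[int(np.argmax(diffs))]
            assert select_gamma0(p) == pytest.approx(expected)

    def test_all_degenerate_pvalues_rejected(self):
        with pytest.raises(ValueError):
            select_gamma0([0.0, 1.0, 1.0])


class TestKsCritical:
    def test_asymptotic_and_exact_agree_at_moderate_s(self):
        exact = ks_one_sided_critical(0.05, 100)
        asym = np.sqrt(np.log(1 / 0.05) / 200)
        assert asym == pytest.approx(0.1224, abs=1e-4)
        assert exact == pytest.approx(asym, abs=0.005)
        # exact path really is the one-sided KS quantile
        assert exact == pytest.approx(stats.ksone.ppf(0.95, 100))

    def test_smaller_alpha_larger_critical(self):
        assert ks_one_sided_critical(0.01, 100) > ks_one_sided_critical(0.05, 100)

    def test_vanishes_with_family_size(self):
        assert ks_one_sided_critical(0.05, 10**8) < 1e-3

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            ks_one_sided_critical(0.0, 10)
        with pytest.raises(ValueError):
            ks_one_sided_critical(1.0, 10)


class TestGofCriticalValue:
    @pytest.mark.parametrize(
        "S, gamma0, expected",
        [(10, 0.5, 8), (100, 0.001, 1)],
    )
    def test_binomial_percentile_examples(self, S, gamma0, expected):
        assert gof_critical_value(S, gamma0, 0.05, mode="binomial") == expected

    def test_alpha_to_zero_approaches_s(self):
        assert gof_critical_value(20, 0.3, 1e-12, mode="binomial") == 20

    def test_matches_exhaustive_cdf_enumeration(self):
        """Smallest k with P(Bin(S, g) <= k) >= 1 - alpha, by direct scan."""
        for S in (1, 7, 23, 118, 200):
            for g in np.linspace(0.01, 0.99, 9):
                cdf = np.cumsum(stats.binom.pmf(np.arange(S + 1), S, g))
                expected = int(np.argmax(cdf >= 0.95 - 1e-12))
                assert gof_critical_value(S, g, 0.05, mode="binomial") == expected

    def test_conservative_rule_is_percentile_plus_one(self):
        for S, g in ((10, 0.5), (100, 0.05), (37, 0.2)):
            b = gof_critical_value(S, g, 0.05, mode="binomial")
            bc = gof_critical_value(S, g, 0.05, mode="binomial", conservative=True)
            assert stats.binom.sf(bc - 1, S, g) <= 0.05
            assert bc >= b

    def test_chi2_mode_close_to_binomial_at_moderate_counts(self):
        b_bin = gof_critical_value(1000, 0.05, 0.05, mode="binomial")
        b_chi = gof_critical_value(1000, 0.05, 0.05, mode="chi2")
        assert abs(b_bin - b_chi) <= 1


class TestSgof:
    def test_no_excess_no_discoveries(self):
        r = sgof(np.full(100, 0.5), alpha=0.05, gamma=0.05)
        assert r.n_discoveries == 0
        assert r.rejected_indices.size == 0

    def test_spike_family_excess(self):
        """50 p-values at 0.001 and 50 at 0.9: b_0.05(Bin(100, 0.05)) = 9 so
        the excess is 50 - 9 + 1 = 42 discoveries."""
        p = np.r_[np.full(50, 0.001), np.full(50, 0.9)]
        r = sgof(p, alpha=0.05, gamma=0.05, gof="binomial")
        assert r.critical_value == 9
        assert r.n_discoveries == 42
        assert set(r.rejected_indices) <= set(range(50))

    def test_observed_equals_expected_cannot_reject(self):
        r = sgof(np.full(10, 0.5), alpha=0.05, gamma=0.5, gof="binomial")
        assert r.n_discoveries == 0


class TestSgofPlus:
    def test_spike_family_step_by_step(self):
        """gamma0 = 0.001, KS distance 0.499 over the critical value,
        b = 1, N = min(50 - 1 + 1, 50) = 50."""
        p = np.r_[np.full(50, 0.001), np.full(50, 0.9)]
        r = sgof_plus(p, alpha=0.05, gof="binomial")
        assert r.gamma0 == pytest.approx(0.001)
        assert r.ks_distance == pytest.approx(0.499)
        assert r.ks_distance > r.ks_critical
        assert r.critical_value == 1
        assert r.n_discoveries == 50
        assert sorted(r.rejected_indices) == list(range(50))

    def test_all_ones_no_discoveries(self):
        r = sgof_plus(np.ones(50), alpha=0.05)
        assert r.n_discoveries == 0

    def test_uniform_null_rarely_discovers(self, rng):
        hits = sum(
            sgof_plus(rng.random(500), alpha=0.05).n_discoveries > 0
            for _ in range(100)
        )
        assert hits <= 10  # weak FWER: ~5 expected, generous MC margin

    def test_guard_failure_forces_zero_discoveries(self, rng):
        # near-uniform family: whenever the guard fails, nothing is declared
        seen_guard_failure = False
        for _ in range(50):
            r = sgof_plus(rng.random(200), alpha=0.05)
            if not r.ks_guard_passed:
                seen_guard_failure = True
                assert r.n_discoveries == 0
            if r.n_discoveries > 0:
                assert r.ks_guard_passed
        assert seen_guard_failure

    @given(pvalue_lists)
    @settings(deadline=None, max_examples=60)
    def test_cap_and_prefix_invariants(self, p):
        arr = np.asarray(p)
        if np.all((arr == 0) | (arr == 1)):
            return
        r = sgof_plus(p, alpha=0.05)
        assert 0 <= r.n_discoveries <= r.k_alpha
        # discoveries are a prefix of the sorted sequence
        if r.n_discoveries:
            rejected = np.sort(arr[r.rejected_indices])
            kept = np.delete(arr, r.rejected_indices)
            if kept.size:
                assert rejected.max() <= kept.min() + 1e-12

    def test_tie_break_by_input_order(self):
        # sgof on the spike family rejects 42 of the 50 tied smallest
        # p-values: the stable tie-break keeps the first 42 in input order
        p = np.r_[np.full(50, 0.001), np.full(50, 0.9)]
        r = sgof(p, alpha=0.05, gamma=0.05, gof="binomial")
        assert r.n_discoveries == 42
        assert list(r.rejected_indices) == list(range(42))
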