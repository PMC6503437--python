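import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genesurrounder import decay_pvalue_curve, kendall_tau_b, observed_discordance
from genesurrounder.decay import prefix_tau_b
from oracles import kendall_tau_b_enumeration


class TestKendallTauB:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((3, 2, 1), (1, 2, 3), -1.0),
            ((1, 2, 3), (1, 2, 3), 1.0),
            # C=0, D=2, one tied pair in each vector: -2/sqrt(2*2)
            ((2, 2, 1), (1, 1, 2), -1.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert kendall_tau_b(x, y) == pytest.approx(expected)

    def test_all_tied_vector_is_undefined(self):
        assert math.isnan(kendall_tau_b([1, 1, 1], [1, 2, 3]))
        assert math.isnan(kendall_tau_b([1, 2, 3], [5, 5, 5]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 4)), min_size=2, max_size=25
        )
    )
    def test_property_matches_enumeration_oracle(self, pairs):
        """For arbitrary small-integer vectors (ties everywhere), tau-b
        equals the O(n^2) pair-enumeration oracle, including the undefined
        all-tied cases."""
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        expected = kendall_tau_b_enumeration(x, y)
        got = kendall_tau_b(x, y)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_with_heavy_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 4, n).astype(float)  # heavy ties
            y = rng.integers(1, 5, n).astype(float)
            expected = kendall_tau_b_enumeration(x, y)
            got = kendall_tau_b(x, y)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestPrefixKernel:
    def test_matches_enumeration_oracle_at_every_radius(self, rng):
        """The incremental prefix kernel equals a fresh O(n^2) enumeration of
        each radius-restricted neighborhood, including heavy ties."""
        for _ in range(20):
            n = int(rng.integers(4, 50))
            d = np.sort(rng.integers(1, 6, n))
            x = np.vstack(
                [rng.integers(0, 5, n).astype(float), rng.standard_normal(n)]
            )
            radii = np.arange(1, 7)
            got = prefix_tau_b(x, d, radii)
            for row in range(2):
                for k, r in enumerate(radii):
                    sel = d <= r
                    if sel.sum() < 2:
                        assert math.isnan(got[row, k])
                        continue
                    expected = kendall_tau_b_enumeration(x[row, sel], d[sel])
                    if math.isnan(expected):
                        assert math.isnan(got[row, k])
                    else:
                        assert got[row, k] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_on_untied_data(self, rng):
        x = rng.standard_normal((1, 40))
        d = np.sort(rng.integers(1, 8, 40))
        got = prefix_tau_b(x, d, np.array([7]))
        expected = stats.kendalltau(x[0], d, variant="b").statistic
        assert got[0, 0] == pytest.approx(expected, abs=1e-12)


class TestObservedDiscordance:
    def test_strict_decay_gives_minus_one(self):
        g = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        d = np.array([1, 2, 3, 4, 5])
        assert observed_discordance(g, d) == pytest.approx(-1.0)

    def test_constant_statistic_is_undefined(self):
        assert math.isnan(observed_discordance([2.0, 2.0, 2.0], [1, 2, 3]))

    def test_small_neighborhood_is_undefined(self):
        assert math.isnan(observed_discordance([1.0, 2.0], [1, 2]))


class TestDecayPvalueCurve:
    def test_observed_below_all_nulls_hits_add_one_floor(self, rng):
        n = 30
        d = np.sort(rng.integers(1, 5, n))
        g_obs = (5.0 - d) + rng.standard_normal(n) * 0.01  # strict decay
        g_null = np.abs(rng.standard_normal((1000, n)))
        res = decay_pvalue_curve(g_obs, g_null, d, diameter=4)
        assert res.p[-1] == pytest.approx(1 / 1001)

    def test_small_neighborhoods_get_p_one(self, rng):
        d = np.array([1, 1, 3, 3, 3, 3])
        g_obs = rng.standard_normal(6)
        g_null = rng.standard_normal((50, 6))
        res = decay_pvalue_curve(g_obs, g_null, d, diameter=3)
        assert res.p[0] == 1.0 and math.isnan(res.d_obs[0])  # only 2 members
        assert res.p[1] == 1.0  # still 2 members at r=2

    def test_single_distance_shell_is_undefined(self, rng):
        d = np.array([1, 1, 1, 1])
        res = decay_pvalue_curve(
            rng.standard_normal(4), rng.standard_normal((50, 4)), d, diameter=1
        )
        assert res.p[0] == 1.0 and math.isnan(res.d_obs[0])

    def test_null_rank_of_observed_sets_p(self):
        """With nulls engineered around the observed discordance, the
        add-one lower-tail count is exact."""
        d = np.array([1, 2, 3, 4, 5, 6])
        g_obs = np.array([6.0, 5, 4, 2, 3, 1])  # tau < 0 but not -1
        tau_obs = kendall_tau_b_enumeration(g_obs, d)
        # one null more discordant (reversal of d), three less discordant
        g_null = np.vstack(
            [
                np.array([1.0, 2, 3, 4, 5, 6])[::-1],
                np.array([1.0, 2, 3, 4, 5, 6]),
                np.array([2.0, 1, 3, 4, 6, 5]),
                np.array([1.0, 3, 2, 5, 4, 6]),
            ]
        )
        res = decay_pvalue_curve(g_obs, g_null, d, diameter=6)
        # D* <= D_obs: the reversal (tau=-1) and the observed's own tie rank
        assert tau_obs < 0
        assert res.p[-1] == pytest.approx((1 + 1) / 5)

    def test_invariant_under_monotone_transform_of_g(self, rng):
        d = np.sort(rng.integers(1, 5, 20))
        g_obs = np.abs(rng.standard_normal(20))
        g_null = np.abs(rng.standard_normal((200, 20)))
        a = decay_pvalue_curve(g_obs, g_null, d, diameter=4)
        b = decay_pvalue_curve(g_obs**3, np.exp(g_null), d, diameter=4)
        assert np.allclose(a.p, b.p)
        assert np.allclose(a.d_obs, b.d_obs, equal_nan=True)

    def test_strict_tail_flag_drops_tied_nulls(self, rng):
        d = np.sort(rng.integers(1, 5, 12))
        g_obs = np.abs(rng.standard_normal(12))
        g_null = np.vstack([g_obs, np.abs(rng.standard_normal((20, 12)))])
        loose = decay_pvalue_curve(g_obs, g_null, d, diameter=4)
        strict = decay_pvalue_curve(g_obs, g_null, d, diameter=4, strict_tail=True)
        assert np.all(strict.p <= loose.p)
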