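"""Circular statistics: ITC, POP, optimal angles, partitions, detrending."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phaseopp as pp
from phaseopp.containers import ConfigurationError
from phaseopp.phase_stats import pop_from_phases


def u(angles):
    return np.exp(1j * np.asarray(angles, dtype=float))


class TestITC:
    def test_identical_angles(self):
        assert pp.itc(u(np.full(10, 0.7))) == pytest.approx(1.0)

    def test_opposed_pairs(self):
        assert pp.itc(u([0, np.pi])) == pytest.approx(0.0, abs=1e-12)
        assert pp.itc(u([0, np.pi / 2, np.pi, 3 * np.pi / 2])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_amplitude_raises_unless_masked(self):
        v = np.array([1.0 + 0j, 0.0 + 0j])
        with pytest.raises(ValueError):
            pp.itc(v)
        assert pp.itc(v, mask=np.array([True, False])) == pytest.approx(1.0)

    def test_uniform_expectation_sqrt_pi_over_2_sqrt_n(self):
        """E[ITC] for uniform phases ~ sqrt(pi)/(2 sqrt(n))."""
        rng = np.random.default_rng(0)
        for n in (10, 100, 1000):
            vals = [
                pp.itc(u(rng.uniform(-np.pi, np.pi, n))) for _ in range(400)
            ]
            expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
            assert np.mean(vals) == pytest.approx(expected, rel=0.08)

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_and_rotation_invariant(self, angles):
        val = pp.itc(u(angles))
        assert 0.0 <= val <= 1.0 + 1e-12
        rotated = pp.itc(u(np.asarray(angles) + 1.234))
        assert val == pytest.approx(rotated, abs=1e-9)


class TestPOP:
    def test_identical_multisets_give_zero(self):
        angles = np.array([0.1, 0.5, 1.2, -0.7, 2.0])
        vecs = u(np.concatenate([angles, angles]))[:, None]
        high = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        p, *_ = pop_from_phases(vecs, high)
        assert p[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_opposition_gives_one(self):
        vecs = u(np.r_[np.zeros(10), np.full(10, np.pi)])[:, None]
        high = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        p, itc_all, itc_a, itc_b = pop_from_phases(vecs, high)
        assert itc_a[0] == pytest.approx(1.0)
        assert itc_b[0] == pytest.approx(1.0)
        assert itc_all[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_quarter_turn_gives_half(self):
        # ITC_ALL = |(1 + e^{i pi/2})/2| = sqrt(2)/2 -> POP = 1 - 1/2
        vecs = u(np.r_[np.zeros(10), np.full(10, np.pi / 2)])[:, None]
        high = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        p, itc_all, *_ = pop_from_phases(vecs, high)
        assert itc_all[0] == pytest.approx(np.sqrt(2) / 2)
        assert p[0] == pytest.approx(0.5)

    def test_label_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(-np.pi, np.pi, 40)
        high = rng.permutation(np.r_[np.ones(20, bool), np.zeros(20, bool)])
        p1, *_ = pop_from_phases(u(angles)[:, None], high)
        p2, *_ = pop_from_phases(u(angles)[:, None], ~high)
        assert p1[0] == pytest.approx(p2[0])
        p3, *_ = pop_from_phases(u(angles + 0.83)[:, None], high)
        assert p1[0] == pytest.approx(p3[0])

    def test_requires_two_trials_per_condition(self):
        with pytest.raises(ConfigurationError):
            pop_from_phases(u([0, 1, 2])[:, None],
                            np.array([True, False, False]))


class TestOptimalAngle:
    def test_exact_opposition(self):
        assert pp.optimal_phase_angle([0.0, 0.0], [np.pi, np.pi]) == (
            pytest.approx(0.0, abs=1e-12)
        )
        assert pp.optimal_phase_angle(
            [np.pi / 2] * 3, [3 * np.pi / 2] * 3
        ) == pytest.approx(np.pi / 2)

    def test_von_mises_monte_carlo(self):
        rng = np.random.default_rng(2)
        high = rng.vonmises(1.0, 5.0, 500)
        low = rng.vonmises(1.0 + np.pi, 5.0, 500)
        assert pp.optimal_phase_angle(high, low) == pytest.approx(1.0, abs=0.1)

    def test_degenerate_resultant_raises(self):
        with pytest.raises(ValueError):
            pp.optimal_phase_angle([0.0, np.pi], [1.0])


class TestPartition:
    def test_uniform_phases_select_about_a_third(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(-np.pi, np.pi, 10_000)
        part = pp.select_phase_trials(phases, 0.4)
        assert part.optimal.size / 10_000 == pytest.approx(1 / 3, abs=0.02)
        assert part.non_optimal.size / 10_000 == pytest.approx(1 / 3, abs=0.02)
        assert not np.intersect1d(part.optimal, part.non_optimal).size

    def test_all_at_optimal(self):
        part = pp.select_phase_trials(np.full(20, 1.1), 1.1)
        assert part.optimal.size == 20 and part.non_optimal.size == 0

    def test_boundary_is_excluded(self):
        part = pp.select_phase_trials(np.array([np.pi / 3]), 0.0)
        assert part.optimal.size == 0 and part.non_optimal.size == 0


class TestCircularDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.0, np.pi, np.pi), (0.1, 0.1, 0.0), (-3.0, 3.0, 2 * np.pi - 6)],
    )
    def test_values(self, a, b, expected):
        assert pp.circular_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_range_and_symmetry(self, a, b):
        d = pp.circular_distance(a, b)
        assert 0.0 <= d <= np.pi + 1e-9
        assert d == pytest.approx(pp.circular_distance(b, a), abs=1e-9)


class TestBinnedProbability:
    def test_all_successes(self):
        rng = np.random.default_rng(4)
        phases = rng.uniform(-np.pi, np.pi, 500)
        out = pp.phase_binned_outcome_probability(phases, np.ones(500), 6, 0.0)
        assert np.all(out["probability"][out["count"] > 0] == 1.0)

    def test_null_outcomes_flat(self):
        rng = np.random.default_rng(5)
        phases = rng.uniform(-np.pi, np.pi, 4000)
        y = rng.integers(0, 2, 4000)
        out = pp.phase_binned_outcome_probability(phases, y, 6, 0.0)
        assert np.all(np.abs(out["probability"] - 0.5) < 0.1)

    def test_cosine_link_monotone_decrease(self):
        rng = np.random.default_rng(6)
        phases = rng.uniform(-np.pi, np.pi, 20_000)
        labels = pp.make_agency_labels_from_phase(phases, 0.5, 0.35, 0.9, seed=7)
        out = pp.phase_binned_outcome_probability(phases, labels.labels, 6, 0.9)
        p = out["probability"]
        assert np.all(np.diff(p) < 0.05)  # monotone within binomial noise
        assert p[0] > 0.7 and p[-1] < 0.3


class TestBootstrapContrast:
    def test_perfect_opposition_split(self):
        rng = np.random.default_rng(8)
        a_high = rng.vonmises(0.5, 20.0, 100)
        a_low = rng.vonmises(0.5 + np.pi, 20.0, 100)
        out = pp.bootstrap_circular_distance_contrast(
            a_high, a_low, a_high, a_low, n_boot=300, seed=1
        )
        assert out["matched"] < 0.2
        assert out["mismatched"] > np.pi - 0.4
        assert out["p_two_sided"] < 0.01

    def test_identical_sets_null(self):
        rng = np.random.default_rng(9)
        s = rng.vonmises(1.0, 2.0, 80)
        out = pp.bootstrap_circular_distance_contrast(s, s, s, s,
                                                      n_boot=200, seed=2)
        assert out["matched"] == pytest.approx(out["mismatched"], abs=1e-12)

    def test_small_bootstrap_warns(self):
        s = np.array([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            pp.bootstrap_circular_distance_contrast(s, s, s, s, n_boot=50)


class TestDetrend:
    def test_exact_linear_dependence_gives_zero_residuals(self):
        delays = np.linspace(0.2, 1.5, 50)
        residuals, flag = pp.detrend_ratings_by_delay(9 - 2 * delays, delays)
        assert not flag
        np.testing.assert_allclose(residuals, 0.0, atol=1e-10)

    def test_constant_delay_flags_and_centres(self):
        ratings = np.array([3.0, 5.0, 7.0])
        residuals, flag = pp.detrend_ratings_by_delay(ratings, np.ones(3))
        assert flag
        np.testing.assert_allclose(residuals, ratings - 5.0)

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(10)
        delays = rng.uniform(0.0, 2.0, 200)
        ratings = 7.0 - 1.0 * delays + rng.normal(0, 0.5, 200)
        residuals, _ = pp.detrend_ratings_by_delay(ratings, delays)
        # residual slope on delay is zero -> planted slope -1 was removed
        slope_before = np.polyfit(delays, ratings, 1)[0]
        slope_after = np.polyfit(delays, residuals, 1)[0]
        assert slope_before == pytest.approx(-1.0, abs=0.1)
        assert abs(slope_after) < 1e-10
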