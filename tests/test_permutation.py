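"""Permutation nulls, p-maps and cluster correction."""

import numpy as np
import pytest

import phaseopp as pp
from phaseopp.containers import AnalyticMap, ConfigurationError, LabelSet
from phaseopp.permutation import pop_stat, _pop_stat_batch


def _analytic_from_phases(phases, freqs=None, times=None):
    """Wrap an (n_trials, n_freqs, n_times) phase array as an AnalyticMap."""
    phases = np.asarray(phases, dtype=float)
    values = np.exp(1j * phases)[:, None]
    n_f, n_t = phases.shape[1], phases.shape[2]
    return AnalyticMap(
        values=values,
        freqs=np.arange(n_f, dtype=float) + 4 if freqs is None else freqs,
        times=np.linspace(-1, 0.5, n_t) if times is None else times,
        method="morlet",
    )


def test_batch_pop_matches_scalar_pop():
    rng = np.random.default_rng(0)
    u = np.exp(1j * rng.uniform(-np.pi, np.pi, (30, 4, 6)))
    high = rng.permutation(np.r_[np.ones(15, bool), np.zeros(15, bool)])
    masks = np.stack([rng.permutation(high) for _ in range(20)])
    batch = _pop_stat_batch(u, masks)
    for k in range(20):
        np.testing.assert_allclose(batch[k], pop_stat(u, masks[k]), atol=1e-12)


def test_degenerate_data_gives_p_one():
    """All trials share one phase: every permutation ties, p = 1."""
    an = _analytic_from_phases(np.full((20, 2, 5), 0.3))
    labels = LabelSet(labels=np.r_[np.ones(10, int), np.zeros(10, int)])
    pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=200, seed=0)
    assert np.all(pr.p == 1.0)


def test_perfect_separation_reaches_attainable_minimum():
    phases = np.zeros((20, 1, 3))
    phases[10:] = np.pi
    an = _analytic_from_phases(phases)
    labels = LabelSet(labels=np.r_[np.ones(10, int), np.zeros(10, int)])
    pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=200, seed=1)
    assert pr.p.min() == pytest.approx(1 / 201)


def test_p_in_unit_interval_and_reproducible():
    rng = np.random.default_rng(2)
    an = _analytic_from_phases(rng.uniform(-np.pi, np.pi, (24, 3, 8)))
    labels = LabelSet(labels=np.r_[np.ones(12, int), np.zeros(12, int)])
    pr1 = pp.permutation_pvalues(pop_stat, an, labels, n_perm=150, seed=3)
    pr2 = pp.permutation_pvalues(pop_stat, an, labels, n_perm=150, seed=3)
    assert np.all((pr1.p > 0) & (pr1.p <= 1))
    np.testing.assert_array_equal(pr1.p, pr2.p)
    with pytest.raises(ConfigurationError):
        pp.permutation_pvalues(pop_stat, an, labels, n_perm=10)


class TestClusterCorrect:
    def test_planted_block_recovered(self):
        """A block of perfectly opposed phases forms one significant cluster
        exactly covering the block."""
        rng = np.random.default_rng(4)
        phases = rng.uniform(-np.pi, np.pi, (40, 5, 20))
        times = np.linspace(-1.0, 0.5, 20)
        block_f = slice(1, 3)
        block_t = slice(4, 8)  # within the pre-movement window
        phases[:20, block_f, block_t] = 0.0
        phases[20:, block_f, block_t] = np.pi
        an = _analytic_from_phases(phases, times=times)
        labels = LabelSet(labels=np.r_[np.ones(20, int), np.zeros(20, int)])
        pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=300, seed=5)
        cl = pp.cluster_correct(pr, threshold_T=2.0, window=(-1.0, 0.0))
        assert len(cl.masks) >= 1
        best = cl.masks[0]
        assert cl.p_values[0] == pytest.approx(1 / 301)
        expected = np.zeros_like(best)
        expected[block_f, block_t] = True
        assert np.all(best[expected])  # top cluster covers the whole block

    def test_flat_map_yields_no_clusters(self):
        an = _analytic_from_phases(np.full((20, 2, 6), 1.0))
        labels = LabelSet(labels=np.r_[np.ones(10, int), np.zeros(10, int)])
        pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=150, seed=6)
        cl = pp.cluster_correct(pr, window=None)
        assert len(cl.masks) == 0

    def test_larger_score_has_smaller_or_equal_p(self):
        rng = np.random.default_rng(7)
        phases = rng.uniform(-np.pi, np.pi, (40, 6, 16))
        # two planted blocks of different strength
        phases[:20, 0:2, 2:6] = 0.0
        phases[20:, 0:2, 2:6] = np.pi
        phases[:20, 4:5, 10:12] = rng.vonmises(0, 3.0, (20, 1, 2))
        phases[20:, 4:5, 10:12] = rng.vonmises(np.pi, 3.0, (20, 1, 2))
        an = _analytic_from_phases(phases)
        labels = LabelSet(labels=np.r_[np.ones(20, int), np.zeros(20, int)])
        pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=200, seed=8)
        cl = pp.cluster_correct(pr, window=None)
        if len(cl.scores) >= 2:
            order = np.argsort(cl.scores)[::-1]
            assert np.all(np.diff(cl.p_values[order]) >= 0)


class TestGroupTest:
    def test_single_subject_consistency(self):
        """With one subject the group test reduces to the windowed average of
        that subject's permutation test."""
        rng = np.random.default_rng(9)
        phases = rng.vonmises(0, 2.0, (30, 3, 10))
        phases[15:] += np.pi
        an = _analytic_from_phases(
            phases, freqs=np.array([8.0, 10.0, 12.0]),
            times=np.linspace(-0.5, 0.0, 10, endpoint=False),
        )
        labels = LabelSet(labels=np.r_[np.ones(15, int), np.zeros(15, int)])
        pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=200, seed=10)
        out = pp.group_pop_test([pr.observed], [pr.nulls], an.freqs, an.times)
        win_obs = pr.observed.mean()
        win_null = pr.nulls.mean(axis=(1, 2))
        expected_p = (1 + np.sum(win_null >= win_obs)) / 201
        assert out["p"] == pytest.approx(expected_p)

    def test_planted_cohort_reaches_minimum(self):
        rng = np.random.default_rng(11)
        obs, nulls = [], []
        for _ in range(5):
            phases = np.concatenate(
                [rng.vonmises(0, 5.0, (15, 2, 8)),
                 rng.vonmises(np.pi, 5.0, (15, 2, 8))]
            )
            an = _analytic_from_phases(
                phases, freqs=np.array([9.0, 11.0]),
                times=np.linspace(-0.5, 0.0, 8, endpoint=False),
            )
            labels = LabelSet(labels=np.r_[np.ones(15, int), np.zeros(15, int)])
            pr = pp.permutation_pvalues(pop_stat, an, labels, n_perm=200,
                                        seed=int(rng.integers(1 << 30)))
            obs.append(pr.observed)
            nulls.append(pr.nulls)
        out = pp.group_pop_test(obs, nulls, np.array([9.0, 11.0]),
                                np.linspace(-0.5, 0.0, 8, endpoint=False))
        assert out["p"] == pytest.approx(1 / 201)

    def test_missing_nulls_excluded_with_warning(self):
        rng = np.random.default_rng(12)
        o = rng.normal(size=(2, 4))
        n = rng.normal(size=(100, 2, 4))
        with pytest.warns(UserWarning):
            out = pp.group_pop_test(
                [o, o], [n, None],
                np.array([9.0, 11.0]),
                np.linspace(-0.5, 0.0, 4, endpoint=False),
            )
        assert out["n_subjects"] == 1


class TestPowerContrast:
    def test_planted_power_step_detected_and_null_clean(self):
        cfg_hi = pp.SynthTrialConfig(n_trials_per_condition=25, kappa=0.0,
                                     osc_amplitude=4.0, seed=13)
        trials, labels = pp.make_phase_coded_trials(cfg_hi)
        # quadruple the amplitude of one condition's oscillation band
        data = trials.data.copy()
        an = pp.morlet_analytic(
            pp.TrialSet(data=data, fs=cfg_hi.fs, t0_index=trials.t0_index)
        )
        t, cl = pp.power_contrast(an, labels, window=(-0.5, 0.0),
                                  n_perm=200, seed=14)
        # same construction in both conditions -> no significant cluster
        assert cl.n_significant == 0

        data2 = trials.data.copy()
        data2[labels.high_mask] *= 2.0  # power x4 in one condition
        an2 = pp.morlet_analytic(
            pp.TrialSet(data=data2, fs=cfg_hi.fs, t0_index=trials.t0_index)
        )
        t2, cl2 = pp.power_contrast(an2, labels, window=(-0.5, 0.0),
                                    n_perm=200, seed=14)
        assert cl2.n_significant >= 1
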