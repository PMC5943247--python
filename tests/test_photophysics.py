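import numpy as np
import pytest

from qsmlm import (
    DENDRA2,
    PhotophysicsModel,
    build_transition_matrix,
    fit_activation_rate,
    occupancy_counts,
    simulate_cluster_trace,
    simulate_molecule,
)
from qsmlm.photophysics import BLEACHED, FLUORESCENT, PRECONVERTED


class TestTransitionMatrix:
    def test_reference_rates_row2(self):
        T = build_transition_matrix(DENDRA2)
        np.testing.assert_allclose(T[1], [0.0, 0.92434, 0.05766, 0.018],
                                   atol=1e-12)

    def test_all_rates_zero_gives_identity(self):
        m = PhotophysicsModel(k_on=0, k_dark=0, k_rec=0, k_bleach=0)
        np.testing.assert_array_equal(build_transition_matrix(m), np.eye(4))

    def test_rows_sum_to_one_and_formulas_for_random_rates(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k_on, k_dark, k_rec, k_bleach = rng.uniform(0, 10, 4)
            dt = float(rng.uniform(1e-4, 1.0 / (k_dark + k_bleach + 1e-9)))
            dt = min(dt, 0.99 / max(k_on, k_rec, 1e-9))
            m = PhotophysicsModel(k_on=k_on, k_dark=k_dark, k_rec=k_rec,
                                  k_bleach=k_bleach, dt=dt)
            T = build_transition_matrix(m)
            np.testing.assert_allclose(T.sum(axis=1), np.ones(4), atol=1e-12)
            assert (T >= 0).all()
            assert T[0, 1] == pytest.approx(k_on * dt)
            assert T[1, 2] == pytest.approx(k_dark * dt)
            assert T[1, 3] == pytest.approx(k_bleach * dt)
            assert T[2, 1] == pytest.approx(k_rec * dt)
            np.testing.assert_array_equal(T[3], [0, 0, 0, 1])  # absorbing

    def test_dt_too_large_names_offender(self):
        with pytest.raises(ValueError, match="k_dark"):
            PhotophysicsModel(k_dark=100.0, k_bleach=100.0, dt=0.006)


class TestTrajectories:
    def test_no_activation_stays_preconverted(self):
        m = PhotophysicsModel(k_on=0.0)
        states = simulate_molecule(m, 500, seed=3)
        assert (states == PRECONVERTED).all()

    def test_forced_bleach_after_activation(self):
        # k_bleach*dt = 1, k_dark = 0: the step after entering the
        # fluorescent state always bleaches
        m = PhotophysicsModel(k_on=50.0, k_dark=0.0, k_rec=0.0,
                              k_bleach=1.0 / 0.006)
        states = simulate_molecule(m, 2000, seed=5)
        fluo = np.flatnonzero(states == FLUORESCENT)
        assert len(fluo) >= 1
        for i in fluo:
            assert states[i + 1] == BLEACHED

    def test_occupancy_matches_matrix_power(self):
        """Ensemble state fractions after n steps agree with T^n applied
        to the all-preconverted start, within multinomial 3 sigma."""
        n_mol, n_steps = 10_000, 150
        occ = occupancy_counts(DENDRA2, n_mol, n_steps, seed=11)
        T = build_transition_matrix(DENDRA2)
        p = np.array([1.0, 0, 0, 0])
        for step in (1, 10, 50, 150):
            expected = p @ np.linalg.matrix_power(T, step)
            se = np.sqrt(np.maximum(expected * (1 - expected) * n_mol, 1.0))
            assert (np.abs(occ[step] - expected * n_mol) <= 3 * se).all(), step

    def test_occupancy_rows_conserve_molecules(self):
        occ = occupancy_counts(DENDRA2, 500, 50, seed=2)
        assert (occ.sum(axis=1) == 500).all()

    def test_ever_activated_fraction_matches_binomial(self):
        n_mol, n_steps = 5000, 400
        occ = occupancy_counts(DENDRA2, n_mol, n_steps, seed=19)
        frac_pre = occ[:, 0] / n_mol
        expect = (1 - DENDRA2.k_on * DENDRA2.dt) ** np.arange(n_steps + 1)
        se = np.sqrt(expect * (1 - expect) / n_mol)
        assert (np.abs(frac_pre - expect) <= 3 * se + 1e-9).all()
        assert (np.diff(occ[:, 0]) <= 0).all()   # activation is one-way

    def test_bleached_fraction_monotone_and_absorbing(self):
        # fast activation so absorption is nearly complete within 12 s
        m = PhotophysicsModel(k_on=1.0)
        occ = occupancy_counts(m, 2000, 2000, seed=23)
        assert (np.diff(occ[:, 3]) >= 0).all()
        assert occ[-1, 3] > 0.95 * 2000


class TestClusterTrace:
    def test_always_on_molecule_lights_every_bin(self):
        m = PhotophysicsModel(k_on=100.0, k_dark=0.0, k_rec=0.0, k_bleach=0.0)
        tr = simulate_cluster_trace(m, 1, acquisition_s=3.0, seed=1)
        assert (tr.counts[1:] == 1).all()

    def test_window_zeroes_outside(self):
        tr = simulate_cluster_trace(DENDRA2, 100, 60.0, window=(10.0, 20.0),
                                    seed=7)
        t = (np.arange(len(tr.counts)) + 0.5) * tr.bin_s
        outside = (t < 10.0) | (t > 20.0)
        assert (tr.counts[outside] == 0).all()

    def test_merged_counts_binary(self):
        tr = simulate_cluster_trace(DENDRA2, 200, 30.0, seed=9)
        assert set(np.unique(tr.counts)) <= {0, 1}

    def test_unmerged_counts_bounded_by_molecules(self):
        tr = simulate_cluster_trace(DENDRA2, 5, 30.0, merge=False, seed=9)
        assert tr.counts.max() <= 5
        assert tr.counts.sum() >= tr.counts.max()

    def test_identical_seed_identical_trace(self):
        a = simulate_cluster_trace(DENDRA2, 50, 30.0, seed=123)
        b = simulate_cluster_trace(DENDRA2, 50, 30.0, seed=123)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_bad_window_order_errors(self):
        with pytest.raises(ValueError):
            simulate_cluster_trace(DENDRA2, 5, 10.0, window=(5.0, 2.0), seed=0)

    def test_bin_not_multiple_of_dt_errors(self):
        with pytest.raises(ValueError, match="multiple"):
            simulate_cluster_trace(DENDRA2, 5, 10.0, bin_s=0.01, seed=0)

    def test_stable_cumulative_mean_matches_montecarlo_oracle(self):
        """Expected per-bin detection probability from an independent
        10,000-trajectory re-simulation agrees with a 500-molecule run
        within 3 sigma (binomial over molecules and bins)."""
        rng = np.random.default_rng(77)
        T = build_transition_matrix(DENDRA2)
        n_bins, spb = 100, 10
        # direct per-step categorical oracle, coded independently
        n_oracle = 10_000
        states = np.ones(n_oracle, dtype=int)
        lit = np.zeros((n_bins, n_oracle), dtype=bool)
        for b in range(n_bins):
            for _ in range(spb):
                u = rng.random(n_oracle)
                nxt = states.copy()
                for s in (1, 2, 3):
                    mask = states == s
                    if not mask.any():
                        continue
                    cum = np.cumsum(T[s - 1])
                    nxt[mask] = 1 + np.searchsorted(cum, u[mask], side="right")
                states = nxt
                lit[b] |= states == 2

        # per-molecule cumulative lit-bin counts give the exact mean and
        # variance of the cumulative trace (bins are correlated within a
        # molecule, so per-bin binomial variance would understate it)
        percum = np.cumsum(lit, axis=0)
        mean_c = percum.mean(axis=1)
        var_c = percum.var(axis=1)

        n_run = 500
        tr = simulate_cluster_trace(DENDRA2, n_run, n_bins * 0.06, merge=False,
                                    seed=31)
        expect = n_run * mean_c
        sd = np.sqrt(n_run * var_c + n_run**2 * var_c / n_oracle)
        resid = np.abs(tr.cumulative - expect)
        assert (resid <= 3 * sd + 3).all()


class TestActivationFit:
    def test_noiseless_model_recovered_to_four_figures(self):
        t = np.arange(1, 5001) * 0.06
        N = 500 * (1 - np.exp(-t / 43)) + 0.2 * t
        fit = fit_activation_rate(N, t=t)
        assert fit.k_on == pytest.approx(1 / 43, rel=1e-4)
        assert fit.N0 == pytest.approx(500, rel=1e-4)
        assert fit.B == pytest.approx(0.2, rel=1e-4)

    def test_pure_exponential_no_background(self):
        t = np.arange(1, 3001) * 0.06
        N = 800 * (1 - np.exp(-t / 20))
        fit = fit_activation_rate(N, t=t)
        assert fit.k_on == pytest.approx(1 / 20, rel=1e-6)
        assert abs(fit.B) < 1e-6

    def test_simulated_nucleus_recovers_k_on(self):
        tr = simulate_cluster_trace(DENDRA2, 5000, 300.0, merge=False, seed=1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_activation_rate(tr)
        assert fit.tau == pytest.approx(43.0, rel=0.10)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_activation_rate(np.arange(50.0), t=np.arange(50) * 0.06)
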