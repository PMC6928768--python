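"""WHAM self-consistency, PMF extraction and ΔG/ΔΔG bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidhs.structures import WindowSeries
from capsidhs.synthetic import SyntheticPotentialSpec, sample_umbrella
from capsidhs.wham import (
    KB_KCAL,
    KJ_PER_KCAL,
    BiasPotential,
    BindingEnergy,
    HistogramSet,
    PMFProfile,
    WHAMSolution,
    binding_dg,
    bootstrap_dg,
    build_histograms,
    delta_delta_g,
    pmf_from_solution,
    solve_wham,
)


def _window(samples, wid=0, center=1.0, k=2000.0):
    return WindowSeries(window_id=wid, center=center, spring_k=k,
                        samples=np.asarray(samples, float))


class TestHistograms:
    def test_small_example(self):
        hist = build_histograms([_window([1.0, 1.0, 2.0])], bin_width=0.5)
        assert hist.totals.tolist() == [3]
        assert (hist.counts > 0).sum() == 2

    def test_left_closed_edge_convention(self):
        hist = build_histograms(
            [_window([1.0, 1.5, 2.0])], bin_width=0.5
        )
        # 1.5 sits exactly on an internal edge: it belongs to [1.5, 2.0)
        assert hist.counts[0].tolist() == [1, 2]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n_windows=st.integers(1, 5),
        n_samples=st.integers(1, 200),
        width=st.floats(0.01, 0.5),
        seed=st.integers(0, 10_000),
    )
    def test_counts_conserve_samples(self, n_windows, n_samples, width, seed):
        rng = np.random.default_rng(seed)
        windows = [
            _window(rng.uniform(0.5, 3.0, size=n_samples), wid=i)
            for i in range(n_windows)
        ]
        hist = build_histograms(windows, bin_width=width)
        assert hist.counts.sum() == n_windows * n_samples

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_histograms([], bin_width=0.1)
        with pytest.raises(ValueError):
            build_histograms([_window([1.0])], bin_width=-1)


class TestSolveWham:
    def test_unbiased_single_window_recovers_histogram(self):
        rng = np.random.default_rng(0)
        w = _window(rng.normal(2.0, 0.3, size=5000))
        hist = build_histograms([w], bin_width=0.1)
        sol = solve_wham(hist, [BiasPotential(center=0.0, spring_k=0.0)])
        occ = hist.counts[0] > 0
        expected = hist.counts[0][occ] / hist.totals[0]
        assert sol.unbiased_prob[occ] == pytest.approx(expected, rel=1e-9)
        assert sol.window_offsets[0] == 0.0
        assert sol.converged

    def test_duplicated_window_idempotent(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(1.5, 0.05, size=4000)
        bias = BiasPotential(center=1.5, spring_k=2000.0)
        one = solve_wham(build_histograms([_window(samples)], bin_width=0.02), [bias])
        two = solve_wham(
            build_histograms([_window(samples, 0), _window(samples, 1)],
                             bin_width=0.02),
            [bias, bias],
        )
        assert two.unbiased_prob == pytest.approx(one.unbiased_prob, abs=1e-9)

    def test_window_permutation_invariance(self):
        spec = SyntheticPotentialSpec(form="harmonic", minimum=1.5, width=0.2,
                                      plateau=3.0)
        biases = [BiasPotential(c, 500.0) for c in (1.2, 1.5, 1.8)]
        windows = sample_umbrella(spec, biases, n_samples=4000, seed=3)
        sol_a = solve_wham(build_histograms(windows, 0.02), biases)
        perm = [2, 0, 1]
        sol_b = solve_wham(
            build_histograms([windows[i] for i in perm], 0.02),
            [biases[i] for i in perm],
        )
        assert sol_b.unbiased_prob == pytest.approx(sol_a.unbiased_prob, abs=1e-6)

    def test_splitting_a_window_invariant(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(1.5, 0.1, size=6000)
        bias = BiasPotential(center=1.5, spring_k=500.0)
        whole = solve_wham(build_histograms([_window(samples)], 0.02), [bias])
        halves = solve_wham(
            build_histograms(
                [_window(samples[:3000], 0), _window(samples[3000:], 1)], 0.02
            ),
            [bias, bias],
        )
        assert halves.unbiased_prob == pytest.approx(whole.unbiased_prob, abs=1e-9)

    def test_disconnected_windows_error_names_gap(self):
        w1 = _window(np.linspace(1.0, 1.1, 50), wid=0, center=1.05)
        w2 = _window(np.linspace(5.0, 5.1, 50), wid=1, center=5.05)
        with pytest.raises(ValueError, match="disconnected"):
            solve_wham(
                build_histograms([w1, w2], bin_width=0.02),
                [BiasPotential(1.05, 2000.0), BiasPotential(5.05, 2000.0)],
            )

    def test_analytic_recovery_harmonic(self):
        """Exact-sampler windows over a harmonic U: −kT ln P matches U."""
        spec = SyntheticPotentialSpec(form="harmonic", minimum=1.5, width=0.15,
                                      plateau=2.4, xi_range=(0.9, 2.1))
        biases = [BiasPotential(c, 1000.0) for c in np.linspace(0.9, 2.1, 13)]
        windows = sample_umbrella(spec, biases, n_samples=20_000, seed=11)
        hist = build_histograms(windows, bin_width=0.02)
        sol = solve_wham(hist, biases)
        assert sol.converged
        kT = KB_KCAL * 300.0
        occ = sol.unbiased_prob > 0
        xi = sol.bin_centers[occ]
        g = -kT * np.log(sol.unbiased_prob[occ])
        u = spec.energy(xi)
        well = hist.counts.sum(axis=0)[occ] >= 200
        resid = (g - u)[well]
        resid -= resid.mean()   # both known up to a constant
        assert np.sqrt(np.mean(resid ** 2)) < 0.08


class TestPMF:
    def _uniform_solution(self, kT_temp=300.0):
        centers = np.linspace(1.0, 2.0, 11)
        P = np.full(11, 1 / 11)
        return WHAMSolution(unbiased_prob=P, window_offsets=np.zeros(1),
                            converged=True, iterations=1,
                            bin_centers=centers, temperature=kT_temp)

    def test_uniform_probability_gives_flat_zero(self):
        pmf = pmf_from_solution(self._uniform_solution())
        assert pmf.g == pytest.approx(np.zeros_like(pmf.g), abs=1e-12)

    def test_flat_profile_stays_zero_at_doubled_temperature(self):
        pmf = pmf_from_solution(self._uniform_solution(600.0))
        assert pmf.g == pytest.approx(np.zeros_like(pmf.g), abs=1e-12)

    def test_boltzmann_probability_recovers_potential(self):
        centers = np.linspace(0.5, 5.0, 200)
        u = 4.0 * ((1 - np.exp(-(centers - 1.0) / 0.3)) ** 2 - 1)
        kT = KB_KCAL * 300.0
        P = np.exp(-u / kT)
        P /= P.sum()
        sol = WHAMSolution(unbiased_prob=P, window_offsets=np.zeros(1),
                           converged=True, iterations=1,
                           bin_centers=centers, temperature=300.0)
        pmf = pmf_from_solution(sol)
        tail = pmf.xi >= pmf.xi[-1] - 0.05 * (pmf.xi[-1] - pmf.xi[0])
        expected = u - u[tail].mean()
        assert pmf.g == pytest.approx(expected, abs=1e-9)

    def test_thermal_energy_at_300K(self):
        assert KB_KCAL * 300.0 == pytest.approx(0.59616, abs=1e-5)
        assert KJ_PER_KCAL == 4.184

    def test_refuses_unconverged_without_force(self):
        sol = self._uniform_solution()
        sol.converged = False
        with pytest.raises(RuntimeError):
            pmf_from_solution(sol)
        assert pmf_from_solution(sol, force=True) is not None


class TestBindingDG:
    def _profile(self, depth, xi_min=1.0):
        # grid spacing 0.02 nm hits xi_min exactly, so min(g) == depth
        xi = np.linspace(0.8, 10.0, 461)
        g = depth * np.exp(-((xi - xi_min) / 0.4) ** 2)
        return PMFProfile(xi=xi, g=g, reference_xi=9.8, temperature=300.0)

    def test_global_minimum_extraction(self):
        dg = binding_dg(self._profile(-144.9))
        assert dg.dg == pytest.approx(-144.9, abs=1e-6)
        assert not dg.no_stable_complex

    def test_monotone_profile_flags_no_complex(self):
        xi = np.linspace(1.0, 10.0, 100)
        pmf = PMFProfile(xi=xi, g=np.linspace(0, 5, 100) - 5.0,
                         reference_xi=9.9, temperature=300.0)
        # minimum sits at the smallest g which is at xi=1.0 here; use rising one
        pmf = PMFProfile(xi=xi, g=np.linspace(0.0, 5.0, 100),
                         reference_xi=9.9, temperature=300.0)
        dg = binding_dg(pmf)
        assert dg.dg == 0.0 and dg.no_stable_complex

    def test_double_well_picks_global_minimum(self):
        xi = np.linspace(0.5, 8.0, 600)
        g = (-3.0 * np.exp(-((xi - 1.0) / 0.2) ** 2)
             - 7.5 * np.exp(-((xi - 2.5) / 0.2) ** 2))
        pmf = PMFProfile(xi=xi, g=g, reference_xi=7.9, temperature=300.0)
        dg = binding_dg(pmf)
        assert dg.dg == pytest.approx(-7.5, abs=0.01)
        assert dg.xi_min == pytest.approx(2.5, abs=0.02)


class TestDeltaDeltaG:
    @pytest.mark.parametrize("dg_mut,dg_wt,expected", [
        (-37.4, -144.9, 107.5),
        (-144.1, -144.9, 0.8),
        (-144.9, -144.9, 0.0),
    ])
    def test_differencing(self, dg_mut, dg_wt, expected):
        ddg, _ = delta_delta_g(BindingEnergy(dg=dg_mut), BindingEnergy(dg=dg_wt))
        assert ddg == pytest.approx(expected, abs=1e-9)

    def test_error_propagation_in_quadrature(self):
        ddg, err = delta_delta_g(
            BindingEnergy(dg=-37.4, dg_err=5.3),
            BindingEnergy(dg=-144.9, dg_err=4.9),
        )
        assert err == pytest.approx(np.hypot(5.3, 4.9))


class TestBootstrap:
    def _setup(self, n_samples=3000, seed=0):
        spec = SyntheticPotentialSpec(form="morse_like_binding", depth=3.0,
                                      minimum=1.5, width=0.3, plateau=4.0)
        biases = [BiasPotential(c, 1000.0) for c in np.linspace(1.35, 4.0, 12)]
        windows = sample_umbrella(spec, biases, n_samples=n_samples, seed=seed)
        return spec, biases, windows

    def test_deterministic_under_seed(self):
        _, biases, windows = self._setup()
        a = bootstrap_dg(windows, biases, n_boot=2, seed=9, bin_width=0.02)
        b = bootstrap_dg(windows, biases, n_boot=2, seed=9, bin_width=0.02)
        assert a == b

    def test_error_shrinks_with_sample_size(self):
        _, biases, small = self._setup(n_samples=800, seed=4)
        _, _, large = self._setup(n_samples=12_800, seed=4)
        err_small = bootstrap_dg(small, biases, n_boot=8, seed=1, bin_width=0.02)
        err_large = bootstrap_dg(large, biases, n_boot=8, seed=1, bin_width=0.02)
        assert err_large < err_small

    def test_error_calibrated_against_regeneration_spread(self):
        """Bootstrap σ within a factor of 2 of the true seed-to-seed spread."""
        spec, biases, windows = self._setup(n_samples=2000, seed=0)
        dgs = []
        for seed in range(15):
            w = sample_umbrella(spec, biases, n_samples=2000, seed=100 + seed)
            hist = build_histograms(w, bin_width=0.02)
            sol = solve_wham(hist, biases, tol=1e-6)
            dgs.append(binding_dg(pmf_from_solution(sol, force=True)).dg)
        spread = np.std(dgs, ddof=1)
        err = bootstrap_dg(windows, biases, n_boot=15, seed=2, bin_width=0.02,
                           tol=1e-6)
        assert spread / 2 <= err <= spread * 2

    def test_rejects_tiny_n_boot(self):
        _, biases, windows = self._setup()
        with pytest.raises(ValueError):
            bootstrap_dg(windows, biases, n_boot=1)
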