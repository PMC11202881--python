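"""Open-system (Lindblad) dynamics: generator structure, limits,
invariants along trajectories, observables."""

import numpy as np
import pytest
from scipy.linalg import expm

from qtrust.exceptions import ParameterError, ValidationError
from qtrust.lindblad import (
    OpenSystemParams,
    build_lindblad_rates,
    classical_master_generator,
    default_value_map,
    delegate_probability,
    evolve_density,
    initial_state,
    lindblad_superoperator,
    mean_delegation,
    validate_density,
)
from qtrust.markov import stationary_distribution


def small_params(**kw):
    base = dict(dim=4, mu_q=2.0, sigma_q=1.0, mu_m=0.5, sigma_m=1.5,
                alpha=0.3, time_scale=1.0)
    base.update(kw)
    return OpenSystemParams(**base)


def brute_force_dissipator(gamma: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Reference dissipator assembled operator by operator."""
    dim = gamma.shape[0]
    out = np.zeros_like(rho, dtype=complex)
    for i in range(dim):
        for j in range(dim):
            g = gamma[i, j]
            if g == 0:
                continue
            L = np.zeros((dim, dim))
            L[i, j] = 1.0
            anti = L.T @ L @ rho + rho @ L.T @ L
            out += g * (L @ rho @ L.conj().T - 0.5 * anti)
    return out


class TestRates:
    def test_symmetric_two_state_intensity_mode(self):
        params = OpenSystemParams(dim=2, mu_m=0.0, sigma_m=1.0,
                                  mu_q=0, sigma_q=1, alpha=0.5)
        gamma = build_lindblad_rates(params)
        assert gamma[0, 1] == gamma[1, 0] == 1.0
        assert gamma[0, 0] == gamma[1, 1] == 0.0

    def test_fitted_rate_values(self):
        gamma = build_lindblad_rates(OpenSystemParams(dim=4))
        assert gamma[1, 0] == pytest.approx(25.57)
        assert gamma[0, 1] == pytest.approx(13.67)

    def test_transition_eps_limit_recovers_intensity_mode(self):
        base = small_params()
        target = build_lindblad_rates(base)
        for eps in (1e-3, 1e-5):
            approx = build_lindblad_rates(
                base.with_updates(gamma_mode="transition_eps", epsilon=eps)
            )
            off = ~np.eye(base.dim, dtype=bool)
            assert np.max(np.abs(approx[off] - target[off])) < 10 * eps * target.max()

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            build_lindblad_rates(
                small_params(gamma_mode="transition_eps", epsilon=-0.1)
            )


class TestGenerator:
    def test_matches_brute_force_dissipator(self, rng):
        params = small_params(alpha=0.7)
        S = lindblad_superoperator(params).toarray()
        gamma = build_lindblad_rates(params)
        H = params.hamiltonian()
        psi = rng.normal(size=4) + 1j * rng.normal(size=4)
        psi /= np.linalg.norm(psi)
        rho = np.outer(psi, psi.conj())
        direct = (S @ rho.reshape(-1)).reshape(4, 4)
        expected = (
            -1j * (1 - params.alpha) * (H @ rho - rho @ H)
            + params.alpha * brute_force_dissipator(gamma, rho)
        )
        assert np.max(np.abs(direct - expected)) < 1e-12

    def test_alpha_zero_pure_commutator(self, rng):
        params = small_params(alpha=0.0)
        S = lindblad_superoperator(params).toarray()
        H = params.hamiltonian()
        rho = np.diag([0.4, 0.3, 0.2, 0.1]).astype(complex)
        direct = (S @ rho.reshape(-1)).reshape(4, 4)
        assert np.allclose(direct, -1j * (H @ rho - rho @ H), atol=1e-12)

    def test_alpha_one_diagonal_master_equation(self):
        params = small_params(alpha=1.0)
        S = lindblad_superoperator(params).toarray()
        gamma = build_lindblad_rates(params)
        p = np.array([0.1, 0.2, 0.3, 0.4])
        rho = np.diag(p).astype(complex)
        drho = (S @ rho.reshape(-1)).reshape(4, 4)
        expected = gamma @ p - gamma.sum(axis=0) * p
        assert np.allclose(np.real(np.diag(drho)), expected, atol=1e-12)

    def test_trace_of_flow_vanishes(self, rng):
        params = small_params(alpha=0.4)
        S = lindblad_superoperator(params).toarray()
        for _ in range(5):
            A = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
            rho = A @ A.conj().T
            rho /= np.trace(rho)
            drho = (S @ rho.reshape(-1)).reshape(4, 4)
            assert abs(np.trace(drho)) < 1e-10


class TestInitialState:
    def test_no_choice_uniform_superposition(self):
        rho = initial_state("no_choice", 9)
        assert np.allclose(rho, 1.0 / 9)
        validate_density(rho)
        # pure state
        assert np.real(np.trace(rho @ rho)) == pytest.approx(1.0)

    def test_choice_dephased_uniform(self):
        rho = initial_state("choice", 9)
        assert np.allclose(np.diag(rho), 1.0 / 9)
        assert np.allclose(rho - np.diag(np.diag(rho)), 0.0)
        validate_density(rho)

    def test_both_start_at_midpoint_delegation(self):
        for condition in ("choice", "no_choice"):
            rho = initial_state(condition, 9)
            assert mean_delegation(rho) == pytest.approx(50.0)

    def test_custom_post_choice_distribution(self):
        p = np.array([0.7, 0.2, 0.1, 0.0])
        rho = initial_state("choice", 4, p)
        assert np.allclose(np.diag(rho), p)


class TestObservables:
    def test_uniform_diagonal_linear_map(self):
        rho = np.eye(5, dtype=complex) / 5
        assert mean_delegation(rho) == pytest.approx(50.0)

    def test_top_state_full_delegation(self):
        rho = np.zeros((5, 5), dtype=complex)
        rho[4, 4] = 1.0
        assert mean_delegation(rho) == pytest.approx(100.0)

    def test_matches_brute_force_weighted_sum(self, rng):
        A = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        rho = A @ A.conj().T
        rho /= np.trace(rho)
        vals = rng.uniform(0, 100, size=6)
        brute = sum(vals[k] * np.real(rho[k, k]) for k in range(6))
        assert mean_delegation(rho, vals) == pytest.approx(brute)

    def test_delegate_probability_tail_sum(self, rng):
        dim = 21
        A = rng.normal(size=(dim, dim))
        rho = A @ A.T
        rho = rho.astype(complex) / np.trace(rho)
        vals = default_value_map(dim)
        # first lattice state whose value reaches the 75 cutoff
        threshold_state = int(np.argmax(vals >= 75.0))
        assert vals[threshold_state] == 75.0
        brute = float(np.sum(np.real(np.diag(rho))[threshold_state:]))
        assert delegate_probability(rho, threshold_state) == pytest.approx(brute)
        assert delegate_probability(rho, 0) == pytest.approx(1.0)
        assert delegate_probability(rho, dim) == pytest.approx(0.0)


class TestEvolution:
    def test_pure_quantum_conserves_purity(self):
        params = small_params(alpha=0.0, dim=6)
        rho0 = initial_state("no_choice", 6)
        traj = evolve_density(rho0, params, np.linspace(0, 3, 10))
        for rho in traj.states:
            assert np.real(np.trace(rho @ rho)) == pytest.approx(1.0, abs=1e-8)

    def test_classical_limit_matches_master_equation(self):
        params = small_params(alpha=1.0, dim=5)
        rho0 = initial_state("choice", 5)
        times = np.linspace(0, 2, 6)
        traj = evolve_density(rho0, params, times)
        gen = classical_master_generator(build_lindblad_rates(params))
        p0 = np.real(np.diag(rho0))
        for t, rho in zip(times, traj.states):
            expected = expm(gen * t) @ p0
            assert np.max(np.abs(np.real(np.diag(rho)) - expected)) < 1e-8

    def test_decoherence_kills_off_diagonals(self):
        params = OpenSystemParams(dim=2, mu_q=0.0, sigma_q=1.0, mu_m=0.0,
                                  sigma_m=1.0, alpha=1.0, time_scale=1.0)
        psi = np.array([1.0, 1.0]) / np.sqrt(2)
        rho0 = np.outer(psi, psi).astype(complex)
        times = np.linspace(0, 10, 11)
        traj = evolve_density(rho0, params, times)
        offs = [abs(rho[0, 1]) for rho in traj.states]
        assert all(b <= a + 1e-12 for a, b in zip(offs, offs[1:]))
        assert offs[-1] < 1e-3

    def test_invariants_hold_along_trajectory(self):
        params = OpenSystemParams()  # fitted defaults, dim 21
        rho0 = initial_state("no_choice", params.dim)
        times = np.array([5, 10, 15, 20, 25, 30, 35]) * params.time_scale
        traj = evolve_density(rho0, params, times)
        for rho in traj.states:
            validate_density(rho)
        assert np.all(traj.mean_delegation >= 0)
        assert np.all(traj.mean_delegation <= 100)

    def test_steady_state_of_classical_flow_is_stationary_distribution(self):
        params = small_params(alpha=1.0, dim=5)
        rho0 = initial_state("no_choice", 5)
        traj = evolve_density(rho0, params, [0.0, 50.0])
        gamma = build_lindblad_rates(params)
        pi = stationary_distribution(classical_master_generator(gamma))
        assert np.max(np.abs(np.real(np.diag(traj.states[-1])) - pi)) < 1e-8

    def test_intermediate_alpha_oscillation_decays_to_steady_state(self):
        params = small_params(alpha=0.3, dim=5, mu_q=1.0, sigma_q=2.0)
        rho0 = initial_state("no_choice", 5)
        times = np.linspace(0, 40, 200)
        traj = evolve_density(rho0, params, times)
        m = traj.mean_delegation
        early_amp = np.ptp(m[:50])
        late_amp = np.ptp(m[-50:])
        assert late_amp < 0.05 * early_amp  # oscillation dissipates

    def test_pure_quantum_mean_oscillates(self):
        params = small_params(alpha=0.0, dim=5, mu_q=1.0, sigma_q=2.0)
        rho0 = initial_state("no_choice", 5)
        times = np.linspace(0, 10, 100)
        traj = evolve_density(rho0, params, times)
        diffs = np.diff(traj.mean_delegation)
        assert np.any(diffs > 1e-6) and np.any(diffs < -1e-6)

    def test_invalid_grid_rejected(self):
        params = small_params()
        rho0 = initial_state("choice", 4)
        with pytest.raises(ValidationError):
            evolve_density(rho0, params, [])
        with pytest.raises(ValidationError):
            evolve_density(rho0, params, [1.0, 0.5])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha=1.5), dict(alpha=-0.1), dict(mu_m=5.0, sigma_m=1.0),
         dict(dim=1), dict(gamma_mode="bogus"), dict(time_scale=0.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            small_params(**kwargs)
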