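"""Open-system (GKSL/Lindblad) model of delegation-strength dynamics.

The model interpolates between the quantum and classical random walks on
a delegation-strength lattice with a single master equation,

    d rho / dt = -i (1 - alpha) [H, rho] + alpha * L(rho),

where H is the tridiagonal Hamiltonian of :mod:`qtrust.quantum`, L is a
Lindblad dissipator built from elementary jump operators
``L_ij = |i><j|`` with non-negative rates ``gamma_ij``, and
``alpha in [0, 1]`` weighs the regimes: alpha = 0 is pure unitary
(quantum walk, oscillatory, purity-conserving) dynamics and alpha = 1 is
the classical Markov master equation on the diagonal of rho.  The jump
rates come from the classical intensity matrix, either directly
(``gamma_mode="intensity"``: gamma_ij = K_ij for i != j) or through a
short-time transition matrix (``gamma_mode="transition_eps"``:
gamma_ij = T_ij(eps) / eps, whose eps -> 0 limit recovers the
intensity-mode off-diagonal rates).

State = density matrix rho (Hermitian, unit trace, positive
semidefinite); the behavioral observable is the mean delegation strength
under a linear 0-100 value map over the lattice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .exceptions import NumericalFailureError, ParameterError, ValidationError
from .markov import build_intensity_matrix
from .quantum import build_hamiltonian

#: Default lattice dimension for delegation-strength dynamics.
DEFAULT_DIM = 21

HERMITICITY_TOL = 1e-10
TRACE_TOL = 1e-9
POSITIVITY_TOL = 1e-8


@dataclass(frozen=True)
class OpenSystemParams:
    """Parameter bundle for the interpolated open-system model.

    Parameters
    ----------
    dim : int
        Lattice dimension (number of delegation-strength states).
    mu_q : float
        Slope of the linear Hamiltonian drift potential mu_Q(x) = mu_q * x.
    sigma_q : float
        Hamiltonian off-diagonal coupling (quantum diffusion).
    mu_m, sigma_m : float
        Drift and diffusion rates of the classical intensity matrix;
        requires ``sigma_m >= |mu_m|`` for non-negative jump rates.
    alpha : float
        Regime weight in [0, 1]: 0 = fully quantum, 1 = fully Markov.
    epsilon : float
        Short-time step for ``gamma_mode="transition_eps"``.
    time_scale : float
        Multiplier mapping experiment seconds to model time before
        propagation.  The fitted drift/diffusion magnitudes imply a model
        time unit much finer than an experiment second; the default 0.01
        places the 5-35 s probe window inside the dynamically
        informative range.
    gamma_mode : str
        ``"intensity"`` or ``"transition_eps"``.
    """

    dim: int = DEFAULT_DIM
    mu_q: float = 390.45
    sigma_q: float = 30.12
    mu_m: float = 5.95
    sigma_m: float = 19.62
    alpha: float = 0.21
    epsilon: float = 0.01
    time_scale: float = 0.01
    gamma_mode: str = "intensity"

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ParameterError("dim must be at least 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must lie in [0, 1]")
        if self.sigma_m < abs(self.mu_m):
            raise ParameterError("sigma_m must be >= |mu_m|")
        if self.gamma_mode not in ("intensity", "transition_eps"):
            raise ParameterError(f"unknown gamma_mode {self.gamma_mode!r}")
        if self.time_scale <= 0:
            raise ParameterError("time_scale must be positive")

    def with_updates(self, **kwargs) -> "OpenSystemParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def hamiltonian(self) -> np.ndarray:
        return build_hamiltonian(self.dim, self.mu_q, self.sigma_q)

    def intensity(self) -> np.ndarray:
        return build_intensity_matrix(self.dim, self.mu_m, self.sigma_m)


@dataclass(frozen=True)
class DensityTrajectory:
    """Propagated open-system states on a time grid with the mean
    delegation-strength observable (0-100 scale)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, dim, dim) complex
    mean_delegation: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def validate_density(rho: np.ndarray, context: str = "") -> None:
    """Enforce Hermiticity, unit trace and positive semidefiniteness."""
    where = f" {context}" if context else ""
    if np.max(np.abs(rho - rho.conj().T)) > HERMITICITY_TOL:
        raise ValidationError(f"density matrix not Hermitian{where}")
    if abs(np.trace(rho).real - 1.0) > TRACE_TOL or abs(np.trace(rho).imag) > TRACE_TOL:
        raise ValidationError(f"density matrix trace != 1{where}")
    w = np.linalg.eigvalsh((rho + rho.conj().T) / 2.0)
    if w.min() < -POSITIVITY_TOL:
        raise ValidationError(
            f"density matrix not positive semidefinite (min eig {w.min():.2e}){where}"
        )


def build_lindblad_rates(params: OpenSystemParams) -> np.ndarray:
    """Jump-rate matrix gamma (dim x dim, zero diagonal).

    ``gamma[i, j]`` is the rate of the elementary jump ``|i><j|``.  In
    ``"intensity"`` mode the off-diagonal entries of the classical
    intensity matrix are used directly (they are non-negative by
    construction); in ``"transition_eps"`` mode ``gamma = T(eps)/eps``
    with the diagonal zeroed, which converges to intensity mode as
    eps -> 0.
    """
    K = params.intensity()
    if params.gamma_mode == "intensity":
        gamma = np.where(K > 0, K, 0.0)
    else:
        if params.epsilon <= 0:
            raise ParameterError("epsilon must be positive in transition_eps mode")
        gamma = la.expm(K * params.epsilon) / params.epsilon
    np.fill_diagonal(gamma, 0.0)
    return gamma


def lindblad_superoperator(params: OpenSystemParams) -> sp.csr_matrix:
    """Vectorized generator of the interpolated master equation.

    Acts on row-major vectorized density matrices:
    ``vec(d rho/dt) = S @ vec(rho)`` with
    ``S = -i (1-alpha) (H (x) I - I (x) H^T) + alpha * D`` where the
    dissipator D for elementary jumps reduces to

        (D rho)_ab = -1/2 (r_a + r_b) rho_ab + delta_ab sum_j gamma_aj rho_jj

    with total exit rates ``r_j = sum_i gamma_ij``.
    """
    dim = params.dim
    alpha = params.alpha
    H = sp.csr_matrix(params.hamiltonian())
    eye = sp.identity(dim, format="csr")
    S = sp.csr_matrix((dim * dim, dim * dim), dtype=complex)
    if alpha < 1.0:
        S = S + (-1j * (1.0 - alpha)) * (sp.kron(H, eye) - sp.kron(eye, H.T))
    if alpha > 0.0:
        gamma = build_lindblad_rates(params)
        r = gamma.sum(axis=0)  # exit rate of each source state
        a_idx, b_idx = np.divmod(np.arange(dim * dim), dim)
        decay = sp.diags(-0.5 * (r[a_idx] + r[b_idx]))
        # gain: (a, a) <- (j, j) with rate gamma[a, j]
        rows = np.repeat(np.arange(dim) * dim + np.arange(dim), dim)
        cols = np.tile(np.arange(dim) * dim + np.arange(dim), dim)
        gain = sp.csr_matrix(
            (gamma.ravel(), (rows, cols)), shape=(dim * dim, dim * dim)
        )
        S = S + alpha * (decay + gain)
    return sp.csr_matrix(S)


def initial_state(
    condition: str,
    dim: int = DEFAULT_DIM,
    post_choice_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Initial density matrix for a condition.

    ``"no_choice"``: the intermediate judgment is never elicited, so the
    state is the *pure* uniform superposition (all entries 1/dim) --
    ontic uncertainty is maintained.  ``"choice"``: the judgment resolves
    the superposition, leaving a dephased diagonal mixture carrying
    ``post_choice_distribution`` (default uniform) -- only epistemic
    uncertainty remains.
    """
    if condition not in ("choice", "no_choice"):
        raise ValidationError(f"unknown condition {condition!r}")
    if condition == "no_choice":
        psi = np.full(dim, 1.0 / np.sqrt(dim), dtype=complex)
        return np.outer(psi, psi.conj())
    if post_choice_distribution is None:
        p = np.full(dim, 1.0 / dim)
    else:
        p = np.asarray(post_choice_distribution, dtype=float)
        if p.shape != (dim,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("post_choice_distribution must be a probability vector")
    return np.diag(p).astype(complex)


def default_value_map(dim: int) -> np.ndarray:
    """Linear 0-100 delegation-strength values over the lattice."""
    return np.linspace(0.0, 100.0, dim)


def mean_delegation(rho: np.ndarray, value_map: np.ndarray | None = None) -> float:
    """Expected delegation strength ``sum_k value_map[k] * rho_kk``."""
    dim = rho.shape[0]
    if value_map is None:
        value_map = default_value_map(dim)
    value_map = np.asarray(value_map, dtype=float)
    if value_map.shape != (dim,):
        raise ValidationError("value_map length must match dim")
    return float(np.real(np.diag(rho)) @ value_map)


def delegate_probability(rho: np.ndarray, threshold_state: int) -> float:
    """Probability mass at or above a lattice threshold state."""
    dim = rho.shape[0]
    if not 0 <= threshold_state <= dim:
        raise ValidationError(f"threshold_state {threshold_state} out of range")
    return float(np.sum(np.real(np.diag(rho))[threshold_state:]))


def evolve_density(
    rho0: np.ndarray,
    params: OpenSystemParams,
    times: Sequence[float],
    value_map: np.ndarray | None = None,
    validate: bool = True,
) -> DensityTrajectory:
    """Propagate the master equation on a model-time grid.

    Uses the eigendecomposition of the vectorized generator, so the cost
    of additional time points is negligible once the generator is
    decomposed.  ``times`` are model-time values (already scaled); they
    must be non-negative and increasing.

    Raises
    ------
    NumericalFailureError
        If a propagated state violates the density-matrix invariants
        beyond tolerance, reporting the offending time.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValidationError("times must be non-empty, non-negative, increasing")
    dim = params.dim
    if rho0.shape != (dim, dim):
        raise ValidationError("rho0 shape does not match params.dim")
    validate_density(rho0, "at t=0")
    S = lindblad_superoperator(params).toarray()
    w, V = la.eig(S)
    c = la.solve(V, rho0.reshape(-1))
    if value_map is None:
        value_map = default_value_map(dim)
    states = np.empty((len(times), dim, dim), dtype=complex)
    means = np.empty(len(times))
    for i, t in enumerate(times):
        vec = V @ (np.exp(w * t) * c)
        rho = vec.reshape(dim, dim)
        if validate:
            try:
                validate_density(rho, f"at t={t:g}")
            except ValidationError as exc:
                raise NumericalFailureError(str(exc)) from exc
        states[i] = (rho + rho.conj().T) / 2.0  # scrub eig round-off asymmetry
        means[i] = mean_delegation(rho, value_map)
    return DensityTrajectory(times=times, states=states, mean_delegation=means)


def classical_master_generator(gamma: np.ndarray) -> np.ndarray:
    """Generator of the diagonal (populations-only) master equation,
    ``d p_k/dt = sum_j gamma_kj p_j - (sum_i gamma_ik) p_k`` -- the
    classical limit the alpha = 1 flow must reproduce."""
    gen = gamma.copy().astype(float)
    np.fill_diagonal(gen, 0.0)
    gen[np.diag_indices(gen.shape[0])] = -gen.sum(axis=0)
    return gen
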