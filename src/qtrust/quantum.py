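"""Quantum random-walk models: amplitudes, unitary propagation, and the
law of total amplitude.

The quantum counterpart of the Markov model replaces probabilities with
complex amplitudes and the intensity matrix with a Hermitian Hamiltonian
H (tridiagonal: diagonal drift potential mu_Q(x) = a*x + b*x^2 + c,
off-diagonal coupling sigma_Q).  Evolution is unitary, U(t) = exp(-iHt),
and the squared magnitudes |U_ij|^2 form a *doubly* stochastic transition
matrix -- the quantum analogue of the Markov model's column
stochasticity.

When no intermediate judgment is made the state remains a superposition
over agree/disagree, and the delegation probability picks up a cross
term: the law of total amplitude

    Pr(D) = p_A Pr(D|A) + p_Dis Pr(D|Dis) + 2 phi_A phi_Dis |<D|A>..| cos(theta).

A nonzero interference phase cos(theta) violates the law of total
probability, which is exactly the empirical signature in the behavioral
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import InfeasibleInterferenceError, ValidationError
from .markov import delegate_projector
from .stats import ConditionTable

#: Basis order of the 4-state joint model (same as the Markov model).
STATE_ORDER_4 = ("agree_delegate", "agree_not", "disagree_delegate", "disagree_not")


@dataclass(frozen=True)
class InterferenceResult:
    """Decomposition of a decision-only delegation probability into its
    classical total-probability part and the interference term."""

    probability: float
    classical_part: float
    interference: float
    cos_theta: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.probability <= 1 + 1e-9:
            raise ValidationError("probability must lie in [0, 1]")
        if abs(self.classical_part + self.interference - self.probability) > 1e-9:
            raise ValidationError("decomposition does not sum to the probability")


def build_hamiltonian(
    dim: int,
    drift_a: float,
    sigma_q: float,
    drift_b: float = 0.0,
    drift_c: float = 0.0,
) -> np.ndarray:
    """Tridiagonal Hermitian Hamiltonian on a ``dim``-state lattice.

    Diagonal entries are the drift potential ``mu_Q(x) = a x + b x^2 + c``
    for lattice coordinate x = 1..dim (larger x = higher delegation
    strength); off-diagonals are the coupling ``sigma_q``.
    """
    if dim < 2:
        raise ValidationError("dim must be at least 2")
    x = np.arange(1, dim + 1, dtype=float)
    H = np.diag(drift_a * x + drift_b * x**2 + drift_c)
    idx = np.arange(dim - 1)
    H[idx, idx + 1] = sigma_q
    H[idx + 1, idx] = sigma_q
    return H


def unitary_propagator(H: np.ndarray, t: float) -> np.ndarray:
    """Unitary propagator ``U(t) = exp(-i H t)`` (negative t allowed)."""
    if np.max(np.abs(H - H.conj().T)) > 1e-12:
        raise ValidationError("H must be Hermitian")
    return expm(-1j * H * float(t))


def transition_from_unitary(U: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Doubly stochastic transition matrix ``T_ij = |U_ij|^2``."""
    eye = np.eye(U.shape[0])
    if np.max(np.abs(U.conj().T @ U - eye)) > tol:
        raise ValidationError("input is not unitary within tolerance")
    return np.abs(U) ** 2


def law_of_total_amplitude(
    phi_a: float,
    phi_dis: float,
    u_da: complex,
    u_ddisa: complex,
    cos_theta: float,
) -> InterferenceResult:
    """Delegation probability under superposed agree/disagree amplitudes.

    ``phi_a``, ``phi_dis`` are real amplitudes with
    ``phi_a**2 + phi_dis**2 = 1``; ``u_da``, ``u_ddisa`` the transition
    amplitudes into the delegate state; ``cos_theta`` the relative
    interference phase.
    """
    if abs(phi_a**2 + phi_dis**2 - 1.0) > 1e-9:
        raise ValidationError("phi_a^2 + phi_dis^2 must equal 1")
    if not -1.0 <= cos_theta <= 1.0:
        raise ValidationError("cos_theta must lie in [-1, 1]")
    classical = phi_a**2 * abs(u_da) ** 2 + phi_dis**2 * abs(u_ddisa) ** 2
    interference = 2.0 * phi_dis * abs(u_ddisa) * phi_a * abs(u_da) * cos_theta
    probability = classical + interference
    if not -1e-9 <= probability <= 1 + 1e-9:
        raise InfeasibleInterferenceError(
            f"amplitudes are inconsistent: probability {probability} outside [0, 1]"
        )
    return InterferenceResult(
        probability=float(np.clip(probability, 0.0, 1.0)),
        classical_part=float(classical),
        interference=float(probability - classical),
        cos_theta=float(cos_theta),
    )


def solve_interference_phase(table: ConditionTable) -> float:
    """Back-solve cos(theta) from an observed probability row.

    The 2-level quantum parameterization has a single free parameter, the
    interference phase; it is identified by

        cos(theta) = violation / (2 sqrt(Pr(A) Pr(D|A) Pr(Dis) Pr(D|Dis))).

    Raises :class:`InfeasibleInterferenceError` if the observed violation
    exceeds what any phase can produce.
    """
    probs = (
        table.pr_agree,
        table.pr_del_given_agree,
        table.pr_disagree,
        table.pr_del_given_dis,
    )
    if not all(0.0 < p < 1.0 for p in probs):
        raise ValidationError(
            "all conditional/marginal probabilities must be strictly inside (0, 1)"
        )
    denom = 2.0 * np.sqrt(np.prod(probs))
    cos_theta = (table.pr_del_nochoice - table.tp_del) / denom
    if abs(cos_theta) > 1.0:
        raise InfeasibleInterferenceError(
            f"observed violation requires |cos theta| = {abs(cos_theta):.4f} > 1"
        )
    return float(cos_theta)


def _initial_choice_amplitudes(choice: str, amplitudes=None) -> np.ndarray:
    """Initial 4-state amplitude vector after an agree/disagree judgment."""
    if choice not in ("agree", "disagree"):
        raise ValidationError(f"choice must be 'agree' or 'disagree', got {choice!r}")
    amp = (
        np.asarray([1.0, 1.0], dtype=complex) / np.sqrt(2.0)
        if amplitudes is None
        else np.asarray(amplitudes, dtype=complex)
    )
    if amp.shape != (2,) or abs(np.sum(np.abs(amp) ** 2) - 1.0) > 1e-9:
        raise ValidationError("amplitudes must be a normalized length-2 vector")
    phi = np.zeros(4, dtype=complex)
    if choice == "agree":
        phi[0], phi[1] = amp
    else:
        phi[2], phi[3] = amp
    return phi


def delegate_prob_given_choice_q(
    U: np.ndarray,
    choice: str,
    projector: np.ndarray | None = None,
    amplitudes=None,
) -> float:
    """Pr(delegate | choice) for the 4-state quantum model:
    ``|| M_D U(t) Phi_choice ||^2``."""
    if projector is None:
        projector = delegate_projector()
    if U.shape != (4, 4) or projector.shape != (4, 4):
        raise ValidationError("U and projector must both be 4x4")
    phi0 = _initial_choice_amplitudes(choice, amplitudes)
    out = projector @ (U @ phi0)
    return float(np.sum(np.abs(out) ** 2))


def delegate_prob_decision_only_q(
    U: np.ndarray,
    phi_agree: float,
    projector: np.ndarray | None = None,
    amplitudes_agree=None,
    amplitudes_disagree=None,
) -> InterferenceResult:
    """Decision-only quantum prediction with its interference
    decomposition.

    The initial state is the maintained superposition
    ``phi_agree * Phi_A + phi_dis * Phi_Dis`` with
    ``phi_dis = sqrt(1 - phi_agree^2)`` (real, non-negative amplitudes by
    convention: all relative phase lives in the propagated vectors).  The
    probability is computed directly as ``|| M_D U Phi_init ||^2`` and
    decomposed as classical part + interference; the two routes agree to
    numerical precision by construction.
    """
    if not 0.0 <= phi_agree <= 1.0:
        raise ValidationError("phi_agree must lie in [0, 1]")
    if projector is None:
        projector = delegate_projector()
    phi_dis = float(np.sqrt(max(0.0, 1.0 - phi_agree**2)))
    phi_a4 = _initial_choice_amplitudes("agree", amplitudes_agree)
    phi_d4 = _initial_choice_amplitudes("disagree", amplitudes_disagree)
    out_a = projector @ (U @ phi_a4)
    out_d = projector @ (U @ phi_d4)
    direct = float(
        np.sum(np.abs(phi_agree * out_a + phi_dis * out_d) ** 2)
    )
    p_da = float(np.sum(np.abs(out_a) ** 2))
    p_ddis = float(np.sum(np.abs(out_d) ** 2))
    classical = phi_agree**2 * p_da + phi_dis**2 * p_ddis
    cross = complex(np.vdot(out_a, out_d))
    interference = 2.0 * phi_agree * phi_dis * float(np.real(cross))
    magnitude = 2.0 * phi_agree * phi_dis * abs(cross)
    cos_theta = 0.0 if magnitude == 0.0 else interference / magnitude
    if abs(direct - (classical + interference)) > 1e-9:
        raise ValidationError("interference decomposition failed to close")
    return InterferenceResult(
        probability=direct,
        classical_part=float(classical),
        interference=float(interference),
        cos_theta=float(np.clip(cos_theta, -1.0, 1.0)),
    )
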