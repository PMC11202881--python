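"""Classical continuous-time Markov models of the delegation process.

Two uses: the 4-state joint choice/decision model over the basis
(|agree, delegate>, |agree, not>, |disagree, delegate>, |disagree, not>),
and birth-death random walks on a delegation-strength lattice.  Both are
driven by a tridiagonal intensity matrix K with drift mu_M (net pull
toward higher delegation states) and diffusion sigma_M; the transition
matrix is the matrix exponential T(t) = exp(K t), column-stochastic and
satisfying the Chapman-Kolmogorov semigroup property.

A key structural fact: because the decision-only prediction is a convex
mixture of the two conditional predictions, the Markov model satisfies
the law of total probability identically and can never produce the
violations seen in the behavioral tables.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .exceptions import ParameterError, ValidationError

#: Basis order of the 4-state joint model.
STATE_ORDER_4 = ("agree_delegate", "agree_not", "disagree_delegate", "disagree_not")

#: Indices of delegate-compatible states in that order.
DELEGATE_STATES_4 = (0, 2)


def build_intensity_matrix(dim: int, mu_m: float, sigma_m: float) -> np.ndarray:
    """Tridiagonal intensity matrix on a ``dim``-state lattice.

    Sub-diagonal rates ``sigma_m + mu_m`` carry probability toward higher
    delegation states (higher row index); super-diagonal rates
    ``sigma_m - mu_m`` carry it back.  Diagonals are the negated column
    sums, so every column sums to zero.

    Requires ``sigma_m >= |mu_m|`` so all off-diagonal rates are
    non-negative.
    """
    if dim < 2:
        raise ParameterError("dim must be at least 2")
    if sigma_m < abs(mu_m):
        raise ParameterError(
            f"sigma_m ({sigma_m}) must be >= |mu_m| ({abs(mu_m)}); "
            "otherwise off-diagonal rates would be negative"
        )
    K = np.zeros((dim, dim))
    idx = np.arange(dim - 1)
    K[idx + 1, idx] = sigma_m + mu_m
    K[idx, idx + 1] = sigma_m - mu_m
    K[np.diag_indices(dim)] = -K.sum(axis=0)
    return K


def validate_intensity(K: np.ndarray, tol: float = 1e-12) -> None:
    """Check off-diagonal non-negativity and zero column sums."""
    off = K - np.diag(np.diag(K))
    if np.any(off < -tol):
        raise ValidationError("intensity matrix has negative off-diagonal entries")
    if np.max(np.abs(K.sum(axis=0))) > 1e-9:
        raise ValidationError("intensity matrix columns must sum to 0")


def transition_matrix(K: np.ndarray, t: float) -> np.ndarray:
    """Column-stochastic transition matrix ``T(t) = exp(K t)``."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    validate_intensity(K)
    return expm(K * float(t))


def delegate_projector(dim: int = 4, delegate_states=DELEGATE_STATES_4) -> np.ndarray:
    """Diagonal 0/1 mask selecting delegate-compatible states."""
    mask = np.zeros(dim)
    mask[list(delegate_states)] = 1.0
    return np.diag(mask)


def _initial_choice_vector(choice: str, weights=None) -> np.ndarray:
    """Initial 4-state probability vector after an agree/disagree judgment.

    The judgment confines probability to the matching pair of joint
    states; ``weights`` splits it between delegate/not (default uniform).
    """
    if choice not in ("agree", "disagree"):
        raise ValidationError(f"choice must be 'agree' or 'disagree', got {choice!r}")
    w = np.asarray([0.5, 0.5] if weights is None else weights, dtype=float)
    if w.shape != (2,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must be a length-2 probability vector")
    p = np.zeros(4)
    if choice == "agree":
        p[0], p[1] = w
    else:
        p[2], p[3] = w
    return p


def delegate_prob_given_choice(
    T: np.ndarray, choice: str, projector: np.ndarray | None = None, weights=None
) -> float:
    """Pr(delegate | choice) for the 4-state model: sum over delegate
    states of ``T(t) @ p_choice``."""
    if projector is None:
        projector = delegate_projector()
    if T.shape != (4, 4) or projector.shape != (4, 4):
        raise ValidationError("T and projector must both be 4x4")
    p0 = _initial_choice_vector(choice, weights)
    return float(np.sum(projector @ T @ p0))


def delegate_prob_decision_only(
    T: np.ndarray,
    p_agree: float,
    projector: np.ndarray | None = None,
    weights_agree=None,
    weights_disagree=None,
) -> float:
    """Decision-only Markov prediction: the convex mixture
    ``p_agree * Pr(D|A) + (1 - p_agree) * Pr(D|Dis)``.

    By construction this satisfies the law of total probability exactly;
    the classical model predicts zero interference.
    """
    if not 0.0 <= p_agree <= 1.0:
        raise ValidationError("p_agree must lie in [0, 1]")
    pa = delegate_prob_given_choice(T, "agree", projector, weights_agree)
    pd_ = delegate_prob_given_choice(T, "disagree", projector, weights_disagree)
    return p_agree * pa + (1.0 - p_agree) * pd_


def stationary_distribution(K: np.ndarray) -> np.ndarray:
    """Stationary probability vector of the chain generated by ``K``."""
    w, v = np.linalg.eig(K)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def mean_state_trajectory(
    K: np.ndarray,
    p0: np.ndarray,
    times: np.ndarray,
    state_values: np.ndarray,
) -> np.ndarray:
    """Mean of ``state_values`` under ``T(t) @ p0`` on a time grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("time grid must be non-empty")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValidationError("time grid must be non-negative and increasing")
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValidationError("p0 must be a probability vector")
    state_values = np.asarray(state_values, dtype=float)
    if state_values.shape[0] != K.shape[0]:
        raise ValidationError("state_values length must match dim")
    out = np.empty(times.shape)
    for i, t in enumerate(times):
        out[i] = float(state_values @ (transition_matrix(K, t) @ p0))
    return out
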