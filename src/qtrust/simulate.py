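"""Synthetic trial generator emulating the two-stage delegation study.

The study design: two between-subject conditions (choice vs. no-choice)
crossed with seven enforced response times (5-35 s); each participant
completes 21 imagery-screening trials (three per timing); the simulated
AI is calibrated to 48% accuracy across a participant's trials; ratings
come from a bimodal 0-100 slider with most delegation-leaning mass above
55.  Ratings are drawn from a two-component truncated-normal mixture
whose component weight is solved per cell so that the probability of a
rating at or above the delegation threshold (75) matches the requested
conditional probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@lru_cache(maxsize=64)
def _frozen_truncnorm(loc: float, scale: float):
    a, b = (0.0 - loc) / scale, (100.0 - loc) / scale
    return sps.truncnorm(a, b, loc=loc, scale=scale)

from .exceptions import ParameterError, ValidationError
from .lindblad import OpenSystemParams
from .fitting import predict_condition_means
from .stats import DEFAULT_THRESHOLD
from .trials import TIMINGS_S, TrialRecord

#: Observed per-timing probabilities from the delegation experiment the
#: generator emulates: choice-condition marginals and conditionals, plus
#: the no-choice delegation probability.  Used as the default generator
#: calibration.
REPORTED_CONDITION_PROBABILITIES: dict[int, dict[str, float]] = {
    5: {"pr_agree": 0.7097, "pr_del_given_agree": 0.5966,
        "pr_del_given_dis": 0.1389, "pr_del_nochoice": 0.4118},
    10: {"pr_agree": 0.8495, "pr_del_given_agree": 0.7089,
         "pr_del_given_dis": 0.2143, "pr_del_nochoice": 0.6097},
    15: {"pr_agree": 0.6231, "pr_del_given_agree": 0.6173,
         "pr_del_given_dis": 0.2143, "pr_del_nochoice": 0.4559},
    20: {"pr_agree": 0.6833, "pr_del_given_agree": 0.6042,
         "pr_del_given_dis": 0.2360, "pr_del_nochoice": 0.4926},
    25: {"pr_agree": 0.8566, "pr_del_given_agree": 0.7225,
         "pr_del_given_dis": 0.2895, "pr_del_nochoice": 0.6182},
    30: {"pr_agree": 0.8327, "pr_del_given_agree": 0.7143,
         "pr_del_given_dis": 0.1556, "pr_del_nochoice": 0.5941},
    35: {"pr_agree": 0.7907, "pr_del_given_agree": 0.6716,
         "pr_del_given_dis": 0.1296, "pr_del_nochoice": 0.5257},
}


@dataclass(frozen=True)
class RatingMixture:
    """Two-component truncated-normal mixture on the 0-100 slider.

    The low component models reluctant ratings, the high component
    delegation-leaning ones (placing the bimodal bulk above 55).
    """

    low_loc: float = 30.0
    low_scale: float = 16.0
    high_loc: float = 85.0
    high_scale: float = 10.0

    def __post_init__(self) -> None:
        for loc in (self.low_loc, self.high_loc):
            if not 0.0 <= loc <= 100.0:
                raise ParameterError("mixture modes must lie in [0, 100]")
        if self.low_scale < 0 or self.high_scale < 0:
            raise ParameterError("mixture scales must be non-negative")

    def _component(self, loc: float, scale: float):
        if scale == 0:
            return None
        return _frozen_truncnorm(loc, scale)

    def tail_mass(self, threshold: float = DEFAULT_THRESHOLD) -> tuple[float, float]:
        """P(rating >= threshold) under the (low, high) components."""
        masses = []
        for loc, scale in ((self.low_loc, self.low_scale),
                           (self.high_loc, self.high_scale)):
            comp = self._component(loc, scale)
            masses.append(float(comp.sf(threshold)) if comp is not None
                          else float(loc >= threshold))
        return masses[0], masses[1]

    def high_weight_for(self, p_delegate: float,
                        threshold: float = DEFAULT_THRESHOLD) -> float:
        """Mixture weight on the high component that yields the target
        delegation probability at the threshold."""
        p_lo, p_hi = self.tail_mass(threshold)
        if not p_lo - 1e-12 <= p_delegate <= p_hi + 1e-12:
            raise ParameterError(
                f"target P(delegate) = {p_delegate:.4f} infeasible for this "
                f"mixture (attainable range [{p_lo:.4f}, {p_hi:.4f}])"
            )
        if p_hi == p_lo:
            return 1.0
        return float(np.clip((p_delegate - p_lo) / (p_hi - p_lo), 0.0, 1.0))

    def draw(self, n: int, high_weight: float, rng: np.random.Generator) -> np.ndarray:
        use_high = rng.uniform(size=n) < high_weight
        out = np.empty(n)
        for is_high in (False, True):
            mask = use_high == is_high
            k = int(mask.sum())
            if k == 0:
                continue
            loc, scale = ((self.high_loc, self.high_scale) if is_high
                          else (self.low_loc, self.low_scale))
            comp = self._component(loc, scale)
            if comp is None:
                out[mask] = loc
            else:
                out[mask] = comp.rvs(size=k, random_state=rng)
        return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic study replicate.

    Defaults mirror the experiment: 96 participants per condition
    (N = 192), 21 trials each (three per timing), AI accuracy calibrated
    to 48% across trials, and the observed per-timing probabilities as
    generating values.
    """

    n_participants_per_condition: int = 96
    timings: tuple[int, ...] = TIMINGS_S
    trials_per_participant: int = 21
    ai_accuracy: float = 0.48
    condition_probabilities: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: REPORTED_CONDITION_PROBABILITIES
    )
    rating_mixture: RatingMixture = field(default_factory=RatingMixture)
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants_per_condition < 1:
            raise ParameterError("need at least one participant per condition")
        if not 0.0 <= self.ai_accuracy <= 1.0:
            raise ParameterError("ai_accuracy must lie in [0, 1]")
        if self.trials_per_participant % len(self.timings) != 0:
            raise ParameterError(
                "trials_per_participant must be a multiple of the number of timings"
            )
        for timing in self.timings:
            if timing not in self.condition_probabilities:
                raise ParameterError(f"no probabilities supplied for timing {timing}")
            cell = self.condition_probabilities[timing]
            for key in ("pr_agree", "pr_del_given_agree",
                        "pr_del_given_dis", "pr_del_nochoice"):
                p = cell[key]
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(f"{key} at {timing}s outside [0, 1]")
        # fail fast if any requested conditional is unreachable
        for timing in self.timings:
            cell = self.condition_probabilities[timing]
            for key in ("pr_del_given_agree", "pr_del_given_dis", "pr_del_nochoice"):
                self.rating_mixture.high_weight_for(cell[key], self.threshold)


def ai_stimulus_schedule(
    n_trials: int, accuracy: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Fixed-count accuracy schedule: ``round(accuracy * n_trials)``
    correct annotations in seeded random order."""
    if n_trials < 1:
        raise ValidationError("n_trials must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_correct = int(round(accuracy * n_trials))
    schedule = np.zeros(n_trials, dtype=bool)
    schedule[:n_correct] = True
    rng.shuffle(schedule)
    return schedule


def generate_trials(spec: GeneratorSpec) -> list[TrialRecord]:
    """Simulate a full study replicate (deterministic given the seed).

    Choice-condition participants draw an agree/disagree judgment per
    trial from the timing's marginal, then a rating whose delegation
    probability matches the corresponding conditional; no-choice
    participants draw ratings targeting the no-choice delegation
    probability.
    """
    rng = np.random.default_rng(spec.seed)
    n_part = spec.n_participants_per_condition
    per_timing = spec.trials_per_participant // len(spec.timings)
    mixture = spec.rating_mixture
    records: list[TrialRecord] = []
    for condition in ("choice", "no_choice"):
        pids = [f"{condition[:2]}{i:04d}" for i in range(n_part)]
        schedules = np.stack([
            ai_stimulus_schedule(spec.trials_per_participant, spec.ai_accuracy, rng)
            for _ in range(n_part)
        ])
        for t_idx, timing in enumerate(spec.timings):
            cell = spec.condition_probabilities[timing]
            n_cell = n_part * per_timing
            correct = schedules[
                :, t_idx * per_timing:(t_idx + 1) * per_timing
            ].reshape(-1)
            if condition == "choice":
                agree = rng.uniform(size=n_cell) < cell["pr_agree"]
                responses = np.where(agree, "agree", "disagree")
                ratings = np.empty(n_cell)
                for is_agree, key in ((True, "pr_del_given_agree"),
                                      (False, "pr_del_given_dis")):
                    mask = agree == is_agree
                    if mask.any():
                        w = mixture.high_weight_for(cell[key], spec.threshold)
                        ratings[mask] = mixture.draw(int(mask.sum()), w, rng)
            else:
                responses = np.full(n_cell, "acknowledge")
                w = mixture.high_weight_for(cell["pr_del_nochoice"], spec.threshold)
                ratings = mixture.draw(n_cell, w, rng)
            for k in range(n_cell):
                records.append(
                    TrialRecord(
                        participant_id=pids[k // per_timing],
                        condition=condition,
                        timing_s=timing,
                        response=str(responses[k]),
                        rating=float(ratings[k]),
                        stimulus_correct=bool(correct[k]),
                    )
                )
    return records


def generate_condition_means(
    params: OpenSystemParams,
    condition: str,
    timings_s: Sequence[float] = TIMINGS_S,
) -> np.ndarray:
    """Noiseless open-system mean delegation strengths at the experiment
    timings (model-generated ground truth for fitting tests)."""
    return predict_condition_means(params, condition, timings_s)
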