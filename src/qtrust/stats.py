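"""Behavioral probability pipeline: delegation binarization, per-timing
conditional probabilities, and the law-of-total-probability check.

For each enforced response time the choice-condition trials yield the
marginal agree/disagree proportions Pr(A), Pr(Dis) and the conditional
delegation probabilities Pr(Del|A), Pr(Del|Dis).  Classically these must
satisfy the law of total probability,

    TP(Del) = Pr(A) Pr(Del|A) + Pr(Dis) Pr(Del|Dis),

and TP(Del) must equal the delegation probability Pr(Del) observed in the
no-choice condition, where no intermediate judgment is elicited.  The
signed difference Pr(Del) - TP(Del) is the empirical interference term: a
nonzero value is a violation of total probability, which classical Markov
models cannot produce but quantum models attribute to unresolved
superposition over the agree/disagree basis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import EstimationError, ValidationError
from .trials import TrialRecord, records_to_frame

#: Rating cutoff at or above which a trial counts as a delegate decision.
DEFAULT_THRESHOLD = 75.0

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ConditionTable:
    """Pooled probabilities for one timing (one row of the results table).

    ``violation`` is signed: no-choice Pr(Del) minus the choice-condition
    total probability.
    """

    timing_s: int
    pr_agree: float
    pr_del_given_agree: float
    pr_disagree: float
    pr_del_given_dis: float
    tp_del: float
    pr_del_nochoice: float
    violation: float

    def __post_init__(self) -> None:
        probs = (
            self.pr_agree,
            self.pr_del_given_agree,
            self.pr_disagree,
            self.pr_del_given_dis,
            self.tp_del,
            self.pr_del_nochoice,
        )
        if not all(-_PROB_TOL <= p <= 1 + _PROB_TOL for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if abs(self.pr_agree + self.pr_disagree - 1.0) > 1e-9:
            raise ValidationError("pr_agree + pr_disagree must equal 1")
        expected_tp = (
            self.pr_agree * self.pr_del_given_agree
            + self.pr_disagree * self.pr_del_given_dis
        )
        if abs(self.tp_del - expected_tp) > 1e-9:
            raise ValidationError("tp_del inconsistent with its own fields")
        if abs(self.violation - (self.pr_del_nochoice - self.tp_del)) > 1e-9:
            raise ValidationError("violation must equal pr_del_nochoice - tp_del")


def binarize_delegation(rating: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff ``rating >= threshold`` (a rating of 75 counts as delegate)."""
    if not 0.0 <= rating <= 100.0:
        raise ValidationError(f"rating {rating!r} outside [0, 100]")
    return rating >= threshold


def total_probability(
    pr_agree: float,
    pr_del_given_agree: float,
    pr_disagree: float,
    pr_del_given_dis: float,
) -> float:
    """Law-of-total-probability prediction for the delegation probability."""
    if abs(pr_agree + pr_disagree - 1.0) > 1e-9:
        raise ValidationError("marginal probabilities must sum to 1")
    return pr_agree * pr_del_given_agree + pr_disagree * pr_del_given_dis


def tp_violation(table: ConditionTable) -> float:
    """Signed violation of total probability (empirical interference term)."""
    return table.pr_del_nochoice - table.tp_del


def pool_condition_table(
    trials: Iterable[TrialRecord],
    timing_s: int,
    threshold: float = DEFAULT_THRESHOLD,
    by_participant: bool = False,
) -> ConditionTable:
    """Estimate the per-timing probability row from pooled trials.

    By default all trials at the timing are pooled across participants
    (trial-level proportions).  ``by_participant=True`` instead averages
    per-participant proportions, an alternative aggregation for unbalanced
    designs.

    Raises
    ------
    EstimationError
        If any conditioning cell (agree, disagree, or no-choice trials at
        the timing) is empty.
    """
    frame = records_to_frame(trials)
    frame = frame[frame["timing_s"] == timing_s]
    choice = frame[frame["condition"] == "choice"]
    nochoice = frame[frame["condition"] == "no_choice"]
    if len(choice) == 0:
        raise EstimationError(f"no choice-condition trials at timing {timing_s}s")
    if len(nochoice) == 0:
        raise EstimationError(f"no no-choice trials at timing {timing_s}s")
    agree = choice[choice["response"] == "agree"]
    disagree = choice[choice["response"] == "disagree"]
    if len(agree) == 0:
        raise EstimationError(f"no agree trials at timing {timing_s}s")
    if len(disagree) == 0:
        raise EstimationError(f"no disagree trials at timing {timing_s}s")

    if by_participant:
        def prop(sub: pd.DataFrame) -> float:
            per = sub.groupby("participant_id", sort=False).apply(
                lambda g: float(np.mean(g["rating"] >= threshold)),
                include_groups=False,
            )
            return float(per.mean())

        pr_agree = float(
            choice.groupby("participant_id", sort=False)
            .apply(lambda g: float(np.mean(g["response"] == "agree")),
                   include_groups=False)
            .mean()
        )
        pr_del_given_agree = prop(agree)
        pr_del_given_dis = prop(disagree)
        pr_del_nochoice = prop(nochoice)
    else:
        pr_agree = float(np.mean(choice["response"] == "agree"))
        pr_del_given_agree = float(np.mean(agree["rating"] >= threshold))
        pr_del_given_dis = float(np.mean(disagree["rating"] >= threshold))
        pr_del_nochoice = float(np.mean(nochoice["rating"] >= threshold))

    pr_disagree = 1.0 - pr_agree
    tp = total_probability(pr_agree, pr_del_given_agree, pr_disagree, pr_del_given_dis)
    return ConditionTable(
        timing_s=timing_s,
        pr_agree=pr_agree,
        pr_del_given_agree=pr_del_given_agree,
        pr_disagree=pr_disagree,
        pr_del_given_dis=pr_del_given_dis,
        tp_del=tp,
        pr_del_nochoice=pr_del_nochoice,
        violation=pr_del_nochoice - tp,
    )


def condition_tables(
    trials: Sequence[TrialRecord],
    threshold: float = DEFAULT_THRESHOLD,
    by_participant: bool = False,
) -> list[ConditionTable]:
    """One :class:`ConditionTable` per timing present in ``trials``."""
    timings = sorted({t.timing_s for t in trials})
    return [
        pool_condition_table(trials, timing, threshold, by_participant)
        for timing in timings
    ]


def tables_to_frame(tables: Iterable[ConditionTable]) -> pd.DataFrame:
    """Results table as a DataFrame, one row per timing."""
    return pd.DataFrame([asdict(t) for t in tables])


def bootstrap_ci(
    trials: Sequence[TrialRecord],
    timing_s: int,
    statistic: Literal["tp_del", "violation"] = "violation",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a per-timing statistic.

    Participants (not trials) are resampled with replacement, preserving
    the within-participant trial structure.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    if statistic not in ("tp_del", "violation"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    at_timing = [t for t in trials if t.timing_s == timing_s]
    by_pid: dict[str, list[TrialRecord]] = {}
    for t in at_timing:
        by_pid.setdefault(t.participant_id, []).append(t)
    pids = sorted(by_pid)
    if len(pids) < 2:
        raise EstimationError("bootstrap requires at least 2 participants")
    # Resample within condition so both conditions survive every replicate.
    choice_pids = [p for p in pids if by_pid[p][0].condition == "choice"]
    nochoice_pids = [p for p in pids if by_pid[p][0].condition == "no_choice"]
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        resampled: list[TrialRecord] = []
        for pool in (choice_pids, nochoice_pids):
            if not pool:
                continue
            picks = rng.choice(len(pool), size=len(pool), replace=True)
            for k in picks:
                resampled.extend(by_pid[pool[k]])
        try:
            table = pool_condition_table(resampled, timing_s, threshold)
        except EstimationError:
            values[b] = np.nan
            continue
        values[b] = getattr(table, statistic)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise EstimationError("all bootstrap replicates had empty cells")
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo)),
        float(np.quantile(values, 1.0 - lo)),
    )
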