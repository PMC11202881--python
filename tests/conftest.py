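import numpy as np
import pytest

from qtrust.stats import ConditionTable, total_probability
from qtrust.simulate import REPORTED_CONDITION_PROBABILITIES
from qtrust.trials import TrialRecord


def make_condition_table(timing_s: int) -> ConditionTable:
    """Build a ConditionTable row from the reported per-timing
    probabilities, recomputing the internally consistent total
    probability from the four inputs."""
    cell = REPORTED_CONDITION_PROBABILITIES[timing_s]
    pr_agree = cell["pr_agree"]
    pr_dis = 1.0 - pr_agree
    tp = total_probability(
        pr_agree, cell["pr_del_given_agree"], pr_dis, cell["pr_del_given_dis"]
    )
    return ConditionTable(
        timing_s=timing_s,
        pr_agree=pr_agree,
        pr_del_given_agree=cell["pr_del_given_agree"],
        pr_disagree=pr_dis,
        pr_del_given_dis=cell["pr_del_given_dis"],
        tp_del=tp,
        pr_del_nochoice=cell["pr_del_nochoice"],
        violation=cell["pr_del_nochoice"] - tp,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240500)


@pytest.fixture
def hand_count_trials():
    """Small fixture with hand-countable proportions at the 5 s timing:
    10 choice trials (6 agree, 4 of them rated >= 75; 4 disagree, 1 rated
    >= 75) plus 4 no-choice trials (2 rated >= 75)."""
    records = []
    agree_ratings = [80, 90, 75, 76, 30, 40]          # 4 of 6 delegate
    disagree_ratings = [85, 10, 20, 74.99]            # 1 of 4 delegates
    nochoice_ratings = [90, 75, 50, 10]               # 2 of 4 delegate
    for i, r in enumerate(agree_ratings):
        records.append(TrialRecord(f"c{i}", "choice", 5, "agree", r))
    for i, r in enumerate(disagree_ratings):
        records.append(TrialRecord(f"d{i}", "choice", 5, "disagree", r))
    for i, r in enumerate(nochoice_ratings):
        records.append(TrialRecord(f"n{i}", "no_choice", 5, "acknowledge", r))
    return records
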