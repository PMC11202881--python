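"""Trial-level behavioral records for the two-stage delegation experiment.

Each trial is one participant decision: in the *choice* condition the
participant first agrees or disagrees with the AI's annotation and then
rates, on a 0-100 slider, how likely they would be to delegate the decision
to the AI in the future; in the *no-choice* condition the participant only
acknowledges the advice before rating.  The rating is the study's
operational trust measure ("delegation strength").
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

CONDITIONS = ("choice", "no_choice")
RESPONSES = ("agree", "disagree", "acknowledge")
TIMINGS_S = (5, 10, 15, 20, 25, 30, 35)

#: Columns every trial table must carry, in canonical order.
REQUIRED_COLUMNS = ("participant_id", "condition", "timing_s", "response", "rating")
OPTIONAL_COLUMNS = ("stimulus_correct",)


@dataclass(frozen=True)
class TrialRecord:
    """One participant x trial observation.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    condition : str
        ``"choice"`` (intermediate agree/disagree judgment elicited) or
        ``"no_choice"`` (acknowledge only).
    timing_s : int
        Enforced response time in seconds; one of 5, 10, ..., 35.
    response : str
        ``"agree"`` / ``"disagree"`` in the choice condition,
        ``"acknowledge"`` in the no-choice condition.
    rating : float
        Delegation strength on the 0-100 slider.
    stimulus_correct : bool or None
        Whether the AI annotation for this trial was correct (hidden from
        the participant; kept for schedule bookkeeping).
    """

    participant_id: str
    condition: str
    timing_s: int
    response: str
    rating: float
    stimulus_correct: bool | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.response not in RESPONSES:
            raise ValidationError(f"unknown response {self.response!r}")
        if int(self.timing_s) not in TIMINGS_S:
            raise ValidationError(f"timing_s {self.timing_s!r} not one of {TIMINGS_S}")
        if not 0.0 <= float(self.rating) <= 100.0:
            raise ValidationError(f"rating {self.rating!r} outside [0, 100]")
        if self.condition == "choice" and self.response not in ("agree", "disagree"):
            raise ValidationError(
                "choice-condition trials must respond 'agree' or 'disagree', "
                f"got {self.response!r}"
            )
        if self.condition == "no_choice" and self.response != "acknowledge":
            raise ValidationError(
                f"no-choice trials must respond 'acknowledge', got {self.response!r}"
            )


def _parse_stimulus(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "1.0", "t", "yes"):
        return True
    if text in ("false", "0", "0.0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse stimulus_correct value {value!r}")


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Represent a record list as a DataFrame with the canonical columns."""
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Validate a DataFrame row by row into :class:`TrialRecord` objects.

    Unknown extra columns are ignored; a missing required column raises
    :class:`SchemaError` naming it, and an invalid row raises
    :class:`ValidationError` reporting the 0-based row index.
    """
    for column in REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")
    has_stim = "stimulus_correct" in frame.columns
    records: list[TrialRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = row._asdict()
        try:
            records.append(
                TrialRecord(
                    participant_id=str(row["participant_id"]),
                    condition=str(row["condition"]),
                    timing_s=int(row["timing_s"]),
                    response=str(row["response"]),
                    rating=float(row["rating"]),
                    stimulus_correct=_parse_stimulus(row["stimulus_correct"])
                    if has_stim
                    else None,
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"invalid trial at row {idx}: {exc}") from exc
    return records


def read_trials(path) -> list[TrialRecord]:
    """Read a trial CSV (UTF-8, header row) into validated records.

    Row order is preserved.  See :func:`frame_to_records` for the error
    contract.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str},
                        float_precision="round_trip")
    return frame_to_records(frame)


def write_trials(records: Sequence[TrialRecord], path) -> None:
    """Write records as CSV such that :func:`read_trials` round-trips."""
    records_to_frame(records).to_csv(path, index=False)
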