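"""Trial-table CSV I/O with schema validation.

The on-disk dialect is one CSV row per (participant, Session-2 trial),
carrying the Session-1 fields alongside.  Judgements are serialized as
strings, feedback as 1/0 integers; fields the design masks or omits are
empty (NA).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .advisee import AdviseeOpinion
from .errors import DataError
from .models import TrialRecord

REQUIRED_COLUMNS = [
    "participant_id",
    "study_id",
    "session_id",
    "trial_index",
    "stimulus_id",
    "opinion_condition",
    "s1_judgement",
    "s1_investment",
    "advisee_judgement",
    "advisee_investment",
    "s2_judgement",
    "s2_investment",
]
OPTIONAL_COLUMNS = ["phase_index", "phase_preference", "advice_type", "feedback"]
_JUDGEMENTS = {"higher", "lower"}


def _check_investment(value, row: int, column: str):
    if pd.isna(value):
        return
    v = float(value)
    if not (v == int(v) and 1 <= v <= 60):
        raise DataError(
            f"row {row}: column {column!r} must be an integer in [1, 60], got {value}"
        )


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; returns the (typed) table."""
    unknown = set(df.columns) - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        raise DataError(f"unknown column(s): {sorted(unknown)}")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"missing required column(s): {sorted(missing)}")
    df = df.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        r = row._asdict()
        for col in ("s1_judgement", "s2_judgement"):
            if r[col] not in _JUDGEMENTS:
                raise DataError(f"row {i}: column {col!r} must be higher/lower")
        if not pd.isna(r["advisee_judgement"]) and r["advisee_judgement"] not in _JUDGEMENTS:
            raise DataError(f"row {i}: column 'advisee_judgement' must be higher/lower or NA")
        for col in ("s1_investment", "s2_investment", "advisee_investment"):
            _check_investment(r[col], i, col)
        if pd.isna(r["advisee_judgement"]) != pd.isna(r["advisee_investment"]):
            raise DataError(
                f"row {i}: advisee judgement and investment must be jointly present or NA"
            )
        if not pd.isna(r["feedback"]) and float(r["feedback"]) not in (0.0, 1.0):
            raise DataError(f"row {i}: column 'feedback' must be 0 or 1")
        if not pd.isna(r["feedback"]) and pd.isna(r["advice_type"]):
            raise DataError(f"row {i}: feedback present without advice_type")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    out = trials.copy()
    # integers with NA must not be written as floats
    for col in ("advisee_investment", "feedback", "phase_index"):
        if col in out.columns:
            out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    df = validate_trials(df)
    for col in ("advisee_investment", "feedback", "phase_index"):
        df[col] = df[col].astype("Int64")
    return df


def records_from_frame(trials: pd.DataFrame) -> dict:
    """Convert a trial table into per-participant TrialRecord lists
    (ordered by trial), the in-memory form the likelihoods consume."""
    out = {}
    for pid, g in trials.groupby("participant_id", sort=True):
        g = g.sort_values("trial_index")
        records = []
        for _, r in g.iterrows():
            masked = pd.isna(r["advisee_judgement"])
            op = AdviseeOpinion(
                None if masked else r["advisee_judgement"],
                None if masked else int(r["advisee_investment"]),
                masked=bool(masked),
            )
            records.append(
                TrialRecord(
                    trial_index=int(r["trial_index"]) - 1,
                    phase_index=None if pd.isna(r["phase_index"]) else int(r["phase_index"]),
                    s1_judgement=r["s1_judgement"],
                    s1_investment=int(r["s1_investment"]),
                    advisee=op,
                    s2_judgement=r["s2_judgement"],
                    s2_investment=int(r["s2_investment"]),
                    advice_type=None if pd.isna(r["advice_type"]) else r["advice_type"],
                    feedback=None if pd.isna(r["feedback"]) else int(r["feedback"]),
                )
            )
        out[pid] = records
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
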