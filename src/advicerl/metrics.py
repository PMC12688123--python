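"""Behavioral measurements on the Opinion Strength (OS) scale.

An opinion is summarized by a signed scalar: the sign encodes the
judgement (+ for "higher", - for "lower") and the magnitude is the 1-60
investment expressing confidence.  From OS values the module derives the
trial-level measures used throughout the analyses — judgement congruency,
opinion discrepancy, judgement switch, and the opinion shift rate (OSR)
with its inexplicable-trial exclusion rules and per-participant M+-3SD
trimming — plus the phase-wise alignment summaries for the feedback
studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidStateError


@dataclass(frozen=True)
class OpinionStrength:
    value: float

    def __post_init__(self):
        if not (1 <= abs(self.value) <= 60):
            raise InvalidArgumentError("|OS| must lie in [1, 60]")

    @property
    def judgement(self) -> str:
        return "higher" if self.value > 0 else "lower"

    @property
    def investment(self) -> float:
        return abs(self.value)


@dataclass(frozen=True)
class OsrResult:
    """OSR value (None on inexplicable trials) plus its exclusion flag."""

    osr: Optional[float]
    exclusion: str  # none | inexplicable_type1 | inexplicable_type2 | extreme_3sd


def opinion_strength(judgement: str, investment) -> float:
    """Signed OS value: +investment for 'higher', -investment for 'lower'."""
    if not (1 <= investment <= 60):
        raise InvalidArgumentError("investment outside [1, 60]")
    if judgement == "higher":
        return float(investment)
    if judgement == "lower":
        return -float(investment)
    raise InvalidArgumentError(f"unknown judgement {judgement!r}")


def judgement_congruency(advice_judgement, advisee_judgement) -> int:
    """1 iff the advised judgement matches the advisee's."""
    if advice_judgement is None or advisee_judgement is None:
        raise InvalidStateError("congruency undefined on masked trials")
    return int(advice_judgement == advisee_judgement)


def opinion_discrepancy(os_advice: float, os_advisee: float) -> float:
    """Absolute distance between two opinions on the OS scale."""
    if os_advice is None or os_advisee is None:
        raise InvalidStateError("discrepancy undefined on masked trials")
    return abs(os_advice - os_advisee)


def judgement_switch(s1_judgement, s2_judgement) -> int:
    """1 iff the advisor switched their Session-1 judgement in Session 2."""
    return int(s1_judgement != s2_judgement)


def compute_osr(os_tns: float, os_tas: float, os_ts: float) -> OsrResult:
    """Opinion shift rate: the signed Session-1-to-Session-2 opinion change
    divided by the baseline advisor-advisee opinion gap,

        OSR = (OS_s - OS_ns) / (OS_as - OS_ns).

    OSR > 0 means the advice moved towards the advisee's opinion, > 0.5
    that the advisee's opinion was over-weighed, > 1 overshoot.  Two trial
    types are inexplicable and excluded: (1) the ratio is positive but the
    final judgement is still incongruent with the advisee's, and (2) the
    baseline gap is zero so the ratio is undefined.
    """
    if os_tas is None:
        raise InvalidStateError("OSR undefined on masked trials")
    if os_tas == os_tns:
        return OsrResult(None, "inexplicable_type2")
    osr = (os_ts - os_tns) / (os_tas - os_tns)
    if osr > 0 and (os_ts > 0) != (os_tas > 0):
        return OsrResult(None, "inexplicable_type1")
    return OsrResult(float(osr), "none")


def trim_extreme_osr(osr_values: Sequence[float]) -> tuple:
    """Single-pass M+-3SD trim of one participant's valid OSR values.

    Mean and (sample) SD are computed once on the pre-trim values; values
    outside mean +- 3 SD are flagged ``extreme_3sd``.  Returns
    (kept_values, flags) with flags aligned to the input order.
    """
    values = np.asarray(list(osr_values), dtype=float)
    if len(values) < 2:
        warnings.warn("fewer than 2 OSR values; no trimming applied")
        return list(values), ["none"] * len(values)
    m = values.mean()
    sd = values.std(ddof=1)
    flags = [
        "extreme_3sd" if abs(v - m) > 3 * sd else "none" for v in values
    ]
    kept = [v for v, f in zip(values, flags) if f == "none"]
    return kept, flags


def trial_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-trial metric table for a trial DataFrame (TrialTable schema).

    One row per (participant, trial, metric); masked trials contribute only
    the judgement_switch metric.  OSR rows carry the exclusion flag,
    including the per-participant extreme_3sd trim."""
    rows = []
    osr_buffer = {}  # pid -> list of (row_position, osr)
    for _, tr in trials.iterrows():
        pid, t = tr["participant_id"], tr["trial_index"]

        def add(metric, value, exclusion="none"):
            rows.append(
                {
                    "participant_id": pid,
                    "trial_index": t,
                    "metric": metric,
                    "value": value,
                    "exclusion_flag": exclusion,
                }
            )

        add("judgement_switch", judgement_switch(tr["s1_judgement"], tr["s2_judgement"]))
        if pd.isna(tr["advisee_judgement"]) or tr["advisee_judgement"] is None:
            continue
        os_ns = opinion_strength(tr["s1_judgement"], tr["s1_investment"])
        os_as = opinion_strength(tr["advisee_judgement"], tr["advisee_investment"])
        os_s = opinion_strength(tr["s2_judgement"], tr["s2_investment"])
        add("judgement_congruency_s1",
            judgement_congruency(tr["s1_judgement"], tr["advisee_judgement"]))
        add("judgement_congruency_s2",
            judgement_congruency(tr["s2_judgement"], tr["advisee_judgement"]))
        add("opinion_discrepancy_s1", opinion_discrepancy(os_ns, os_as))
        add("opinion_discrepancy_s2", opinion_discrepancy(os_s, os_as))
        res = compute_osr(os_ns, os_as, os_s)
        add("osr", res.osr if res.osr is not None else np.nan, res.exclusion)
        if res.exclusion == "none":
            osr_buffer.setdefault(pid, []).append((len(rows) - 1, res.osr))

    # per-participant single-pass 3SD trim on the valid OSR values
    for pid, entries in osr_buffer.items():
        positions = [p for p, _ in entries]
        values = [v for _, v in entries]
        _, flags = trim_extreme_osr(values)
        for p, f in zip(positions, flags):
            if f != "none":
                rows[p]["exclusion_flag"] = f
    return pd.DataFrame(rows)


def overall_judgement_switch(trials: pd.DataFrame) -> pd.Series:
    """Participant mean of judgement switch over opinion-shown Session-2
    trials (the participant-level summary used in parameter correlations)."""
    shown = trials[trials["advisee_judgement"].notna()]
    return shown.groupby("participant_id").apply(
        lambda g: np.mean(
            [judgement_switch(a, b) for a, b in zip(g["s1_judgement"], g["s2_judgement"])]
        ),
        include_groups=False,
    )


def phase_alignment_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, phase) mean P(aligned advice), phase preference,
    and the adaptation score relative to the neutral phase."""
    if trials["phase_index"].isna().all():
        raise InvalidArgumentError("phase alignment requires a feedback-study design")
    shown = trials[trials["advice_type"].notna()].copy()
    shown["aligned"] = (shown["advice_type"] == "aligned").astype(float)
    summary = (
        shown.groupby(["participant_id", "phase_index", "phase_preference"])["aligned"]
        .mean()
        .rename("p_aligned")
        .reset_index()
    )
    neutral = (
        summary[summary["phase_preference"] == "neutral"]
        .set_index("participant_id")["p_aligned"]
    )
    summary["adaptation"] = summary.apply(
        lambda r: r["p_aligned"] - neutral.get(r["participant_id"], np.nan)
        if r["phase_preference"] != "neutral"
        else 0.0,
        axis=1,
    )
    return summary


def overall_alignment(trials: pd.DataFrame) -> pd.Series:
    """Participant-level P(aligned advice) over all feedback trials."""
    shown = trials[trials["advice_type"].notna()].copy()
    return (
        (shown["advice_type"] == "aligned")
        .astype(float)
        .groupby(shown["participant_id"])
        .mean()
    )
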