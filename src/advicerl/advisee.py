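"""Scripted-advisee generation: opinions and acceptance/rejection feedback.

Advisees in the task are preprogrammed.  Their judgements are derived from
the advisor's own Session-1 advice (copied on congruent trials, flipped on
incongruent ones, hidden on masked ones); their investments are drawn from
Normal(10, 10) (risk-avoiding) or Normal(50, 10) (risk-seeking), rounded
and clipped onto the 1-60 wager scale; and in the feedback studies their
acceptance of advice is an independent Bernoulli draw whose probability is
given by the phase schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import FeedbackSchedule
from .errors import InvalidArgumentError, InvalidStateError

INVESTMENT_MIN, INVESTMENT_MAX = 1, 60


@dataclass(frozen=True)
class AdviseeProfile:
    risk_preference: str  # "avoiding" | "seeking"
    investment_mean: float
    investment_sd: float = 10.0
    schedule: Optional[FeedbackSchedule] = None

    def __post_init__(self):
        if self.investment_sd <= 0:
            raise InvalidArgumentError("investment_sd must be > 0")

    @classmethod
    def risk_avoiding(cls, schedule=None) -> "AdviseeProfile":
        return cls("avoiding", 10.0, 10.0, schedule)

    @classmethod
    def risk_seeking(cls, schedule=None) -> "AdviseeProfile":
        return cls("seeking", 50.0, 10.0, schedule)


@dataclass(frozen=True)
class AdviseeOpinion:
    """What the advisor sees on one Session-2 trial. On masked trials the
    judgement and investment are hidden (None)."""

    judgement: Optional[str]
    investment: Optional[int]
    masked: bool


@dataclass(frozen=True)
class InvestmentDraws:
    """Raw Gaussian draws plus the rounded/clipped values shown on screen.
    Raw values are kept so distributional tests can target the generating
    Normal before truncation."""

    raw: np.ndarray
    exported: np.ndarray


_OPPOSITE = {"higher": "lower", "lower": "higher"}


def generate_advisee_judgements(
    s1_advice_judgements: Sequence[str], conditions: Sequence[str]
) -> list:
    """Derive the advisee's judgement on each trial from the advisor's
    Session-1 advice and the trial's opinion condition."""
    if len(s1_advice_judgements) != len(conditions):
        raise InvalidArgumentError("judgement and condition lists differ in length")
    out = []
    for j, cond in zip(s1_advice_judgements, conditions):
        if cond == "masked":
            out.append(None)
        elif cond == "congruent":
            out.append(j)
        elif cond == "incongruent":
            out.append(_OPPOSITE[j])
        else:
            raise InvalidArgumentError(f"unknown opinion condition {cond!r}")
    return out


def sample_advisee_investments(
    profile: AdviseeProfile, n: int, rng_seed=0
) -> InvestmentDraws:
    """Draw ``n`` investments from the profile's Normal, returning both the
    raw draws and the integer values clipped to the 1-60 scale."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    raw = rng.normal(profile.investment_mean, profile.investment_sd, size=n)
    exported = np.clip(np.rint(raw), INVESTMENT_MIN, INVESTMENT_MAX).astype(int)
    return InvestmentDraws(raw=raw, exported=exported)


def sample_feedback(
    advice_aligned: bool,
    phase_preference: str,
    schedule: Optional[FeedbackSchedule],
    rng: np.random.Generator,
) -> int:
    """One Bernoulli acceptance draw: 1 = accept, 0 = reject."""
    if schedule is None:
        raise InvalidStateError("no feedback schedule defined for this session")
    advice_type = "aligned" if advice_aligned else "misaligned"
    p = schedule.prob(phase_preference, advice_type)
    return int(rng.random() < p)


def build_opinion_stream(
    profile: AdviseeProfile,
    s1_advice_judgements: Sequence[str],
    conditions: Sequence[str],
    rng_seed=0,
) -> list:
    """Assemble the full per-trial list of :class:`AdviseeOpinion`."""
    judgements = generate_advisee_judgements(s1_advice_judgements, conditions)
    draws = sample_advisee_investments(profile, len(conditions), rng_seed=rng_seed)
    opinions = []
    for j, inv in zip(judgements, draws.exported):
        if j is None:
            opinions.append(AdviseeOpinion(None, None, masked=True))
        else:
            opinions.append(AdviseeOpinion(j, int(inv), masked=False))
    return opinions
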