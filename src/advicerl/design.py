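"""Trial, session and phase structure of the advice-giving task.

The task is a two-session investment advice game: in Session 1 the advisor
judges whether a shown estate price is higher or lower than the true price
and wagers 1-60 on the judgement; in Session 2 the same stimuli reappear,
now (on most trials) together with the scripted advisee's opinion.  In the
feedback studies (S3, S4) Session 2 is additionally divided into three
22-trial phases during which the advisee's probability of accepting aligned
vs. misaligned advice changes (a probabilistic reversal schedule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

Judgement = Literal["higher", "lower"]
OpinionCondition = Literal["congruent", "incongruent", "masked"]
PhasePreference = Literal["neutral", "prefer_aligned", "prefer_misaligned"]

STUDIES = ("S1", "S2", "S3", "S4")
FEEDBACK_STUDIES = ("S3", "S4")

#: Phase-wise acceptance probabilities P(accept | advice type) per study.
#: The mild-advisee schedule (S3) averages to an overall 50% acceptance,
#: the insusceptible-advisee schedule (S4) to 30%.
ACCEPTANCE_LEVELS = {
    "S3": {"low": 0.30, "mid": 0.50, "high": 0.70},
    "S4": {"low": 0.10, "mid": 0.30, "high": 0.50},
}


@dataclass(frozen=True)
class Stimulus:
    """One estate stimulus: a true market price and a shown price deviating
    from it by a fixed fraction (20% by default) up or down."""

    stimulus_id: int
    true_price: int
    shown_price: int
    correct_judgement: Judgement

    def __post_init__(self):
        if self.true_price <= 0 or self.shown_price <= 0:
            raise InvalidArgumentError("prices must be positive")
        expected = "higher" if self.shown_price > self.true_price else "lower"
        if self.correct_judgement != expected:
            raise InvalidArgumentError(
                "correct_judgement inconsistent with price deviation sign"
            )


@dataclass(frozen=True)
class TrialSpec:
    """Design-level description of a single trial (no behavior)."""

    trial_index: int  # 0-based
    stimulus_id: int
    opinion_condition: Optional[OpinionCondition] = None
    phase_index: Optional[int] = None


@dataclass(frozen=True)
class FeedbackSchedule:
    """Phase-wise acceptance probabilities for aligned/misaligned advice."""

    phase_lengths: tuple = (22, 22, 22)
    phase_preferences: tuple = ("neutral", "prefer_aligned", "prefer_misaligned")
    p_accept: dict = field(default_factory=dict)  # (preference, advice_type) -> prob

    def phase_of_trial(self, trial_index: int) -> int:
        edges = np.cumsum(self.phase_lengths)
        return int(np.searchsorted(edges, trial_index, side="right"))

    def preference_of_trial(self, trial_index: int) -> PhasePreference:
        return self.phase_preferences[self.phase_of_trial(trial_index)]

    def prob(self, preference: PhasePreference, advice_type: str) -> float:
        return self.p_accept[(preference, advice_type)]


@dataclass(frozen=True)
class SessionDesign:
    study_id: str
    session_id: int
    trials: tuple  # of TrialSpec
    stimuli: tuple  # of Stimulus
    schedule: Optional[FeedbackSchedule] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class DesignConfig:
    """Configurable study-design constants, defaulting to the published task."""

    n_trials: int = 66
    n_masked: Optional[int] = None  # None -> study default (14 for S1/S2, 0 for S3/S4)
    deviation: float = 0.2
    price_range: tuple = (500_000, 5_000_000)
    schedule_order: Literal["aligned_first", "misaligned_first"] = "aligned_first"

    def masked_default(self, study_id: str) -> int:
        if self.n_masked is not None:
            return self.n_masked
        return 14 if study_id in ("S1", "S2") else 0


def make_stimuli(
    n: int,
    price_range: Sequence[int] = (500_000, 5_000_000),
    deviation: float = 0.2,
    rng_seed: int = 0,
) -> list:
    """Generate ``n`` stimuli whose shown price is ``true_price*(1±deviation)``
    rounded to the nearest whole number, with higher/lower deviations
    balanced to within one stimulus."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not (0.0 < deviation < 1.0):
        raise InvalidArgumentError("deviation must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    lo, hi = int(price_range[0]), int(price_range[1])
    if lo <= 0 or hi < lo:
        raise InvalidArgumentError("price_range must be positive and ordered")
    true_prices = rng.integers(lo, hi + 1, size=n)
    signs = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    rng.shuffle(signs)
    stimuli = []
    for i, (price, s) in enumerate(zip(true_prices, signs)):
        shown = int(np.rint(price * (1 + s * deviation)))
        stimuli.append(
            Stimulus(
                stimulus_id=i,
                true_price=int(price),
                shown_price=shown,
                correct_judgement="higher" if s > 0 else "lower",
            )
        )
    return stimuli


def assign_opinion_conditions(
    n_trials: int, n_masked: int = 14, rng_seed: int = 0
) -> list:
    """Randomly assign each Session-2 trial to masked / congruent /
    incongruent, with the non-masked trials split exactly in half."""
    if n_masked < 0 or n_masked > n_trials:
        raise InvalidArgumentError("n_masked must lie in [0, n_trials]")
    remainder = n_trials - n_masked
    if remainder % 2:
        raise InvalidArgumentError(
            "n_trials - n_masked must be even to split congruent/incongruent equally"
        )
    labels = (
        ["masked"] * n_masked
        + ["congruent"] * (remainder // 2)
        + ["incongruent"] * (remainder // 2)
    )
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(labels)
    return labels


def build_phase_schedule(
    study_id: str, order: str = "aligned_first"
) -> FeedbackSchedule:
    """Three 22-trial phases: neutral first, then the two preference phases
    in the requested (counterbalanced) order."""
    if study_id not in FEEDBACK_STUDIES:
        raise InvalidArgumentError(
            f"study {study_id} has no feedback schedule (only S3/S4 do)"
        )
    if order not in ("aligned_first", "misaligned_first"):
        raise InvalidArgumentError(f"unknown order {order!r}")
    levels = ACCEPTANCE_LEVELS[study_id]
    p_accept = {
        ("neutral", "aligned"): levels["mid"],
        ("neutral", "misaligned"): levels["mid"],
        ("prefer_aligned", "aligned"): levels["high"],
        ("prefer_aligned", "misaligned"): levels["low"],
        ("prefer_misaligned", "aligned"): levels["low"],
        ("prefer_misaligned", "misaligned"): levels["high"],
    }
    if order == "aligned_first":
        prefs = ("neutral", "prefer_aligned", "prefer_misaligned")
    else:
        prefs = ("neutral", "prefer_misaligned", "prefer_aligned")
    return FeedbackSchedule(
        phase_lengths=(22, 22, 22), phase_preferences=prefs, p_accept=p_accept
    )


def build_session_design(
    study_id: str,
    session_id: int,
    config: DesignConfig = DesignConfig(),
    rng_seed: int = 0,
    stimuli: Optional[Sequence[Stimulus]] = None,
) -> SessionDesign:
    """Construct a fully specified session.

    Session 2 must reuse the Session-1 stimuli: pass the same ``stimuli``
    list (or the same ``rng_seed``, from which stimuli are regenerated
    deterministically).
    """
    if study_id not in STUDIES:
        raise InvalidArgumentError(f"unknown study {study_id!r}")
    if session_id not in (1, 2):
        raise InvalidArgumentError("session_id must be 1 or 2")
    from .seeding import as_seed_sequence

    ss = as_seed_sequence(rng_seed)
    stim_seed, cond_seed = ss.spawn(2)
    if stimuli is None:
        stimuli = make_stimuli(
            config.n_trials,
            config.price_range,
            config.deviation,
            rng_seed=stim_seed.generate_state(1)[0] % (2**31),
        )
    if len(stimuli) != config.n_trials:
        raise InvalidArgumentError("stimulus count does not match n_trials")

    schedule = None
    phase_index = [None] * config.n_trials
    if study_id in FEEDBACK_STUDIES and session_id == 2:
        schedule = build_phase_schedule(study_id, config.schedule_order)
        if sum(schedule.phase_lengths) != config.n_trials:
            raise InvalidArgumentError("phase lengths must sum to n_trials")
        phase_index = [schedule.phase_of_trial(t) for t in range(config.n_trials)]

    if session_id == 2:
        conditions = assign_opinion_conditions(
            config.n_trials,
            config.masked_default(study_id),
            rng_seed=cond_seed.generate_state(1)[0] % (2**31),
        )
    else:
        conditions = [None] * config.n_trials

    trials = tuple(
        TrialSpec(
            trial_index=t,
            stimulus_id=stimuli[t].stimulus_id,
            opinion_condition=conditions[t],
            phase_index=phase_index[t],
        )
        for t in range(config.n_trials)
    )
    return SessionDesign(
        study_id=study_id,
        session_id=session_id,
        trials=trials,
        stimuli=tuple(stimuli),
        schedule=schedule,
    )


def design_to_frame(design: SessionDesign) -> pd.DataFrame:
    """Export a session design as a tidy table (1-based trial indices)."""
    stim = {s.stimulus_id: s for s in design.stimuli}
    rows = []
    for spec in design.trials:
        pref = (
            design.schedule.phase_preferences[spec.phase_index]
            if design.schedule is not None
            else None
        )
        rows.append(
            {
                "study_id": design.study_id,
                "session_id": design.session_id,
                "trial_index": spec.trial_index + 1,
                "stimulus_id": spec.stimulus_id,
                "shown_price": stim[spec.stimulus_id].shown_price,
                "true_price": stim[spec.stimulus_id].true_price,
                "opinion_condition": spec.opinion_condition,
                "phase_index": spec.phase_index,
                "phase_preference": pref,
            }
        )
    return pd.DataFrame(rows)


def session1_design_from(design: SessionDesign) -> SessionDesign:
    """The Session-1 counterpart of a Session-2 design (same stimuli,
    no opinion conditions, no schedule)."""
    trials = tuple(
        replace(spec, opinion_condition=None, phase_index=None)
        for spec in design.trials
    )
    return SessionDesign(
        study_id=design.study_id,
        session_id=1,
        trials=trials,
        stimuli=design.stimuli,
        schedule=None,
    )
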