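"""The seven advisor models: forward simulators and per-trial likelihoods.

All models choose between the judgement options "higher" and "lower" on
each Session-2 trial by combining values and passing their difference
through an inverse-logit link.

* M1 (baseline): only the advisor's own Session-1 opinion matters.  The
  non-social value of the initially selected option is its normalized
  wager, Q_ns(selected) = wager/60, the other option gets 0, and choice
  probability is a softmax with inverse temperature ``tau``.
* M2-M4 (social bias): a social value pair over advice types
  (align, misalign) is combined with the non-social pair,
  Q = w_ns*Q_ns + w_s*Q_s, with no temperature parameter.  M2 holds the
  social value constant at (1, 0); M3 scales it by the advisee's expressed
  confidence, (|OS_advisee|/60, 0); M4 starts at (1, 0) and increments the
  aligned value by kappa after every accepted trial.
* M5-M7 (social learning): the social value of the chosen advice type is
  updated by a Rescorla-Wagner rule, Q += alpha * (R - Q), with R = 1 for
  acceptance and 0 for rejection.  M5 uses one learning rate; M6 splits it
  by advice type; M7 splits it by advice type x feedback, which is how a
  confirmation-bias-like asymmetry (large alpha_al_ac, small alpha_al_re)
  is expressed.

On masked trials (advisee opinion hidden) every model falls back to the
non-social value alone: M1 uses its softmax, M2-M7 use the inverse logit of
``w_ns * (Q_ns(higher) - Q_ns(lower))``.

Only the Session-2 judgement choices enter the likelihood; Session-1
behavior and all investments are conditioning inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .advisee import AdviseeOpinion, AdviseeProfile, build_opinion_stream
from .design import SessionDesign
from .errors import InvalidArgumentError, InvalidStateError

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")

PARAM_NAMES = {
    "M1": ("tau",),
    "M2": ("w_ns", "w_s"),
    "M3": ("w_ns", "w_s"),
    "M4": ("w_ns", "w_s", "kappa"),
    "M5": ("w_ns", "w_s", "alpha"),
    "M6": ("w_ns", "w_s", "alpha_al", "alpha_mis"),
    "M7": (
        "w_ns",
        "w_s",
        "alpha_al_ac",
        "alpha_al_re",
        "alpha_mis_ac",
        "alpha_mis_re",
    ),
}

_BOUNDS = {
    "tau": (0.0, 20.0),
    "w_ns": (0.0, 10.0),
    "w_s": (0.0, 10.0),
}
_UNIT = (0.0, 1.0)  # learning rates and kappa


@dataclass(frozen=True)
class ModelParams:
    """Per-participant parameter set for one of M1-M7."""

    model_id: str
    values: dict

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise InvalidArgumentError(f"unknown model {self.model_id!r}")
        names = PARAM_NAMES[self.model_id]
        if set(self.values) != set(names):
            raise InvalidArgumentError(
                f"{self.model_id} requires exactly parameters {names}, "
                f"got {tuple(self.values)}"
            )
        for name, v in self.values.items():
            lo, hi = _BOUNDS.get(name, _UNIT)
            if not (lo < v < hi):
                raise InvalidArgumentError(
                    f"{name}={v} outside open bounds ({lo}, {hi})"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES[self.model_id]])

    @classmethod
    def from_vector(cls, model_id: str, theta: Sequence[float]) -> "ModelParams":
        names = PARAM_NAMES[model_id]
        if len(theta) != len(names):
            raise InvalidArgumentError("parameter vector length mismatch")
        return cls(model_id, dict(zip(names, map(float, theta))))


@dataclass
class ValueState:
    """Evolving value state carried through a session."""

    q_ns: tuple = (0.0, 0.0)  # (higher, lower)
    q_s: tuple = (1.0, 0.0)  # (align, misalign)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    phase_index: Optional[int]
    s1_judgement: str
    s1_investment: int
    advisee: AdviseeOpinion
    s2_judgement: Optional[str] = None
    s2_investment: Optional[int] = None
    advice_type: Optional[str] = None  # "aligned" | "misaligned" | None if masked
    feedback: Optional[int] = None  # 1 accept, 0 reject, None if no feedback


def phi_normalize(wager) -> float:
    """Map a wager on the 1-60 scale to (0, 1]."""
    w = np.asarray(wager, dtype=float)
    if np.any((w < 1) | (w > 60)):
        raise InvalidArgumentError("wager must lie in [1, 60]")
    out = w / 60.0
    return float(out) if out.ndim == 0 else out


def init_nonsocial_values(s1_judgement: str, s1_investment: int) -> tuple:
    """Non-social value pair (higher, lower): the selected option carries the
    normalized wager, the other 0."""
    v = phi_normalize(s1_investment)
    if s1_judgement == "higher":
        return (v, 0.0)
    if s1_judgement == "lower":
        return (0.0, v)
    raise InvalidArgumentError(f"unknown judgement {s1_judgement!r}")


def social_value(
    model_id: str,
    params: ModelParams,
    state: ValueState,
    trial: TrialRecord,
) -> tuple:
    """Current social value pair (align, misalign) for a shown trial."""
    if trial.advisee.masked:
        raise InvalidStateError("social value is undefined on a masked trial")
    if model_id == "M1":
        raise InvalidArgumentError("M1 has no social value")
    if model_id == "M2":
        return (1.0, 0.0)
    if model_id == "M3":
        return (phi_normalize(abs(trial.advisee.investment)), 0.0)
    # M4-M7 carry the evolving state
    return state.q_s


def rl_update(
    model_id: str,
    params: ModelParams,
    q_s: tuple,
    advice_type: str,
    feedback: int,
) -> tuple:
    """Rescorla-Wagner update of the chosen advice type's value (M5-M7)."""
    if model_id not in ("M5", "M6", "M7"):
        raise InvalidArgumentError("rl_update applies to M5-M7 only")
    if feedback not in (0, 1):
        raise InvalidArgumentError("feedback must be 0 or 1")
    if model_id == "M5":
        alpha = params["alpha"]
    elif model_id == "M6":
        alpha = params["alpha_al"] if advice_type == "aligned" else params["alpha_mis"]
    else:
        key = {
            ("aligned", 1): "alpha_al_ac",
            ("aligned", 0): "alpha_al_re",
            ("misaligned", 1): "alpha_mis_ac",
            ("misaligned", 0): "alpha_mis_re",
        }[(advice_type, feedback)]
        alpha = params[key]
    q_al, q_mis = q_s
    if advice_type == "aligned":
        q_al = q_al + alpha * (feedback - q_al)
    else:
        q_mis = q_mis + alpha * (feedback - q_mis)
    return (q_al, q_mis)


def m4_update(
    params: ModelParams, q_s: tuple, feedback: int, signed_feedback: bool = False
) -> tuple:
    """M4's feedback increment: the aligned value grows by kappa*R after each
    feedback trial (literal published rule; with R in {1, 0} it can only
    increase).  ``signed_feedback`` switches to R in {1, -1}."""
    r = (2 * feedback - 1) if signed_feedback else feedback
    return (q_s[0] + params["kappa"] * r, q_s[1])


def _logistic_loglik(x: float, chose_higher: bool) -> float:
    # log P(choice) for p_higher = logistic(x), numerically stable
    if chose_higher:
        return -np.logaddexp(0.0, -x)
    return -np.logaddexp(0.0, x)


def choice_probability(
    model_id: str,
    params: ModelParams,
    q_ns: tuple,
    q_s: Optional[tuple],
    advisee_judgement: Optional[str],
    masked: bool,
) -> float:
    """P(advise 'higher') for the current trial state."""
    dns = q_ns[0] - q_ns[1]
    if model_id == "M1":
        x = params["tau"] * dns
    elif masked:
        x = params["w_ns"] * dns
    else:
        if advisee_judgement == "higher":
            ds = q_s[0] - q_s[1]
        elif advisee_judgement == "lower":
            ds = q_s[1] - q_s[0]
        else:
            raise InvalidArgumentError(f"unknown judgement {advisee_judgement!r}")
        x = params["w_ns"] * dns + params["w_s"] * ds
    return float(1.0 / (1.0 + np.exp(-x)))


# ---------------------------------------------------------------------------
# Fast array representation of a participant-session, used by the fitters.
# ---------------------------------------------------------------------------


@dataclass
class SessionArrays:
    """Numpy view of one participant's Session-2 trials, in trial order."""

    dns: np.ndarray  # Q_ns(higher) - Q_ns(lower)
    shown: np.ndarray  # bool: advisee opinion visible
    adv_higher: np.ndarray  # bool: advisee judgement == "higher" (False if masked)
    adv_phi: np.ndarray  # phi(|advisee investment|), 0 where masked
    chose_higher: np.ndarray  # bool: observed s2 judgement
    aligned: np.ndarray  # bool: observed advice type == aligned (shown trials)
    has_feedback: np.ndarray  # bool
    feedback: np.ndarray  # float 0/1 (0 where absent)

    @property
    def n_trials(self) -> int:
        return len(self.dns)


def prepare_session_arrays(trials: Sequence[TrialRecord]) -> SessionArrays:
    n = len(trials)
    if n == 0:
        raise InvalidArgumentError("empty trial list")
    dns = np.empty(n)
    shown = np.zeros(n, dtype=bool)
    adv_higher = np.zeros(n, dtype=bool)
    adv_phi = np.zeros(n)
    chose_higher = np.zeros(n, dtype=bool)
    aligned = np.zeros(n, dtype=bool)
    has_feedback = np.zeros(n, dtype=bool)
    feedback = np.zeros(n)
    for i, tr in enumerate(trials):
        if tr.s2_judgement is None:
            raise InvalidArgumentError(
                f"trial {tr.trial_index}: missing Session-2 judgement"
            )
        qns = init_nonsocial_values(tr.s1_judgement, tr.s1_investment)
        dns[i] = qns[0] - qns[1]
        chose_higher[i] = tr.s2_judgement == "higher"
        if not tr.advisee.masked:
            shown[i] = True
            adv_higher[i] = tr.advisee.judgement == "higher"
            adv_phi[i] = phi_normalize(abs(tr.advisee.investment))
            aligned[i] = tr.s2_judgement == tr.advisee.judgement
        if tr.feedback is not None:
            has_feedback[i] = True
            feedback[i] = float(tr.feedback)
    return SessionArrays(
        dns, shown, adv_higher, adv_phi, chose_higher, aligned, has_feedback, feedback
    )


def session_loglik_arrays(
    model_id: str,
    theta: np.ndarray,
    arr: SessionArrays,
    m4_signed_feedback: bool = False,
) -> np.ndarray:
    """Pointwise log-likelihood over a session for parameter vector ``theta``
    (ordered as PARAM_NAMES[model_id]).  Scalar trial loop: the value state
    is a two-element recursion that cannot be vectorized across trials."""
    n = arr.n_trials
    out = np.empty(n)
    dns = arr.dns
    chose = arr.chose_higher
    if model_id == "M1":
        x = theta[0] * dns
        return np.where(chose, -np.logaddexp(0.0, -x), -np.logaddexp(0.0, x))

    w_ns, w_s = theta[0], theta[1]
    q_al, q_mis = 1.0, 0.0
    kappa = theta[2] if model_id == "M4" else 0.0
    for t in range(n):
        if not arr.shown[t]:
            x = w_ns * dns[t]
        else:
            if model_id == "M2":
                a, m = 1.0, 0.0
            elif model_id == "M3":
                a, m = arr.adv_phi[t], 0.0
            else:
                a, m = q_al, q_mis
            ds = (a - m) if arr.adv_higher[t] else (m - a)
            x = w_ns * dns[t] + w_s * ds
        out[t] = _logistic_loglik(x, chose[t])

        if arr.has_feedback[t]:
            r = arr.feedback[t]
            if model_id == "M4":
                q_al += kappa * ((2 * r - 1) if m4_signed_feedback else r)
            elif model_id in ("M5", "M6", "M7") and arr.shown[t]:
                al = arr.aligned[t]
                if model_id == "M5":
                    alpha = theta[2]
                elif model_id == "M6":
                    alpha = theta[2] if al else theta[3]
                else:
                    if al:
                        alpha = theta[2] if r == 1 else theta[3]
                    else:
                        alpha = theta[4] if r == 1 else theta[5]
                if al:
                    q_al += alpha * (r - q_al)
                else:
                    q_mis += alpha * (r - q_mis)
    return out


def session_loglik(
    model_id: str,
    params: ModelParams,
    trials: Sequence[TrialRecord],
    m4_signed_feedback: bool = False,
) -> tuple:
    """Total and pointwise log-likelihood of the observed Session-2
    judgements under one model/parameter set."""
    if params.model_id != model_id:
        raise InvalidArgumentError("params.model_id does not match model_id")
    arr = prepare_session_arrays(trials)
    pointwise = session_loglik_arrays(
        model_id, params.as_vector(), arr, m4_signed_feedback=m4_signed_feedback
    )
    return float(pointwise.sum()), pointwise


def simulate_agent(
    model_id: str,
    params: ModelParams,
    design: SessionDesign,
    advisee,
    rng_seed=0,
    s1_judgements: Optional[Sequence[str]] = None,
    s1_investments: Optional[Sequence[int]] = None,
    advisor_investment_mean: float = 30.0,
    advisor_investment_sd: float = 10.0,
    m4_signed_feedback: bool = False,
) -> list:
    """Forward-simulate one advisor through a Session-2 design.

    ``advisee`` may be an :class:`AdviseeProfile` (the opinion stream is
    generated from the sampled Session-1 advice, as in the task) or a
    prebuilt list of :class:`AdviseeOpinion`.  Session-1 judgements default
    to fair coin flips, investments to clipped Normal(30, 10) integers.
    """
    if params.model_id != model_id:
        raise InvalidArgumentError("params.model_id does not match model_id")
    from .seeding import as_seed_sequence

    ss = as_seed_sequence(rng_seed)
    s_s1, s_adv, s_choice = ss.spawn(3)
    rng_s1 = np.random.default_rng(s_s1)
    n = design.n_trials

    if s1_judgements is None:
        s1_judgements = np.where(rng_s1.random(n) < 0.5, "higher", "lower").tolist()
    if s1_investments is None:
        raw = rng_s1.normal(advisor_investment_mean, advisor_investment_sd, size=n)
        s1_investments = np.clip(np.rint(raw), 1, 60).astype(int).tolist()

    conditions = [spec.opinion_condition for spec in design.trials]
    if isinstance(advisee, AdviseeProfile):
        stream = build_opinion_stream(
            advisee,
            s1_judgements,
            ["masked" if c is None else c for c in conditions],
            rng_seed=s_adv,
        )
    else:
        stream = list(advisee)
        if len(stream) != n:
            raise InvalidArgumentError("advisee stream length mismatch")

    rng = np.random.default_rng(s_choice)
    schedule = design.schedule
    state = ValueState(q_s=(1.0, 0.0))
    records = []
    for t, spec in enumerate(design.trials):
        op = stream[t]
        q_ns = init_nonsocial_values(s1_judgements[t], s1_investments[t])
        if model_id == "M1" or op.masked:
            q_s_pair = None
        else:
            q_s_pair = social_value(model_id, params, state, _peek(t, spec, op,
                                    s1_judgements[t], s1_investments[t]))
        p_hi = choice_probability(
            model_id, params, q_ns, q_s_pair, op.judgement, op.masked
        )
        s2_j = "higher" if rng.random() < p_hi else "lower"
        s2_inv = int(np.clip(np.rint(
            rng.normal(advisor_investment_mean, advisor_investment_sd)), 1, 60))

        advice_type = None
        fb = None
        if not op.masked:
            advice_type = "aligned" if s2_j == op.judgement else "misaligned"
            if schedule is not None:
                pref = schedule.phase_preferences[spec.phase_index]
                p_acc = schedule.prob(pref, advice_type)
                fb = int(rng.random() < p_acc)
                if model_id == "M4":
                    state.q_s = m4_update(params, state.q_s, fb, m4_signed_feedback)
                elif model_id in ("M5", "M6", "M7"):
                    state.q_s = rl_update(model_id, params, state.q_s, advice_type, fb)
        records.append(
            TrialRecord(
                trial_index=spec.trial_index,
                phase_index=spec.phase_index,
                s1_judgement=s1_judgements[t],
                s1_investment=int(s1_investments[t]),
                advisee=op,
                s2_judgement=s2_j,
                s2_investment=s2_inv,
                advice_type=advice_type,
                feedback=fb,
            )
        )
    return records


def _peek(t, spec, op, s1_j, s1_inv) -> TrialRecord:
    # minimal TrialRecord view for social_value() during simulation
    return TrialRecord(
        trial_index=t,
        phase_index=spec.phase_index,
        s1_judgement=s1_j,
        s1_investment=s1_inv,
        advisee=op,
    )
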