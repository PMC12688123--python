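"""Synthetic multi-participant cohorts.

Generates complete datasets with the statistical structure the analysis
pipeline assumes: hierarchically sampled individual parameters, the study's
trial/phase design, scripted advisees, and model-simulated advisor
behavior, together with the ground-truth parameters needed for recovery
studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import transforms
from .advisee import AdviseeProfile
from .design import DesignConfig, FEEDBACK_STUDIES, build_session_design
from .errors import InvalidArgumentError
from .models import MODEL_IDS, PARAM_NAMES, ModelParams, TrialRecord, simulate_agent
from .seeding import as_seed_sequence

#: Constrained-scale group means used when a config does not override them.
#: Learning-rate asymmetries for M7 follow the reported acceptance/rejection
#: mean differences (0.51/-0.32 in the 50%-acceptance schedule, 0.55/-0.45
#: in the 30%-acceptance schedule); weights and the remaining rates are
#: package defaults chosen to produce a realistic mix of alignment and
#: self-reliance (see docs/methods.md).
DEFAULT_GROUP_MEANS = {
    "tau": 2.0,
    "w_ns": 2.0,
    "w_s": 1.0,
    "kappa": 0.3,
    "alpha": 0.3,
    "alpha_al": 0.2,
    "alpha_mis": 0.4,
    "alpha_al_ac": 0.60,
    "alpha_al_re": 0.18,
    "alpha_mis_ac": 0.09,
    "alpha_mis_re": 0.50,
}
DEFAULT_GROUP_MEANS_S4 = dict(
    DEFAULT_GROUP_MEANS,
    alpha_al_ac=0.60,
    alpha_al_re=0.05,
    alpha_mis_ac=0.05,
    alpha_mis_re=0.50,
)
DEFAULT_GROUP_SD = 0.5  # on the unconstrained scale


@dataclass(frozen=True)
class GroupConfig:
    """Group-level generating distribution for one model and study."""

    model_id: str
    study_id: str = "S3"
    n_participants: int = 12
    group_means: dict = field(default_factory=dict)  # unconstrained scale
    group_sds: dict = field(default_factory=dict)
    advisor_investment_mean: float = 30.0
    advisor_investment_sd: float = 10.0
    order_counterbalance: bool = True
    design: DesignConfig = DesignConfig()

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise InvalidArgumentError(f"unknown model {self.model_id!r}")
        if self.n_participants < 1:
            raise InvalidArgumentError("n_participants must be >= 1")
        if any(sd < 0 for sd in self.group_sds.values()):
            raise InvalidArgumentError("group sds must be >= 0")

    def resolved_means(self) -> dict:
        """Unconstrained group means, filled from the package defaults."""
        base = (
            DEFAULT_GROUP_MEANS_S4 if self.study_id == "S4" else DEFAULT_GROUP_MEANS
        )
        out = {}
        for name in PARAM_NAMES[self.model_id]:
            if name in self.group_means:
                out[name] = float(self.group_means[name])
            else:
                out[name] = float(transforms.to_unconstrained(base[name], name))
        return out

    def resolved_sds(self) -> dict:
        return {
            name: float(self.group_sds.get(name, DEFAULT_GROUP_SD))
            for name in PARAM_NAMES[self.model_id]
        }


@dataclass
class Cohort:
    """A simulated dataset: trial table plus ground truth."""

    trials: pd.DataFrame
    truth: dict

    @property
    def participant_ids(self) -> list:
        return sorted(self.trials["participant_id"].unique())


def sample_group_parameters(config: GroupConfig, rng_seed=0) -> list:
    """Draw individual parameter sets Normal(mean, sd) on the unconstrained
    scale, then map to bounds with the same transform the fitter uses.
    Returns (params, z) pairs via .truth-style dicts."""
    rng = np.random.default_rng(rng_seed)
    means = config.resolved_means()
    sds = config.resolved_sds()
    names = PARAM_NAMES[config.model_id]
    out = []
    for _ in range(config.n_participants):
        z = {n: float(rng.normal(means[n], sds[n])) for n in names}
        theta = {n: float(transforms.to_constrained(z[n], n)) for n in names}
        out.append((ModelParams(config.model_id, theta), z))
    return out


def records_to_rows(
    participant_id: str, study_id: str, records, schedule=None
) -> list:
    rows = []
    for r in records:
        pref = (
            schedule.phase_preferences[r.phase_index]
            if (schedule is not None and r.phase_index is not None)
            else None
        )
        rows.append(
            {
                "participant_id": participant_id,
                "study_id": study_id,
                "session_id": 2,
                "trial_index": r.trial_index + 1,
                "phase_index": r.phase_index,
                "phase_preference": pref,
                "stimulus_id": r.trial_index,
                "opinion_condition": (
                    "masked"
                    if r.advisee.masked
                    else ("congruent" if r.advisee.judgement == r.s1_judgement
                          else "incongruent")
                ),
                "s1_judgement": r.s1_judgement,
                "s1_investment": r.s1_investment,
                "advisee_judgement": r.advisee.judgement,
                "advisee_investment": r.advisee.investment,
                "s2_judgement": r.s2_judgement,
                "s2_investment": r.s2_investment,
                "advice_type": r.advice_type,
                "feedback": r.feedback,
            }
        )
    return rows


def generate_cohort(config: GroupConfig, rng_seed=0) -> Cohort:
    """Simulate a full cohort under one generating model."""
    ss = as_seed_sequence(rng_seed)
    param_seed, *p_seeds = ss.spawn(config.n_participants + 1)
    draws = sample_group_parameters(config, rng_seed=param_seed)

    rows = []
    truth_participants = []
    for i, ((params, z), seed_i) in enumerate(zip(draws, p_seeds)):
        order = (
            "aligned_first"
            if (not config.order_counterbalance or i % 2 == 0)
            else "misaligned_first"
        )
        risk = "seeking" if (i // 2) % 2 == 0 else "avoiding"
        design_cfg = DesignConfig(
            n_trials=config.design.n_trials,
            n_masked=config.design.n_masked,
            deviation=config.design.deviation,
            price_range=config.design.price_range,
            schedule_order=order,
        )
        d_seed, a_seed = (s.generate_state(1)[0] % (2**31) for s in seed_i.spawn(2))
        design = build_session_design(config.study_id, 2, design_cfg, rng_seed=d_seed)
        profile = (
            AdviseeProfile.risk_seeking()
            if risk == "seeking"
            else AdviseeProfile.risk_avoiding()
        )
        records = simulate_agent(
            config.model_id,
            params,
            design,
            profile,
            rng_seed=a_seed,
            advisor_investment_mean=config.advisor_investment_mean,
            advisor_investment_sd=config.advisor_investment_sd,
        )
        pid = f"P{i + 1:03d}"
        rows.extend(records_to_rows(pid, config.study_id, records, design.schedule))
        truth_participants.append(
            {
                "participant_id": pid,
                "order": order,
                "risk_preference": risk,
                "design_seed": int(d_seed),
                "agent_seed": int(a_seed),
                "params": dict(params.values),
                "z": z,
            }
        )

    trials = pd.DataFrame(rows)
    truth = {
        "model_id": config.model_id,
        "study_id": config.study_id,
        "seed": int(np.asarray(rng_seed).item()) if np.isscalar(rng_seed) else None,
        "config": {
            "n_participants": config.n_participants,
            "group_means": config.resolved_means(),
            "group_sds": config.resolved_sds(),
            "advisor_investment_mean": config.advisor_investment_mean,
            "advisor_investment_sd": config.advisor_investment_sd,
            "order_counterbalance": config.order_counterbalance,
            "design": asdict(config.design),
        },
        "participants": truth_participants,
    }
    return Cohort(trials=trials, truth=truth)
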