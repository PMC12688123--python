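import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from advicerl import (
    AdviseeOpinion,
    DesignConfig,
    ModelParams,
    TrialRecord,
    build_session_design,
    choice_probability,
    init_nonsocial_values,
    phi_normalize,
    rl_update,
    session_loglik,
    simulate_agent,
    social_value,
)
from advicerl.errors import InvalidArgumentError, InvalidStateError
from advicerl.models import PARAM_NAMES, ValueState


def naive_session_loglik(model_id, params, trials):
    """Independent transliteration of the model equations with dict-based
    state; the oracle against which the vectorized path is checked."""
    q = {"align": 1.0, "misalign": 0.0}
    pointwise = []
    for tr in trials:
        qns = {"higher": 0.0, "lower": 0.0}
        qns[tr.s1_judgement] = tr.s1_investment / 60.0
        if model_id == "M1":
            x = params["tau"] * (qns["higher"] - qns["lower"])
        elif tr.advisee.masked:
            x = params["w_ns"] * (qns["higher"] - qns["lower"])
        else:
            if model_id == "M2":
                qs = {"align": 1.0, "misalign": 0.0}
            elif model_id == "M3":
                qs = {"align": abs(tr.advisee.investment) / 60.0, "misalign": 0.0}
            else:
                qs = dict(q)
            if tr.advisee.judgement == "higher":
                qh, ql = qs["align"], qs["misalign"]
            else:
                qh, ql = qs["misalign"], qs["align"]
            x = (
                params["w_ns"] * qns["higher"] + params["w_s"] * qh
                - params["w_ns"] * qns["lower"] - params["w_s"] * ql
            )
        p_higher = 1.0 / (1.0 + math.exp(-x))
        p = p_higher if tr.s2_judgement == "higher" else 1.0 - p_higher
        pointwise.append(math.log(p))
        if tr.feedback is not None:
            r = tr.feedback
            if model_id == "M4":
                q["align"] = q["align"] + params["kappa"] * r
            elif model_id in ("M5", "M6", "M7") and not tr.advisee.masked:
                at = tr.advice_type
                if model_id == "M5":
                    alpha = params["alpha"]
                elif model_id == "M6":
                    alpha = params["alpha_al"] if at == "aligned" else params["alpha_mis"]
                else:
                    alpha = {
                        ("aligned", 1): params["alpha_al_ac"],
                        ("aligned", 0): params["alpha_al_re"],
                        ("misaligned", 1): params["alpha_mis_ac"],
                        ("misaligned", 0): params["alpha_mis_re"],
                    }[(at, r)]
                key = "align" if at == "aligned" else "misalign"
                q[key] = q[key] + alpha * (r - q[key])
    return pointwise


def random_trials(rng, n=30, with_feedback=True, p_masked=0.2):
    trials = []
    for t in range(n):
        s1_j = "higher" if rng.random() < 0.5 else "lower"
        s1_inv = int(rng.integers(1, 61))
        masked = rng.random() < p_masked
        if masked:
            op = AdviseeOpinion(None, None, masked=True)
        else:
            op = AdviseeOpinion(
                "higher" if rng.random() < 0.5 else "lower",
                int(rng.integers(1, 61)),
                masked=False,
            )
        s2_j = "higher" if rng.random() < 0.5 else "lower"
        advice_type = None
        fb = None
        if not masked:
            advice_type = "aligned" if s2_j == op.judgement else "misaligned"
            if with_feedback:
                fb = int(rng.random() < 0.5)
        trials.append(
            TrialRecord(
                trial_index=t,
                phase_index=None,
                s1_judgement=s1_j,
                s1_investment=s1_inv,
                advisee=op,
                s2_judgement=s2_j,
                s2_investment=int(rng.integers(1, 61)),
                advice_type=advice_type,
                feedback=fb,
            )
        )
    return trials


def random_params(model_id, rng):
    vals = {}
    for name in PARAM_NAMES[model_id]:
        if name == "tau":
            vals[name] = float(rng.uniform(0.1, 5.0))
        elif name in ("w_ns", "w_s"):
            vals[name] = float(rng.uniform(0.1, 3.0))
        elif name == "kappa":
            vals[name] = float(rng.uniform(0.01, 0.2))
        else:
            vals[name] = float(rng.uniform(0.05, 0.95))
    return ModelParams(model_id, vals)


class TestPrimitives:
    @pytest.mark.parametrize("wager,expected", [(60, 1.0), (30, 0.5), (1, 1 / 60)])
    def test_phi_normalize(self, wager, expected):
        assert phi_normalize(wager) == pytest.approx(expected)

    def test_phi_rejects_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            phi_normalize(0)
        with pytest.raises(InvalidArgumentError):
            phi_normalize(61)

    @pytest.mark.parametrize(
        "judgement,inv,expected",
        [("higher", 60, (1.0, 0.0)), ("lower", 30, (0.0, 0.5)),
         ("higher", 15, (0.25, 0.0))],
    )
    def test_init_nonsocial_values(self, judgement, inv, expected):
        assert init_nonsocial_values(judgement, inv) == pytest.approx(expected)


class TestSocialValue:
    def shown_trial(self, investment=30):
        return TrialRecord(
            trial_index=0, phase_index=None, s1_judgement="higher", s1_investment=30,
            advisee=AdviseeOpinion("lower", investment, masked=False),
        )

    def test_m2_constant(self):
        params = ModelParams("M2", {"w_ns": 1.0, "w_s": 1.0})
        assert social_value("M2", params, ValueState(), self.shown_trial()) == (1.0, 0.0)

    def test_m3_scaled_by_advisee_confidence(self):
        params = ModelParams("M3", {"w_ns": 1.0, "w_s": 1.0})
        assert social_value("M3", params, ValueState(), self.shown_trial(30)) == (
            0.5, 0.0)

    def test_m4_grows_with_acceptance(self):
        from advicerl.models import m4_update

        params = ModelParams("M4", {"w_ns": 1.0, "w_s": 1.0, "kappa": 0.5})
        q = m4_update(params, (1.0, 0.0), feedback=1)
        assert q == (1.5, 0.0)
        # literal rule: rejection leaves the value unchanged
        assert m4_update(params, (1.0, 0.0), feedback=0) == (1.0, 0.0)
        # signed-feedback variant decreases on rejection
        assert m4_update(params, (1.0, 0.0), feedback=0, signed_feedback=True) == (
            0.5, 0.0)

    def test_masked_trial_rejected(self):
        params = ModelParams("M2", {"w_ns": 1.0, "w_s": 1.0})
        trial = TrialRecord(
            trial_index=0, phase_index=None, s1_judgement="higher", s1_investment=30,
            advisee=AdviseeOpinion(None, None, masked=True),
        )
        with pytest.raises(InvalidStateError):
            social_value("M2", params, ValueState(), trial)


class TestRlUpdate:
    def test_m5_rejection_example(self):
        params = ModelParams("M5", {"w_ns": 1.0, "w_s": 1.0, "alpha": 0.2})
        assert rl_update("M5", params, (1.0, 0.0), "aligned", 0) == pytest.approx(
            (0.8, 0.0))

    def test_m7_misaligned_acceptance(self):
        vals = {"w_ns": 1.0, "w_s": 1.0, "alpha_al_ac": 0.1, "alpha_al_re": 0.1,
                "alpha_mis_ac": 0.5, "alpha_mis_re": 0.1}
        params = ModelParams("M7", vals)
        assert rl_update("M7", params, (1.0, 0.0), "misaligned", 1) == pytest.approx(
            (1.0, 0.5))

    def test_vanishing_alpha_freezes_values(self):
        params = ModelParams("M5", {"w_ns": 1.0, "w_s": 1.0, "alpha": 1e-12})
        q = rl_update("M5", params, (0.7, 0.2), "aligned", 0)
        assert q == pytest.approx((0.7, 0.2), abs=1e-10)

    @given(
        alphas=st.lists(st.floats(0.01, 0.99), min_size=4, max_size=4),
        seq=st.lists(st.tuples(st.booleans(), st.booleans()), max_size=40),
    )
    def test_values_stay_in_unit_interval(self, alphas, seq):
        vals = {"w_ns": 1.0, "w_s": 1.0, "alpha_al_ac": alphas[0],
                "alpha_al_re": alphas[1], "alpha_mis_ac": alphas[2],
                "alpha_mis_re": alphas[3]}
        params = ModelParams("M7", vals)
        q = (1.0, 0.0)
        for aligned, accepted in seq:
            q = rl_update(
                "M7", params, q, "aligned" if aligned else "misaligned", int(accepted))
            assert 0.0 <= q[0] <= 1.0 and 0.0 <= q[1] <= 1.0


class TestChoiceProbability:
    def test_m1_softmax_example(self):
        params = ModelParams("M1", {"tau": 1.0})
        p = choice_probability("M1", params, (1.0, 0.0), None, None, masked=True)
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_symmetric_values_give_half(self):
        params = ModelParams("M2", {"w_ns": 1.0, "w_s": 1.0})
        p = choice_probability("M2", params, (0.3, 0.3), (0.5, 0.5), "higher", False)
        assert p == pytest.approx(0.5)

    def test_m2_social_cancels_nonsocial(self):
        # q_ns favors higher by 1; advisee says lower so the aligned value
        # maps onto lower; with unit weights the sums tie
        params = ModelParams("M2", {"w_ns": 1.0, "w_s": 1.0})
        p = choice_probability("M2", params, (1.0, 0.0), (1.0, 0.0), "lower", False)
        assert p == pytest.approx(0.5)

    @given(
        w_ns=st.floats(0.1, 5.0), w_s=st.floats(0.1, 5.0),
        qh=st.floats(0, 1), ql=st.floats(0, 1), qa=st.floats(0, 1),
        adv_higher=st.booleans(),
    )
    def test_probabilities_sum_to_one(self, w_ns, w_s, qh, ql, qa, adv_higher):
        params = ModelParams("M2", {"w_ns": w_ns, "w_s": w_s})
        adv = "higher" if adv_higher else "lower"
        p = choice_probability("M2", params, (qh, ql), (qa, 1 - qa), adv, False)
        q = choice_probability("M2", params, (ql, qh), (1 - qa, qa), adv, False)
        assert 0.0 < p < 1.0
        # swapping both value pairs swaps the options, so probabilities mirror
        adv_flip = "lower" if adv_higher else "higher"
        p_flip = choice_probability(
            "M2", params, (ql, qh), (qa, 1 - qa), adv_flip, False)
        assert p + p_flip == pytest.approx(1.0, abs=1e-12)


class TestSessionLoglik:
    def test_single_trial_closed_form(self):
        trial = TrialRecord(
            trial_index=0, phase_index=None, s1_judgement="higher", s1_investment=30,
            advisee=AdviseeOpinion("lower", 30, masked=False),
            s2_judgement="higher", s2_investment=30, advice_type="misaligned",
        )
        params = ModelParams("M2", {"w_ns": 1.0, "w_s": 0.5})
        # Q(h)-Q(l) = 1*0.5 + 0.5*(0-1) = 0  ->  p = 0.5
        total, pointwise = session_loglik("M2", params, [trial])
        assert total == pytest.approx(math.log(0.5), abs=1e-12)
        assert len(pointwise) == 1

    @pytest.mark.parametrize("model_id", list(PARAM_NAMES))
    def test_matches_naive_oracle(self, model_id):
        rng = np.random.default_rng(42)
        for _ in range(15):
            trials = random_trials(rng)
            params = random_params(model_id, rng)
            total, pointwise = session_loglik(model_id, params, trials)
            oracle = naive_session_loglik(model_id, params.values, trials)
            assert np.allclose(pointwise, oracle, atol=1e-10, rtol=0)
            assert total == pytest.approx(sum(oracle), abs=1e-9)

    def test_pointwise_sums_to_total(self):
        rng = np.random.default_rng(7)
        trials = random_trials(rng)
        params = random_params("M7", rng)
        total, pointwise = session_loglik("M7", params, trials)
        assert total == pytest.approx(pointwise.sum(), abs=1e-12)

    def test_nesting_m7_to_m6_to_m5_to_m2(self):
        rng = np.random.default_rng(11)
        trials = random_trials(rng)
        a1, a2 = 0.3, 0.6
        w = {"w_ns": 1.2, "w_s": 0.8}
        m7 = ModelParams("M7", dict(w, alpha_al_ac=a1, alpha_al_re=a1,
                                    alpha_mis_ac=a2, alpha_mis_re=a2))
        m6 = ModelParams("M6", dict(w, alpha_al=a1, alpha_mis=a2))
        t7, _ = session_loglik("M7", m7, trials)
        t6, _ = session_loglik("M6", m6, trials)
        assert t7 == pytest.approx(t6, abs=1e-9)

        m6_eq = ModelParams("M6", dict(w, alpha_al=a1, alpha_mis=a1))
        m5 = ModelParams("M5", dict(w, alpha=a1))
        assert session_loglik("M6", m6_eq, trials)[0] == pytest.approx(
            session_loglik("M5", m5, trials)[0], abs=1e-9)

        m5_frozen = ModelParams("M5", dict(w, alpha=1e-13))
        m2 = ModelParams("M2", w)
        assert session_loglik("M5", m5_frozen, trials)[0] == pytest.approx(
            session_loglik("M2", m2, trials)[0], abs=1e-9)

    def test_missing_session2_judgement_names_trial(self):
        trial = TrialRecord(
            trial_index=4, phase_index=None, s1_judgement="higher", s1_investment=30,
            advisee=AdviseeOpinion(None, None, masked=True),
        )
        params = ModelParams("M1", {"tau": 1.0})
        with pytest.raises(InvalidArgumentError, match="trial 4"):
            session_loglik("M1", params, [trial])


class TestSimulateAgent:
    def test_same_seed_identical_records(self):
        design = build_session_design("S3", 2, rng_seed=3)
        params = ModelParams("M5", {"w_ns": 1.0, "w_s": 1.0, "alpha": 0.3})
        from advicerl import AdviseeProfile

        a = simulate_agent("M5", params, design, AdviseeProfile.risk_seeking(), 5)
        b = simulate_agent("M5", params, design, AdviseeProfile.risk_seeking(), 5)
        assert a == b

    def test_m2_dominant_social_weight_aligns_almost_always(self):
        config = DesignConfig(n_trials=660, n_masked=0)
        design = build_session_design("S1", 2, config, rng_seed=1)
        params = ModelParams("M2", {"w_ns": 0.1, "w_s": 9.5})
        from advicerl import AdviseeProfile

        records = simulate_agent("M2", params, design, AdviseeProfile.risk_seeking(), 2)
        aligned = [r.advice_type == "aligned" for r in records if r.advice_type]
        assert np.mean(aligned) > 0.95

    def test_m1_alignment_matches_analytic_mixture(self):
        # without social value, P(align) is the analytic mixture of
        # P(repeat Session-1 judgement) over congruent/incongruent trials
        config = DesignConfig(n_trials=660, n_masked=0)
        design = build_session_design("S1", 2, config, rng_seed=8)
        params = ModelParams("M1", {"tau": 1.5})
        from advicerl import AdviseeProfile

        records = simulate_agent("M1", params, design, AdviseeProfile.risk_seeking(), 4)
        expected, simulated = [], []
        for r in records:
            if r.advice_type is None:
                continue
            p_repeat = 1 / (1 + math.exp(-params["tau"] * r.s1_investment / 60))
            congruent = r.advisee.judgement == r.s1_judgement
            expected.append(p_repeat if congruent else 1 - p_repeat)
            simulated.append(r.advice_type == "aligned")
        se = np.sqrt(np.mean(expected) * (1 - np.mean(expected)) / len(simulated))
        assert abs(np.mean(simulated) - np.mean(expected)) < 4 * se
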