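"""Model fitting and comparison.

Two fitting routes share one probability model:

* individual parameters live on an unconstrained scale and are mapped to
  their bounds through the standard-normal CDF (learning rates and kappa
  to (0,1), weights to (0,10), tau to (0,20));
* the hierarchical prior is non-centered: theta_i = F(mu + sigma * z_i)
  with mu ~ Normal(0,1), sigma ~ HalfNormal(1), z_i ~ Normal(0,1).

``method="map"`` (the fast default) maximizes each participant's
posterior under the standard-normal prior and approximates the posterior
with a Laplace (Gaussian) expansion around the mode, from which draws and
the pointwise log-likelihood matrix are generated.  ``method="mcmc"``
samples the full hierarchical posterior with an affine-invariant ensemble
sampler and checks split-Rhat.

Model comparison uses PSIS-LOO (via arviz) on the trial-pointwise
log-likelihood, and pseudo-BMA+ model weights via the Bayesian bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, ndtr

from . import transforms
from .errors import ConvergenceError, InvalidArgumentError
from .models import (
    PARAM_NAMES,
    ModelParams,
    SessionArrays,
    prepare_session_arrays,
    session_loglik_arrays,
)


@dataclass(frozen=True)
class FitConfig:
    method: str = "map"  # "map" | "mcmc"
    seed: int = 0
    # MAP / Laplace
    n_laplace_draws: int = 200
    n_restarts: int = 2
    # MCMC
    chains: int = 4  # walker groups folded into chains for diagnostics
    warmup: int = 1000
    draws: int = 1000
    rhat_threshold: float = 1.05
    raise_on_diagnostics: bool = True


@dataclass
class PosteriorFit:
    model_id: str
    method: str
    param_names: tuple
    participant_ids: list
    #: individual-level draws on the constrained scale,
    #: name -> array (n_draws, n_participants)
    draws: dict
    #: group-level draws on the unconstrained scale, name -> (n_draws,)
    group_mean_draws: dict
    group_sd_draws: dict
    #: (n_draws, n_total_trials), trials ordered participant-major
    pointwise_loglik: np.ndarray
    diagnostics: dict
    config: FitConfig

    def posterior_mean_params(self) -> pd.DataFrame:
        """Posterior-mean individual parameters (participants x parameters)."""
        data = {name: self.draws[name].mean(axis=0) for name in self.param_names}
        return pd.DataFrame(data, index=self.participant_ids)

    def posterior_median_params(self) -> pd.DataFrame:
        data = {name: np.median(self.draws[name], axis=0) for name in self.param_names}
        return pd.DataFrame(data, index=self.participant_ids)


@dataclass(frozen=True)
class LooResult:
    looic: float
    se: float
    elpd: float
    elpd_pointwise: np.ndarray
    p_loo: float
    pareto_k: Optional[np.ndarray]


def _sessions_from_dataset(dataset) -> dict:
    """Accept a Cohort, a trial DataFrame, or a {pid: [TrialRecord]} dict."""
    from .io import records_from_frame  # local import to avoid cycles

    if hasattr(dataset, "trials"):
        dataset = dataset.trials
    if isinstance(dataset, pd.DataFrame):
        dataset = records_from_frame(dataset)
    if not isinstance(dataset, dict) or not dataset:
        raise InvalidArgumentError("dataset must contain at least one participant")
    return {pid: prepare_session_arrays(recs) for pid, recs in dataset.items()}


def _neg_log_post(z, model_id, arr, prior_mean, prior_sd):
    theta = np.array(
        [transforms.to_constrained(zi, n) for zi, n in zip(z, PARAM_NAMES[model_id])]
    )
    ll = session_loglik_arrays(model_id, theta, arr).sum()
    lp = -0.5 * np.sum(((z - prior_mean) / prior_sd) ** 2)
    return -(ll + lp)


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy()
            xi[i] += eps
            xi[j] += eps
            fpp = f(xi)
            xi = x.copy()
            xi[i] += eps
            xi[j] -= eps
            fpm = f(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] += eps
            fmp = f(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] -= eps
            fmm = f(xi)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


def _fit_map(model_id, sessions, config: FitConfig) -> PosteriorFit:
    names = PARAM_NAMES[model_id]
    p = len(names)
    pids = sorted(sessions)
    rng = np.random.default_rng(config.seed)
    prior_mean = np.zeros(p)
    prior_sd = np.ones(p)

    z_maps, covs, successes = [], [], []
    for pid in pids:
        arr = sessions[pid]
        obj = lambda z: _neg_log_post(z, model_id, arr, prior_mean, prior_sd)
        best = None
        starts = [np.zeros(p)] + [
            rng.normal(0, 1, size=p) for _ in range(config.n_restarts)
        ]
        for x0 in starts:
            res = optimize.minimize(obj, x0, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        hess = _numeric_hessian(obj, best.x)
        # regularize to a valid covariance
        w, v = np.linalg.eigh(hess)
        w = np.clip(w, 1e-4, None)
        cov = (v / w) @ v.T
        z_maps.append(best.x)
        covs.append(cov)
        successes.append(bool(best.success))

    n_draws = config.n_laplace_draws
    draws_c = {n: np.empty((n_draws, len(pids))) for n in names}
    blocks = []
    for k, pid in enumerate(pids):
        zs = rng.multivariate_normal(z_maps[k], covs[k], size=n_draws)
        arr = sessions[pid]
        block = np.empty((n_draws, arr.n_trials))
        for s in range(n_draws):
            theta = np.array(
                [transforms.to_constrained(zi, n) for zi, n in zip(zs[s], names)]
            )
            block[s] = session_loglik_arrays(model_id, theta, arr)
            for j, n in enumerate(names):
                draws_c[n][s, k] = theta[j]
        blocks.append(block)
    pointwise = np.hstack(blocks)

    z_arr = np.asarray(z_maps)
    group_mean = {n: np.full(n_draws, z_arr[:, j].mean()) for j, n in enumerate(names)}
    group_sd = {
        n: np.full(n_draws, z_arr[:, j].std(ddof=1) if len(pids) > 1 else 0.0)
        for j, n in enumerate(names)
    }
    diagnostics = {
        "method": "map_laplace",
        "rhat": {n: 1.0 for n in names},
        "ess": {n: float(n_draws) for n in names},
        "divergences": 0,
        "optimizer_success": successes,
        "converged": all(successes),
    }
    return PosteriorFit(
        model_id=model_id,
        method="map",
        param_names=names,
        participant_ids=pids,
        draws=draws_c,
        group_mean_draws=group_mean,
        group_sd_draws=group_sd,
        pointwise_loglik=pointwise,
        diagnostics=diagnostics,
        config=config,
    )


def _hier_log_prob(x, model_id, arr_list, p, n_sub):
    mu = x[:p]
    log_sigma = x[p : 2 * p]
    sigma = np.exp(log_sigma)
    z = x[2 * p :].reshape(n_sub, p)
    lp = -0.5 * np.sum(mu**2)
    lp += np.sum(-0.5 * sigma**2 + log_sigma)  # HalfNormal(1) + Jacobian
    lp += -0.5 * np.sum(z**2)
    names = PARAM_NAMES[model_id]
    for i, arr in enumerate(arr_list):
        zi = mu + sigma * z[i]
        theta = np.array(
            [transforms.to_constrained(v, n) for v, n in zip(zi, names)]
        )
        lp += session_loglik_arrays(model_id, theta, arr).sum()
    if not np.isfinite(lp):
        return -np.inf
    return lp


def _fit_mcmc(model_id, sessions, config: FitConfig) -> PosteriorFit:
    import emcee

    names = PARAM_NAMES[model_id]
    p = len(names)
    pids = sorted(sessions)
    arr_list = [sessions[pid] for pid in pids]
    n_sub = len(pids)
    ndim = 2 * p + n_sub * p
    nwalkers = max(2 * ndim + 2, 2 * config.chains)
    if nwalkers % 2:
        nwalkers += 1
    rng = np.random.default_rng(config.seed)
    p0 = 0.1 * rng.standard_normal((nwalkers, ndim))
    p0[:, p : 2 * p] -= 1.0  # start sigmas below 1

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, _hier_log_prob, args=(model_id, arr_list, p, n_sub)
    )
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed).get_state())
    state = sampler.run_mcmc(state, config.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.draws, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim)

    # fold walkers into config.chains pseudo-chains for split-Rhat
    steps = chain.shape[0]
    per = nwalkers // config.chains
    folded = np.concatenate(
        [
            chain[:, c * per : (c + 1) * per, :].reshape(-1, ndim)[None]
            for c in range(config.chains)
        ],
        axis=0,
    )  # (chains, chain_draws, ndim)

    mu_draws = {n: folded[:, :, j] for j, n in enumerate(names)}
    sd_draws = {n: np.exp(folded[:, :, p + j]) for j, n in enumerate(names)}
    rhat_vals = {}
    for n in names:
        rhat_vals[f"mu_{n}"] = float(az.rhat(mu_draws[n]))
        rhat_vals[f"sigma_{n}"] = float(az.rhat(sd_draws[n]))

    flat = folded.reshape(-1, ndim)
    total = flat.shape[0]
    keep = min(config.draws, total)
    idx = np.linspace(0, total - 1, keep).astype(int)
    flat = flat[idx]

    draws_c = {n: np.empty((keep, n_sub)) for n in names}
    pointwise_blocks = [np.empty((keep, a.n_trials)) for a in arr_list]
    for s, x in enumerate(flat):
        mu = x[:p]
        sigma = np.exp(x[p : 2 * p])
        z = x[2 * p :].reshape(n_sub, p)
        for i, arr in enumerate(arr_list):
            zi = mu + sigma * z[i]
            theta = np.array(
                [transforms.to_constrained(v, n) for v, n in zip(zi, names)]
            )
            for j, n in enumerate(names):
                draws_c[n][s, i] = theta[j]
            pointwise_blocks[i][s] = session_loglik_arrays(model_id, theta, arr)
    pointwise = np.hstack(pointwise_blocks)

    diagnostics = {
        "method": "emcee_ensemble",
        "rhat": rhat_vals,
        "ess": {
            n: float(az.ess(mu_draws[n])) for n in names
        },
        "divergences": 0,
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "converged": all(v <= config.rhat_threshold for v in rhat_vals.values()),
    }
    fit = PosteriorFit(
        model_id=model_id,
        method="mcmc",
        param_names=names,
        participant_ids=pids,
        draws=draws_c,
        group_mean_draws={n: flat[:, j] for j, n in enumerate(names)},
        group_sd_draws={n: np.exp(flat[:, p + j]) for j, n in enumerate(names)},
        pointwise_loglik=pointwise,
        diagnostics=diagnostics,
        config=config,
    )
    if config.raise_on_diagnostics and not diagnostics["converged"]:
        worst = max(rhat_vals.items(), key=lambda kv: kv[1])
        raise ConvergenceError(
            f"{model_id}: split-Rhat {worst[1]:.3f} for {worst[0]} exceeds "
            f"{config.rhat_threshold}; increase warmup/draws",
            fit=fit,
        )
    return fit


def fit_model(model_id: str, dataset, config: FitConfig = FitConfig()) -> PosteriorFit:
    """Fit one of M1-M7 to a dataset (Cohort, trial table or record dict)."""
    if model_id not in PARAM_NAMES:
        raise InvalidArgumentError(f"unknown model {model_id!r}")
    sessions = _sessions_from_dataset(dataset)
    if config.method == "map":
        return _fit_map(model_id, sessions, config)
    if config.method == "mcmc":
        return _fit_mcmc(model_id, sessions, config)
    raise InvalidArgumentError(f"unknown fit method {config.method!r}")


# ---------------------------------------------------------------------------
# LOO and model weights
# ---------------------------------------------------------------------------


def compute_looic(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO information criterion from a (draws x trials) matrix."""
    mat = np.asarray(pointwise_loglik, dtype=float)
    if mat.ndim != 2:
        raise InvalidArgumentError("pointwise_loglik must be 2-D (draws x trials)")
    if not np.all(np.isfinite(mat)):
        raise InvalidArgumentError("pointwise_loglik contains non-finite values")
    n_draws, n_obs = mat.shape
    if n_draws == 1:
        # a single draw carries no importance-sampling information; the LOO
        # estimate degenerates to the plug-in log predictive density
        elpd_i = mat[0]
        elpd = float(elpd_i.sum())
        se = float(np.sqrt(n_obs * np.var(elpd_i)))
        return LooResult(-2 * elpd, 2 * se, elpd, elpd_i, 0.0, None)
    if np.allclose(mat, mat[0]):
        warnings.warn("all posterior draws identical; LOO is degenerate")
        elpd_i = mat[0]
        elpd = float(elpd_i.sum())
        se = float(np.sqrt(n_obs * np.var(elpd_i)))
        return LooResult(-2 * elpd, 2 * se, elpd, elpd_i, 0.0, None)
    idata = az.from_dict(
        posterior={"theta": np.zeros((1, n_draws))},
        log_likelihood={"obs": mat[None, :, :]},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(idata, pointwise=True, reff=1.0)
    elpd = float(loo.elpd_loo)
    se = float(loo.se)
    return LooResult(
        looic=-2 * elpd,
        se=2 * se,
        elpd=elpd,
        elpd_pointwise=np.asarray(loo.loo_i.values),
        p_loo=float(loo.p_loo),
        pareto_k=np.asarray(loo.pareto_k.values),
    )


def model_weights(
    pointwise_logliks: Sequence[np.ndarray],
    n_bootstrap: int = 1000,
    rng_seed: int = 0,
) -> np.ndarray:
    """Pseudo-BMA+ model weights via the Bayesian bootstrap.

    Each model's trial-pointwise elpd (from PSIS-LOO) is resampled with
    Dirichlet(1,...,1) weights; per replicate the models are weighted by a
    softmax of their weighted-total elpd, and the final weight is the
    average over replicates.
    """
    mats = [np.asarray(m) for m in pointwise_logliks]
    if len(mats) < 2:
        raise InvalidArgumentError("need at least two models to weight")
    n_obs = mats[0].shape[1]
    if any(m.shape[1] != n_obs for m in mats):
        raise InvalidArgumentError("pointwise matrices differ in trial dimension")
    elpds = np.array([compute_looic(m).elpd_pointwise for m in mats])  # (M, n)
    rng = np.random.default_rng(rng_seed)
    alpha = rng.dirichlet(np.ones(n_obs), size=n_bootstrap)  # (B, n)
    totals = n_obs * alpha @ elpds.T  # (B, M)
    totals -= totals.max(axis=1, keepdims=True)
    w = np.exp(totals)
    w /= w.sum(axis=1, keepdims=True)
    return w.mean(axis=0)


def compare_models(
    fits: Dict[str, PosteriorFit], n_bootstrap: int = 1000, rng_seed: int = 0
) -> pd.DataFrame:
    """Comparison table: parameter count, LOOIC, delta-LOOIC vs best, SE,
    and pseudo-BMA+ weight, sorted best first."""
    model_ids = list(fits)
    loos = {m: compute_looic(fits[m].pointwise_loglik) for m in model_ids}
    weights = model_weights(
        [fits[m].pointwise_loglik for m in model_ids],
        n_bootstrap=n_bootstrap,
        rng_seed=rng_seed,
    )
    best = min(loos.values(), key=lambda r: r.looic).looic
    table = pd.DataFrame(
        {
            "model_id": model_ids,
            "n_params": [len(PARAM_NAMES[m]) for m in model_ids],
            "looic": [loos[m].looic for m in model_ids],
            "delta_looic": [loos[m].looic - best for m in model_ids],
            "se": [loos[m].se for m in model_ids],
            "weight": weights,
        }
    ).sort_values("looic", ignore_index=True)
    return table


def compute_delta_a(params: ModelParams) -> float:
    """Learning bias index for M7:
    (alpha_al_ac - alpha_mis_ac) + (alpha_mis_re - alpha_al_re)."""
    if params.model_id != "M7":
        raise InvalidArgumentError("delta-a is defined for M7 only")
    return (params["alpha_al_ac"] - params["alpha_mis_ac"]) + (
        params["alpha_mis_re"] - params["alpha_al_re"]
    )


def delta_a_from_fit(fit: PosteriorFit) -> pd.Series:
    """Per-participant posterior-mean delta-a from an M7 fit."""
    if fit.model_id != "M7":
        raise InvalidArgumentError("delta-a is defined for M7 only")
    means = fit.posterior_mean_params()
    return (means["alpha_al_ac"] - means["alpha_mis_ac"]) + (
        means["alpha_mis_re"] - means["alpha_al_re"]
    )
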