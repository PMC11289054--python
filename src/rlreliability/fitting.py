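"""Parameter estimation: MLE, MAP, hierarchical Bayes, and model selection.

Three estimation regimes are provided as scikit-learn-style estimators:

* :class:`MLEFitter` — bounded L-BFGS-B maximum likelihood with random
  restarts (20 by default);
* :class:`MAPFitter` — penalised likelihood with beta priors on the
  unit-interval parameters (tau on the tau/20 scale); with uniform
  priors this reduces to MLE;
* :class:`HierarchicalBayesFitter` — participant parameters drawn from
  group-level beta distributions (group means uniform on [0, 1], group
  precisions uniform on [2, 600]), sampled by MCMC; and
* :class:`JointHierarchicalFitter` — both sessions modelled at once
  with a free cross-session correlation per parameter.

Fit indices are BIC (per session, summed over participants for study
tables) and DIC for the hierarchical fits. Module-level functions
(:func:`fit_mle` etc.) are thin wrappers over the estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._samplers import CohortLikelihood, sample_hierarchical, sample_joint
from .models import ModelSpec, ParamSet, TAU_MAX, encode_session, nll_vector

__all__ = [
    "FitResult",
    "PriorSpec",
    "GroupFitResult",
    "JointFitResult",
    "MLEFitter",
    "MAPFitter",
    "HierarchicalBayesFitter",
    "JointHierarchicalFitter",
    "fit_mle",
    "fit_map",
    "fit_hbayes",
    "fit_joint_hbayes",
    "compute_bic",
    "compute_dic",
    "empirical_priors",
    "select_model",
    "results_to_frame",
]


def compute_bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``k*ln(n) + 2*nll``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) + 2.0 * nll


def compute_dic(deviance_samples: np.ndarray, deviance_at_posterior_mean: float) -> float:
    """Deviance information criterion: mean deviance plus pD."""
    dev = np.asarray(deviance_samples, dtype=float).ravel()
    if dev.size == 0:
        raise ValueError("empty deviance trace")
    mean_dev = float(dev.mean())
    pd_ = mean_dev - float(deviance_at_posterior_mean)
    return mean_dev + pd_


def select_model(fit_table: dict[str, float], n_params: Optional[dict[str, int]] = None) -> str:
    """Best model by total BIC/DIC; ties go to the model with fewer parameters."""
    if len(fit_table) < 2:
        raise ValueError("need at least two models to select among")
    items = list(fit_table.items())
    best_score = min(v for _, v in items)
    tied = [name for name, v in items if v == best_score]
    if len(tied) == 1 or n_params is None:
        return tied[0]
    return min(tied, key=lambda m: (n_params.get(m, np.inf), m))


@dataclass(frozen=True)
class FitResult:
    """Point-estimate fit of one session."""

    params: ParamSet
    nll: float
    bic: float
    n_restarts_used: int
    best_restart_index: int
    converged: bool
    objective: float = math.nan  # penalised objective for MAP; nll for MLE

    def to_dict(self) -> dict:
        d = {"nll": self.nll, "bic": self.bic, "converged": self.converged,
             "n_restarts_used": self.n_restarts_used,
             "best_restart_index": self.best_restart_index}
        d.update(self.params.to_dict())
        return d


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior shapes per parameter; tau's apply to tau/20."""

    shapes: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (a, b) in self.shapes.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"beta shapes for {name} must be positive")

    @classmethod
    def uniform(cls, spec: ModelSpec) -> "PriorSpec":
        return cls({name: (1.0, 1.0) for name in spec.param_names})

    def log_pdf(self, name: str, x_unit: float) -> float:
        a, b = self.shapes[name]
        if x_unit <= 0.0 or x_unit >= 1.0:
            return -np.inf
        return ((a - 1.0) * math.log(x_unit) + (b - 1.0) * math.log(1.0 - x_unit)
                - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)))


def _moment_match_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta shapes with the given mean and sd on [0, 1]."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} outside (0, 1)")
    var = sd * sd
    cap = mean * (1.0 - mean)
    if var >= cap:
        var = 0.98 * cap  # clip into the feasible beta range
    nu = cap / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def empirical_priors(mle_results: Sequence[FitResult], spec: ModelSpec) -> PriorSpec:
    """Moment-matched beta priors from a cohort of MLE fits.

    Each parameter's estimates (tau first divided by 20) are summarised
    by mean and sd and matched to beta shapes; degenerate estimate
    distributions fall back to a uniform prior with a warning.
    """
    if len(mle_results) < 3:
        raise ValueError("need at least three participants to form empirical priors")
    mat = np.array([r.params.to_vector(spec) for r in mle_results])
    shapes = {}
    for j, name in enumerate(spec.param_names):
        vals = mat[:, j] / (TAU_MAX if name == "tau" else 1.0)
        m, s = float(vals.mean()), float(vals.std(ddof=1))
        if s < 1e-8 or not 0.0 < m < 1.0:
            warnings.warn(f"degenerate MLE estimate distribution for {name}; "
                          "using uniform prior")
            shapes[name] = (1.0, 1.0)
        else:
            shapes[name] = _moment_match_beta(m, s)
    return PriorSpec(shapes)


class _PointFitter(BaseEstimator):
    """Shared restart machinery for MLE and MAP."""

    def __init__(self, model=None, n_restarts=20, seed=None, gating="pe_sign"):
        self.model = model
        self.n_restarts = n_restarts
        self.seed = seed
        self.gating = gating

    def _penalty(self, x: np.ndarray, spec: ModelSpec) -> float:
        return 0.0

    def _bounds(self, spec: ModelSpec):
        return spec.bounds

    def fit(self, session):
        """Fit one session; sets params_, nll_, bic_, result_."""
        spec = self.model if self.model is not None else ModelSpec(task_kind=session.task_kind)
        if session.task_kind != spec.task_kind:
            raise ValueError(
                f"session task {session.task_kind!r} does not match model task {spec.task_kind!r}")
        enc = encode_session(session)
        if enc.n_valid == 0:
            raise ValueError("session has no valid trials after timeout removal")
        rng = np.random.default_rng(self.seed)
        bounds = self._bounds(spec)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def objective(x):
            return nll_vector(x, enc, spec, self.gating) + self._penalty(x, spec)

        best = None
        best_idx = -1
        any_ok = False
        for i in range(self.n_restarts):
            x0 = rng.uniform(lo, hi)
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best, best_idx = res, i
        params = ParamSet.from_vector(np.clip(best.x, lo, hi), spec)
        nll = float(nll_vector(best.x, enc, spec, self.gating))
        self.model_ = spec
        self.params_ = params
        self.nll_ = nll
        self.objective_ = float(best.fun)
        self.bic_ = compute_bic(nll, spec.n_params, enc.n_valid)
        self.converged_ = bool(any_ok)
        self.result_ = FitResult(params, nll, self.bic_, self.n_restarts, best_idx,
                                 self.converged_, objective=float(best.fun))
        return self


class MLEFitter(_PointFitter):
    """Maximum-likelihood fit with bounded L-BFGS-B and random restarts."""


class MAPFitter(_PointFitter):
    """Maximum a posteriori fit: likelihood penalised by beta prior densities.

    ``priors=None`` means uniform priors, in which case MAP equals MLE.
    """

    def __init__(self, model=None, priors=None, n_restarts=20, seed=None, gating="pe_sign"):
        super().__init__(model=model, n_restarts=n_restarts, seed=seed, gating=gating)
        self.priors = priors

    def _bounds(self, spec: ModelSpec):
        # keep strictly inside (0, 1) where the beta log-density is finite
        eps = 1e-6
        return tuple((b[0] + eps * (b[1] - b[0]), b[1] - eps * (b[1] - b[0]))
                     for b in spec.bounds)

    def _penalty(self, x: np.ndarray, spec: ModelSpec) -> float:
        priors = self.priors if self.priors is not None else PriorSpec.uniform(spec)
        pen = 0.0
        for j, name in enumerate(spec.param_names):
            unit = x[j] / (TAU_MAX if name == "tau" else 1.0)
            pen -= priors.log_pdf(name, unit)
        return pen


def fit_mle(session, spec: ModelSpec, n_restarts: int = 20, seed=None,
            gating: str = "pe_sign") -> FitResult:
    """Maximum-likelihood fit of one session (20 random restarts by default)."""
    return MLEFitter(spec, n_restarts=n_restarts, seed=seed, gating=gating).fit(session).result_


def fit_map(session, spec: ModelSpec, priors: Optional[PriorSpec] = None,
            n_restarts: int = 20, seed=None, gating: str = "pe_sign") -> FitResult:
    """Maximum a posteriori fit of one session under beta priors."""
    return MAPFitter(spec, priors=priors, n_restarts=n_restarts,
                     seed=seed, gating=gating).fit(session).result_


@dataclass
class GroupFitResult:
    """Posterior summary of a hierarchical fit of one session cohort."""

    model: ModelSpec
    participant_ids: list[str]
    participant_summary: pd.DataFrame  # participant, parameter, mean, sd, lo, hi (native scale)
    group_mean: dict[str, float]       # posterior mean of omega per parameter (unit scale)
    group_mean_sd: dict[str, float]
    group_precision: dict[str, float]
    dic: float
    max_rhat: float
    min_ess: float
    converged: bool
    informed_prior_source: str = "none"

    def point_estimates(self) -> pd.DataFrame:
        """Wide per-participant posterior means (native scale)."""
        return self.participant_summary.pivot(index="participant", columns="parameter",
                                              values="mean")


def _native(x_unit: np.ndarray, spec: ModelSpec) -> np.ndarray:
    out = x_unit.copy()
    out[..., 0] *= TAU_MAX
    return out


def _diagnostics(draws: dict[str, np.ndarray]) -> tuple[float, float]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=draws)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = max(float(np.nanmax(rhat[v].values)) for v in draws)
    min_ess = min(float(np.nanmin(ess[v].values)) for v in draws)
    return max_rhat, min_ess


class HierarchicalBayesFitter(BaseEstimator):
    """Hierarchical Bayesian fit of a cohort of single-session data.

    Per model parameter, participant values on the unit scale follow a
    beta distribution whose mean (uniform on [0, 1]) and precision
    (uniform on [2, 600]) are themselves sampled; tau is modelled on the
    tau/20 scale and rescaled in the summaries. Point estimates are
    posterior means. Non-convergence (max split R-hat > 1.1) flags the
    result but does not raise.
    """

    def __init__(self, model=None, n_chains=4, n_draws=1000, n_warmup=1000,
                 seed=None, gating="pe_sign", informed_prior=None, init_restarts=5):
        self.model = model
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.seed = seed
        self.gating = gating
        self.informed_prior = informed_prior
        self.init_restarts = init_restarts

    def fit(self, sessions):
        sessions = list(sessions)
        if len(sessions) < 2:
            raise ValueError("hierarchical fitting needs at least two participants")
        spec = self.model if self.model is not None else ModelSpec(task_kind=sessions[0].task_kind)
        cohort = CohortLikelihood(sessions, spec, self.gating)
        ss = np.random.SeedSequence(self.seed)
        s_init, s_mcmc = ss.spawn(2)
        init = self._initial_values(sessions, spec, s_init)

        omega_prior = None
        source = "none"
        if self.informed_prior is not None:
            omega_prior = self._omega_prior(self.informed_prior, spec)
            source = "T1"

        draws = sample_hierarchical(
            cohort, init, n_chains=self.n_chains, n_draws=self.n_draws,
            n_warmup=self.n_warmup, seed=int(s_mcmc.generate_state(1)[0] % (2**31)),
            omega_prior=omega_prior)

        x_native = _native(draws.x, spec)  # (chains, draws, n, k)
        flat = x_native.reshape(-1, *x_native.shape[2:])
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        lo = np.quantile(flat, 0.025, axis=0)
        hi = np.quantile(flat, 0.975, axis=0)
        ids = [s.participant_id for s in sessions]
        rows = []
        for i, pid in enumerate(ids):
            for j, name in enumerate(spec.param_names):
                rows.append({"participant": pid, "parameter": name, "mean": mean[i, j],
                             "sd": sd[i, j], "hdi_2.5%": lo[i, j], "hdi_97.5%": hi[i, j]})
        summary = pd.DataFrame(rows)

        dic = compute_dic(draws.deviance, self._dev_at_mean(cohort, draws))
        max_rhat, min_ess = _diagnostics({"omega": draws.omega, "phi": draws.phi})

        om_flat = draws.omega.reshape(-1, spec.n_params)
        ph_flat = draws.phi.reshape(-1, spec.n_params)
        self.model_ = spec
        self.draws_ = draws
        self.result_ = GroupFitResult(
            model=spec,
            participant_ids=ids,
            participant_summary=summary,
            group_mean={n: float(om_flat[:, j].mean()) for j, n in enumerate(spec.param_names)},
            group_mean_sd={n: float(om_flat[:, j].std()) for j, n in enumerate(spec.param_names)},
            group_precision={n: float(ph_flat[:, j].mean()) for j, n in enumerate(spec.param_names)},
            dic=dic,
            max_rhat=max_rhat,
            min_ess=min_ess,
            converged=bool(max_rhat <= 1.1),
            informed_prior_source=source,
        )
        if not self.result_.converged:
            warnings.warn(f"hierarchical fit may not have converged (max R-hat {max_rhat:.3f})")
        return self

    @staticmethod
    def _dev_at_mean(cohort: CohortLikelihood, draws) -> float:
        x_mean_unit = draws.x.reshape(-1, *draws.x.shape[2:]).mean(axis=0)
        return 2.0 * float(cohort.nll(x_mean_unit).sum())

    def _initial_values(self, sessions, spec, seed_seq) -> np.ndarray:
        seeds = seed_seq.spawn(len(sessions))
        init = np.empty((len(sessions), spec.n_params))
        for i, s in enumerate(sessions):
            r = fit_mle(s, spec, n_restarts=self.init_restarts,
                        seed=int(seeds[i].generate_state(1)[0] % (2**31)), gating=self.gating)
            v = r.params.to_vector(spec)
            v[0] /= TAU_MAX
            init[i] = v
        return init

    @staticmethod
    def _omega_prior(t1_result: "GroupFitResult", spec: ModelSpec) -> np.ndarray:
        shapes = np.empty((spec.n_params, 2))
        for j, name in enumerate(spec.param_names):
            m = np.clip(t1_result.group_mean[name], 1e-3, 1 - 1e-3)
            s = max(t1_result.group_mean_sd[name], 1e-3)
            shapes[j] = _moment_match_beta(float(m), float(s))
        return shapes


def fit_hbayes(sessions, spec: ModelSpec, prior_mode: str = "uninformed",
               informed_from: Optional[GroupFitResult] = None,
               n_chains: int = 4, n_draws: int = 1000, n_warmup: int = 1000,
               seed=None, gating: str = "pe_sign") -> GroupFitResult:
    """Hierarchical Bayesian fit of one session cohort.

    ``prior_mode='informed'`` replaces the uniform prior on each group
    mean with a beta distribution matched to ``informed_from``'s group
    mean posterior (the T1-informed refit of the second session).
    """
    if prior_mode not in ("uninformed", "informed"):
        raise ValueError("prior_mode must be 'uninformed' or 'informed'")
    informed = informed_from if prior_mode == "informed" else None
    if prior_mode == "informed" and informed is None:
        raise ValueError("informed prior_mode requires informed_from")
    return HierarchicalBayesFitter(
        spec, n_chains=n_chains, n_draws=n_draws, n_warmup=n_warmup, seed=seed,
        gating=gating, informed_prior=informed).fit(sessions).result_


@dataclass
class JointFitResult:
    """Posterior summary of the joint two-session model."""

    model: ModelSpec
    participant_ids: list[str]
    participant_summary: pd.DataFrame  # participant, session, parameter, mean, sd
    correlations: dict[str, float]     # posterior mean of rho per parameter
    correlation_ci: dict[str, tuple[float, float]]
    dic: float
    max_rhat: float
    min_ess: float
    converged: bool
    with_correlation: bool = True

    def point_estimates(self, session: str) -> pd.DataFrame:
        sub = self.participant_summary[self.participant_summary["session"] == session]
        return sub.pivot(index="participant", columns="parameter", values="mean")


class JointHierarchicalFitter(BaseEstimator):
    """Joint two-session hierarchical fit with cross-session correlations.

    Participant-level parameters are logit-normal per session; each
    parameter's (T1, T2) pair is bivariate normal on the logit scale
    with a free correlation, whose posterior mean is the model-based
    test-retest reliability estimate.
    """

    def __init__(self, model=None, with_correlation=True, n_chains=4, n_draws=1000,
                 n_warmup=1000, seed=None, gating="pe_sign", init_restarts=5):
        self.model = model
        self.with_correlation = with_correlation
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.seed = seed
        self.gating = gating
        self.init_restarts = init_restarts

    def fit(self, sessions_t1, sessions_t2):
        sessions_t1, sessions_t2 = list(sessions_t1), list(sessions_t2)
        ids1 = [s.participant_id for s in sessions_t1]
        ids2 = [s.participant_id for s in sessions_t2]
        if ids1 != ids2:
            if set(ids1) != set(ids2):
                raise ValueError("participant sets differ between sessions")
            order = {pid: i for i, pid in enumerate(ids1)}
            sessions_t2 = sorted(sessions_t2, key=lambda s: order[s.participant_id])
        spec = self.model if self.model is not None else ModelSpec(task_kind=sessions_t1[0].task_kind)
        c1 = CohortLikelihood(sessions_t1, spec, self.gating)
        c2 = CohortLikelihood(sessions_t2, spec, self.gating)

        ss = np.random.SeedSequence(self.seed)
        s_init, s_mcmc = ss.spawn(2)
        seeds = s_init.spawn(2)
        init = np.empty((len(sessions_t1), 2, spec.n_params))
        for s_idx, sess in enumerate((sessions_t1, sessions_t2)):
            sub = seeds[s_idx].spawn(len(sess))
            for i, s in enumerate(sess):
                r = fit_mle(s, spec, n_restarts=self.init_restarts,
                            seed=int(sub[i].generate_state(1)[0] % (2**31)), gating=self.gating)
                v = r.params.to_vector(spec)
                v[0] /= TAU_MAX
                init[i, s_idx] = v

        draws = sample_joint(
            c1, c2, init, with_correlation=self.with_correlation,
            n_chains=self.n_chains, n_draws=self.n_draws, n_warmup=self.n_warmup,
            seed=int(s_mcmc.generate_state(1)[0] % (2**31)))

        x_native = _native(draws.x, spec)  # (chains, draws, n, 2, k)
        flat = x_native.reshape(-1, *x_native.shape[2:])
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        rows = []
        for i, pid in enumerate(ids1):
            for s_idx, label in enumerate(("T1", "T2")):
                for j, name in enumerate(spec.param_names):
                    rows.append({"participant": pid, "session": label, "parameter": name,
                                 "mean": mean[i, s_idx, j], "sd": sd[i, s_idx, j]})
        summary = pd.DataFrame(rows)

        rho_flat = draws.rho.reshape(-1, spec.n_params)
        corr = {n: float(rho_flat[:, j].mean()) for j, n in enumerate(spec.param_names)}
        ci = {n: (float(np.quantile(rho_flat[:, j], 0.025)),
                  float(np.quantile(rho_flat[:, j], 0.975)))
              for j, n in enumerate(spec.param_names)}

        x_mean_unit = draws.x.reshape(-1, *draws.x.shape[2:]).mean(axis=0)
        dev_at_mean = 2.0 * float(c1.nll(x_mean_unit[:, 0, :]).sum()
                                  + c2.nll(x_mean_unit[:, 1, :]).sum())
        dic = compute_dic(draws.deviance, dev_at_mean)
        diag_vars = {"mu": draws.mu, "sigma": draws.sigma}
        if self.with_correlation:
            diag_vars["rho"] = draws.rho
        max_rhat, min_ess = _diagnostics(diag_vars)

        self.model_ = spec
        self.draws_ = draws
        self.result_ = JointFitResult(
            model=spec, participant_ids=ids1, participant_summary=summary,
            correlations=corr, correlation_ci=ci, dic=dic,
            max_rhat=max_rhat, min_ess=min_ess, converged=bool(max_rhat <= 1.1),
            with_correlation=self.with_correlation)
        if not self.result_.converged:
            warnings.warn(f"joint fit may not have converged (max R-hat {max_rhat:.3f})")
        return self


def fit_joint_hbayes(sessions_t1, sessions_t2, spec: ModelSpec, with_correlation: bool = True,
                     n_chains: int = 4, n_draws: int = 1000, n_warmup: int = 1000,
                     seed=None, gating: str = "pe_sign") -> JointFitResult:
    """Joint hierarchical fit of both sessions; see :class:`JointHierarchicalFitter`."""
    return JointHierarchicalFitter(
        spec, with_correlation=with_correlation, n_chains=n_chains, n_draws=n_draws,
        n_warmup=n_warmup, seed=seed, gating=gating).fit(sessions_t1, sessions_t2).result_


def results_to_frame(results: dict[str, FitResult], spec: ModelSpec,
                     session_label: str = "T1") -> pd.DataFrame:
    """Tidy (participant, session, model, parameter, estimate) table."""
    rows = []
    for pid, r in results.items():
        for name in spec.param_names:
            rows.append({"participant": pid, "session": session_label, "model": spec.name,
                         "parameter": name, "estimate": getattr(r.params, name)})
    return pd.DataFrame(rows)
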