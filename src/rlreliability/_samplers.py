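"""Adaptive Metropolis-within-Gibbs samplers for the hierarchical models.

The hierarchical posterior factorises into conditionally independent
participant blocks given the group-level parameters, so the sampler
alternates (i) a joint random-walk proposal per participant on the
logit scale, accepted independently across participants and evaluated
through the batched compiled likelihood, and (ii) random-walk updates
of the group-level parameters, which touch only the prior terms.
Proposal scales adapt during warmup (Robbins-Monro toward a target
acceptance rate) and are frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import betainc, betaincinv, betaln, expit, logit

__all__ = ["CohortLikelihood", "sample_hierarchical", "sample_joint"]

from .models import EncodedSession, ModelSpec, encode_session, _nll_batch_core

_EPS = 1e-9


class CohortLikelihood:
    """Batched likelihood of a cohort of sessions under one model.

    Parameters are given on the unit scale (tau divided by 20); rows are
    participants. Sessions of unequal length are padded with timed-out
    trials, which the likelihood skips.
    """

    def __init__(self, sessions, spec: ModelSpec, gating: str = "pe_sign"):
        self.spec = spec
        self.gating = gating
        encs = [s if isinstance(s, EncodedSession) else encode_session(s) for s in sessions]
        self.n = len(encs)
        if self.n == 0:
            raise ValueError("empty cohort")
        T = max(e.pair_id.shape[0] for e in encs)
        self.n_pairs = max(e.n_pairs for e in encs)
        self.pair_id = np.zeros((self.n, T), dtype=np.int64)
        self.chosen = np.zeros((self.n, T), dtype=np.int64)
        self.reward = np.zeros((self.n, T), dtype=np.int64)
        self.valence = np.zeros((self.n, T), dtype=np.int64)
        self.timed_out = np.ones((self.n, T), dtype=np.bool_)
        for i, e in enumerate(encs):
            t = e.pair_id.shape[0]
            self.pair_id[i, :t] = e.pair_id
            self.chosen[i, :t] = np.maximum(e.chosen, 0)
            self.reward[i, :t] = e.reward
            self.valence[i, :t] = e.valence
            self.timed_out[i, :t] = e.timed_out
        self.n_valid = np.array([e.n_valid for e in encs])

    def nll(self, unit_params: np.ndarray) -> np.ndarray:
        """(n,) negative log likelihoods at unit-scale parameters (n, k)."""
        spec = self.spec
        tau = unit_params[:, 0] * 20.0
        if spec.n_learning_rates == 1:
            a_gain = a_loss = unit_params[:, 1]
            k_idx = 2
        else:
            a_gain, a_loss = unit_params[:, 1], unit_params[:, 2]
            k_idx = 3
        if spec.update_rule == "single":
            kappa = np.zeros(self.n)
            du = False
        elif spec.update_rule == "full_du":
            kappa = np.ones(self.n)
            du = True
        else:
            kappa = unit_params[:, k_idx]
            du = True
        return _nll_batch_core(
            self.pair_id, self.chosen, self.reward, self.valence, self.timed_out,
            self.n_pairs, np.ascontiguousarray(tau), np.ascontiguousarray(a_gain),
            np.ascontiguousarray(a_loss), np.ascontiguousarray(kappa),
            du, spec.task_kind == "bandit", self.gating == "reward_sign",
        )


def _log_beta_pdf(x, a, b):
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log(1.0 - x) - betaln(a, b)


def _adapt(log_s, acc, target, it):
    return log_s + (acc - target) * (it + 1.0) ** -0.6


@dataclass
class HierarchicalDraws:
    """Pooled posterior draws from the hierarchical beta model."""

    x: np.ndarray       # (chains, draws, n, k) unit scale
    omega: np.ndarray   # (chains, draws, k)
    phi: np.ndarray     # (chains, draws, k)
    deviance: np.ndarray  # (chains, draws)


def sample_hierarchical(
    cohort: CohortLikelihood,
    init_unit: np.ndarray,
    n_chains: int = 4,
    n_draws: int = 1000,
    n_warmup: int = 1000,
    seed: Optional[int] = None,
    omega_prior: Optional[np.ndarray] = None,
) -> HierarchicalDraws:
    """Sample the disjoint hierarchical model for one session cohort.

    Group-level means are uniform on (0, 1) and precisions uniform on
    (2, 600); participant-level unit-scale parameters follow
    Beta(omega*phi, (1-omega)*phi). ``omega_prior`` optionally holds
    beta shapes (k, 2) replacing the uniform prior on the group means
    (the informed-prior mode seeded from a previous session's fit).
    """
    n, k = init_unit.shape
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    xs = np.empty((n_chains, n_draws, n, k))
    oms = np.empty((n_chains, n_draws, k))
    phs = np.empty((n_chains, n_draws, k))
    devs = np.empty((n_chains, n_draws))

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        x0 = np.clip(init_unit, 0.02, 0.98)
        z = logit(x0) + 0.1 * rng.standard_normal((n, k))
        x = expit(z)
        omega = np.clip(x.mean(axis=0), 0.05, 0.95)
        var = np.maximum(x.var(axis=0), 1e-4)
        phi = np.clip(omega * (1 - omega) / var - 1.0, 2.5, 580.0)
        w = logit(omega)
        v = logit((phi - 2.0) / 598.0)

        a = omega * phi
        b = (1 - omega) * phi
        ll = -cohort.nll(x)
        P = _log_beta_pdf(x, a, b) + np.log(x * (1 - x))  # (n, k) incl. jacobian

        log_s = np.full(n, np.log(0.25))
        log_sw = np.full(k, np.log(0.15))
        log_sv = np.full(k, np.log(0.3))
        log_snc = np.full(k, np.log(0.3))

        def group_logp(w_, v_, x_):
            omega_ = expit(w_)
            phi_ = 2.0 + 598.0 * expit(v_)
            a_ = omega_ * phi_
            b_ = (1 - omega_) * phi_
            P_ = _log_beta_pdf(x_, a_, b_) + np.log(x_ * (1 - x_))
            # transform jacobians for the uniform priors
            prior = np.log(omega_ * (1 - omega_)) + np.log(expit(v_) * (1 - expit(v_)))
            if omega_prior is not None:
                prior = prior + _log_beta_pdf(omega_, omega_prior[:, 0], omega_prior[:, 1])
            return P_, prior, omega_, phi_

        _, group_prior, omega, phi = group_logp(w, v, x)

        total = n_warmup + n_draws
        for it in range(total):
            # participant block
            z_prop = z + np.exp(log_s)[:, None] * rng.standard_normal((n, k))
            x_prop = np.clip(expit(z_prop), _EPS, 1 - _EPS)
            ll_prop = -cohort.nll(x_prop)
            P_prop = _log_beta_pdf(x_prop, a, b) + np.log(x_prop * (1 - x_prop))
            logr = (ll_prop + P_prop.sum(axis=1)) - (ll + P.sum(axis=1))
            acc = np.exp(np.minimum(0.0, logr))
            take = rng.random(n) < acc
            z[take] = z_prop[take]
            x[take] = x_prop[take]
            ll[take] = ll_prop[take]
            P[take] = P_prop[take]
            if it < n_warmup:
                log_s = _adapt(log_s, acc, 0.3, it)

            # group block: several mean-only and precision-only sub-updates
            # per sweep (they only touch the cheap prior terms)
            for _ in range(5):
                for which in (0, 1):
                    if which == 0:
                        w_prop = w + np.exp(log_sw) * rng.standard_normal(k)
                        v_prop = v
                    else:
                        w_prop = w
                        v_prop = v + np.exp(log_sv) * rng.standard_normal(k)
                    P_new, prior_new, omega_new, phi_new = group_logp(w_prop, v_prop, x)
                    logr_g = (P_new.sum(axis=0) + prior_new) - (P.sum(axis=0) + group_prior)
                    acc_g = np.exp(np.minimum(0.0, logr_g))
                    take_g = rng.random(k) < acc_g
                    w = np.where(take_g, w_prop, w)
                    v = np.where(take_g, v_prop, v)
                    omega = np.where(take_g, omega_new, omega)
                    phi = np.where(take_g, phi_new, phi)
                    P[:, take_g] = P_new[:, take_g]
                    group_prior = np.where(take_g, prior_new, group_prior)
                    if it < n_warmup:
                        if which == 0:
                            log_sw = _adapt(log_sw, acc_g, 0.35, it)
                        else:
                            log_sv = _adapt(log_sv, acc_g, 0.35, it)
            a = omega * phi
            b = (1 - omega) * phi

            # interweaved non-centred group update: move (omega, phi) while
            # holding each participant's prior quantile fixed, so the
            # participant values travel with the group distribution. This
            # breaks the funnel coupling between precision and participant
            # spread; it costs one likelihood evaluation per parameter.
            for p in range(k):
                w_p = w[p] + np.exp(log_snc[p]) * rng.standard_normal()
                v_p = v[p] + np.exp(log_snc[p]) * rng.standard_normal()
                omega_p = expit(w_p)
                phi_p = 2.0 + 598.0 * expit(v_p)
                a_p = omega_p * phi_p
                b_p = (1 - omega_p) * phi_p
                u = betainc(a[p], b[p], x[:, p])
                x_new = np.clip(betaincinv(a_p, b_p, u), _EPS, 1 - _EPS)
                x_prop = x.copy()
                x_prop[:, p] = x_new
                ll_prop = -cohort.nll(x_prop)
                prior_p = np.log(omega_p * (1 - omega_p)) + np.log(expit(v_p) * (1 - expit(v_p)))
                prior_old = np.log(omega[p] * (1 - omega[p])) + np.log(
                    expit(v[p]) * (1 - expit(v[p])))
                if omega_prior is not None:
                    prior_p += float(_log_beta_pdf(omega_p, omega_prior[p, 0], omega_prior[p, 1]))
                    prior_old += float(_log_beta_pdf(omega[p], omega_prior[p, 0], omega_prior[p, 1]))
                logr_nc = (ll_prop.sum() + prior_p) - (ll.sum() + prior_old)
                acc_nc = math.exp(min(0.0, logr_nc))
                if rng.random() < acc_nc:
                    x = x_prop
                    z[:, p] = logit(x_new)
                    ll = ll_prop
                    w[p], v[p] = w_p, v_p
                    omega[p], phi[p] = omega_p, phi_p
                    a[p], b[p] = a_p, b_p
                    P[:, p] = _log_beta_pdf(x_new, a_p, b_p) + np.log(x_new * (1 - x_new))
                    group_prior[p] = prior_p
                if it < n_warmup:
                    log_snc[p] = float(_adapt(log_snc[p], acc_nc, 0.25, it))

            if it >= n_warmup:
                d = it - n_warmup
                xs[c, d] = x
                oms[c, d] = omega
                phs[c, d] = phi
                devs[c, d] = -2.0 * ll.sum()

    return HierarchicalDraws(xs, oms, phs, devs)


@dataclass
class JointDraws:
    """Pooled posterior draws from the joint two-session model."""

    x: np.ndarray       # (chains, draws, n, 2, k) unit scale
    mu: np.ndarray      # (chains, draws, 2, k)
    sigma: np.ndarray   # (chains, draws, 2, k)
    rho: np.ndarray     # (chains, draws, k)
    deviance: np.ndarray


#: atanh-spaced grid for the conditional draw of rho (dense near +/-1)
_RHO_GRID = np.tanh(np.linspace(-7.0, 7.0, 1401))


def _bvn_logpdf(y, mu, sigma, rho):
    """Log density of participant pairs. y: (n, 2, k); mu/sigma: (2, k); rho: (k,)."""
    e1 = (y[:, 0, :] - mu[0]) / sigma[0]
    e2 = (y[:, 1, :] - mu[1]) / sigma[1]
    om = 1.0 - rho**2
    quad = (e1**2 + e2**2 - 2.0 * rho * e1 * e2) / om
    return (-np.log(2 * np.pi) - np.log(sigma[0]) - np.log(sigma[1])
            - 0.5 * np.log(om) - 0.5 * quad)


def sample_joint(
    cohort_t1: CohortLikelihood,
    cohort_t2: CohortLikelihood,
    init_unit: np.ndarray,
    with_correlation: bool = True,
    n_chains: int = 4,
    n_draws: int = 1000,
    n_warmup: int = 1000,
    seed: Optional[int] = None,
) -> JointDraws:
    """Sample the joint two-session model with cross-session correlations.

    Participant-level parameters are logit-normal per session; for each
    model parameter the participant's (T1, T2) pair on the logit scale
    is bivariate normal with a free correlation ``rho`` (uniform on
    (-1, 1)). With ``with_correlation=False`` rho is fixed at 0, which
    makes the two sessions independent.

    ``init_unit`` has shape (n, 2, k): unit-scale starting values per
    participant and session.
    """
    n, two, k = init_unit.shape
    assert two == 2
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    xs = np.empty((n_chains, n_draws, n, 2, k))
    mus = np.empty((n_chains, n_draws, 2, k))
    sigs = np.empty((n_chains, n_draws, 2, k))
    rhos = np.empty((n_chains, n_draws, k))
    devs = np.empty((n_chains, n_draws))

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        y = logit(np.clip(init_unit, 0.02, 0.98)) + 0.1 * rng.standard_normal((n, 2, k))
        mu = y.mean(axis=0)                      # (2, k)
        sigma = np.clip(y.std(axis=0), 0.25, 3.0)
        rho = np.full(k, 0.5 if with_correlation else 0.0)
        arho = np.arctanh(np.clip(rho, -0.99, 0.99))

        x = expit(y)
        ll = np.stack([-cohort_t1.nll(x[:, 0, :]), -cohort_t2.nll(x[:, 1, :])])  # (2, n)
        Pp = _bvn_logpdf(y, mu, sigma, rho)      # (n, k)

        def group_prior(mu_, logsig_, arho_):
            sig = np.exp(logsig_)
            lp = (-(mu_**2) / (2 * 2.5**2)).sum(axis=0)       # (k,)
            lp += (-(sig**2) / (2 * 1.5**2) + logsig_).sum(axis=0)  # half-normal + jac
            if with_correlation:
                lp += np.log(1.0 - np.tanh(arho_) ** 2)       # uniform rho + jac
            return lp

        logsig = np.log(sigma)
        gp = group_prior(mu, logsig, arho)

        log_s = np.full(n, np.log(0.2))
        log_sg = np.full(k, np.log(0.12))

        log_snc = np.full(k, np.log(0.1))
        log_snr = np.full(k, np.log(0.3))

        total = n_warmup + n_draws
        for it in range(total):
            # participant block: propose both sessions jointly, with the
            # T1/T2 increments correlated according to the current rho so
            # proposals stay inside the ridge that a high correlation
            # induces (at rho near 1 an independent pair proposal is
            # almost surely rejected)
            e = rng.standard_normal((n, 2, k))
            d2 = rho[None, :] * e[:, 0, :] + np.sqrt(1.0 - rho[None, :] ** 2) * e[:, 1, :]
            step_pair = np.stack([e[:, 0, :], d2], axis=1)
            y_prop = y + np.exp(log_s)[:, None, None] * step_pair
            x_prop = np.clip(expit(y_prop), _EPS, 1 - _EPS)
            ll_prop = np.stack([-cohort_t1.nll(x_prop[:, 0, :]),
                                -cohort_t2.nll(x_prop[:, 1, :])])
            Pp_prop = _bvn_logpdf(y_prop, mu, sigma, rho)
            logr = (ll_prop.sum(axis=0) + Pp_prop.sum(axis=1)) - (ll.sum(axis=0) + Pp.sum(axis=1))
            acc = np.exp(np.minimum(0.0, logr))
            take = rng.random(n) < acc
            y[take] = y_prop[take]
            x[take] = x_prop[take]
            ll[:, take] = ll_prop[:, take]
            Pp[take] = Pp_prop[take]
            if it < n_warmup:
                log_s = _adapt(log_s, acc, 0.25, it)

            # centred group block for mu and sigma (cheap: prior terms only)
            for _ in range(5):
                step = np.exp(log_sg)
                mu_prop = mu + step * rng.standard_normal((2, k))
                logsig_prop = logsig + step * rng.standard_normal((2, k))
                sigma_prop = np.exp(logsig_prop)
                Pp_new = _bvn_logpdf(y, mu_prop, sigma_prop, rho)
                gp_new = group_prior(mu_prop, logsig_prop, arho)
                logr_g = (Pp_new.sum(axis=0) + gp_new) - (Pp.sum(axis=0) + gp)
                acc_g = np.exp(np.minimum(0.0, logr_g))
                take_g = rng.random(k) < acc_g
                mu[:, take_g] = mu_prop[:, take_g]
                logsig[:, take_g] = logsig_prop[:, take_g]
                sigma[:, take_g] = sigma_prop[:, take_g]
                Pp[:, take_g] = Pp_new[:, take_g]
                gp = np.where(take_g, gp_new, gp)
                if it < n_warmup:
                    log_sg = _adapt(log_sg, acc_g, 0.3, it)

            # exact conditional draw of rho given the latent pairs
            # (griddy Gibbs on an atanh-spaced grid; the conditional is
            # one-dimensional and cheap, and this removes the random-walk
            # bottleneck near |rho| = 1)
            if with_correlation:
                e1 = (y[:, 0, :] - mu[0]) / sigma[0]   # (n, k)
                e2 = (y[:, 1, :] - mu[1]) / sigma[1]
                s11 = (e1**2 + e2**2).sum(axis=0)      # (k,)
                s12 = (e1 * e2).sum(axis=0)
                rg = _RHO_GRID[:, None]                # (G, 1)
                omr = 1.0 - rg**2
                logp = (-0.5 * n * np.log(omr)
                        - (s11[None, :] - 2.0 * rg * s12[None, :]) / (2.0 * omr)
                        + np.log(omr))                 # uniform prior, atanh jacobian
                logp -= logp.max(axis=0, keepdims=True)
                wts = np.exp(logp)
                cdf = np.cumsum(wts, axis=0)
                u_r = rng.random(k) * cdf[-1]
                idx = np.array([np.searchsorted(cdf[:, j], u_r[j]) for j in range(k)])
                idx = np.minimum(idx, _RHO_GRID.size - 1)
                rho = _RHO_GRID[idx]
                arho = np.arctanh(rho)
                Pp = _bvn_logpdf(y, mu, sigma, rho)
                gp = group_prior(mu, logsig, arho)

                # interweaved non-centred rho move: change rho while
                # holding each participant's conditional T2 quantile
                # fixed, so the T2 latents travel with the correlation
                for p in range(k):
                    step_r = math.exp(log_snr[p])
                    arho_p = arho[p] + step_r * rng.standard_normal()
                    rho_p = math.tanh(arho_p)
                    e1p = (y[:, 0, p] - mu[0, p]) / sigma[0, p]
                    e2p = (y[:, 1, p] - mu[1, p]) / sigma[1, p]
                    eta = (e2p - rho[p] * e1p) / math.sqrt(1.0 - rho[p] ** 2)
                    e2_new = rho_p * e1p + math.sqrt(1.0 - rho_p**2) * eta
                    y_prop_p = y.copy()
                    y_prop_p[:, 1, p] = mu[1, p] + sigma[1, p] * e2_new
                    x_prop_p = np.clip(expit(y_prop_p), _EPS, 1 - _EPS)
                    ll2_prop = -cohort_t2.nll(x_prop_p[:, 1, :])
                    dprior = (math.log(1.0 - rho_p**2) - math.log(1.0 - rho[p] ** 2))
                    logr_r = (ll2_prop.sum() - ll[1].sum()) + dprior
                    acc_r = math.exp(min(0.0, logr_r))
                    if rng.random() < acc_r:
                        y = y_prop_p
                        x = x_prop_p
                        ll[1] = ll2_prop
                        arho[p] = arho_p
                        rho[p] = rho_p
                        Pp = _bvn_logpdf(y, mu, sigma, rho)
                        gp = group_prior(mu, logsig, arho)
                    if it < n_warmup:
                        log_snr[p] = float(_adapt(log_snr[p], acc_r, 0.25, it))

            # interweaved non-centred group update: move (mu, sigma, rho)
            # while preserving each participant's standardized residuals,
            # so the whole cloud of participant pairs travels with the
            # group distribution (one likelihood evaluation per parameter)
            for p in range(k):
                step_nc = math.exp(log_snc[p])
                mu_p = mu[:, p] + step_nc * rng.standard_normal(2)
                logsig_p = logsig[:, p] + step_nc * rng.standard_normal(2)
                sig_p = np.exp(logsig_p)
                # translate/rescale the participant cloud with the group
                y_prop_p = y.copy()
                y_prop_p[:, 0, p] = mu_p[0] + sig_p[0] * (y[:, 0, p] - mu[0, p]) / sigma[0, p]
                y_prop_p[:, 1, p] = mu_p[1] + sig_p[1] * (y[:, 1, p] - mu[1, p]) / sigma[1, p]
                x_prop_p = np.clip(expit(y_prop_p), _EPS, 1 - _EPS)
                ll_prop_p = np.stack([-cohort_t1.nll(x_prop_p[:, 0, :]),
                                      -cohort_t2.nll(x_prop_p[:, 1, :])])
                mu_try = mu.copy(); mu_try[:, p] = mu_p
                logsig_try = logsig.copy(); logsig_try[:, p] = logsig_p
                gp_new = group_prior(mu_try, logsig_try, arho)
                logr_nc = (ll_prop_p.sum() + gp_new[p]) - (ll.sum() + gp[p])
                acc_nc = math.exp(min(0.0, logr_nc))
                if rng.random() < acc_nc:
                    y = y_prop_p
                    x = x_prop_p
                    ll = ll_prop_p
                    mu[:, p] = mu_p
                    logsig[:, p] = logsig_p
                    sigma[:, p] = sig_p
                    gp[p] = gp_new[p]
                    Pp = _bvn_logpdf(y, mu, sigma, rho)
                if it < n_warmup:
                    log_snc[p] = float(_adapt(log_snc[p], acc_nc, 0.25, it))

            if it >= n_warmup:
                d = it - n_warmup
                xs[c, d] = x
                mus[c, d] = mu
                sigs[c, d] = sigma
                rhos[c, d] = rho
                devs[c, d] = -2.0 * ll.sum()

    return JointDraws(xs, mus, sigs, rhos, devs)
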