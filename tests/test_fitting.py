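"""Estimation regimes: MLE restarts, MAP shrinkage, hierarchical fits, selection."""

import math

import numpy as np
import pytest

from rlreliability import (
    BanditConfig,
    HierarchicalBayesFitter,
    JointHierarchicalFitter,
    MAPFitter,
    MLEFitter,
    ModelSpec,
    ParamSet,
    PriorSpec,
    compute_bic,
    compute_dic,
    empirical_priors,
    fit_map,
    fit_mle,
    make_agent,
    run_bandit_session,
    select_model,
)
from rlreliability.fitting import FitResult


def _simulate(params, spec, agent_seed, env_seed, config=BanditConfig()):
    return run_bandit_session(make_agent(params, spec, seed=agent_seed),
                              config, seed=env_seed)


class TestInformationCriteria:
    def test_bic_zero_case(self):
        assert compute_bic(0.0, 0, 5) == 0.0

    def test_bic_formula(self):
        assert compute_bic(100.0, 3, 160) == pytest.approx(3 * math.log(160) + 200, abs=1e-9)

    def test_bic_monotone_in_k(self):
        assert compute_bic(50.0, 4, 100) > compute_bic(50.0, 3, 100)

    def test_bic_rejects_empty_data(self):
        with pytest.raises(ValueError):
            compute_bic(1.0, 1, 0)

    def test_dic_constant_trace(self):
        assert compute_dic(np.full(10, 7.5), 7.5) == pytest.approx(7.5)

    def test_dic_hand_case(self):
        # mean deviance 11, pD = 11 - 10.5 -> DIC = 11.5
        assert compute_dic(np.array([10.0, 12.0]), 10.5) == pytest.approx(11.5)


class TestModelSelection:
    def test_argmin(self):
        assert select_model({"A": 100.0, "B": 90.0}) == "B"

    def test_tie_goes_to_simpler_model(self):
        assert select_model({"A": 90.0, "B": 90.0}, {"A": 2, "B": 4}) == "A"

    def test_needs_at_least_two_models(self):
        with pytest.raises(ValueError):
            select_model({"A": 1.0})

    def test_recovers_dual_rate_model_from_dual_rate_data(self):
        # cohort generated by the dual-rate model: its total BIC beats the
        # single-rate model's
        dual = ModelSpec(2, "single", "bandit")
        single = ModelSpec(1, "single", "bandit")
        totals = {"dual": 0.0, "single": 0.0}
        for i in range(8):
            s = _simulate(ParamSet(tau=6.0, alpha_gain=0.8, alpha_loss=0.15),
                          dual, 100 + i, 200 + i)
            totals["dual"] += fit_mle(s, dual, n_restarts=8, seed=i).bic
            totals["single"] += fit_mle(s, single, n_restarts=8, seed=i).bic
        assert select_model(totals) == "dual"


class TestEmpiricalPriors:
    def _results(self, values, spec):
        out = []
        for v in values:
            p = ParamSet(tau=v["tau"], alpha_gain=v["ag"], alpha_loss=v["al"])
            out.append(FitResult(p, 0.0, 0.0, 1, 0, True))
        return out

    def test_moment_matching_reproduces_known_shapes(self):
        # alpha_gain sample moments mean .70, sd .23 -> shapes (2.079, 0.891)
        spec = ModelSpec(2, "single", "bandit")
        vals = [{"tau": 4.0, "ag": 0.47, "al": 0.2},
                {"tau": 5.0, "ag": 0.70, "al": 0.3},
                {"tau": 6.0, "ag": 0.93, "al": 0.4}]
        priors = empirical_priors(self._results(vals, spec), spec)
        a, b = priors.shapes["alpha_gain"]
        assert a == pytest.approx(2.079, abs=1e-3)
        assert b == pytest.approx(0.891, abs=1e-3)

    def test_prior_mean_matches_sample_mean(self):
        spec = ModelSpec(2, "single", "bandit")
        vals = [{"tau": 2.0, "ag": 0.35, "al": 0.1},
                {"tau": 9.0, "ag": 0.55, "al": 0.5},
                {"tau": 5.0, "ag": 0.85, "al": 0.3}]
        priors = empirical_priors(self._results(vals, spec), spec)
        for name, sample_mean in (("alpha_gain", 0.35 + 0.55 + 0.85),
                                  ("alpha_loss", 0.1 + 0.5 + 0.3)):
            a, b = priors.shapes[name]
            assert a / (a + b) == pytest.approx(sample_mean / 3, abs=1e-9)

    def test_degenerate_estimates_fall_back_to_uniform(self):
        spec = ModelSpec(2, "single", "bandit")
        vals = [{"tau": 5.0, "ag": 0.6, "al": 0.3}] * 4
        with pytest.warns(UserWarning):
            priors = empirical_priors(self._results(vals, spec), spec)
        assert priors.shapes["alpha_gain"] == (1.0, 1.0)

    def test_needs_three_participants(self):
        spec = ModelSpec(2, "single", "bandit")
        with pytest.raises(ValueError):
            empirical_priors(self._results([{"tau": 5.0, "ag": .6, "al": .3}] * 2, spec), spec)


class TestMLE:
    def test_flat_likelihood_at_zero_temperature_reaches_n_log_two(self):
        spec = ModelSpec(1, "single", "bandit")
        s = _simulate(ParamSet(tau=0.0, alpha=0.5), spec, 1, 2)
        r = fit_mle(s, spec, n_restarts=5, seed=3)
        assert r.nll <= 160 * math.log(2) + 1e-6

    def test_large_sample_parameter_recovery(self):
        """10,000 bandit-style trials from the dual-rate model: every
        parameter recovered within +/-0.05 (tau on its native scale)."""
        spec = ModelSpec(2, "single", "bandit")
        truth = ParamSet(tau=5.0, alpha_gain=0.7, alpha_loss=0.25)
        cfg = BanditConfig(presentations_per_pair=1250)
        s = _simulate(truth, spec, 7, 8, cfg)
        r = fit_mle(s, spec, n_restarts=10, seed=9)
        assert r.params.tau == pytest.approx(truth.tau, abs=0.05 * 20)
        assert r.params.alpha_gain == pytest.approx(truth.alpha_gain, abs=0.05)
        assert r.params.alpha_loss == pytest.approx(truth.alpha_loss, abs=0.05)

    def test_result_bookkeeping_and_bounds(self, bandit_session, dual_spec):
        r = fit_mle(bandit_session, dual_spec, n_restarts=6, seed=1)
        assert r.converged
        assert 0 <= r.best_restart_index < 6
        assert 0.0 <= r.params.tau <= 20.0
        assert 0.0 <= r.params.alpha_gain <= 1.0
        assert 0.0 <= r.params.alpha_loss <= 1.0
        assert r.bic == pytest.approx(compute_bic(r.nll, 3, 160))

    def test_best_solution_no_worse_than_any_restart_start(self, bandit_session, dual_spec):
        from rlreliability.models import encode_session, nll_vector

        r = fit_mle(bandit_session, dual_spec, n_restarts=6, seed=11)
        enc = encode_session(bandit_session)
        rng = np.random.default_rng(11)
        lo = np.array([b[0] for b in dual_spec.bounds])
        hi = np.array([b[1] for b in dual_spec.bounds])
        starts = [rng.uniform(lo, hi) for _ in range(6)]
        assert r.nll <= min(nll_vector(x, enc, dual_spec) for x in starts) + 1e-9

    def test_task_mismatch_rejected(self, bandit_session):
        with pytest.raises(ValueError):
            fit_mle(bandit_session, ModelSpec(1, "single", "reversal"))


class TestMAP:
    def test_uniform_priors_reproduce_mle(self, dual_spec):
        """MAP with flat beta priors equals MLE within 1e-3 per parameter."""
        for i in range(6):
            s = _simulate(ParamSet(tau=4.0, alpha_gain=0.65, alpha_loss=0.3),
                          dual_spec, 300 + i, 400 + i)
            mle = fit_mle(s, dual_spec, n_restarts=8, seed=i)
            mp = fit_map(s, dual_spec, priors=None, n_restarts=8, seed=i)
            for name in dual_spec.param_names:
                scale = 20.0 if name == "tau" else 1.0
                assert getattr(mp.params, name) / scale == pytest.approx(
                    getattr(mle.params, name) / scale, abs=1e-3)

    def test_tight_prior_shrinks_estimate_toward_prior_mean(self, dual_spec):
        s = _simulate(ParamSet(tau=5.0, alpha_gain=0.9, alpha_loss=0.3), dual_spec, 21, 22)
        mle = fit_mle(s, dual_spec, n_restarts=10, seed=5)
        tight = PriorSpec({"tau": (1.0, 1.0), "alpha_gain": (200.0, 200.0),
                           "alpha_loss": (1.0, 1.0)})
        mp = fit_map(s, dual_spec, priors=tight, n_restarts=10, seed=5)
        assert abs(mp.params.alpha_gain - 0.5) < abs(mle.params.alpha_gain - 0.5)
        assert min(mle.params.alpha_gain, 0.5) - 1e-6 <= mp.params.alpha_gain \
            <= max(mle.params.alpha_gain, 0.5) + 1e-6

    def test_penalized_objective_no_worse_than_at_mle_solution(self, bandit_session, dual_spec):
        priors = PriorSpec({"tau": (2.0, 5.0), "alpha_gain": (2.0, 2.0),
                            "alpha_loss": (2.0, 4.0)})
        mle = fit_mle(bandit_session, dual_spec, n_restarts=8, seed=2)
        fitter = MAPFitter(dual_spec, priors=priors, n_restarts=8, seed=2).fit(bandit_session)
        x_mle = mle.params.to_vector(dual_spec)
        pen_at_mle = fitter._penalty(np.clip(x_mle, 1e-6, None), dual_spec)
        assert fitter.objective_ <= mle.nll + pen_at_mle + 1e-6


class TestSklearnInterface:
    def test_get_set_params_round_trip(self, dual_spec):
        f = MLEFitter(dual_spec, n_restarts=7, seed=3)
        params = f.get_params()
        assert params["n_restarts"] == 7
        g = MLEFitter().set_params(**params)
        assert g.n_restarts == 7 and g.model == dual_spec

    def test_fitted_attributes(self, bandit_session, dual_spec):
        f = MLEFitter(dual_spec, n_restarts=4, seed=0).fit(bandit_session)
        for attr in ("params_", "nll_", "bic_", "converged_", "result_"):
            assert hasattr(f, attr)


@pytest.fixture(scope="module")
def small_cohort():
    spec = ModelSpec(2, "single", "bandit")
    rng = np.random.default_rng(123)
    truths, sessions = [], []
    for i in range(12):
        p = ParamSet(tau=float(np.clip(rng.normal(5.25, 2.18), 0.5, 15)),
                     alpha_gain=float(rng.beta(2.08, 0.89)),
                     alpha_loss=float(rng.beta(1.58, 4.74)))
        truths.append(p)
        s = _simulate(p, spec, 1000 + i, 2000 + i)
        s.participant_id = f"p{i:02d}"
        sessions.append(s)
    return spec, truths, sessions


class TestHierarchicalBayes:
    def test_shrinkage_toward_group_mean(self, small_cohort):
        """hBayes point estimates lie between the participant's own MLE and
        the group mean for the large majority of participants."""
        spec, truths, sessions = small_cohort
        fitter = HierarchicalBayesFitter(spec, n_chains=2, n_draws=400, n_warmup=600,
                                         seed=5).fit(sessions)
        est = fitter.result_.point_estimates()
        mles = [fit_mle(s, spec, n_restarts=8, seed=i) for i, s in enumerate(sessions)]
        inside = total = 0
        for name in spec.param_names:
            scale = 20.0 if name == "tau" else 1.0
            mle_vals = np.array([getattr(r.params, name) for r in mles]) / scale
            hb_vals = est[name].to_numpy() / scale
            group = fitter.result_.group_mean[name]
            for m, h in zip(mle_vals, hb_vals):
                lo, hi = min(m, group), max(m, group)
                inside += (lo - 0.02 <= h <= hi + 0.02)
                total += 1
        assert inside / total >= 0.9

    def test_group_mean_posterior_covers_generating_mean(self, small_cohort):
        spec, truths, sessions = small_cohort
        fitter = HierarchicalBayesFitter(spec, n_chains=2, n_draws=400, n_warmup=600,
                                         seed=6).fit(sessions)
        om = fitter.draws_.omega.reshape(-1, spec.n_params)
        j = spec.param_names.index("alpha_gain")
        lo, hi = np.quantile(om[:, j], [0.025, 0.975])
        assert lo <= 0.70 <= hi

    def test_informed_priors_change_little_on_same_data(self, small_cohort):
        spec, truths, sessions = small_cohort
        base = HierarchicalBayesFitter(spec, n_chains=2, n_draws=300, n_warmup=500,
                                       seed=7).fit(sessions).result_
        informed = HierarchicalBayesFitter(spec, n_chains=2, n_draws=300, n_warmup=500,
                                           seed=8, informed_prior=base).fit(sessions).result_
        assert informed.informed_prior_source == "T1"
        a = base.point_estimates().to_numpy()
        b = informed.point_estimates().to_numpy()
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.95

    def test_cloned_participants_cluster_tightly(self, dual_spec):
        # the same strongly-informative session cloned: participant posterior
        # means nearly identical across clones
        s = _simulate(ParamSet(tau=8.0, alpha_gain=0.7, alpha_loss=0.2), dual_spec, 1, 2)
        clones = []
        for i in range(10):
            import copy

            c = copy.deepcopy(s)
            c.participant_id = f"c{i:02d}"
            clones.append(c)
        f = HierarchicalBayesFitter(dual_spec, n_chains=2, n_draws=300, n_warmup=500,
                                    seed=9).fit(clones)
        est = f.result_.point_estimates()
        assert est["tau"].std() < 0.5
        assert est["alpha_gain"].std() < 0.05


class TestJoint:
    def test_independent_sessions_give_near_zero_correlations(self):
        spec = ModelSpec(2, "single", "bandit")
        rng = np.random.default_rng(31)

        def cohort(label, offset):
            sessions = []
            for i in range(20):
                p = ParamSet(tau=float(np.clip(rng.normal(5.25, 2.18), 0.5, 15)),
                             alpha_gain=float(rng.beta(2.08, 0.89)),
                             alpha_loss=float(rng.beta(1.58, 4.74)))
                s = _simulate(p, spec, offset + i, offset + 100 + i)
                s.participant_id = f"p{i:02d}"
                s.session_label = label
                sessions.append(s)
            return sessions

        t1 = cohort("T1", 5000)
        t2 = cohort("T2", 6000)  # parameters drawn independently of T1
        f = JointHierarchicalFitter(spec, n_chains=2, n_draws=400, n_warmup=800,
                                    seed=10).fit(t1, t2)
        for name, rho in f.result_.correlations.items():
            assert abs(rho) < 0.5

    def test_without_correlation_matches_disjoint_posterior_means(self):
        # rho fixed at 0 makes the two sessions independent; participant
        # posterior means agree with separately fitted sessions up to MCMC
        # error and the marginal-family difference (logit-normal vs beta)
        spec = ModelSpec(2, "single", "bandit")
        rng = np.random.default_rng(41)
        t1, t2 = [], []
        for i in range(12):
            p = ParamSet(tau=float(np.clip(rng.normal(5.25, 2.18), 0.5, 15)),
                         alpha_gain=float(rng.beta(2.08, 0.89)),
                         alpha_loss=float(rng.beta(1.58, 4.74)))
            for label, dest, off in (("T1", t1, 7000), ("T2", t2, 8000)):
                s = _simulate(p, spec, off + i, off + 100 + i)
                s.participant_id = f"p{i:02d}"
                s.session_label = label
                dest.append(s)
        joint = JointHierarchicalFitter(spec, with_correlation=False, n_chains=2,
                                        n_draws=400, n_warmup=800, seed=11).fit(t1, t2)
        assert all(v == 0.0 for v in joint.result_.correlations.values())
        disjoint = HierarchicalBayesFitter(spec, n_chains=2, n_draws=400, n_warmup=800,
                                           seed=12).fit(t1).result_.point_estimates()
        joint_t1 = joint.result_.point_estimates("T1")
        pooled_a, pooled_b = [], []
        for name in spec.param_names:
            scale = 20.0 if name == "tau" else 1.0
            a = disjoint[name].to_numpy() / scale
            b = joint_t1[name].to_numpy() / scale
            assert np.mean(np.abs(a - b)) < 0.1
            pooled_a.append(a)
            pooled_b.append(b)
        # pooled over parameters (per-parameter correlation is meaningless
        # when the beta hierarchy shrinks a parameter to a near-constant)
        assert np.corrcoef(np.concatenate(pooled_a), np.concatenate(pooled_b))[0, 1] > 0.95

    def test_participant_mismatch_rejected(self, small_cohort):
        spec, truths, sessions = small_cohort
        with pytest.raises(ValueError):
            JointHierarchicalFitter(spec).fit(sessions, sessions[:-1])
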