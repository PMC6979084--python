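import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eiphlca import (
    CohortDesign,
    LatentClassParams,
    McmcConfig,
    PosteriorSummary,
    PriorSpec,
    convergence_diagnostics,
    fit_mcmc,
    generate_cohort,
    log_joint,
    map_estimate,
    prior_sensitivity,
)
from eiphlca.cohort import PARAM_NAMES
from conftest import exercised_record, sedentary_record

FAST = McmcConfig(n_chains=4, n_iterations=2500, n_burn_in=750, seed=77)


def scipy_log_joint(params: LatentClassParams, records, priors: PriorSpec = PriorSpec()):
    """Independent oracle: direct density evaluation with scipy.stats."""
    lp = stats.norm.logpdf(params.mu_pos, priors.mu_prior_mean, priors.mu_prior_sd)
    lp += stats.norm.logpdf(params.mu_neg, priors.mu_prior_mean, priors.mu_prior_sd)
    for lo, hi in (
        priors.sigma_prior_range,
        priors.sigma_prior_range,
        priors.se_prior_range,
        priors.fpr_prior_range,
        priors.prev_prior_range,
    ):
        lp -= math.log(hi - lo)
    for r in records:
        y = math.log(r.balf_rbc)
        if r.group == "sedentary":
            lp += stats.norm.logpdf(y, params.mu_neg, params.sigma_neg)
        else:
            t = 1 if r.tbe_score >= 1 else 0
            pos = (
                params.prev
                * stats.norm.pdf(y, params.mu_pos, params.sigma_pos)
                * params.se_tbe**t
                * (1 - params.se_tbe) ** (1 - t)
            )
            neg = (
                (1 - params.prev)
                * stats.norm.pdf(y, params.mu_neg, params.sigma_neg)
                * params.fpr_tbe**t
                * (1 - params.fpr_tbe) ** (1 - t)
            )
            lp += math.log(pos + neg)
    return lp


@pytest.fixture(scope="module")
def mid_params():
    return LatentClassParams(
        mu_pos=8.0, sigma_pos=1.5, mu_neg=5.5, sigma_neg=0.5,
        se_tbe=0.6, fpr_tbe=0.005, prev=0.5,
    )


class TestLogJoint:
    def test_single_record_matches_density_oracle(self, mid_params):
        records = [exercised_record("h1", 1, math.exp(6.0))]
        assert log_joint(mid_params, records) == pytest.approx(
            scipy_log_joint(mid_params, records), rel=1e-12
        )

    def test_mixed_cohort_matches_density_oracle(self, mid_params, small_cohort):
        assert log_joint(mid_params, small_cohort) == pytest.approx(
            scipy_log_joint(mid_params, small_cohort), rel=1e-10
        )

    @pytest.mark.parametrize(
        "bad",
        [
            {"fpr_tbe": 0.02},
            {"sigma_pos": -0.5},
            {"sigma_neg": 150.0},
            {"se_tbe": 1.2},
            {"prev": -0.1},
        ],
    )
    def test_outside_prior_support_is_minus_inf(self, mid_params, bad, small_cohort):
        assert log_joint(replace(mid_params, **bad), small_cohort) == -np.inf

    def test_degenerate_mixture_reduces_to_positive_component(self, mid_params):
        """With prev = 1 the exercised likelihood is the single positive
        component exactly."""
        params = replace(mid_params, prev=1.0)
        records = [exercised_record(f"h{i}", s, v) for i, (s, v) in
                   enumerate([(1, 800.0), (0, 12_000.0), (2, 300_000.0)])]
        single = 0.0
        for r in records:
            t = 1 if r.tbe_score >= 1 else 0
            single += stats.norm.logpdf(math.log(r.balf_rbc), params.mu_pos, params.sigma_pos)
            single += t * math.log(params.se_tbe) + (1 - t) * math.log(1 - params.se_tbe)
        prior = scipy_log_joint(params, [])  # oracle with no data = prior term
        assert log_joint(params, records) == pytest.approx(prior + single, rel=1e-12)

    def test_additive_over_records_and_permutation_invariant(self, mid_params, small_cohort):
        a, b = small_cohort[:40], small_cohort[40:]
        lj_all = log_joint(mid_params, list(small_cohort))
        lj_a = log_joint(mid_params, a)
        lj_b = log_joint(mid_params, b)
        prior_term = scipy_log_joint(mid_params, [])
        assert lj_all == pytest.approx(lj_a + lj_b - prior_term, rel=1e-10)
        shuffled = list(small_cohort)
        np.random.default_rng(0).shuffle(shuffled)
        assert log_joint(mid_params, shuffled) == pytest.approx(lj_all, rel=1e-12)

    def test_empty_records_rejected(self, mid_params):
        with pytest.raises(ValueError, match="empty"):
            log_joint(mid_params, [])


class TestConvergenceDiagnostics:
    def test_identical_chains_with_matching_halves(self):
        """Copies of one sequence whose halves coincide: B = 0, so
        R-hat = sqrt((n-1)/n) with n the split length."""
        seq = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        rhat, ess = convergence_diagnostics(np.stack([seq, seq]))
        assert rhat == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-12)

    def test_textbook_formula_oracle(self):
        """Two chains (1..4) and (11..14): hand-evaluated between/within
        decomposition after splitting gives W=0.5, B=2*104/3."""
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [11.0, 12.0, 13.0, 14.0]])
        w = 0.5
        b = 2.0 * (104.0 / 3.0)
        var_hat = (2 - 1) / 2 * w + b / 2
        rhat, _ = convergence_diagnostics(chains)
        assert rhat == pytest.approx(math.sqrt(var_hat / w), rel=1e-12)

    def test_independent_draws_rhat_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.normal(0, 1, size=(4, 10_000))
        rhat, ess = convergence_diagnostics(chains)
        assert abs(rhat - 1.0) < 0.01
        assert ess > 0.5 * chains.size

    def test_matches_arviz_identity_rhat(self):
        import arviz as az

        rng = np.random.default_rng(9)
        chains = rng.normal(0, 1, size=(4, 500)).cumsum(axis=1) * 0.05 + rng.normal(
            0, 1, size=(4, 500)
        )
        rhat, _ = convergence_diagnostics(chains)
        data = az.from_dict(posterior={"x": chains})
        ref = float(az.rhat(data, method="split").x)
        assert rhat == pytest.approx(ref, rel=1e-6)

    def test_unequal_chain_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            convergence_diagnostics([np.arange(10.0), np.arange(8.0)])


def _summary_from_draws(draws: np.ndarray, ljs: np.ndarray) -> PosteriorSummary:
    pooled = draws.reshape(-1, len(PARAM_NAMES))
    table = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "median": np.median(pooled, axis=0),
            "map": pooled[np.argmax(ljs)],
            "ci_2.5": np.percentile(pooled, 2.5, axis=0),
            "ci_97.5": np.percentile(pooled, 97.5, axis=0),
            "rhat": np.ones(len(PARAM_NAMES)),
            "ess": np.full(len(PARAM_NAMES), float(pooled.shape[0])),
        },
        index=list(PARAM_NAMES),
    )
    return PosteriorSummary(table, draws, ljs.reshape(draws.shape[:2]), 0, True)


class TestMapEstimate:
    def test_single_draw_returned(self):
        theta = np.array([9.0, 1.5, 5.7, 0.5, 0.6, 0.005, 0.9])
        s = _summary_from_draws(theta[None, None, :], np.array([-3.0]))
        assert map_estimate(s) == LatentClassParams.from_array(theta)

    def test_argmax_of_three_draws(self):
        draws = np.stack(
            [
                np.array([8.0, 1.0, 5.0, 0.4, 0.5, 0.004, 0.8]),
                np.array([9.0, 1.5, 5.7, 0.5, 0.6, 0.005, 0.9]),
                np.array([7.0, 2.0, 5.2, 0.6, 0.7, 0.006, 0.7]),
            ]
        )[None]
        ljs = np.array([-10.0, -5.0, -7.0])
        assert map_estimate(_summary_from_draws(draws, ljs)).mu_pos == 9.0

    def test_unknown_method_rejected(self):
        theta = np.array([9.0, 1.5, 5.7, 0.5, 0.6, 0.005, 0.9])
        s = _summary_from_draws(theta[None, None, :], np.array([-3.0]))
        with pytest.raises(ValueError, match="method"):
            map_estimate(s, method="posterior_mean")


@pytest.fixture(scope="module")
def recovery_fit():
    truth = LatentClassParams(
        mu_pos=9.0, sigma_pos=1.5, mu_neg=5.7, sigma_neg=0.5,
        se_tbe=0.6, fpr_tbe=0.005, prev=0.9,
    )
    records = generate_cohort(truth, CohortDesign(1000, 9, 2, seed=314))
    return truth, fit_mcmc(records, PriorSpec(), replace(FAST, seed=2718))


class TestFitMcmc:
    def test_parameter_recovery_single_cohort(self, recovery_fit):
        """Generating values fall inside their own 95% credible intervals
        on a 1000-event cohort, and the chains converge."""
        truth, summary = recovery_fit
        for name in PARAM_NAMES:
            lo, hi = summary.credible_interval(name)
            assert lo <= getattr(truth, name) <= hi, name
        assert summary.converged

    def test_map_consistent_with_recovery(self, recovery_fit):
        """The joint-MAP draw lies inside the marginal 95% intervals of the
        data-identified parameters.  fpr_tbe is excluded: its posterior is
        essentially its flat Uniform(0, 0.01) prior, so the joint mode's
        coordinate is arbitrary within the prior range while the
        equal-tailed interval clips 5% of it."""
        truth, summary = recovery_fit
        m = map_estimate(summary)
        for name in PARAM_NAMES:
            if name == "fpr_tbe":
                assert 0.0 <= m.fpr_tbe <= 0.01
                continue
            lo, hi = summary.credible_interval(name)
            assert lo <= getattr(m, name) <= hi, name

    def test_marginal_mode_map_near_joint_map(self, recovery_fit):
        _, summary = recovery_fit
        joint = map_estimate(summary)
        marginal = map_estimate(summary, method="marginal_mode")
        assert marginal.mu_pos == pytest.approx(joint.mu_pos, abs=0.3)
        assert marginal.mu_neg == pytest.approx(joint.mu_neg, abs=0.3)

    def test_draws_inside_prior_support_and_identified(self, recovery_fit):
        _, summary = recovery_fit
        pooled = summary.draws.reshape(-1, 7)
        d = dict(zip(PARAM_NAMES, pooled.T))
        assert (d["sigma_pos"] > 0).all() and (d["sigma_pos"] <= 100).all()
        assert (d["sigma_neg"] > 0).all() and (d["sigma_neg"] <= 100).all()
        for name in ("se_tbe", "prev"):
            assert (d[name] >= 0).all() and (d[name] <= 1).all()
        assert (d["fpr_tbe"] >= 0).all() and (d["fpr_tbe"] <= 0.01).all()
        assert (d["mu_pos"] >= d["mu_neg"]).all()

    def test_interval_brackets_median(self, recovery_fit):
        _, summary = recovery_fit
        t = summary.table
        assert (t["ci_2.5"] <= t["median"]).all()
        assert (t["median"] <= t["ci_97.5"]).all()

    def test_seed_determinism(self, small_cohort):
        cfg = McmcConfig(n_chains=2, n_iterations=600, n_burn_in=200, seed=5)
        a = fit_mcmc(small_cohort, PriorSpec(), cfg)
        b = fit_mcmc(small_cohort, PriorSpec(), cfg)
        assert np.array_equal(a.draws, b.draws)
        assert a.table.equals(b.table)

    def test_mixture_collapse_matches_plain_normal_fit(self, study_params):
        """With the prevalence prior collapsed onto 1, the positive
        component posterior matches a plain normal fit to all exercised
        log counts."""
        records = generate_cohort(replace(study_params, prev=1.0), CohortDesign(400, 9, 2, seed=6))
        y = np.log([r.balf_rbc for r in records if r.group == "exercised"])
        priors = PriorSpec(prev_prior_range=(0.999999, 1.0))
        summary = fit_mcmc(records, priors, replace(FAST, n_chains=2, seed=8))
        assert summary.posterior_mean("mu_pos") == pytest.approx(y.mean(), abs=4 * y.std() / math.sqrt(y.size))
        assert summary.posterior_mean("sigma_pos") == pytest.approx(y.std(ddof=1), rel=0.1)

    def test_requires_exercised_records(self, small_cohort):
        sed = [r for r in small_cohort if r.group == "sedentary"]
        with pytest.raises(ValueError, match="exercised"):
            fit_mcmc(sed, PriorSpec(), FAST)


@pytest.fixture(scope="module")
def dominated(study_params):
    """Cohort with no TBE positives among EIPH-negatives: the
    false-positive posterior is its (scaled) uniform prior."""
    params = replace(study_params, se_tbe=0.6, fpr_tbe=0.0, prev=0.96)
    records = generate_cohort(params, CohortDesign(102, 9, 2, seed=99))
    return prior_sensitivity(records, PriorSpec(), replace(FAST, seed=41), (0.9, 1.0, 1.1))


class TestPriorSensitivity:

    def test_scale_one_identical_to_base(self, study_params):
        params = replace(study_params, prev=0.9)
        records = generate_cohort(params, CohortDesign(120, 9, 2, seed=13))
        cfg = McmcConfig(n_chains=2, n_iterations=800, n_burn_in=300, seed=3)
        base = fit_mcmc(records, PriorSpec(), cfg)
        res = prior_sensitivity(records, PriorSpec(), cfg, scales=(1.0,))
        assert np.allclose(res.means.loc[1.0].to_numpy(), base.table["mean"].to_numpy())

    def test_prior_dominated_fpr_scales_with_upper_bound(self, dominated):
        """Posterior mean of the false-positive probability tracks the
        scaled Uniform(0, u) prior mean u/2 (mild (1-u)^k tilt)."""
        for scale in (0.9, 1.0, 1.1):
            expected = 0.005 * scale
            assert dominated.means.loc[scale, "fpr_tbe"] == pytest.approx(expected, rel=0.05)

    def test_substantive_posteriors_stable(self, dominated):
        assert dominated.max_abs_deviation["se_tbe"] < 0.01
        assert dominated.max_abs_deviation["mu_pos"] < 0.05
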