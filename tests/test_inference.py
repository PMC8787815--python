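"""Likelihood, fitting, AIC ranking, profiles, confidence intervals."""

import json

import numpy as np
import pytest
from scipy import stats

from cfekit import (
    BULK_MLE, NoiseSpec, OptimizerConfig, ProfileCurve, TitrationDataset,
    aic, fit_mle, likelihood_ci, negative_log_likelihood, profile_likelihood,
    rank_models, simulate,
)
from cfekit.generate import GeneratorConfig, generate_bulk_titration
from cfekit.inference import Experiment, profile_function, resolve_noise
from cfekit.io import fit_result_to_dict
from cfekit.studies import FIT_H

FIXED_AT_TRUTH = {
    n: getattr(BULK_MLE, n)
    for n in ("K_r", "K_p", "k_mat", "delta_TsR", "delta_TlR", "K_l",
              "a", "b", "tau_d")
} | {"tau_l": 0.0}

SIGMA1 = NoiseSpec(kind="fixed", sigma_rna=1.0, sigma_protein=1.0)


class TestNLL:
    def test_zero_residuals_gives_normalizing_constant(self, clean_dataset):
        n_total = sum(len(e.time_h) * 2 for e in clean_dataset.experiments)
        nll = negative_log_likelihood(BULK_MLE, "V1", clean_dataset,
                                      noise=SIGMA1)
        assert nll == pytest.approx(n_total / 2 * np.log(2 * np.pi), rel=1e-9)

    def test_hand_summed_residuals(self):
        # three RNA residuals (1, -1, 2) at unit SD on top of an exact fit
        t = np.array([1.0, 2.0, 3.0])
        traj = simulate(BULK_MLE, "V1", dna0=3.75,
                        t_grid=np.insert(t, 0, 0.0))
        rna = traj.observed_rna[1:] + np.array([1.0, -1.0, 2.0])
        prot = traj.observed_protein[1:]
        exps = [
            Experiment("e1", "dna", 3.75, 1, t, rna, prot),
            Experiment("e2", "dna", 1.875, 1, t, np.zeros(3), np.zeros(3)),
        ]
        # second experiment: make it exact too
        traj2 = simulate(BULK_MLE, "V1", dna0=1.875,
                         t_grid=np.insert(t, 0, 0.0))
        exps[1] = Experiment("e2", "dna", 1.875, 1, t,
                             traj2.observed_rna[1:],
                             traj2.observed_protein[1:])
        data = TitrationDataset(experiments=exps)
        nll = negative_log_likelihood(BULK_MLE, "V1", data, noise=SIGMA1)
        n_total = 12
        assert nll == pytest.approx(
            n_total / 2 * np.log(2 * np.pi) + 3.0, rel=1e-6
        )

    def test_doubling_sigma_adds_n_log2(self, clean_dataset):
        n_total = sum(len(e.time_h) * 2 for e in clean_dataset.experiments)
        nll1 = negative_log_likelihood(BULK_MLE, "V1", clean_dataset,
                                       noise=SIGMA1)
        nll2 = negative_log_likelihood(
            BULK_MLE, "V1", clean_dataset,
            noise=NoiseSpec(kind="fixed", sigma_rna=2.0, sigma_protein=2.0),
        )
        assert nll2 - nll1 == pytest.approx(n_total * np.log(2.0), rel=1e-9)

    def test_extreme_parameters_return_finite_penalty(self, clean_dataset):
        bad = BULK_MLE.replace(k_r=1e30)
        v = negative_log_likelihood(bad, "V1", clean_dataset)
        assert np.isfinite(v)

    def test_replicate_noise_resolution(self, small_noisy_dataset):
        spec = resolve_noise(small_noisy_dataset, NoiseSpec(kind="auto"))
        assert spec.kind == "fixed"
        assert spec.sigma_rna > 0 and spec.sigma_protein > 0

    def test_concentrated_fallback_without_replicates(self, clean_dataset):
        spec = resolve_noise(clean_dataset, NoiseSpec(kind="auto"))
        assert spec.kind == "concentrated"
        with pytest.raises(ValueError):
            resolve_noise(clean_dataset, NoiseSpec(kind="replicate"))

    def test_invalid_noise_spec(self):
        with pytest.raises(ValueError):
            NoiseSpec(kind="fixed")
        with pytest.raises(ValueError):
            NoiseSpec(kind="bogus")


class TestAic:
    def test_formula(self):
        assert aic(0, 0.0) == 0.0
        assert aic(12, 100.0) == 224.0

    def test_parsimony_ordering(self, clean_dataset):
        f1 = fit_mle(clean_dataset, "V1", fixed=FIXED_AT_TRUTH,
                     free=("k_r", "delta_r", "k_p"), n_starts=1,
                     init_params=[BULK_MLE], noise=SIGMA1, h_target=FIT_H)
        import dataclasses

        f2 = dataclasses.replace(f1, k=f1.k + 1, aic=aic(f1.k + 1, f1.nll_hat))
        ranked = rank_models([f2, f1])
        assert ranked[0].k < ranked[1].k

    def test_rank_rejects_mixed_datasets(self, clean_dataset,
                                         small_noisy_dataset):
        kw = dict(fixed=FIXED_AT_TRUTH, free=("k_r", "delta_r", "k_p"),
                  n_starts=1, init_params=[BULK_MLE], noise=SIGMA1,
                  h_target=FIT_H)
        f1 = fit_mle(clean_dataset, "V1", **kw)
        f2 = fit_mle(small_noisy_dataset, "V1", **kw)
        with pytest.raises(ValueError):
            rank_models([f1, f2])

    def test_rank_permutation_invariant(self, clean_dataset):
        kw = dict(fixed=FIXED_AT_TRUTH, free=("k_r", "delta_r", "k_p"),
                  n_starts=1, init_params=[BULK_MLE], noise=SIGMA1,
                  h_target=FIT_H)
        fits = [fit_mle(clean_dataset, c, **kw) for c in ("V1", "V3")]
        a = [f.variant.code for f in rank_models(fits)]
        b = [f.variant.code for f in rank_models(fits[::-1])]
        assert a == b


class TestFit:
    def test_start_at_truth_cannot_worsen(self, clean_dataset):
        nll_true = negative_log_likelihood(BULK_MLE, "V1", clean_dataset,
                                           noise=SIGMA1, h_target=FIT_H)
        fit = fit_mle(clean_dataset, "V1", fixed=FIXED_AT_TRUTH,
                      free=("k_r", "delta_r", "k_p"), n_starts=1,
                      init_params=[BULK_MLE], noise=SIGMA1, h_target=FIT_H)
        assert fit.nll_hat <= nll_true + 1e-6

    def test_zero_noise_round_trip_within_one_percent(self, clean_dataset):
        fit = fit_mle(clean_dataset, "V1", fixed=FIXED_AT_TRUTH,
                      free=("k_r", "delta_r", "k_p"), n_starts=2, seed=3,
                      noise=SIGMA1, h_target=FIT_H)
        for name in ("k_r", "delta_r", "k_p"):
            true = getattr(BULK_MLE, name)
            assert getattr(fit.theta_hat, name) == pytest.approx(true, rel=0.01)

    def test_aic_consistent_with_stored_fields(self, clean_dataset):
        fit = fit_mle(clean_dataset, "V1", fixed=FIXED_AT_TRUTH,
                      free=("k_r", "delta_r", "k_p"), n_starts=1,
                      init_params=[BULK_MLE], noise=SIGMA1, h_target=FIT_H)
        assert fit.aic == pytest.approx(2 * fit.k + 2 * fit.nll_hat)
        assert fit.k == 3

    def test_seeded_determinism(self, small_noisy_dataset):
        kw = dict(fixed=FIXED_AT_TRUTH, free=("k_r", "delta_r", "k_p"),
                  n_starts=2, seed=11, h_target=FIT_H,
                  optimizer=OptimizerConfig(maxiter_grad=60,
                                            maxiter_polish=100, n_screen=16))
        a = json.dumps(fit_result_to_dict(
            fit_mle(small_noisy_dataset, "V1", **kw)), sort_keys=True)
        b = json.dumps(fit_result_to_dict(
            fit_mle(small_noisy_dataset, "V1", **kw)), sort_keys=True)
        assert a == b

    def test_single_level_rejected(self):
        cfg = GeneratorConfig(dna_levels_nM=(3.75,), replicates=2,
                              noise_cv=0.0, dt_h=1.0, seed=1)
        data = generate_bulk_titration(cfg)
        with pytest.raises(ValueError):
            fit_mle(data, "V1")

    def test_inactive_free_parameter_rejected(self, clean_dataset):
        with pytest.raises(ValueError):
            fit_mle(clean_dataset, "V7", free=("K_r",))


@pytest.fixture(scope="module")
def small_fit(clean_dataset):
    return fit_mle(
        clean_dataset, "V1", fixed=FIXED_AT_TRUTH,
        free=("k_r", "delta_r", "k_p"), n_starts=1, init_params=[BULK_MLE],
        noise=SIGMA1, h_target=FIT_H,
    )


class TestProfile:
    def test_profile_touches_minimum_at_estimate(self, small_fit,
                                                 clean_dataset):
        prof = profile_likelihood(small_fit, clean_dataset, "k_r", n_grid=9)
        i = np.argmin(np.abs(np.log10(prof.grid / prof.theta_hat)))
        assert prof.nll[i] == pytest.approx(small_fit.nll_hat, abs=1e-4)
        # profiled NLL can never undercut the MLE (within optimizer slack)
        assert np.nanmin(prof.nll) >= small_fit.nll_hat - 1e-4

    def test_ci_brackets_estimate_and_grows_with_df(self, small_fit,
                                                    clean_dataset):
        prof = profile_likelihood(small_fit, clean_dataset, "k_r", n_grid=9)
        lo1, hi1 = likelihood_ci(prof, df=1)
        lo12, hi12 = likelihood_ci(prof, df=12)
        assert lo1 <= small_fit.theta_hat.k_r <= hi1
        # a larger chi-squared threshold can only widen the interval
        assert lo12 <= lo1 and hi12 >= hi1

    def test_non_free_parameter_rejected(self, small_fit, clean_dataset):
        with pytest.raises(ValueError):
            profile_likelihood(small_fit, clean_dataset, "k_mat")

    def test_single_parameter_profile_is_the_function(self):
        # no nuisance parameters: the profile IS the objective
        def quad(z):
            theta = 10.0 ** z[0]
            return 0.5 * ((theta - 1.0) / 0.1) ** 2

        grid, nll, ok = profile_function(quad, np.array([0.0]), 0, 0.0,
                                         n_grid=21)
        assert ok.all()
        expect = 0.5 * ((10.0 ** grid - 1.0) / 0.1) ** 2
        assert nll == pytest.approx(expect, rel=1e-12)

    def test_exact_ridge_profiles_flat(self):
        # theta1 * theta2 = 1 is a perfect ridge: profile of theta1 is flat
        def ridge(z):
            return 0.5 * ((10.0 ** z[0] * 10.0 ** z[1] - 1.0) / 0.1) ** 2

        grid, nll, ok = profile_function(
            ridge, np.array([0.0, 0.0]), 0, 0.0, n_grid=11,
            lo=np.array([-8.0, -8.0]), hi=np.array([8.0, 8.0]),
        )
        assert np.nanmax(nll[ok]) < 1e-6


class TestLikelihoodCI:
    @staticmethod
    def _quad_profile(n_grid=201):
        grid = np.logspace(-1, 1, n_grid)
        nll = 0.5 * ((grid - 1.0) / 0.1) ** 2
        return ProfileCurve(parameter="theta", grid=grid, nll=nll,
                            nll_hat=0.0, theta_hat=1.0)

    @pytest.mark.parametrize("df,halfwidth", [
        (1, 0.1 * np.sqrt(stats.chi2.ppf(0.95, 1))),
        (12, 0.1 * np.sqrt(stats.chi2.ppf(0.95, 12))),
    ])
    def test_quadratic_closed_form(self, df, halfwidth):
        lo, hi = likelihood_ci(self._quad_profile(), df=df)
        assert lo == pytest.approx(1.0 - halfwidth, abs=1e-3)
        assert hi == pytest.approx(1.0 + halfwidth, abs=1e-3)

    def test_flat_profile_reports_infinite_bounds(self):
        grid = np.logspace(-1, 1, 21)
        prof = ProfileCurve(parameter="theta", grid=grid,
                            nll=np.zeros(21), nll_hat=0.0, theta_hat=1.0)
        lo, hi = likelihood_ci(prof, df=12)
        assert lo == -np.inf and hi == np.inf

    def test_inconsistent_profile_rejected(self):
        grid = np.logspace(-1, 1, 21)
        prof = ProfileCurve(parameter="theta", grid=grid,
                            nll=np.full(21, 50.0), nll_hat=0.0, theta_hat=1.0)
        with pytest.raises(ValueError):
            likelihood_ci(prof, df=1)


class TestCoverage:
    def test_profile_ci_coverage_gaussian_mean(self):
        """Profile-likelihood CIs through the real machinery achieve ~95%
        coverage on a 1-parameter Gaussian-mean problem (chi-squared df=1)."""
        rng = np.random.default_rng(2024)
        mu, sigma, n = 1.0, 0.3, 25
        n_rep, covered = 150, 0
        for _ in range(n_rep):
            y = rng.normal(mu, sigma, n)

            def nll_fn(z):
                theta = 10.0 ** z[0]
                return float(np.sum((y - theta) ** 2) / (2 * sigma**2))

            theta_hat = max(float(np.mean(y)), 1e-6)
            z_hat = np.array([np.log10(theta_hat)])
            nll_hat = nll_fn(z_hat)
            grid, nll, ok = profile_function(nll_fn, z_hat, 0, nll_hat,
                                             n_grid=41)
            prof = ProfileCurve(parameter="mu", grid=10.0 ** grid, nll=nll,
                                nll_hat=nll_hat, theta_hat=theta_hat, ok=ok)
            lo, hi = likelihood_ci(prof, df=1)
            covered += lo <= mu <= hi
        assert covered / n_rep >= 0.90
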