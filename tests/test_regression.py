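"""Weighted simultaneous regression: objective, recovery, dof, uncertainties."""

import numpy as np
import pytest

from foci_kinetics import (
    FociDataset,
    ModelOptions,
    difference_dataset,
    independent_fit,
    objective,
    radiation_mean,
    reference_params,
    simultaneous_fit,
    standard_errors,
)
from foci_kinetics.kinetics import sham_mean, total_mean
from foci_kinetics.regression import covariance_from_jacobian

from conftest import QUALITIES, TIMES, closed_form_datasets


class TestObjective:
    def test_zero_residuals_when_model_equals_data(
        self, ref_params, fixed_spectra, noise_free_datasets
    ):
        r = objective(ref_params, noise_free_datasets, fixed_spectra)
        assert np.allclose(r, 0.0, atol=1e-12)
        assert len(r) == 25

    def test_two_sigma_residual_contributes_four(self, ref_params, fixed_spectra):
        model = float(sham_mean(2.0, ref_params))
        ds = FociDataset("sham", [2.0], [model + 0.2], [0.1])
        r = objective(ref_params, [ds], fixed_spectra)
        assert np.sum(r**2) == pytest.approx(4.0)

    def test_matches_scalar_loop_oracle(self, rng, ref_params, fixed_spectra,
                                        noise_free_datasets):
        # perturb the data so residuals are non-trivial, then recompute chi2
        # with an independently coded point-by-point loop
        datasets = []
        for d in noise_free_datasets:
            datasets.append(
                FociDataset(d.quality, d.t, d.mean + rng.normal(0, 0.2, len(d)),
                            d.sd, d.n_replicates)
            )
        chi2 = float(np.sum(objective(ref_params, datasets, fixed_spectra) ** 2))
        total = 0.0
        for d in datasets:
            for t, m, sd in zip(d.t, d.mean, d.sd):
                if d.quality == "sham":
                    mod = sham_mean(t, ref_params)
                else:
                    mod = total_mean(t, d.quality, fixed_spectra[d.quality],
                                     ref_params)
                total += ((m - mod) / sd) ** 2
        assert chi2 == pytest.approx(total, rel=1e-12)

    def test_zero_sd_rejected_with_guidance(self, ref_params, fixed_spectra):
        ds = FociDataset("sham", [2.0], [0.5], [0.0])
        with pytest.raises(ValueError, match="weight floor"):
            objective(ref_params, [ds], fixed_spectra)


class TestSimultaneousFit:
    def test_noise_free_recovery(self, ref_params, fixed_spectra,
                                 noise_free_datasets):
        fit = simultaneous_fit(
            noise_free_datasets, fixed_spectra, n_random_starts=2, seed=0
        )
        truth = {
            "n_b": 0.24, "n_s": 0.26, "beta0": 0.27, "beta1": 0.27,
            "beta2": 0.01,
        }
        for q in QUALITIES:
            truth[f"n[{q}]"] = ref_params.tracks[q].n_track
            truth[f"p[{q}]"] = ref_params.tracks[q].p_persistent
        for name, tv in truth.items():
            assert fit.estimates[name] == pytest.approx(tv, rel=1e-4), name
        assert fit.chi2 < 1e-10

    def test_degrees_of_freedom_accounting(self, fixed_spectra,
                                           noise_free_datasets):
        fit = simultaneous_fit(noise_free_datasets, fixed_spectra,
                               n_random_starts=0, seed=0)
        assert len(fit.free_names) == 13
        assert fit.n_points == 25
        assert fit.dof == 12
        tied = simultaneous_fit(
            noise_free_datasets, fixed_spectra,
            ModelOptions(beta0_equals_beta1=True), n_random_starts=0, seed=0,
        )
        assert len(tied.free_names) == 12
        assert tied.dof == 13

    def test_refit_from_optimum_is_fixed_point(self, fixed_spectra,
                                               noise_free_datasets):
        fit = simultaneous_fit(noise_free_datasets, fixed_spectra,
                               n_random_starts=1, seed=0)
        refit = simultaneous_fit(
            noise_free_datasets, fixed_spectra, starts=[fit.x],
            n_random_starts=0,
        )
        assert refit.chi2 <= fit.chi2 + 1e-10
        assert np.allclose(refit.x, fit.x, atol=1e-6)

    def test_chi2_invariant_under_reordering(self, rng, ref_params,
                                             fixed_spectra,
                                             noise_free_datasets):
        datasets = [
            FociDataset(d.quality, d.t, d.mean + rng.normal(0, 0.1, len(d)),
                        d.sd, d.n_replicates)
            for d in noise_free_datasets
        ]
        fit_a = simultaneous_fit(datasets, fixed_spectra, n_random_starts=2,
                                 seed=0)
        shuffled = [
            FociDataset(d.quality, d.t[::-1], d.mean[::-1], d.sd[::-1],
                        d.n_replicates)
            for d in reversed(datasets)
        ]
        fit_b = simultaneous_fit(shuffled, fixed_spectra, n_random_starts=2,
                                 seed=0)
        assert fit_a.chi2 == pytest.approx(fit_b.chi2, rel=1e-6)

    def test_equivalent_parameterizations_reach_same_objective(
        self, rng, ref_params, fixed_spectra, noise_free_datasets
    ):
        datasets = [
            FociDataset(d.quality, d.t, d.mean + rng.normal(0, 0.05, len(d)),
                        d.sd, d.n_replicates)
            for d in noise_free_datasets
        ]
        fr = simultaneous_fit(datasets, fixed_spectra, ModelOptions(),
                              n_random_starts=4, seed=0)
        # transform the fraction-form optimum exactly into mean-number
        # coordinates and refit from there
        x0 = fr.x.copy()
        names = fr.free_names
        for q in QUALITIES:
            i_n = names.index(f"n[{q}]")
            i_p = names.index(f"p[{q}]")
            x0[i_p] = x0[i_n] * x0[i_p]
        mn = simultaneous_fit(
            datasets, fixed_spectra, ModelOptions(parameterization="mean-number"),
            starts=[x0], n_random_starts=0,
        )
        assert mn.chi2 == pytest.approx(fr.chi2, abs=1e-6)

    def test_missing_sham_rejected(self, fixed_spectra, noise_free_datasets):
        with pytest.raises(ValueError, match="sham"):
            simultaneous_fit(noise_free_datasets[:-1], fixed_spectra,
                             n_random_starts=0)


class TestIndependentFit:
    @pytest.fixture
    def diff_dataset(self, ref_params, fixed_spectra):
        q = "a_10MeV"
        mean = np.asarray(
            radiation_mean(TIMES, fixed_spectra[q], ref_params)
        )
        return FociDataset(q, TIMES.copy(), mean, np.full_like(TIMES, 0.05))

    def test_five_points_leave_one_degree_of_freedom(self, diff_dataset,
                                                     fixed_spectra):
        fit = independent_fit(diff_dataset, fixed_spectra["a_10MeV"],
                              n_random_starts=2, seed=0)
        assert fit.dof == 1

    def test_frozen_persistent_rate_gives_two(self, diff_dataset,
                                              fixed_spectra):
        fit = independent_fit(
            diff_dataset, fixed_spectra["a_10MeV"],
            ModelOptions(beta2_zero=True), n_random_starts=2, seed=0,
        )
        assert fit.dof == 2

    def test_noise_free_recovery(self, diff_dataset, fixed_spectra, ref_params):
        fit = independent_fit(diff_dataset, fixed_spectra["a_10MeV"],
                              n_random_starts=4, seed=0)
        tp = ref_params.tracks["a_10MeV"]
        assert fit.estimates["n[a_10MeV]"] == pytest.approx(tp.n_track, rel=1e-4)
        assert fit.estimates["p[a_10MeV]"] == pytest.approx(
            tp.p_persistent, rel=1e-3
        )
        assert fit.estimates["beta1"] == pytest.approx(0.27, rel=1e-3)

    def test_difference_dataset_propagates_sd(self):
        irr = FociDataset("q", [0.5, 2], [2.0, 1.5], [0.3, 0.4])
        sham = FociDataset("sham", [0.5, 2], [0.5, 0.4], [0.4, 0.3])
        diff = difference_dataset(irr, sham)
        assert np.allclose(diff.mean, [1.5, 1.1])
        assert np.allclose(diff.sd, [0.5, 0.5])  # root-sum-square


class TestStandardErrors:
    def test_weighted_linear_model_closed_form(self):
        # textbook oracle: weighted least squares of y = a + b x has
        # covariance (X^T W X)^{-1}; compare our helper on the same Jacobian
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        sd = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        X = np.column_stack([np.ones_like(x), x])
        W = np.diag(1 / sd**2)
        closed = np.linalg.inv(X.T @ W @ X)
        jac = -X / sd[:, None]  # d residual / d params for r = (y - a - bx)/sd
        cov_u, cov_s, deficient = covariance_from_jacobian(jac, chi2=3.0, dof=3)
        assert not deficient
        assert np.allclose(cov_u, closed, atol=1e-10)
        assert np.allclose(cov_s, closed * 1.0, atol=1e-10)

    def test_rank_deficient_jacobian_flagged(self):
        jac = np.column_stack([np.ones(5), np.ones(5)])  # duplicated parameter
        _, _, deficient = covariance_from_jacobian(jac, chi2=1.0, dof=3)
        assert deficient

    def test_parameter_at_bound_flagged(self, fixed_spectra):
        params = reference_params()
        from dataclasses import replace

        truth = replace(params, beta2=0.0)
        datasets = closed_form_datasets(truth, fixed_spectra)
        fit = simultaneous_fit(datasets, fixed_spectra, n_random_starts=2, seed=0)
        assert fit.at_bound["beta2"]
        assert any("beta2" in m and "bound" in m for m in fit.messages)

    def test_scaled_and_unscaled_exposed(self, fixed_spectra,
                                         noise_free_datasets, rng):
        datasets = [
            FociDataset(d.quality, d.t, d.mean + rng.normal(0, 0.1, len(d)),
                        d.sd, d.n_replicates)
            for d in noise_free_datasets
        ]
        fit = simultaneous_fit(datasets, fixed_spectra, n_random_starts=2, seed=0)
        scale = np.sqrt(fit.chi2_per_dof)
        for name in fit.free_names:
            se_s = standard_errors(fit, scaled=True)[name]
            se_u = standard_errors(fit, scaled=False)[name]
            assert se_s == pytest.approx(se_u * scale, rel=1e-9)
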