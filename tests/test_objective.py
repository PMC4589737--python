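"""Weighted objective F, dispersion estimation, information criteria, GOF."""

import numpy as np
import pytest
from scipy import optimize, stats

from multihill import (
    DoseResponseDataset,
    HillPhase,
    MultiphasicModel,
    compute_sigma,
    goodness_of_fit,
    information_criteria,
    objective_f,
)
from multihill.objective import fit_statistics

from conftest import random_dataset, random_model


def flat_dataset(rows, conc=None):
    rows = np.asarray(rows, dtype=float)
    if conc is None:
        conc = np.arange(1.0, rows.shape[0] + 1)
    return DoseResponseDataset(concentrations=conc, effects=rows)


class TestComputeSigma:
    def test_sample_sd_per_concentration(self):
        # homoscedastic rows: moderation toward the pooled variance is
        # exactly neutral and the sample sd comes straight through
        ds = flat_dataset([[0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        sigma, unit_rec = compute_sigma(ds)
        assert sigma == pytest.approx([0.1, 0.1], abs=1e-12)
        assert not unit_rec

    def test_heteroscedastic_rows_shrink_toward_pooled(self):
        ds = flat_dataset([[0.5, 0.52], [0.1, 0.5]])
        sigma, _ = compute_sigma(ds)
        raw = np.array([np.std([0.5, 0.52], ddof=1), np.std([0.1, 0.5], ddof=1)])
        assert sigma[0] > raw[0] and sigma[1] < raw[1]  # pulled together
        assert sigma[0] < sigma[1]  # ordering preserved

    def test_single_replicate_everywhere_recommends_unit_weights(self):
        ds = flat_dataset(np.array([[0.9], [0.5], [0.1]]))
        sigma, unit_rec = compute_sigma(ds)
        assert unit_rec
        assert np.all(sigma == 1.0)

    def test_degenerate_zero_spread_row_gets_pooled_value(self):
        ds = flat_dataset([[0.5, 0.5], [0.4, 0.6], [0.1, 0.3]])
        sigma, _ = compute_sigma(ds)
        assert np.all(sigma > 0)
        assert sigma[0] > 0.01  # not the zero sample sd of (0.5, 0.5)

    def test_all_missing_row_rejected(self):
        with pytest.raises(ValueError):
            flat_dataset([[0.5, 0.5], [np.nan, np.nan]])


class TestObjectiveF:
    def test_perfect_interpolation_gives_zero(self, mono_model):
        conc = np.logspace(-2, 2, 7)
        truth = mono_model(conc)
        ds = DoseResponseDataset(conc, np.tile(truth[:, None], (1, 3)))
        assert objective_f(mono_model, ds, "unit") == 0.0

    def test_hand_summed_unit_weights(self):
        # residuals (0.1, -0.2) at two single-replicate concentrations
        model = MultiphasicModel([HillPhase(1.0, 1.0, 1.0)])  # identity: flat at 1
        ds = DoseResponseDataset(
            np.array([1.0, 2.0]), np.array([[1.1], [0.8]]), sigma=np.array([0.1, 0.1])
        )
        assert objective_f(model, ds, "unit") == pytest.approx(0.05, rel=1e-9)
        assert objective_f(model, ds, "sd") == pytest.approx(5.0, rel=1e-9)

    def test_row_and_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        conc = np.logspace(-2, 2, 6)
        effects = rng.uniform(0, 1.2, size=(6, 4))
        sigma = rng.uniform(0.05, 0.2, size=6)
        base = objective_f(model, DoseResponseDataset(conc, effects, sigma=sigma), "sd")
        cols = rng.permutation(4)
        shuffled = objective_f(
            model, DoseResponseDataset(conc, effects[:, cols], sigma=sigma), "sd"
        )
        assert shuffled == pytest.approx(base, rel=1e-12)

    def test_unit_sigma_equals_unit_weighting(self):
        rng = np.random.default_rng(4)
        model = random_model(rng)
        ds = random_dataset(rng)
        ds.sigma = np.ones(ds.n_concentrations)
        assert objective_f(model, ds, "sd") == pytest.approx(
            objective_f(model, ds, "unit"), rel=1e-12
        )

    def test_identity_phase_leaves_f_unchanged(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng)
        model = random_model(rng)
        extended = MultiphasicModel(
            list(model.phases) + [HillPhase(1e4, 1.0, 1.0)], model.baseline_scale
        )
        assert objective_f(extended, ds, "unit") == pytest.approx(
            objective_f(model, ds, "unit"), rel=1e-12
        )

    def test_missing_cells_are_skipped(self):
        model = MultiphasicModel([HillPhase(1.0, 1.0, 0.0)])
        conc = np.array([0.5, 1.0, 2.0])
        full = np.tile(model(conc)[:, None], (1, 2))
        with_nan = full.copy()
        with_nan[1, 1] = np.nan
        f = objective_f(model, DoseResponseDataset(conc, with_nan), "unit")
        assert f == 0.0

    def test_minimizing_f_recovers_weighted_mean(self):
        # for a flat model (free baseline only), the MLE under Gaussian
        # noise with known sigma is the inverse-variance weighted mean
        conc = np.array([1.0, 10.0, 100.0])
        effects = np.array([[0.9], [1.1], [0.7]])
        sigma = np.array([0.1, 0.2, 0.05])
        ds = DoseResponseDataset(conc, effects, sigma=sigma)

        def f_of_baseline(b):
            m = MultiphasicModel([HillPhase(1.0, 1.0, 1.0)], baseline_scale=b)
            return objective_f(m, ds, "sd")

        res = optimize.minimize_scalar(f_of_baseline, bounds=(0.5, 1.5), method="bounded")
        w = 1.0 / sigma**2
        analytic = float(np.sum(w * effects[:, 0]) / np.sum(w))
        assert res.x == pytest.approx(analytic, rel=1e-5)


class TestInformationCriteria:
    def test_closed_forms(self):
        aic, bic = information_criteria(10.0, 20, 4)
        assert aic == pytest.approx(18.0)
        assert bic == pytest.approx(10.0 + 4 * np.log(20))

    def test_ln_e_identity(self):
        aic, bic = information_criteria(0.0, int(round(np.e)), 1)
        # N=3 is the integer closest to e; check the algebraic identity instead
        assert bic - aic == pytest.approx(1 * (np.log(3) - 2))

    def test_bic_aic_gap_is_k_lnN_minus_2(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            f = float(rng.uniform(0, 100))
            n = int(rng.integers(5, 500))
            k = int(rng.integers(1, 10))
            aic, bic = information_criteria(f, n, k)
            assert bic - aic == pytest.approx(k * (np.log(n) - 2), rel=1e-12)


class TestGoodnessOfFit:
    def test_perfect_fit_p_is_one(self):
        assert goodness_of_fit(0.0, 20, 3, "sd") == pytest.approx(1.0)

    @pytest.mark.parametrize("dof", [10, 20, 40])
    def test_f_equal_dof_moderate_p(self, dof):
        p = goodness_of_fit(float(dof), dof + 3, 3, "sd")
        assert p == pytest.approx(stats.chi2.sf(dof, dof), rel=1e-12)
        assert 0.40 < p < 0.50

    def test_unit_weighting_has_no_gof(self):
        assert goodness_of_fit(5.0, 20, 3, "unit") is None

    def test_no_degrees_of_freedom_warns(self):
        with pytest.warns(UserWarning):
            assert goodness_of_fit(1.0, 3, 3, "sd") is None

    def test_fit_statistics_bundle(self):
        st_ = fit_statistics(12.0, 30, 6, "sd")
        assert st_.aic == pytest.approx(24.0)
        assert st_.bic == pytest.approx(12.0 + 6 * np.log(30))
        assert st_.gof_p == pytest.approx(stats.chi2.sf(12.0, 24), rel=1e-12)
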