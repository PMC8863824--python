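"""Posterior over chemical identity with concentration marginalised."""

import numpy as np
import pytest

import desiram as ds
from desiram.template import N_INDICES

from conftest import make_linear_models


def vector_from(models, chemical, x):
    """Noiseless observation on one chemical's curves at concentration x."""
    y = np.array([
        models.function(chemical, i).predict(x) for i in range(1, N_INDICES + 1)
    ])
    y = np.clip(y, 0.0, None)
    y[10] = np.clip(y[10], 0, 1)
    y[11] = np.clip(y[11], 0, 1)
    y[12] = np.clip(y[12], 0, 1)
    return ds.CharacteristicVector(y=y)


class TestPosterior:
    def test_identical_models_give_uniform_posterior(self):
        models = make_linear_models({"A": (10.0, 5.0), "B": (10.0, 5.0)})
        res = ds.posterior(vector_from(models, "A", 1.0), models)
        np.testing.assert_allclose(res.probabilities, [0.5, 0.5], atol=1e-12)
        assert res.tie
        assert res.decision == "A"  # tie broken toward the first model label

    def test_dominant_chemical_wins_decisively(self):
        # B's predictions are >= 20 sigma away from the observation everywhere
        # on the grid, so chemical A takes essentially all the mass.
        models = make_linear_models({"A": (10.0, 1.0), "B": (200.0, 1.0)}, sigma=1.0)
        res = ds.posterior(vector_from(models, "A", 1.0), models)
        assert res.probability("A") > 0.999
        assert res.decision == "A"

    def test_probabilities_normalised_to_machine_precision(self, six_chem_models,
                                                           six_chem_training):
        for rec in six_chem_training.records[::7]:
            res = ds.posterior(rec, six_chem_models)
            assert abs(res.probabilities.sum() - 1.0) <= 1e-12
            assert (res.probabilities >= 0).all()

    def test_quadrature_refinement_converges(self, six_chem_models, six_chem_training):
        # Probabilities from the default grid must match a 20001-point
        # brute-force grid: the independent quadrature oracle.
        for rec in six_chem_training.records[::11]:
            p_default = ds.posterior(rec, six_chem_models).probabilities
            p_fine = ds.posterior(rec, six_chem_models,
                                  ds.ClassifierConfig(grid_points=20001)).probabilities
            np.testing.assert_allclose(p_default, p_fine, atol=1e-6)

    def test_halving_grid_spacing_changes_probabilities_negligibly(
            self, six_chem_models, six_chem_training):
        rec = six_chem_training.records[0]
        n = ds.ClassifierConfig().grid_points
        p1 = ds.posterior(rec, six_chem_models).probabilities
        p2 = ds.posterior(rec, six_chem_models,
                          ds.ClassifierConfig(grid_points=2 * n - 1)).probabilities
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_label_order_equivariance(self, six_chem_training):
        models = ds.fit_model_functions(six_chem_training)
        rev_training = ds.TrainingSet(records=six_chem_training.records,
                                      chemicals=list(reversed(six_chem_training.chemicals)))
        rev_models = ds.fit_model_functions(rev_training)
        rec = six_chem_training.records[3]
        p_fwd = ds.posterior(rec, models)
        p_rev = ds.posterior(rec, rev_models)
        np.testing.assert_allclose(p_fwd.probabilities, p_rev.probabilities[::-1],
                                   atol=1e-12)

    def test_uninformative_indices_barely_move_posterior(self):
        # Indices whose model functions are identical across chemicals carry
        # no discriminative information; adding them must not move the
        # posterior beyond quadrature noise.
        rng = np.random.default_rng(2)
        specs = {"A": (10.0, 4.0), "B": (14.0, -3.0)}
        models = make_linear_models(specs, sigma=1.0)
        # Overwrite indices 6..15 with one shared flat model for both chemicals.
        for s in specs:
            for i in range(6, N_INDICES + 1):
                models.functions[(s, i)] = ds.ModelFunction(
                    chemical=s, index=i, coef=np.array([0.5, 0.0]),
                    sigma=2.0, x_lo=0.1, x_hi=10.0,
                )
        y = vector_from(models, "A", 2.0).y.copy()
        y[5:] = 0.5 + rng.normal(0, 2.0, 10)
        y[10:13] = np.clip(y[10:13], 0, 1)
        y[[0, 3, 6, 9, 13]] = np.abs(y[[0, 3, 6, 9, 13]])
        vec = ds.CharacteristicVector(y=y)
        p_active = ds.posterior(vec, models,
                                ds.ClassifierConfig(active_indices=tuple(range(1, 6)))
                                ).probabilities
        p_all = ds.posterior(vec, models).probabilities
        np.testing.assert_allclose(p_active, p_all, atol=1e-5)

    def test_empty_active_set_rejected(self):
        with pytest.raises(ds.BadConfigError):
            ds.ClassifierConfig(active_indices=())

    def test_nonfinite_vector_rejected(self):
        models = make_linear_models({"A": (1.0, 0.0), "B": (2.0, 0.0)})
        y = np.full(N_INDICES, 0.1)
        vec = ds.CharacteristicVector(y=y)
        vec.y[0] = np.nan
        with pytest.raises(ds.InvalidDataError):
            ds.posterior(vec, models)


class TestClassify:
    def test_loo_on_separable_synthetic_pair(self, two_chem_training):
        report = ds.loo_accuracy(two_chem_training)
        assert report.accuracy >= 0.9

    def test_classify_returns_argmax_label(self):
        models = make_linear_models({"A": (10.0, 1.0), "B": (200.0, 1.0)})
        assert ds.classify(vector_from(models, "B", 1.0), models) == "B"


class TestEstimateConcentration:
    def test_forward_model_inversion(self):
        # Coefficients kept small so every index (including the [0,1]-bounded
        # levels) lies exactly on the model curve.
        models = make_linear_models({"A": (0.5, 0.04), "B": (0.3, -0.02)},
                                    x_lo=0.1, x_hi=10.0, sigma=0.02)
        vec = vector_from(models, "A", 1.0)
        est = ds.estimate_concentration(vec, models, "A")
        # Within one grid step of the true concentration (in log10 units).
        step = 3.0 / (ds.ClassifierConfig().grid_points - 1)  # u span is 3.0
        assert abs(np.log10(est) - np.log10(1.0)) <= step + 1e-12

    def test_flat_models_non_identifiable_but_total(self):
        models = make_linear_models({"A": (5.0, 0.0), "B": (9.0, 0.0)})
        vec = vector_from(models, "A", 1.0)
        est = ds.estimate_concentration(vec, models, "A")
        assert np.isfinite(est) and est > 0

    def test_far_vector_still_returns_map_with_low_evidence(self):
        models = make_linear_models({"A": (0.0, 0.0), "B": (0.1, 0.0)}, sigma=0.01)
        y = np.full(N_INDICES, 50.0)
        y[10:13] = 0.5
        vec = ds.CharacteristicVector(y=y)
        res = ds.posterior(vec, models)
        assert np.isfinite(res.probabilities).all()
        assert all(np.isfinite(v) and v > 0 for v in res.map_concentration.values())

    def test_unknown_chemical_rejected(self):
        models = make_linear_models({"A": (1.0, 0.0), "B": (2.0, 0.0)})
        with pytest.raises(ds.BadConfigError):
            ds.estimate_concentration(vector_from(models, "A", 1.0), models, "Z")
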