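"""SVM engine: training-set assembly, scaling, grids, parameter selection,
scoring and serialisation."""

import numpy as np
import pandas as pd
import pytest

import driversvm as dv
from driversvm.errors import InputError
from driversvm.model import KERNELS, _feature_matrix


def _entry(sample, gene, **overrides):
    row = {c: 0 for c in dv.ALL_FEATURES}
    row.update({"sample": sample, "gene": gene, "copy_number": 2.0})
    row.update(overrides)
    return row


@pytest.fixture()
def annotation():
    return dv.GeneAnnotation(
        canonical_roles={"EGFR": "OG", "PTEN": "TSG", "TP53": "both", "NOROLE": None},
        candidates={"CAND1"},
        false_positives={"FP1"},
    )


class TestAssembleTrainingSet:
    def test_gain_loss_of_function_filter(self, annotation):
        feats = pd.DataFrame(
            [
                _entry("S1", "EGFR", n_truncating=1),           # OG with LoF only: out
                _entry("S1", "PTEN", n_truncating=1),           # TSG with LoF: in
                _entry("S2", "EGFR", is_amplified=True),        # OG amplified: in
                _entry("S2", "PTEN", n_nontrunc_damaging=2),    # TSG with GoF only: out
                _entry("S2", "TP53", n_nontrunc_damaging=1),    # dual role, any damage: in
                _entry("S3", "TP53", n_truncating=1),           # dual role, any damage: in
                _entry("S3", "NOROLE", n_truncating=3),         # canonical without role: out
                _entry("S3", "CAND1", n_truncating=3),          # not canonical: out
            ]
        )
        training = dv.assemble_training_set(feats, annotation)
        kept = set(zip(training["sample"], training["gene"]))
        assert kept == {("S1", "PTEN"), ("S2", "EGFR"), ("S2", "TP53"), ("S3", "TP53")}

    def test_hotspot_counts_as_gain_of_function(self, annotation):
        feats = pd.DataFrame([_entry("S1", "EGFR", n_hotspot=1)])
        assert len(dv.assemble_training_set(feats, annotation)) == 1

    def test_empty_training_set_rejected(self, annotation):
        feats = pd.DataFrame([_entry("S1", "REST1", n_truncating=1)])
        with pytest.raises(InputError, match="training set"):
            dv.assemble_training_set(feats, annotation)


class TestScaleFeatures:
    def test_unit_sd_no_centering(self):
        train = pd.DataFrame([_entry("S1", "A", mutational_load=2),
                              _entry("S2", "A", mutational_load=4),
                              _entry("S3", "A", mutational_load=6)])
        with pytest.warns(UserWarning):
            scaled, _, divisors = dv.scale_features(train)
        assert divisors["mutational_load"] == pytest.approx(2.0)  # sample SD of [2,4,6]
        assert list(scaled["mutational_load"]) == pytest.approx([1.0, 2.0, 3.0])

    def test_constant_column_unchanged_with_warning(self):
        train = pd.DataFrame([_entry("S1", "A"), _entry("S2", "B")])
        with pytest.warns(UserWarning, match="constant"):
            scaled, _, divisors = dv.scale_features(train)
        assert divisors["n_hotspot"] == 1.0
        assert (scaled["n_hotspot"] == 0).all()

    def test_divisors_reused_for_prediction(self):
        train = pd.DataFrame([_entry("S1", "A", mutational_load=2),
                              _entry("S2", "A", mutational_load=4),
                              _entry("S3", "A", mutational_load=6)])
        pred = pd.DataFrame([_entry("S4", "B", mutational_load=10)])
        with pytest.warns(UserWarning):
            _, scaled_pred, divisors = dv.scale_features(train, pred)
        assert scaled_pred["mutational_load"].iloc[0] == pytest.approx(10 / divisors["mutational_load"])

    def test_non_finite_rejected(self):
        train = pd.DataFrame([_entry("S1", "A", ppin_betweenness=np.inf), _entry("S2", "B")])
        with pytest.raises(InputError, match="non-finite"):
            dv.scale_features(train)


class TestParameterGrid:
    def test_linear_uses_nu_only(self):
        grid = dv.build_parameter_grid()
        assert len(grid["linear"]) == 4
        assert all(c.gamma is None and c.degree is None for c in grid["linear"])

    def test_every_kernel_has_configs(self):
        grid = dv.build_parameter_grid()
        for kernel in KERNELS:
            assert len(grid[kernel]) >= 4

    def test_deterministic_ordering(self):
        a, b = dv.build_parameter_grid(), dv.build_parameter_grid()
        assert a == b

    def test_reduced_grid_small(self):
        grid = dv.reduced_grid()
        for kernel in KERNELS:
            assert 1 <= len(grid[kernel]) <= 24

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            dv.build_parameter_grid(nu_values=())


class TestCvSensitivity:
    def test_compact_cluster_mostly_in_class(self):
        # held-out points from the training distribution land in-class at a
        # rate near 1 - nu (edge effects cost a little more)
        rng = np.random.default_rng(0)
        X = rng.normal(loc=5.0, scale=1.0, size=(60, 4))
        cfg = dv.KernelConfig("radial", nu=0.05, gamma=0.1)
        sens = dv.cv_sensitivity(cfg, X, seed=1)
        assert sens > 0.7

    def test_bounded_and_deterministic(self, small_features, small_cohort, tiny_grid):
        training = dv.assemble_training_set(small_features, small_cohort.annotation)
        scaled, _, _ = dv.scale_features(training)
        X = _feature_matrix(scaled)
        cfg = tiny_grid["radial"][0]
        a = dv.cv_sensitivity(cfg, X, seed=7)
        b = dv.cv_sensitivity(cfg, X, seed=7)
        assert a == b and 0.0 <= a <= 1.0

    def test_too_few_entries_rejected(self):
        with pytest.raises(InputError):
            dv.cv_sensitivity(dv.KernelConfig("linear", nu=0.1), np.zeros((2, 3)), folds=3)


@pytest.fixture(scope="module")
def scaled_training(small_features, small_cohort):
    training = dv.assemble_training_set(small_features, small_cohort.annotation)
    with pytest.warns(UserWarning):
        scaled, _, _ = dv.scale_features(training)
    return scaled


class TestSelectParameters:
    def test_single_config_converges_at_window(self, scaled_training):
        grid = [dv.KernelConfig("linear", nu=0.1)]
        result = dv.select_parameters("linear", grid, scaled_training, max_iterations=50, window=5, seed=3)
        assert result.config == grid[0]
        assert result.converged and result.iterations == 5

    def test_same_seed_same_selection(self, scaled_training, tiny_grid):
        grid = tiny_grid["radial"]
        a = dv.select_parameters("radial", grid, scaled_training, max_iterations=20, window=5, seed=11)
        b = dv.select_parameters("radial", grid, scaled_training, max_iterations=20, window=5, seed=11)
        assert a == b

    def test_unconverged_flagged(self, scaled_training, tiny_grid):
        grid = tiny_grid["radial"]
        result = dv.select_parameters("radial", grid, scaled_training, max_iterations=3, window=100, seed=1)
        assert not result.converged and result.iterations == 3

    def test_empty_grid_rejected(self, scaled_training):
        with pytest.raises(InputError):
            dv.select_parameters("linear", [], scaled_training)


class TestTrainedModel:
    def test_weights_normalised(self, small_model):
        assert sum(small_model.weights.values()) == pytest.approx(1.0)

    def test_weights_equal_converged_sensitivities(self, small_model):
        total = sum(small_model.sensitivities.values())
        for k in KERNELS:
            assert small_model.weights[k] == pytest.approx(small_model.sensitivities[k] / total)

    def test_training_roster_excludes_unroled_canonicals(self, small_model, small_cohort):
        unroled = {g for g in small_cohort.annotation.canonical if small_cohort.annotation.role(g) is None}
        roster_genes = {g for _, g in small_model.training_roster}
        assert not (roster_genes & unroled)

    def test_save_load_roundtrip_scores(self, small_model, small_features, tmp_path):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        assert (tmp_path / "model.joblib.json").exists()
        reloaded = dv.TrainedModel.load(path)
        a = dv.score_predictions(small_model, small_features)
        b = dv.score_predictions(reloaded, small_features)
        pd.testing.assert_frame_equal(a, b)


class TestScorePredictions:
    def test_ranks_are_permutation(self, small_predictions):
        for _, grp in small_predictions.groupby("sample"):
            assert sorted(grp["rank"]) == list(range(1, len(grp) + 1))

    def test_training_entries_excluded(self, small_model, small_predictions):
        roster = set(small_model.training_roster)
        pairs = set(zip(small_predictions["sample"], small_predictions["gene"]))
        assert not (pairs & roster)

    def test_equal_sensitivities_give_mean_of_z(self, small_model, small_features):
        import copy

        model = copy.deepcopy(small_model)
        model.sensitivities = {k: 0.5 for k in KERNELS}
        preds = dv.score_predictions(model, small_features)
        zcols = [f"z_{k}" for k in KERNELS]
        expected = preds[zcols].mean(axis=1)
        assert np.allclose(preds["combined_score"], expected)

    def test_zero_sensitivity_kernel_contributes_nothing(self, small_model, small_features):
        import copy

        base = copy.deepcopy(small_model)
        base.sensitivities = {"linear": 0.6, "radial": 0.3, "sigmoid": 0.0, "polynomial": 0.1}
        preds = dv.score_predictions(base, small_features)
        manual = sum(
            base.weights[k] * preds[f"z_{k}"] for k in KERNELS if base.sensitivities[k] > 0
        )
        assert np.allclose(preds["combined_score"], manual)

    def test_all_zero_sensitivities_rejected(self, small_model, small_features):
        import copy

        model = copy.deepcopy(small_model)
        model.sensitivities = {k: 0.0 for k in KERNELS}
        with pytest.raises(InputError, match="untrained"):
            dv.score_predictions(model, small_features)

    def test_combined_score_invariant_to_affine_rescaling(self, small_model, small_features):
        """Standardisation absorbs an affine transform of one kernel's raw scores."""
        import copy

        base = dv.score_predictions(small_model, small_features)

        class Affine:
            def __init__(self, inner):
                self.inner = inner

            def decision_function(self, X):
                return 3.5 * self.inner.decision_function(X) + 7.0

        model = copy.deepcopy(small_model)
        model.estimators["radial"] = Affine(model.estimators["radial"])
        rescaled = dv.score_predictions(model, small_features)
        assert np.allclose(base["combined_score"], rescaled["combined_score"])
        assert (base["rank"] == rescaled["rank"]).all()
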