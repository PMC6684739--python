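"""Metrics, LOOCV harness contracts, subgroups, paired-bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest

from lesion2score import mae, r_squared
from lesion2score.evaluation import (
    EvalResult,
    RidgeSpec,
    compare_models,
    loocv,
    subgroup_eval,
)
from lesion2score.exceptions import (
    ConfigurationError,
    DegeneracyError,
    ValidationError,
)


def make_result(ids, actual, predicted, label="m"):
    return EvalResult(
        predictions=pd.DataFrame(
            {"patient_id": ids, "actual": actual, "predicted": predicted}
        ),
        model_label=label,
    )


class TestMetrics:
    def test_r_squared_identities(self):
        y = np.array([0.3, -1.2, 2.0, 0.7])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, -y) == pytest.approx(1.0)  # sign-blind

    def test_r_squared_hand_computed_example(self):
        assert r_squared([0, 1, 2], [0, 0, 2]) == pytest.approx(0.75)

    def test_r_squared_constant_vector_convention(self):
        assert r_squared([1, 2, 3], [5, 5, 5]) == 0.0

    def test_r_squared_shape_mismatch(self):
        with pytest.raises(ValidationError):
            r_squared([1, 2, 3], [1, 2])

    def test_mae_examples(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([0.0, 1.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_mae_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, p = rng.normal(size=10), rng.normal(size=10)
        assert mae(a, p) == pytest.approx(mae(a + 3.7, p + 3.7))


class TestLOOCV:
    def test_one_prediction_per_patient_excluding_self(self, small_cohort):
        """With noise-free targets that a left-out patient cannot influence,
        LOOCV yields n pooled predictions; determinism on rerun."""
        images, manifest = small_cohort
        res = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)), master_seed=0)
        r = res["pca+rr"]
        assert r.n == len(images)
        assert r.predictions["patient_id"].tolist() == manifest.patient_ids
        res2 = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)), master_seed=0)
        assert np.allclose(r.predicted, res2["pca+rr"].predicted)

    def test_held_out_patient_does_not_influence_its_fold(self, small_cohort):
        """Perturbing patient i's score must not change the prediction for i
        (it only enters as the evaluation target)."""
        images, manifest = small_cohort
        res_a = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)))
        records = manifest.records.copy()
        records.loc[0, "score"] += 100.0
        from lesion2score.imaging import CohortManifest

        res_b = loocv(images, CohortManifest(records), RidgeSpec(lambda_grid=(10,)))
        assert res_b["pca+rr"].predicted[0] == pytest.approx(
            res_a["pca+rr"].predicted[0], abs=1e-9
        )
        assert res_b["pca+rr"].predicted[1] != pytest.approx(
            res_a["pca+rr"].predicted[1], abs=1e-9
        )

    def test_pca_scope_whole_dataset_mode_runs(self, small_cohort):
        images, manifest = small_cohort
        res = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)),
                    pca_scope="whole-dataset")
        assert res["pca+rr"].n == len(images)

    def test_small_leakage_guard(self, medium_cohort):
        """Permuted scores should carry no signal through the per-fold PCA
        pipeline: mean r^2 over a few permutation seeds stays near 0 (pooled
        LOOCV r^2 is noisy at small n, hence n=40 and a loose bound here; the
        full-scale check runs at n=200)."""
        images, manifest = medium_cohort
        from lesion2score.imaging import CohortManifest

        r2s = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            records = manifest.records.copy()
            records["score"] = rng.permutation(records["score"].to_numpy())
            res = loocv(images, CohortManifest(records), RidgeSpec(), master_seed=seed)
            r2s.append(res["pca+rr"].r_squared)
        assert np.mean(r2s) < 0.15

    def test_too_few_patients_rejected(self, small_cohort):
        images, manifest = small_cohort
        with pytest.raises(ValidationError):
            loocv(images[:2], manifest.subset(np.arange(2)), RidgeSpec())

    def test_unknown_score_column_rejected(self, small_cohort):
        images, manifest = small_cohort
        with pytest.raises(ConfigurationError):
            loocv(images, manifest, RidgeSpec(), score_column="chronic")

    def test_degenerate_constant_predictor_flagged(self):
        r = make_result(list("abcd"), [1.0, 2.0, 3.0, 4.0], [2.0] * 4)
        assert r.degenerate
        assert r.r_squared == 0.0
        assert r.mae == pytest.approx(np.mean([1, 0, 1, 2]))


class TestSubgroups:
    def test_identity_filter_preserves_metrics(self, small_cohort):
        images, manifest = small_cohort
        res = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)))["pca+rr"]
        left = subgroup_eval(res, manifest, "left_hemisphere")
        keep = manifest.hemispheres == "L"
        assert left.n == int(keep.sum())
        assert left.r_squared == pytest.approx(
            r_squared(res.actual[keep], res.predicted[keep])
        )

    def test_deficit_dichotomy_partitions_cohort(self, small_cohort):
        images, manifest = small_cohort
        res = loocv(images, manifest, RidgeSpec(lambda_grid=(10,)))["pca+rr"]
        deficit = subgroup_eval(res, manifest, "deficit_only")
        intact = subgroup_eval(res, manifest, "no_deficit")
        assert deficit.n + intact.n == res.n
        assert (deficit.actual < 0).all()
        assert (intact.actual >= 0).all()

    def test_perfect_for_deficit_noise_elsewhere(self):
        rng = np.random.default_rng(1)
        actual = np.concatenate([-rng.uniform(1, 5, 10), rng.uniform(0, 3, 10)])
        predicted = actual.copy()
        predicted[10:] = rng.normal(size=10)  # pure noise for the intact half
        ids = [f"p{i}" for i in range(20)]
        manifest_df = pd.DataFrame(
            {"patient_id": ids, "score": actual, "hemisphere": "L",
             "score_followup": np.nan}
        )
        from lesion2score.imaging import CohortManifest

        res = make_result(ids, actual, predicted)
        deficit = subgroup_eval(res, CohortManifest(manifest_df), "deficit_only")
        intact = subgroup_eval(res, CohortManifest(manifest_df), "no_deficit")
        assert deficit.r_squared == pytest.approx(1.0)
        assert intact.r_squared < 0.4

    def test_small_subgroup_rejected(self):
        ids = list("abc")
        res = make_result(ids, [-1.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        df = pd.DataFrame({"patient_id": ids, "score": [-1.0, 1, 2],
                           "hemisphere": ["L", "R", "R"], "score_followup": np.nan})
        from lesion2score.imaging import CohortManifest

        with pytest.raises(DegeneracyError):
            subgroup_eval(res, CohortManifest(df), "left_hemisphere")


class TestCompareModels:
    def test_identical_results_give_zero_delta_p_one(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(30)]
        a = rng.normal(size=30)
        pred = a + rng.normal(size=30) * 0.5
        r1 = make_result(ids, a, pred, "m1")
        r2 = make_result(ids, a, pred, "m2")
        delta, p = compare_models(r1, r2, n_boot=500, seed=1)
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        ids = [f"p{i}" for i in range(25)]
        a = rng.normal(size=25)
        r1 = make_result(ids, a, a + 0.1 * rng.normal(size=25), "m1")
        r2 = make_result(ids, a, rng.normal(size=25), "m2")
        out1 = compare_models(r1, r2, n_boot=1000, seed=7)
        out2 = compare_models(r1, r2, n_boot=1000, seed=7)
        assert out1 == out2

    def test_perfect_vs_noise_is_significant(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(100)]
        a = rng.normal(size=100)
        r1 = make_result(ids, a, a.copy(), "perfect")
        r2 = make_result(ids, a, rng.normal(size=100), "noise")
        delta, p = compare_models(r1, r2, n_boot=2000, seed=11)
        assert delta > 0.8
        assert p < 0.01

    def test_different_patient_sets_rejected(self):
        r1 = make_result(list("abc"), [1.0, 2, 3], [1.0, 2, 3])
        r2 = make_result(list("abd"), [1.0, 2, 3], [1.0, 2, 3])
        with pytest.raises(ValidationError):
            compare_models(r1, r2)
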