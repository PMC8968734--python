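import numpy as np
import pytest

from csvmtk import (KernelParams, PhantomSpec, build_feature_stack,
                    csvm_segment, gaussian_kernel, make_brain_phantom,
                    overall_accuracy, predict, sample_training_pixels,
                    train_svm)
from csvmtk.csvm import TrainingSet, gram_matrix
from csvmtk.errors import StratificationError
from csvmtk.phantom import LabeledImage


def toy_training_set(x, y):
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    return TrainingSet(features=(x - mean) / sd, labels=np.asarray(y),
                       mean=mean, sd=sd,
                       indices=np.zeros((len(y), 2), dtype=int))


class TestGaussianKernel:
    def test_zero_distance_gives_one(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], sigma=0.5) == 1.0

    def test_unit_distance_at_paper_sigma(self):
        value = gaussian_kernel([0.0], [1.0], sigma=0.5)
        assert value == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_symmetry_over_random_pairs(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=(2, 6))
            assert gaussian_kernel(a, b, 0.7) == \
                pytest.approx(gaussian_kernel(b, a, 0.7), abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel([1.0, 2.0], [1.0], sigma=0.5)

    def test_gram_matrices_are_psd(self, rng):
        for _ in range(5):
            x = rng.normal(size=(30, 8))
            k = gram_matrix(x, sigma=0.5)
            assert np.allclose(k, k.T)
            assert np.linalg.eigvalsh(k).min() >= -1e-8


class TestSampling:
    def test_stratified_counts_on_default_phantom(self, default_phantom):
        feats = build_feature_stack(default_phantom.intensity)
        mask = default_phantom.labels > 0
        train = sample_training_pixels(default_phantom, mask, feats,
                                       1500, seed=7)
        assert train.n == 1500
        counts = np.bincount(train.labels, minlength=4)
        assert (counts[1:] >= 300).all()

    def test_seeded_sampling_is_deterministic(self, default_phantom):
        feats = build_feature_stack(default_phantom.intensity)
        mask = default_phantom.labels > 0
        a = sample_training_pixels(default_phantom, mask, feats, 400, seed=3)
        b = sample_training_pixels(default_phantom, mask, feats, 400, seed=3)
        assert np.array_equal(a.indices, b.indices)

    def test_zscore_columns_standardized(self, default_phantom):
        feats = build_feature_stack(default_phantom.intensity)
        mask = default_phantom.labels > 0
        train = sample_training_pixels(default_phantom, mask, feats,
                                       600, seed=1)
        assert np.allclose(train.features.mean(axis=0), 0.0, atol=1e-9)
        sd = train.features.std(axis=0)
        assert np.allclose(sd[sd > 0], 1.0, atol=1e-9)

    def test_absent_class_raises_naming_it(self, default_phantom):
        mask = default_phantom.labels == 2  # only grey matter available
        feats = build_feature_stack(default_phantom.intensity)
        with pytest.raises(StratificationError, match="csf|wm"):
            sample_training_pixels(default_phantom, mask, feats, 100, seed=0)


class TestTrainPredict:
    def test_separable_clusters_reach_perfect_training_accuracy(self):
        x = [(0, 0), (0, 1), (5, 5), (5, 6)]
        y = [1, 1, 2, 2]
        model = train_svm(toy_training_set(x, y),
                          KernelParams(sigma=0.5, c=1000.0))
        pred = predict(model, np.asarray(x, dtype=float))
        assert np.array_equal(pred, y)

    def test_xor_layout_fit_exactly_by_gaussian_kernel(self):
        x = [(0, 0), (1, 1), (0, 1), (1, 0)]
        y = [1, 1, 2, 2]
        model = train_svm(toy_training_set(x, y),
                          KernelParams(sigma=0.5, c=1000.0))
        assert np.array_equal(predict(model, np.asarray(x, float)), y)

    def test_dual_coefficients_respect_box_constraint(self):
        x = [(0, 0), (0, 1), (5, 5), (5, 6), (2, 2), (3, 3)]
        y = [1, 1, 2, 2, 3, 3]
        kernel = KernelParams(sigma=0.5, c=10.0)
        model = train_svm(toy_training_set(x, y), kernel)
        assert np.all(np.abs(model.dual_coef) <= kernel.c + 1e-9)

    def test_duplicating_training_points_leaves_predictions_unchanged(self, rng):
        x = rng.normal(size=(40, 2))
        y = (x[:, 0] + x[:, 1] > 0).astype(int) + 1
        model_a = train_svm(toy_training_set(x, y), KernelParams(1.0, 100.0))
        model_b = train_svm(toy_training_set(np.vstack([x, x]),
                                             np.concatenate([y, y])),
                            KernelParams(1.0, 100.0))
        gx, gy = np.meshgrid(np.linspace(-2, 2, 10), np.linspace(-2, 2, 10))
        probe = np.stack([gx.ravel(), gy.ravel()], axis=1)
        assert np.array_equal(predict(model_a, probe), predict(model_b, probe))

    def test_identical_features_collapse_to_one_class(self):
        x = [(0, 0), (0, 1), (5, 5), (5, 6)]
        y = [1, 1, 2, 2]
        model = train_svm(toy_training_set(x, y), KernelParams(0.5, 1000.0))
        pred = predict(model, np.tile([[2.0, 2.0]], (7, 1)))
        assert np.unique(pred).size == 1

    def test_ovo_vote_matches_sklearn_multiclass_prediction(self, rng):
        x = rng.normal(size=(60, 3)) + np.repeat(
            np.array([[0, 0, 0], [4, 4, 0], [0, 4, 4]]), 20, axis=0)
        y = np.repeat([1, 2, 3], 20)
        model = train_svm(toy_training_set(x, y), KernelParams(1.0, 10.0))
        probe = rng.normal(size=(50, 3)) * 3
        z = (probe - model.mean) / model.sd
        assert np.array_equal(predict(model, probe), model.svc.predict(z))


class TestPipeline:
    def test_noiseless_phantom_accuracy(self, noiseless_phantom):
        result = csvm_segment(noiseless_phantom, n_train=1500, seed=7)
        m = overall_accuracy(result.labels, noiseless_phantom.labels,
                             region_mask=noiseless_phantom.labels > 0)
        assert m.overall_accuracy >= 0.99

    def test_default_phantom_benchmark_accuracy(self, benchmark_segmentation):
        assert benchmark_segmentation["metrics"].overall_accuracy >= 0.80

    def test_pixels_outside_contour_labeled_background(
            self, benchmark_segmentation, default_phantom):
        result = benchmark_segmentation["result"]
        outside = ~result.cv_result.inside_mask
        assert not result.labels[outside].any()
        assert not result.provenance[outside].any()

    def test_pipeline_deterministic_at_fixed_seed(self, default_phantom):
        small = make_brain_phantom(PhantomSpec(height=64, width=64, seed=5))
        a = csvm_segment(small, n_train=400, seed=9)
        b = csvm_segment(small, n_train=400, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_accuracy_degrades_monotonically_with_noise(self):
        means = {}
        for noise in (0.0, 0.02, 0.10):
            accs = []
            for rep in range(3):
                spec = PhantomSpec(height=64, width=64,
                                   noise_fraction=noise, seed=100 + rep)
                ph = make_brain_phantom(spec)
                res = csvm_segment(ph, n_train=600, seed=100 + rep)
                m = overall_accuracy(res.labels, ph.labels,
                                     region_mask=ph.labels > 0)
                accs.append(m.overall_accuracy)
            means[noise] = np.mean(accs)
        assert means[0.0] >= means[0.02] >= means[0.10]
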