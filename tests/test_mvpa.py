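"""MVPA preprocessing, decoding, RDMs and representational connectivity."""

import numpy as np
import pytest

import sleepsig as ss
from sleepsig.errors import (DegenerateVoxelError, DesignOverflowError,
                             IncompleteDesignError, InvalidLabelsError,
                             UndefinedCorrelationError)
from sleepsig.mvpa import _stratified_folds, compute_rdm, decode_region
from sleepsig.synthetic import (CATEGORIES, TaskDesign, TaskRegionData,
                                default_task_design)


def _toy_data(fill=100.0, design=None):
    design = design or default_task_design()
    return TaskRegionData(1, 1,
                          np.full((2, design.n_volumes), fill), design)


class TestPreprocess:
    def test_constant_voxel_gives_zero_psc(self):
        run = ss.preprocess_run(_toy_data(100.0))
        assert np.allclose(run.samples, 0.0, atol=1e-10)
        assert len(run.samples) == 60

    def test_sixty_balanced_samples(self):
        run = ss.preprocess_run(_toy_data())
        assert (run.class_labels == "face").sum() == 30
        assert (run.class_labels == "shape").sum() == 30

    def test_linear_trend_removed_exactly(self):
        design = default_task_design()
        t = np.arange(design.n_volumes, dtype=float)
        data = TaskRegionData(1, 1, np.vstack([100 + t, 100 + t]), design)
        run = ss.preprocess_run(data)
        # a pure linear trend detrends to a constant -> PSC identically 0
        assert np.allclose(run.samples, 0.0, atol=1e-10)

    def test_shift_overflow_raises(self):
        with pytest.raises(DesignOverflowError):
            ss.preprocess_run(_toy_data(), shift_volumes=50)

    def test_zero_mean_voxel_raises_naming_voxel(self):
        design = default_task_design()
        x = np.full((3, design.n_volumes), 100.0)
        x[1] = 0.0
        with pytest.raises(DegenerateVoxelError, match="voxel 1"):
            ss.preprocess_run(TaskRegionData(1, 1, x, design))

    def test_shuffle_is_seeded(self):
        d = _toy_data()
        a = ss.preprocess_run(d, seed=1)
        b = ss.preprocess_run(d, seed=1)
        c = ss.preprocess_run(d, seed=2)
        assert np.array_equal(a.category_labels, b.category_labels)
        assert not np.array_equal(a.category_labels, c.category_labels)


class TestDecode:
    def test_fold_sizes_are_ten_with_five_per_class(self):
        y = np.array([-1.0, 1.0] * 30)
        fold = _stratified_folds(y, 6, np.random.default_rng(0))
        for k in range(6):
            assert (fold == k).sum() == 10
            assert (y[fold == k] == 1).sum() == 5

    def test_separable_blobs_decode_perfectly(self, rng):
        X = rng.normal(size=(60, 8))
        labels = np.array(["face", "shape"] * 30)
        X[labels == "face"] += 6.0
        res = decode_region(X, labels, seed=0)
        assert res.accuracy == 1.0
        assert res.n_samples == 60
        assert res.accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_permuted_labels_decode_at_chance(self):
        rng = np.random.default_rng(10)
        accs = []
        X = rng.normal(size=(60, 12))
        for seed in range(200):
            labels = rng.permutation(np.array(["face", "shape"] * 30))
            accs.append(decode_region(X, labels, seed=seed).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)

    def test_accuracy_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(60, 6))
        labels = np.array(["face", "shape"] * 30)
        base = decode_region(X, labels, seed=3).accuracy
        perm = rng.permutation(60)
        assert decode_region(X[perm], labels[perm], seed=3).accuracy == base

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidLabelsError):
            decode_region(rng.normal(size=(10, 3)), np.array(["face"] * 10))

    def test_backends_agree_on_average(self, rng):
        """The dual-CD solver and libsvm agree in mean accuracy (they solve
        the same margin problem up to intercept handling)."""
        diffs = []
        for _ in range(30):
            X = rng.normal(size=(60, 12))
            labels = np.array(["face", "shape"] * 30)
            X[labels == "face"] += rng.normal(size=12) * 0.25
            a = decode_region(X, labels, seed=1, backend="dcd").accuracy
            b = decode_region(X, labels, seed=1, backend="libsvm").accuracy
            diffs.append(a - b)
        assert abs(np.mean(diffs)) < 0.02
        assert np.max(np.abs(diffs)) < 0.15


class TestContrastAndRdm:
    def test_contrast_zero_when_classes_equal(self, rng):
        X = np.ones((20, 4))
        labels = np.array(["face", "shape"] * 10)
        assert ss.univariate_contrast(X, labels) == 0.0

    def test_contrast_unit_offset(self, rng):
        labels = np.array(["face", "shape"] * 10)
        X = np.zeros((20, 4))
        X[labels == "face"] = 1.0
        assert ss.univariate_contrast(X, labels) == pytest.approx(1.0)

    def test_contrast_linear_in_planted_amplitude(self, rng):
        labels = np.array(["face", "shape"] * 10)
        base = rng.normal(size=(20, 6))
        vals = []
        for a in (0.5, 1.0, 1.5):
            X = base.copy()
            X[labels == "face"] += a
            vals.append(ss.univariate_contrast(X, labels))
        assert vals[1] - vals[0] == pytest.approx(0.5, abs=1e-9)
        assert vals[2] - vals[1] == pytest.approx(0.5, abs=1e-9)

    def _samples_with_categories(self, rng, patterns=None):
        labels = np.repeat(CATEGORIES, 3)
        X = rng.normal(size=(len(labels), 10))
        return X, np.array(labels)

    def test_rdm_shape_and_invariants(self, rng):
        X, labels = self._samples_with_categories(rng)
        rdm = compute_rdm(X, labels)
        m = rdm.matrix
        assert m.shape == (7, 7)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert len(rdm.lower_triangle) == 21

    def test_rdm_extreme_entries(self):
        # identical category vectors -> 0; anti-correlated -> 2
        v = np.array([1.0, -1.0, 2.0, 0.0])
        X = []
        labels = []
        for c in CATEGORIES:
            X.append(v if c != "circle" else -v)
            labels.append(c)
        rdm = compute_rdm(np.array(X), np.array(labels))
        assert rdm.matrix[1, 2] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_missing_category_raises_listing_it(self, rng):
        X, labels = self._samples_with_categories(rng)
        keep = labels != "angry_face"
        with pytest.raises(IncompleteDesignError, match="angry_face"):
            compute_rdm(X[keep], labels[keep])

    def test_representational_connectivity_extremes(self, rng):
        X, labels = self._samples_with_categories(rng)
        rdm_a = compute_rdm(X, labels)
        assert ss.representational_connectivity(rdm_a, rdm_a) == \
            pytest.approx(1.0)
        from sleepsig.mvpa import RDM
        flipped = RDM(np.max(rdm_a.matrix) - rdm_a.matrix)
        flipped = RDM(flipped.matrix - np.diag(np.diag(flipped.matrix)))
        assert ss.representational_connectivity(rdm_a, flipped) == \
            pytest.approx(-1.0)

    def test_repconn_matches_direct_formula(self, rng):
        X, labels = self._samples_with_categories(rng)
        Y = rng.normal(size=X.shape)
        rdm_a, rdm_b = compute_rdm(X, labels), compute_rdm(Y, labels)
        want = np.corrcoef(rdm_a.lower_triangle, rdm_b.lower_triangle)[0, 1]
        assert ss.representational_connectivity(rdm_a, rdm_b) == \
            pytest.approx(want, abs=1e-12)

    def test_repconn_matrix_symmetric_unit_diagonal(self, rng):
        tris = rng.normal(size=(9, 21))
        m = ss.representational_connectivity_matrix(tris)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_constant_triangle_rejected(self):
        tris = np.ones((3, 21))
        with pytest.raises(UndefinedCorrelationError):
            ss.representational_connectivity_matrix(tris)
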