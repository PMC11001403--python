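import h5py
import numpy as np
import pytest

from sfxtriage.classify import (ALGORITHMS, ClassifyError, FeatureMatrix,
                                FrameClassifier, SplitSpec, build_features,
                                persist_model, predict, restore_model,
                                split_dataset, train_model)
from sfxtriage.frame_store import FrameRef
from sfxtriage.labels import LabelSet
from sfxtriage.profiling import ROI


def toy_features(n_per_class=10, n_features=6, offset=10.0, seed=0,
                 fingerprint="rect:ss[0:2]fs[0:3]"):
    """Linearly separable two-cluster features at +/- offset."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(+offset, 1.0, size=(n_per_class, n_features)),
                   rng.normal(-offset, 1.0, size=(n_per_class, n_features))])
    refs = tuple(FrameRef("toy.h5", i) for i in range(2 * n_per_class))
    labels = ("good",) * n_per_class + ("bad",) * n_per_class
    return FeatureMatrix(X, refs, fingerprint), labels


class TestBuildFeatures:
    def test_shape_and_bruteforce_oracle(self, tmp_path):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(3, 8, 10))
        path = tmp_path / "f.h5"
        with h5py.File(path, "w") as h5:
            h5.create_dataset("/data/data", data=frames)
        roi = ROI.from_rect(2, 6, 1, 6)
        refs = [FrameRef(str(path), e) for e in range(3)]
        fm = build_features(refs, roi)
        assert fm.X.shape == (3, 20)
        for i in range(3):
            expected = [frames[i, r, c] for r in range(2, 6) for c in range(1, 6)]
            np.testing.assert_allclose(fm.X[i], expected)

    def test_constant_frames(self, tmp_path):
        path = tmp_path / "c.h5"
        with h5py.File(path, "w") as h5:
            h5.create_dataset("/data/data", data=np.full((2, 4, 5), 7.0))
        fm = build_features([FrameRef(str(path), 0), FrameRef(str(path), 1)],
                            ROI.from_rect(0, 4, 0, 5))
        assert (fm.X == 7.0).all()

    def test_unreadable_ref_named(self, tmp_path):
        ref = FrameRef(str(tmp_path / "missing.h5"), 0)
        with pytest.raises(ClassifyError, match="missing.h5"):
            build_features([ref], ROI.from_rect(0, 2, 0, 2))

    def test_roi_outside_frame_rejected(self, tmp_path):
        path = tmp_path / "s.h5"
        with h5py.File(path, "w") as h5:
            h5.create_dataset("/data/data", data=np.zeros((1, 4, 4)))
        with pytest.raises(Exception, match="outside"):
            build_features([FrameRef(str(path), 0)], ROI.from_rect(0, 9, 0, 4))

    def test_whole_file_ref_rejected(self):
        with pytest.raises(ClassifyError, match="whole-file"):
            build_features([FrameRef("a.h5", None)], ROI.from_rect(0, 2, 0, 2))


class TestSplit:
    @staticmethod
    def labelled(n=10):
        return LabelSet({FrameRef("a.h5", i): ("good" if i % 2 else "bad")
                         for i in range(n)})

    def test_70_30_gives_7_3_disjoint_partition(self):
        (tr, _), (te, _) = split_dataset(self.labelled(10), SplitSpec(seed=4))
        assert len(tr) == 7 and len(te) == 3
        assert not set(tr) & set(te)
        assert set(tr) | set(te) == set(self.labelled(10).labels)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ClassifyError, match=r"0\.7.*0\.2"):
            SplitSpec(train_frac=0.7, test_frac=0.2)

    def test_same_seed_reproduces_partition(self):
        a = split_dataset(self.labelled(20), SplitSpec(seed=9))
        b = split_dataset(self.labelled(20), SplitSpec(seed=9))
        assert a == b

    def test_different_seeds_usually_differ(self):
        base = split_dataset(self.labelled(20), SplitSpec(seed=0))
        diff = sum(split_dataset(self.labelled(20), SplitSpec(seed=s)) != base
                   for s in range(1, 101))
        assert diff > 90

    def test_empty_side_rejected(self):
        small = LabelSet({FrameRef("a.h5", 0): "good", FrameRef("a.h5", 1): "bad"})
        with pytest.raises(ClassifyError, match="empty"):
            # floor(0.3 * 2) = 0 training frames
            split_dataset(small, SplitSpec(train_frac=0.3, test_frac=0.7))

    def test_single_class_rejected(self):
        ls = LabelSet({FrameRef("a.h5", i): "good" for i in range(10)})
        with pytest.raises(ClassifyError, match="both classes"):
            split_dataset(ls, SplitSpec())

    def test_stratified_preserves_class_balance(self):
        ls = LabelSet({FrameRef("a.h5", i): ("good" if i < 30 else "bad")
                       for i in range(40)})
        (tr_refs, tr_labs), _ = split_dataset(
            ls, SplitSpec(seed=1, stratify=True))
        assert tr_labs.count("good") == 21 and tr_labs.count("bad") == 7

    def test_skip_labels_excluded(self):
        ls = self.labelled(10)
        ls = LabelSet({**ls.labels, FrameRef("a.h5", 99): "skip"})
        (tr, _), (te, _) = split_dataset(ls, SplitSpec(seed=0))
        assert FrameRef("a.h5", 99) not in set(tr) | set(te)


class TestTrainPredict:
    @pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
    def test_separable_clusters_memorized(self, algorithm):
        fm, labels = toy_features()
        model = train_model(fm, labels, algorithm=algorithm, seed=0)
        assert predict(model, fm) == labels

    def test_single_class_rejected(self):
        fm, _ = toy_features()
        with pytest.raises(ClassifyError, match="both good and bad"):
            train_model(fm, ("good",) * fm.n_frames)

    def test_unknown_algorithm_lists_supported(self):
        fm, labels = toy_features()
        with pytest.raises(ClassifyError, match="dtree.*knn.*logreg.*rforest"):
            train_model(fm, labels, algorithm="svm")

    def test_forest_is_deterministic_under_seed(self):
        fm, labels = toy_features(offset=1.0)
        held, _ = toy_features(seed=99, offset=1.0)
        p1 = train_model(fm, labels, "rforest", seed=7).predict(held)
        p2 = train_model(fm, labels, "rforest", seed=7).predict(held)
        assert p1 == p2

    def test_knn_k1_returns_own_label(self):
        fm, labels = toy_features(offset=1.0)
        model = train_model(fm, labels, "knn",
                            hyperparams={"n_neighbors": 1})
        assert model.predict(fm) == labels

    def test_feature_width_mismatch_cites_both(self):
        fm, labels = toy_features(n_features=6)
        other, _ = toy_features(n_features=8, fingerprint="rect:ss[0:2]fs[0:4]")
        model = train_model(fm, labels)
        with pytest.raises(ClassifyError, match="6.*8|8.*6"):
            model.predict(other)

    def test_standardize_pipeline_trains(self):
        fm, labels = toy_features()
        model = train_model(fm, labels, "logreg", standardize=True)
        assert model.predict(fm) == labels

    def test_results_summary_mentions_provenance(self):
        fm, labels = toy_features()
        model = FrameClassifier(fm, labels, algorithm="knn", seed=3).fit()
        text = model.summary()
        assert "knn" in text and "seed" in text
        assert model.training_class_counts == {"good": 10, "bad": 10}


class TestPersistence:
    def test_round_trip_predicts_identically(self, tmp_path):
        fm, labels = toy_features(offset=1.0)
        model = train_model(fm, labels, "rforest", seed=1)
        path = tmp_path / "model.joblib"
        persist_model(model, path)
        restored = restore_model(path)
        probe, _ = toy_features(seed=50, n_per_class=25, offset=1.0)
        assert restored.predict(probe) == model.predict(probe)
        assert restored.algorithm == "rforest"
        assert restored.roi_fingerprint == model.roi_fingerprint
        assert restored.seed == 1

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "junk.joblib"
        path.write_bytes(b"not a model")
        with pytest.raises(ClassifyError, match="restore"):
            restore_model(path)

    def test_roi_fingerprint_guard_on_predict(self, tmp_path):
        fm, labels = toy_features()
        model = train_model(fm, labels)
        path = tmp_path / "model.joblib"
        model.save(path)
        other, _ = toy_features(fingerprint="panel:p3")
        with pytest.raises(ClassifyError, match="fingerprint"):
            restore_model(path).predict(other)
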