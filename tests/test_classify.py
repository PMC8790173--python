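import numpy as np
import pandas as pd
import pytest

from stimdecode import DegenerateDataError
from stimdecode.classify import (DiffFeatureSet, build_diff_samples,
                                 classify_all, crossval_f1, crossval_f1_batch,
                                 f1_from_counts, fit_lda, pool_diff_features,
                                 stratified_folds, _lw_shrinkage_batch)
from stimdecode.spectral import SpectralFeatures


def _features(data, freqs=(10.0,)):
    return SpectralFeatures(power=data, freqs=np.asarray(freqs),
                            times=np.arange(data.shape[-1]) * 0.05,
                            channel_names=[f"ch{i}" for i in range(data.shape[1])],
                            meta=pd.DataFrame(index=range(data.shape[0])))


class TestDiffSamples:
    def test_identical_constant_epochs_give_zero_differences(self):
        stack = np.ones((10, 2, 1, 8)) * 3.3
        d = build_diff_samples(_features(stack), _features(stack), seed=0)
        assert np.allclose(d, 0)

    def test_unequal_counts_pair_min_and_subset(self, rng):
        pre = rng.standard_normal((3, 1, 1, 8))
        post = rng.standard_normal((5, 1, 1, 8))
        d = build_diff_samples(_features(pre), _features(post), seed=1)
        assert d.shape[0] == 3
        # every sample is some POST epoch minus some PRE epoch
        for s in d:
            diffs = post[None, :, 0, 0] - pre[:, None, 0, 0]
            assert np.any(np.all(np.isclose(diffs, s[0, 0]), axis=-1))

    def test_deterministic_given_seed(self, rng):
        pre = _features(rng.standard_normal((6, 2, 1, 8)))
        post = _features(rng.standard_normal((6, 2, 1, 8)))
        d1 = build_diff_samples(pre, post, seed=7)
        d2 = build_diff_samples(pre, post, seed=7)
        assert np.array_equal(d1, d2)
        assert not np.array_equal(d1, build_diff_samples(pre, post, seed=8))

    def test_too_few_epochs_raise(self, rng):
        one = _features(rng.standard_normal((1, 1, 1, 8)))
        with pytest.raises(DegenerateDataError):
            build_diff_samples(one, one, seed=0)

    def test_pooling_labels_classes(self, rng):
        per = {p: (_features(rng.standard_normal((5, 1, 1, 8))),
                   _features(rng.standard_normal((5, 1, 1, 8))))
               for p in ("lMC", "rCB", "sham")}
        ds = pool_diff_features(per, seed=0)
        assert ds.samples.shape[0] == 15
        assert ds.classes == ["lMC", "rCB", "sham"]


class TestShrinkageLDA:
    def _blobs(self, rng, sep=10.0, sigma=0.1, n=30, d=8):
        y = np.repeat(["a", "b", "c"], n)
        centers = {"a": 0.0, "b": sep, "c": 2 * sep}
        X = sigma * rng.standard_normal((3 * n, d))
        for c, mu in centers.items():
            X[y == c, 0] += mu
        return X, y

    def test_separable_blobs_train_f1_is_one(self, rng):
        X, y = self._blobs(rng)
        model = fit_lda(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_shared_blob_cv_f1_near_chance(self, rng):
        X = rng.standard_normal((150, 8))
        y = np.repeat(["a", "b", "c"], 50)
        res = crossval_f1(X, y, k=10, seed=0)
        assert abs(res.macro_f1 - 1 / 3) < 0.12

    def test_lambda_one_equals_nearest_centroid(self, rng):
        X, y = self._blobs(rng, sep=1.0, sigma=1.0)
        model = fit_lda(X, y, lam=1.0)
        z = model.transform(X)
        cz = np.stack([z[y == c].mean(0) for c in model.classes_])
        oracle = model.classes_[
            np.argmin(((z[:, None, :] - cz[None]) ** 2).sum(-1), axis=1)]
        assert np.array_equal(model.predict(X), oracle)

    def test_subspace_is_two_dimensional(self, rng):
        X, y = self._blobs(rng)
        model = fit_lda(X, y)
        assert model.subspace.shape == (8, 2)
        assert np.linalg.matrix_rank(model.subspace) == 2
        assert 0.0 <= model.lam <= 1.0

    def test_class_with_single_sample_raises(self, rng):
        X = rng.standard_normal((5, 4))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.raises(DegenerateDataError):
            fit_lda(X, y)

    def test_lw_shrinkage_matches_sklearn(self, rng):
        from sklearn.covariance import ledoit_wolf

        resid = rng.standard_normal((4, 50, 8)) * rng.uniform(0.5, 2, (4, 1, 8))
        ours = _lw_shrinkage_batch(resid)
        theirs = [ledoit_wolf(r, assume_centered=True)[1] for r in resid]
        assert np.allclose(ours, theirs)


class TestCrossvalF1:
    def test_label_leak_gives_perfect_f1(self, rng):
        y = np.repeat(["a", "b", "c"], 30)
        X = rng.standard_normal((90, 8))
        X[:, 0] = np.unique(y, return_inverse=True)[1] * 100.0
        res = crossval_f1(X, y, k=10, seed=0)
        assert res.macro_f1 == 1.0

    def test_printed_equation_example(self):
        precision, recall, f1 = f1_from_counts([2], [1], [1])
        assert precision[0] == pytest.approx(2 / 3)
        assert recall[0] == pytest.approx(2 / 3)
        assert f1[0] == pytest.approx(2 / 3)

    def test_f1_zero_when_no_predictions(self):
        _, _, f1 = f1_from_counts([0], [0], [5])
        assert f1[0] == 0.0

    def test_counts_conserved_over_folds(self, rng):
        y = np.repeat(["a", "b", "c"], 20)
        X = rng.standard_normal((60, 8))
        res = crossval_f1(X, y, k=5, seed=1)
        # tp + fn per class equals that class's total sample count
        assert np.array_equal(res.tp + res.fn, [20, 20, 20])

    def test_fold_reduction_warns(self, rng):
        y = np.repeat(["a", "b", "c"], 6)
        X = rng.standard_normal((18, 4))
        with pytest.warns(UserWarning, match="reducing folds"):
            crossval_f1(X, y, k=10, seed=0)

    def test_batch_path_equals_reference_loop(self, rng):
        n, d, p = 90, 8, 7
        y = np.repeat(["a", "b", "c"], n // 3)
        X = rng.standard_normal((p, n, d))
        X[:, y == "a"] += 0.4
        folds = stratified_folds(y, k=5, seed=3)
        classes, tp, fp, fn = crossval_f1_batch(X, y, folds)
        for i in range(p):
            ref = crossval_f1(X[i], y, folds=folds)
            assert np.array_equal(ref.tp, tp[i])
            assert np.array_equal(ref.fp, fp[i])
            assert np.array_equal(ref.fn, fn[i])

    def test_f1_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        y = np.repeat(["a", "b", "c"], 40)
        pred = rng.choice(["a", "b", "c"], size=len(y))
        classes = np.unique(y)
        tp = [(np.sum((pred == c) & (y == c))) for c in classes]
        fp = [(np.sum((pred == c) & (y != c))) for c in classes]
        fn = [(np.sum((pred != c) & (y == c))) for c in classes]
        p_, r_, f_ = f1_from_counts(tp, fp, fn)
        sp, sr, sf, _ = precision_recall_fscore_support(
            y, pred, labels=classes, zero_division=0)
        assert np.allclose(p_, sp) and np.allclose(r_, sr)
        assert np.allclose(f_, sf)


class TestClassifyAll:
    def _diff_set(self, rng, n_per=20, n_ch=2, n_f=2):
        samples = rng.standard_normal((3 * n_per, n_ch, n_f, 8))
        labels = np.repeat(["lMC", "rCB", "sham"], n_per)
        return DiffFeatureSet(samples=samples, labels=labels,
                              freqs=np.array([9.0, 10.0]),
                              channel_names=["FC3", "O2"][:n_ch])

    def test_score_map_shape(self, rng):
        ds = {"S00": self._diff_set(rng)}
        sm = classify_all(ds, freqs=[9.0, 10.0], k=5, seed=0)
        assert sm.f1.shape == (1, 3, 2, 2)
        assert sm.macro_f1.shape == (1, 2, 2)
        assert sm.subjects == ["S00"]

    def test_missing_session_skipped_with_warning(self, rng):
        good = self._diff_set(rng)
        bad = DiffFeatureSet(samples=good.samples[:40], labels=good.labels[:40],
                             freqs=good.freqs, channel_names=good.channel_names)
        with pytest.warns(UserWarning, match="lacks a session"):
            sm = classify_all({"S00": good, "S01": bad},
                              freqs=[9.0, 10.0], k=5, seed=0)
        assert sm.subjects == ["S00"]

    def test_effect_monotone_in_separation(self, rng):
        """Macro F1 grows monotonically with planted class separation
        (scaled-down version of the effect-size monotonicity property)."""
        seps = [0.0, 0.3, 0.6, 1.2]
        scores = []
        for sep in seps:
            vals = []
            for seed in range(3):
                r = np.random.default_rng(seed)
                ds = self._diff_set(r)
                ds.samples[ds.labels == "lMC", 0] += sep
                sm = classify_all({"S": ds}, freqs=[9.0, 10.0], k=5,
                                  seed=seed)
                vals.append(sm.macro_f1[0, 0].mean())
            scores.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(scores, scores[1:]))
        assert scores[-1] > scores[0] + 0.2
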