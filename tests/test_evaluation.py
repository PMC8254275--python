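import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.model_selection import KFold

from anmda import ensemble as ens
from anmda.data_model import PairDataset, undetected_pairs
from anmda.evaluation import (
    CVProtocol,
    compute_metrics,
    cross_validate,
    gip_matrices,
    inject_label_noise,
    label_noise_experiment,
)
from anmda.similarity import build_pair_features
from anmda.synthetic import (
    SyntheticAssociationConfig,
    SyntheticBlobConfig,
    make_associations,
    make_blob_pools,
    make_blobs,
)


class TestMetricArithmetic:
    # eight-pair fixture worked out from the confusion table by threshold
    # enumeration: ranking 0.9P 0.8P 0.7P 0.6N 0.45P 0.3N 0.2N 0.1N gives
    # 15/16 concordant pairs; at the 0.5 threshold TP=3 FP=1 FN=1 TN=3.
    Y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    S = np.array([0.9, 0.8, 0.45, 0.7, 0.3, 0.6, 0.2, 0.1])

    def test_eight_point_fixture(self):
        m = compute_metrics(self.Y, self.S)
        assert m["auroc"] == pytest.approx(15 / 16)
        assert m["aupr"] == pytest.approx(0.95)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_auroc_equals_mann_whitney_normalisation(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n1, n0 = int(rng.integers(3, 30)), int(rng.integers(3, 30))
            y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            s = rng.random(n1 + n0)
            u = mannwhitneyu(s[:n1], s[n1:], alternative="two-sided").statistic
            assert compute_metrics(y, s)["auroc"] == pytest.approx(
                u / (n1 * n0), abs=1e-12
            )


class TestCrossValidate:
    def test_separable_data_perfect_every_repeat(self):
        data = make_blobs(SyntheticBlobConfig(n_per_class=40, separation=12.0, seed=0))
        report = cross_validate(
            data, CVProtocol(n_folds=5, n_repeats=3, seed=0),
            model_factory=lambda s: ens.make_learner("logreg", seed=s),
        )
        assert (report.per_repeat["auroc"] == 1.0).all()
        assert report.std["auroc"] == 0.0

    def test_permuted_labels_score_at_chance(self):
        # a fresh uniform permutation per repeat realises the label null
        means = []
        for rep in range(20):
            data = make_blobs(SyntheticBlobConfig(n_per_class=100, seed=rep))
            rng = np.random.default_rng(1000 + rep)
            y = data.y.copy()
            rng.shuffle(y)
            shuffled = PairDataset(data.pairs, data.X, y)
            report = cross_validate(
                shuffled, CVProtocol(n_folds=5, n_repeats=1, seed=rep),
                model_factory=lambda s: ens.make_learner("logreg", seed=s),
            )
            means.append(report.mean["auroc"])
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) < max(3 * se, 0.05)

    def test_every_sample_in_exactly_one_test_fold(self):
        data = make_blobs(SyntheticBlobConfig(n_per_class=20, seed=1))
        splitter = KFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(len(data), dtype=int)
        for _, test_idx in splitter.split(data.X):
            seen[test_idx] += 1
        assert (seen == 1).all()

    def test_fewer_samples_than_folds_rejected(self):
        data = make_blobs(SyntheticBlobConfig(n_per_class=2, seed=0))
        with pytest.raises(ValueError):
            cross_validate(data, CVProtocol(n_folds=10, n_repeats=1, seed=0))


class TestInjectLabelNoise:
    def test_zero_flips_identical_arms(self):
        X_pos, X_neg = make_blob_pools(20, 20, seed=0)
        clean, noisy = inject_label_noise(X_pos, X_neg, 20, 0, seed=0)
        assert np.array_equal(clean.X, noisy.X)
        assert np.array_equal(clean.y, noisy.y)

    def test_arms_stay_balanced(self):
        X_pos, X_neg = make_blob_pools(27, 20, seed=1)
        clean, noisy = inject_label_noise(X_pos, X_neg, 20, 7, seed=1)
        for arm in (clean, noisy):
            assert arm.y.sum() == 20 and len(arm) == 40

    def test_noisy_arm_contains_exactly_nflip_mislabeled(self):
        X_pos, X_neg = make_blob_pools(27, 20, seed=2)
        _, noisy = inject_label_noise(X_pos, X_neg, 20, 7, seed=2)
        pos_rows = {tuple(r) for r in X_pos}
        mislabeled = sum(
            1 for x, label in zip(noisy.X, noisy.y)
            if label == 0 and tuple(x) in pos_rows
        )
        assert mislabeled == 7

    def test_insufficient_reserve_rejected(self):
        X_pos, X_neg = make_blob_pools(22, 20, seed=3)
        with pytest.raises(ValueError, match="reserve"):
            inject_label_noise(X_pos, X_neg, 20, 7, seed=3)


class TestLabelNoiseExperiment:
    def test_zero_flip_deltas_vanish(self):
        X_pos, X_neg = make_blob_pools(40, 40, seed=0)
        out = label_noise_experiment(
            X_pos, X_neg, 0, ["logreg"], CVProtocol(n_folds=4, n_repeats=2, seed=0),
            n_per_class=40,
        )
        for v in out["logreg"]["delta"].values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_noise_lowers_logreg_auroc_on_one_seed(self):
        X_pos, X_neg = make_blob_pools(221, 200, seed=4)
        out = label_noise_experiment(
            X_pos, X_neg, 21, ["logreg"], CVProtocol(n_folds=5, n_repeats=2, seed=4),
        )
        assert out["logreg"]["delta"]["auroc"] < 0


class TestGipLeakageModes:
    def test_full_mode_identical_across_folds(self, identity_assoc):
        g1 = gip_matrices(identity_assoc, "full", [(0, 0)])
        g2 = gip_matrices(identity_assoc, "full", [(1, 1)])
        assert np.array_equal(g1[0].values, g2[0].values)

    def test_fold_safe_changes_with_held_out_pairs(self):
        from anmda.data_model import AssociationMatrix

        a = AssociationMatrix(
            ["m1", "m2", "m3"], ["d1", "d2"], np.array([[1, 0], [0, 1], [1, 1]])
        )
        full = gip_matrices(a, "full")
        safe = gip_matrices(a, "fold_safe", [(0, 0)])
        assert not np.allclose(full[0].values, safe[0].values)

    def test_fold_safe_never_inflates_scores(self):
        """Held-out associations boost full-mode GIP features, so fold-safe
        evaluation should score no higher on average."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        gaps = []
        for seed in range(20):
            cfg = SyntheticAssociationConfig(
                n_m=20, n_d=15, density=0.2, hidden_positive_fraction=0.0, seed=seed
            )
            assoc, _ = make_associations(cfg)
            pos = assoc.positive_pairs().pairs
            pool = undetected_pairs(assoc).pairs
            neg = [pool[i] for i in rng.choice(len(pool), len(pos), replace=False)]
            pairs = pos + neg
            y = np.array([1] * len(pos) + [0] * len(neg))
            splitter = KFold(n_splits=4, shuffle=True, random_state=seed)
            for mode in ("full", "fold_safe"):
                scores = np.empty(len(pairs))
                for train_idx, test_idx in splitter.split(np.arange(len(pairs))):
                    held_out = [pairs[i] for i in test_idx if y[i] == 1]
                    gm, gd = gip_matrices(assoc, mode, held_out)
                    from anmda.data_model import PairIndex

                    feats = build_pair_features(
                        gm, gd, PairIndex(list(pairs), label="undetected")
                    )
                    clf = ens.make_learner("logreg", seed=seed)
                    clf.fit(feats.X[train_idx], y[train_idx])
                    scores[test_idx] = clf.predict_proba(feats.X[test_idx])[:, 1]
                if mode == "full":
                    auroc_full = roc_auc_score(y, scores)
                else:
                    gaps.append(auroc_full - roc_auc_score(y, scores))
        assert np.mean(gaps) >= 0

    def test_unknown_mode_rejected(self, identity_assoc):
        with pytest.raises(ValueError):
            gip_matrices(identity_assoc, "leaky")
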