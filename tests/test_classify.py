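"""Chi-square distance, sigma fit, OvR scoring, ROC and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texton3d import classify, textons
from texton3d.exceptions import (
    ConsistencyError,
    DegenerateLibraryError,
    ParameterError,
    StratificationError,
)


def mann_whitney_auroc(scores, positives):
    """Rank-based oracle: P(score+ > score-) + 0.5*P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positives, dtype=bool)
    pos, neg = s[y], s[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


class TestChi2Distance:
    def test_identity_is_zero(self, rng):
        f = rng.dirichlet(np.ones(10))
        assert classify.chi2_distance(f, f) == 0.0

    def test_disjoint_support_is_one(self):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.25, 0.75])
        assert classify.chi2_distance(a, b) == pytest.approx(1.0, abs=1e-15)

    def test_hand_computed_value(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.25, 0.25, 0.5])
        assert classify.chi2_distance(a, b) == pytest.approx(1.0 / 3.0, abs=1e-12)

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_bounds_and_separation(self, k, seed):
        r = np.random.default_rng(seed)
        a, b = r.dirichlet(np.ones(k)), r.dirichlet(np.ones(k))
        d_ab = classify.chi2_distance(a, b)
        assert d_ab == pytest.approx(classify.chi2_distance(b, a), abs=1e-15)
        assert 0.0 <= d_ab <= 1.0 + 1e-12
        if not np.allclose(a, b):
            assert d_ab > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            classify.chi2_distance(np.ones(3) / 3, np.ones(4) / 4)

    def test_pairwise_matrix_matches_scalar(self, rng):
        hists = [rng.dirichlet(np.ones(6)) for _ in range(5)]
        D = classify.pairwise_chi2(hists)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(classify.chi2_distance(hists[i], hists[j]), abs=1e-12)


class TestFitSigma:
    def test_equal_distances_closed_form(self):
        # three histograms pairwise equidistant at d0 -> sigma = d0
        h = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])]
        assert classify.fit_sigma(h) == pytest.approx(1.0, abs=1e-12)

    def test_two_distance_formula(self):
        D = np.array([[0, 0.3, 0.4], [0.3, 0, 0], [0.4, 0, 0]])
        # only the upper triangle {0.3, 0.4, 0.0} enters: sqrt(mean of squares)
        assert classify.fit_sigma(D) == pytest.approx(np.sqrt((0.09 + 0.16 + 0) / 3), abs=1e-12)

    def test_degenerate_library_rejected(self):
        h = [np.array([0.5, 0.5]), np.array([0.5, 0.5])]
        with pytest.raises(DegenerateLibraryError):
            classify.fit_sigma(h)


def make_model(distances_labels, sigma=0.4, q=5.0, nn=10):
    """Library of histograms engineered to sit at given chi2 distances from
    the all-mass-in-bin-0 test histogram (distance d <-> freqs [1-m, m, ...])."""
    # chi2([1,0],[1-m, m]) = 0.5*(m^2/(2-m) + m) ; invert numerically
    from scipy.optimize import brentq

    lib = []
    for d, label in distances_labels:
        if d == 0:
            m = 0.0
        else:
            m = brentq(lambda m: 0.5 * (m**2 / (2 - m) + m) - d, 0, 1)
        lib.append(textons.TextonHistogram(freqs=np.array([1 - m, m]), label=label))
    return classify.TrainedModel(
        dictionary=textons.TextonDictionary(centers=np.zeros((2, 2))),
        library=lib,
        sigma=sigma,
        q=q,
        nn=min(nn, len(lib)),
    )


class TestOvrConfidence:
    def test_all_positive_at_zero_distance(self):
        model = make_model([(0.0, "a")] * 10, q=5.0)
        test = textons.TextonHistogram(freqs=np.array([1.0, 0.0]))
        assert classify.ovr_confidence(test, model, "a") == pytest.approx(50.0, abs=1e-9)

    def test_all_negative_at_zero_distance(self):
        model = make_model([(0.0, "b")] * 10 + [(0.9, "a")], q=5.0, nn=10)
        test = textons.TextonHistogram(freqs=np.array([1.0, 0.0]))
        assert classify.ovr_confidence(test, model, "a") == pytest.approx(-10.0, abs=1e-9)

    def test_hand_computed_mixed_score(self):
        # 3 positives at d=0.2, 7 negatives at d=0.5, sigma=0.4, q=5:
        # 15 e^{-0.25} - 7 e^{-1.5625} = 10.215
        model = make_model([(0.2, "a")] * 3 + [(0.5, "b")] * 7, sigma=0.4, q=5.0)
        test = textons.TextonHistogram(freqs=np.array([1.0, 0.0]))
        expected = 15 * np.exp(-0.25) - 7 * np.exp(-1.5625)
        score = classify.ovr_confidence(test, model, "a")
        assert score == pytest.approx(expected, abs=1e-9)
        assert score == pytest.approx(10.215, abs=1e-3)

    def test_monotone_in_neighbor_distances(self):
        test = textons.TextonHistogram(freqs=np.array([1.0, 0.0]))
        base = classify.ovr_confidence(
            test, make_model([(0.2, "a")] * 3 + [(0.5, "b")] * 7), "a"
        )
        farther_pos = classify.ovr_confidence(
            test, make_model([(0.3, "a")] * 3 + [(0.5, "b")] * 7), "a"
        )
        farther_neg = classify.ovr_confidence(
            test, make_model([(0.2, "a")] * 3 + [(0.6, "b")] * 7), "a"
        )
        assert farther_pos < base
        assert farther_neg > base

    def test_absent_positive_class_rejected(self):
        model = make_model([(0.2, "a")] * 5)
        test = textons.TextonHistogram(freqs=np.array([1.0, 0.0]))
        with pytest.raises(ParameterError):
            classify.ovr_confidence(test, model, "zz")


class TestRoc:
    def test_perfect_separation(self):
        r = classify.roc_from_scores([(2.0, True), (1.5, True), (0.5, False), (0.1, False)])
        assert r.auroc == 1.0

    def test_all_ties_give_half(self):
        r = classify.roc_from_scores([(1.0, True), (1.0, False), (1.0, True), (1.0, False)])
        assert r.auroc == pytest.approx(0.5)

    def test_worked_ranking(self):
        r = classify.roc_from_scores([(0.9, True), (0.8, False), (0.7, True), (0.1, False)])
        assert r.auroc == pytest.approx(0.75)

    def test_curve_monotone_from_origin_to_corner(self, rng):
        pairs = [(float(s), bool(y)) for s, y in zip(rng.normal(size=30), rng.integers(0, 2, 30))]
        if not any(p[1] for p in pairs) or all(p[1] for p in pairs):
            pairs[0] = (pairs[0][0], True)
            pairs[1] = (pairs[1][0], False)
        r = classify.roc_from_scores(pairs)
        fpr, tpr = zip(*r.points)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert all(np.diff(fpr) >= 0) and all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            classify.roc_from_scores([(1.0, True), (2.0, True)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_mann_whitney_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 30))
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        y = r.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            y[0], y[1] = True, False
        roc = classify.roc_from_scores(list(zip(scores, y)))
        assert roc.auroc == pytest.approx(mann_whitney_auroc(scores, y), abs=1e-12)


def synthetic_two_class_samples(n_per_class=8, n_vectors=300, seed=0):
    """Two classes with disjoint response clusters -> separable histograms."""
    r = np.random.default_rng(seed)
    samples, labels = [], []
    for c, center in enumerate([0.0, 8.0]):
        for _ in range(n_per_class):
            samples.append(center + r.normal(size=(n_vectors, 4)))
            labels.append("pos" if c else "neg")
    return samples, labels


class TestCrossValidate:
    def test_leave_one_out_partition(self):
        samples, labels = synthetic_two_class_samples(3)
        res = classify.cross_validate(samples, labels, folds=6, seed=0, K=4, nn=3)
        tested = np.concatenate([f.test_indices for f in res.fold_records])
        assert sorted(tested) == list(range(6))

    def test_seed_determinism(self):
        samples, labels = synthetic_two_class_samples(5)
        a = classify.cross_validate(samples, labels, folds=5, seed=3, K=4, nn=3)
        b = classify.cross_validate(samples, labels, folds=5, seed=3, K=4, nn=3)
        assert a.scores.equals(b.scores)
        for fa, fb in zip(a.fold_records, b.fold_records):
            assert np.array_equal(fa.dictionary.centers, fb.dictionary.centers)
            assert fa.sigma == fb.sigma

    def test_separable_classes_reach_auroc_one(self):
        samples, labels = synthetic_two_class_samples(6, seed=5)
        res = classify.cross_validate(samples, labels, folds=4, seed=1, K=4, nn=3)
        assert res.auroc("pos") == 1.0
        assert res.auroc("neg") == 1.0

    def test_heldout_mutation_leaves_training_artifacts_unchanged(self):
        samples, labels = synthetic_two_class_samples(5, seed=2)
        ref = classify.cross_validate(samples, labels, folds=5, seed=7, K=4, nn=3)
        fold = ref.fold_records[2]
        mutated = [s.copy() for s in samples]
        for i in fold.test_indices:
            mutated[i] += 100.0  # corrupt only stacks held out of fold 2
        out = classify.cross_validate(mutated, labels, folds=5, seed=7, K=4, nn=3)
        mfold = out.fold_records[2]
        assert np.array_equal(fold.dictionary.centers, mfold.dictionary.centers)
        assert fold.sigma == mfold.sigma
        assert np.array_equal(fold.train_freqs, mfold.train_freqs)
        assert fold.q_by_class == mfold.q_by_class

    def test_missing_class_in_training_fold_raises(self):
        samples, labels = synthetic_two_class_samples(2)  # 2 per class
        with pytest.raises((StratificationError, ValueError)):
            # 4 folds of 1 from 4 stacks leaves folds whose training side
            # can still cover both classes, so force the failure with a
            # class of size 1
            classify.cross_validate(
                samples[:3], ["a", "a", "b"], folds=3, seed=0, K=3, nn=2
            )
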