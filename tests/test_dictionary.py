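import numpy as np
import pytest
from sklearn.base import clone

from lvprop.dictionary import (
    DictionaryClassifier,
    DiscriminativeDictionary,
    classify,
    eq7_value,
    objective,
    scatter_penalty,
    sparse_code_class,
    train,
    update_subdictionary,
)


def random_instance(seed=0, c=3, n=4, d=8, ni=6, scale=0.3):
    rng = np.random.default_rng(seed)
    Y = [rng.standard_normal((d, ni)) for _ in range(c)]
    D = [rng.standard_normal((d, n)) for _ in range(c)]
    D = [Di / np.linalg.norm(Di, axis=0) for Di in D]
    X = [rng.standard_normal((c * n, ni)) * scale for _ in range(c)]
    return Y, D, X


def naive_objective(Y, D, X, e1, e2):
    """Term-by-term loop evaluation of the training objective."""
    c, n = len(D), D[0].shape[1]
    Dfull = np.hstack(D)
    val = 0.0
    for i in range(c):
        val += ((Y[i] - Dfull @ X[i]) ** 2).sum()
        val += ((Y[i] - D[i] @ X[i][i * n : (i + 1) * n]) ** 2).sum()
        for j in range(c):
            if j != i:
                val += ((D[j] @ X[i][j * n : (j + 1) * n]) ** 2).sum()
    val += e1 * sum(np.abs(Xi).sum() for Xi in X)
    allcols = np.hstack(X)
    m = allcols.mean(axis=1)
    sw = sb = 0.0
    for i in range(c):
        mi = X[i].mean(axis=1)
        for k in range(X[i].shape[1]):
            sw += ((X[i][:, k] - mi) ** 2).sum()
        sb += X[i].shape[1] * ((mi - m) ** 2).sum()
    return val + e2 * (sw - sb + sum((Xi**2).sum() for Xi in X))


class TestObjective:
    def test_all_zero_terms_vanish(self):
        _, D, _ = random_instance()
        Y = [np.zeros((8, 6)) for _ in range(3)]
        X = [np.zeros((12, 6)) for _ in range(3)]
        assert objective(Y, D, X, 0.1, 0.001) == 0.0

    def test_hand_computed_scatter(self):
        # two classes of codes (1,0),(1,0) and (-1,0),(-1,0):
        # S_W = 0, S_B = 4, ||X||_F^2 = 4 -> f(X) = 0
        X1 = np.array([[1.0, 1.0], [0.0, 0.0]])
        X2 = np.array([[-1.0, -1.0], [0.0, 0.0]])
        assert scatter_penalty([X1, X2]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_loop_oracle(self, seed):
        Y, D, X = random_instance(seed)
        assert objective(Y, D, X, 0.1, 0.001) == pytest.approx(
            naive_objective(Y, D, X, 0.1, 0.001), abs=1e-10
        )

    def test_empty_class_rejected(self):
        Y, D, X = random_instance()
        Y[1] = np.zeros((8, 0))
        X[1] = np.zeros((12, 0))
        with pytest.raises(ValueError):
            objective(Y, D, X, 0.1, 0.001)


def coordinate_descent_oracle(Yi, D_list, i, eps1, eps2, mi, n_sweeps=300):
    """Exact per-coordinate minimization of the fixed-means coding objective."""
    c, n = len(D_list), D_list[0].shape[1]
    cn, ni = c * n, Yi.shape[1]
    X = np.zeros((cn, ni))

    def g(Xc):
        D = np.hstack(D_list)
        val = ((Yi - D @ Xc) ** 2).sum()
        val += ((Yi - D_list[i] @ Xc[i * n : (i + 1) * n]) ** 2).sum()
        for j in range(c):
            if j != i:
                val += ((D_list[j] @ Xc[j * n : (j + 1) * n]) ** 2).sum()
        val += eps2 * (((Xc - mi[:, None]) ** 2).sum() + (Xc**2).sum())
        return val

    for _ in range(n_sweeps):
        changed = 0.0
        for r in range(cn):
            for col in range(ni):
                old = X[r, col]
                X[r, col] = 0.0
                g0 = g(X)
                X[r, col] = 1.0
                g1 = g(X)
                X[r, col] = -1.0
                gm1 = g(X)
                a = (g1 + gm1) / 2.0 - g0
                b = (g1 - gm1) / 2.0
                new = (
                    np.sign(-b) * max(abs(b) - eps1, 0.0) / (2 * a)
                    if a > 1e-14
                    else 0.0
                )
                X[r, col] = new
                changed = max(changed, abs(new - old))
        if changed < 1e-12:
            break
    return X


class TestSparseCoding:
    def test_exact_recovery_with_orthonormal_dictionary(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        xstar = rng.standard_normal((4, 3))
        Yi = Q @ xstar
        Xi = sparse_code_class(Yi, [Q], 0, eps1=0.0, eps2=0.0, n_iter=500)
        np.testing.assert_allclose(Xi, xstar, atol=1e-6)
        np.testing.assert_allclose(Yi - Q @ Xi, 0.0, atol=1e-6)

    def test_l1_dominance_drives_codes_to_zero(self):
        Y, D, _ = random_instance()
        Xi = sparse_code_class(Y[0], D, 0, eps1=1e6, eps2=0.001)
        assert np.all(Xi == 0.0)

    def test_nonfinite_input_rejected(self):
        Y, D, _ = random_instance()
        Y[0][0, 0] = np.nan
        with pytest.raises(ValueError):
            sparse_code_class(Y[0], D, 0, 0.1, 0.001)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_at_least_as_good_as_coordinate_descent(self, seed):
        Y, D, _ = random_instance(seed, c=2, n=2, d=5, ni=3)
        mi = np.zeros(4)

        def full(Xc):
            v = ((Y[0] - np.hstack(D) @ Xc) ** 2).sum()
            v += ((Y[0] - D[0] @ Xc[:2]) ** 2).sum()
            v += ((D[1] @ Xc[2:]) ** 2).sum()
            v += 0.001 * (((Xc - mi[:, None]) ** 2).sum() + (Xc**2).sum())
            return v + 0.1 * np.abs(Xc).sum()

        Xi = sparse_code_class(Y[0], D, 0, 0.1, 0.001, mi=mi, n_iter=500)
        Xcd = coordinate_descent_oracle(Y[0], D, 0, 0.1, 0.001, mi)
        assert full(Xi) <= full(Xcd) + 1e-6


class TestSubdictionaryUpdate:
    def test_rank_one_case_gives_normalized_residual(self):
        # one class, one atom, single active coefficient
        rng = np.random.default_rng(0)
        y = rng.standard_normal((6, 1))
        D = [rng.standard_normal((6, 1))]
        D[0] /= np.linalg.norm(D[0])
        X = [np.ones((1, 1))]
        Di, _ = update_subdictionary([y], D, X, 0)
        # optimum of ||[y, y] - d c||^2 with c = [1, 1]: d ~ y
        np.testing.assert_allclose(
            Di[:, 0], (y[:, 0] / np.linalg.norm(y[:, 0])), atol=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_eq7_descent(self, seed):
        Y, D, X = random_instance(seed)
        before = eq7_value(Y, D, X, 1)
        Di, Xn = update_subdictionary(Y, D, X, 1)
        Dn = [D[0], Di, D[2]]
        assert eq7_value(Y, Dn, Xn, 1) <= before + 1e-10

    def test_atoms_unit_norm_after_update(self):
        Y, D, X = random_instance(3)
        Di, _ = update_subdictionary(Y, D, X, 0)
        np.testing.assert_allclose(
            np.linalg.norm(Di, axis=0), 1.0, atol=1e-8
        )

    def test_matches_closed_form_oracle(self):
        """Independent loop construction of the per-atom least squares."""
        Y, D, X = random_instance(7, c=2, n=3, d=6, ni=4)
        i = 0
        c, n = 2, 3
        Di_ref = D[i].copy()
        Xref = [x.copy() for x in X]
        # oracle: build stacked targets/codes explicitly and sweep atoms
        for k in range(n):
            Yall = np.hstack(Y)
            Xall = np.hstack(Xref)
            R = Yall - sum(
                D[j] @ Xall[j * n : (j + 1) * n] for j in range(c) if j != i
            )
            T = np.hstack([R, Y[i]] + [np.zeros_like(Y[j]) for j in range(c)
                                       if j != i])
            C = np.hstack(
                [Xall[i * n : (i + 1) * n],
                 Xref[i][i * n : (i + 1) * n]]
                + [Xref[j][i * n : (i + 1) * n] for j in range(c) if j != i]
            )
            ck = C[k]
            E = T - Di_ref @ C + np.outer(Di_ref[:, k], ck)
            dk = E @ ck / (ck @ ck)
            norm = np.linalg.norm(dk)
            Di_ref[:, k] = dk / norm
            for Xj in Xref:
                Xj[i * n + k] *= norm
        Di, Xn = update_subdictionary(Y, D, X, i)
        np.testing.assert_allclose(Di, Di_ref, atol=1e-8)
        for a, b in zip(Xn, Xref):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_dead_atom_reseeded_to_unit_norm(self):
        Y, D, X = random_instance(4)
        for Xi in X:
            Xi[0, :] = 0.0  # kill atom 0 of class 0 everywhere
        Di, _ = update_subdictionary(Y, D, X, 0)
        assert np.linalg.norm(Di[:, 0]) == pytest.approx(1.0, abs=1e-8)


def separable_classes(rng, c=7, d=32, n_train=50, n_test=20, sep=10.0):
    means = [rng.standard_normal(d) * sep for _ in range(c)]
    Ytr = [means[i][:, None] + rng.standard_normal((d, n_train))
           for i in range(c)]
    Yte = [means[i][:, None] + rng.standard_normal((d, n_test))
           for i in range(c)]
    return Ytr, Yte


class TestTraining:
    def test_huge_tolerance_stops_after_one_iteration(self):
        Y, _, _ = random_instance(0, ni=8)
        model = train(Y, n_atoms=2, max_iter=50, tol=1e12, seed=0)
        assert len(model.objective_history) == 2

    def test_training_is_deterministic(self):
        Y, _, _ = random_instance(1, ni=8)
        a = train(Y, n_atoms=2, max_iter=5, seed=3)
        b = train(Y, n_atoms=2, max_iter=5, seed=3)
        for Da, Db in zip(a.sub_dictionaries, b.sub_dictionaries):
            np.testing.assert_array_equal(Da, Db)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        Ytr, _ = separable_classes(rng, c=3, d=16, n_train=20)
        model = train(Ytr, n_atoms=4, max_iter=10, seed=0)
        h = np.array(model.objective_history)
        assert np.all(np.diff(h) <= 1e-6 * np.maximum(np.abs(h[:-1]), 1.0))

    def test_atoms_unit_norm_after_training(self):
        rng = np.random.default_rng(1)
        Ytr, _ = separable_classes(rng, c=3, d=16, n_train=20)
        model = train(Ytr, n_atoms=4, max_iter=5, seed=0)
        for Di in model.sub_dictionaries:
            np.testing.assert_allclose(np.linalg.norm(Di, axis=0), 1.0,
                                       atol=1e-8)

    def test_too_few_samples_rejected(self):
        Y, _, _ = random_instance(0, ni=3)
        with pytest.raises(ValueError, match="n_atoms"):
            train(Y, n_atoms=4)

    def test_heldout_accuracy_on_separable_classes(self):
        """>= 95% held-out accuracy on 7 well-separated Gaussian classes."""
        rng = np.random.default_rng(0)
        Ytr, Yte = separable_classes(rng)
        model = train(Ytr, n_atoms=8, max_iter=15, seed=0)
        correct = total = 0
        for i, Yi in enumerate(Yte):
            for k in range(Yi.shape[1]):
                label, _, _ = classify(Yi[:, k], model)
                correct += label == i
                total += 1
        assert correct / total >= 0.95

    def test_planted_dictionary_recovery(self):
        """Orthogonal planted atoms are recovered up to sign/permutation."""
        rng = np.random.default_rng(0)
        c, n, d = 3, 4, 32
        Q, _ = np.linalg.qr(rng.standard_normal((d, c * n)))
        D_true = [Q[:, i * n : (i + 1) * n] for i in range(c)]
        Y = []
        for i in range(c):
            codes = np.zeros((n, 40))
            for col in range(40):  # 1-sparse codes: identifiable regime
                codes[rng.integers(n), col] = rng.uniform(1.0, 2.0) * rng.choice(
                    [-1, 1]
                )
            Y.append(D_true[i] @ codes)
        model = train(Y, n_atoms=n, max_iter=20, seed=1)
        corrs = []
        for i in range(c):
            M = np.abs(model.sub_dictionaries[i].T @ D_true[i])
            corrs.extend(M.max(axis=1))
        assert np.mean(corrs) >= 0.95


def orthogonal_model(eta1=0.1, eta2=0.005, means=None, c=3, n=2, d=8):
    rng = np.random.default_rng(0)
    Q, _ = np.linalg.qr(rng.standard_normal((d, c * n)))
    subs = [Q[:, i * n : (i + 1) * n] for i in range(c)]
    if means is None:
        means = [np.zeros(n) for _ in range(c)]
    return DiscriminativeDictionary(subs, means, 0.1, 0.001, eta1, eta2, [])


class TestClassify:
    def test_own_atom_is_reconstructed_by_its_class(self):
        model = orthogonal_model(eta2=0.0)
        y = model.sub_dictionaries[2][:, 0]
        label, scores, codes = classify(y, model)
        assert label == 2
        resid = y - model.sub_dictionaries[2] @ codes[2]
        assert np.linalg.norm(resid) < 0.1

    def test_zero_input_scored_by_mean_code_norm(self):
        means = [np.full(2, 0.5), np.full(2, 0.1), np.full(2, 0.9)]
        model = orthogonal_model(means=means)
        label, scores, _ = classify(np.zeros(8), model)
        expected = [0.005 * (m**2).sum() for m in means]
        np.testing.assert_allclose(scores, expected, atol=1e-10)
        assert label == 1  # smallest mean-code norm

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        model = orthogonal_model()
        y = rng.standard_normal(8)
        _, scores, _ = classify(y, model)
        perm = [2, 0, 1]
        permuted = DiscriminativeDictionary(
            [model.sub_dictionaries[p] for p in perm],
            [model.class_code_means[p] for p in perm],
            0.1, 0.001, 0.1, 0.005, [],
        )
        _, scores_p, _ = classify(y, permuted)
        np.testing.assert_allclose(scores_p, scores[perm], atol=1e-9)

    def test_nonfinite_feature_rejected(self):
        model = orthogonal_model()
        with pytest.raises(ValueError):
            classify(np.full(8, np.inf), model)


class TestSklearnEstimator:
    def test_fit_predict_roundtrip_labels(self):
        rng = np.random.default_rng(0)
        Ytr, Yte = separable_classes(rng, c=3, d=16, n_train=20, n_test=10)
        X = np.vstack([Y.T for Y in Ytr])
        y = np.repeat(["bg", "lv", "mid"], 20)
        clf = DictionaryClassifier(n_atoms=4, max_iter=8, random_state=0)
        clf.fit(X, y)
        pred = clf.predict(np.vstack([Y.T for Y in Yte]))
        assert set(pred) <= {"bg", "lv", "mid"}
        assert (pred == np.repeat(["bg", "lv", "mid"], 10)).mean() >= 0.95

    def test_estimator_is_cloneable_with_params(self):
        clf = DictionaryClassifier(n_atoms=5, eps1=0.2)
        c2 = clone(clf)
        assert c2.get_params()["n_atoms"] == 5
        assert c2.get_params()["eps1"] == 0.2

    def test_batched_scores_agree_with_single_sample_path(self):
        rng = np.random.default_rng(0)
        Ytr, Yte = separable_classes(rng, c=3, d=16, n_train=20, n_test=3)
        X = np.vstack([Y.T for Y in Ytr])
        y = np.repeat([1, 2, 3], 20)
        clf = DictionaryClassifier(n_atoms=4, max_iter=8, random_state=0)
        clf.fit(X, y)
        Xte = np.vstack([Y.T for Y in Yte])
        batch = clf.decision_scores(Xte)
        single = np.vstack([classify(x, clf.model_)[1] for x in Xte])
        np.testing.assert_allclose(batch, single, rtol=1e-4, atol=1e-6)
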