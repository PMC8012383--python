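import numpy as np
import pandas as pd
import pytest

from howlid import LDAModel, classify, fit_lda, project_ld
from howlid.exceptions import HowlIdError, SchemaError


def gaussian_classes(rng, means, n_per=10, sd=1.0):
    """Labelled score frame with spherical Gaussian classes."""
    rows, labels = [], []
    for k, m in enumerate(means):
        rows.append(np.asarray(m) + sd * rng.standard_normal((n_per, len(m))))
        labels += [f"W{k + 1}"] * n_per
    X = np.vstack(rows)
    cols = [f"PC{j + 1}" for j in range(X.shape[1])]
    idx = [f"h{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx, columns=cols), labels


class TestFitLDA:
    def test_two_classes_give_single_discriminant(self, rng):
        scores, labels = gaussian_classes(rng, [[-2.0], [2.0]])
        model = fit_lda(scores, labels)
        assert model.n_discriminants == 1
        np.testing.assert_allclose(model.discriminant_proportion, [1.0])

    def test_rank_bound_five_classes(self, rng):
        means = 6 * np.eye(5)[:, :4]  # 5 classes in 4-D
        scores, labels = gaussian_classes(rng, means)
        model = fit_lda(scores, labels)
        assert model.n_discriminants == 4
        assert model.discriminant_proportion.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.discriminant_proportion) <= 1e-12)

    def test_single_class_rejected(self, rng):
        scores, _ = gaussian_classes(rng, [[0.0]])
        with pytest.raises(HowlIdError):
            fit_lda(scores, ["W1"] * len(scores))

    def test_singleton_class_named_in_error(self, rng):
        scores, labels = gaussian_classes(rng, [[-2.0], [2.0]], n_per=5)
        labels[-5:] = ["W2"] * 4 + ["LONER"]
        with pytest.raises(HowlIdError, match="LONER"):
            fit_lda(scores, labels)

    def test_priors_sum_and_modes(self, rng):
        scores, labels = gaussian_classes(rng, [[-3, 0], [3, 0], [0, 3]], n_per=6)
        prop = fit_lda(scores, labels, priors="proportional")
        uni = fit_lda(scores, labels, priors="uniform")
        assert prop.priors.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(uni.priors, np.full(3, 1 / 3))

    def test_separable_classes_classified_perfectly(self, rng):
        """Between-class separation 6x the within-class spread -> 100%."""
        means = 6 * np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, -1, -1], [1, 1, -1]], dtype=float
        )
        scores, labels = gaussian_classes(rng, means, n_per=10, sd=1.0)
        model = fit_lda(scores, labels)
        pred = classify(model, scores)
        assert (pred.to_numpy() == np.array(labels, dtype=object)).mean() == 1.0

    def test_matches_generalised_eigenproblem_oracle(self, rng):
        """Eigenvalue ratios agree with a direct solve of Sw^-1 Sb."""
        scores, labels = gaussian_classes(rng, [[-2, 1], [2, -1], [0, 3]], n_per=8)
        model = fit_lda(scores, labels)

        X = scores.to_numpy()
        labs = np.array(labels)
        classes = sorted(set(labels))
        gm = X.mean(0)
        Sw = np.zeros((2, 2))
        Sb = np.zeros((2, 2))
        for c in classes:
            Xc = X[labs == c]
            m = Xc.mean(0)
            Sw += (Xc - m).T @ (Xc - m)
            Sb += len(Xc) * np.outer(m - gm, m - gm)
        eig = np.linalg.eigvals(np.linalg.solve(Sw, Sb))
        eig = np.sort(np.real(eig))[::-1]
        np.testing.assert_allclose(
            model.discriminant_proportion, eig / eig.sum(), atol=1e-8
        )

    def test_agreement_with_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        scores, labels = gaussian_classes(
            rng, [[-3, 0, 1], [3, 1, 0], [0, -3, 2], [1, 3, -2]], n_per=8, sd=1.2
        )
        model = fit_lda(scores, labels)
        pred = classify(model, scores)
        sk = LinearDiscriminantAnalysis().fit(scores.to_numpy(), labels)
        sk_pred = sk.predict(scores.to_numpy())
        assert (pred.to_numpy() == sk_pred).mean() == 1.0

    def test_fisher_criterion_random_probes(self, rng):
        """No random direction beats LD1's between/within variance ratio."""
        scores, labels = gaussian_classes(rng, [[-3, 1, 0], [3, 0, 1], [0, 3, -1]], n_per=10)
        model = fit_lda(scores, labels)
        X = scores.to_numpy()
        labs = np.array(labels)

        def fisher(direction):
            z = X @ direction
            gm = z.mean()
            classes = sorted(set(labels))
            between = sum(
                (z[labs == c]).size * (z[labs == c].mean() - gm) ** 2 for c in classes
            )
            within = sum(
                ((z[labs == c] - z[labs == c].mean()) ** 2).sum() for c in classes
            )
            return between / within

        best = fisher(model.scaling[:, 0])
        for _ in range(100):
            d = rng.standard_normal(3)
            assert fisher(d / np.linalg.norm(d)) <= best + 1e-9


class TestProjectClassify:
    def test_pooled_training_mean_maps_to_origin(self, rng):
        scores, labels = gaussian_classes(rng, [[-2, 0], [2, 1], [0, -2]], n_per=7)
        model = fit_lda(scores, labels)
        mean_row = scores.mean().to_frame().T
        z = project_ld(model, mean_row, n_lds=2)
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-9)

    def test_class_means_classified_to_their_class(self, rng):
        scores, labels = gaussian_classes(rng, [[-3, 0], [3, 0], [0, 3]], n_per=6)
        model = fit_lda(scores, labels)
        means = pd.DataFrame(
            model.class_means, columns=scores.columns, index=model.class_labels
        )
        pred = classify(model, means)
        assert list(pred) == list(model.class_labels)

    def test_equidistant_point_breaks_tie_lexicographically(self):
        scores = pd.DataFrame(
            {"PC1": [-1.0, -1.2, 1.0, 1.2]}, index=["a", "b", "c", "d"]
        )
        model = fit_lda(scores, ["B", "B", "A", "A"], priors="uniform")
        mid = pd.DataFrame({"PC1": [0.0]}, index=["q"])
        assert classify(model, mid).iloc[0] == "A"

    def test_hand_projection_three_class_toy(self, rng):
        scores, labels = gaussian_classes(rng, [[-2, 1], [2, -1], [0, 3]], n_per=6)
        model = fit_lda(scores, labels)
        x = np.array([[0.7, -0.3]])
        expected = (x - model.grand_mean) @ model.scaling[:, :2]
        frame = pd.DataFrame(x, columns=scores.columns, index=["q"])
        got = project_ld(model, frame, n_lds=2)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)

    def test_projection_then_classify_consistent(self, rng):
        scores, labels = gaussian_classes(rng, [[-4, 0], [4, 0], [0, 4]], n_per=8)
        model = fit_lda(scores, labels)
        pred = classify(model, scores)
        z = project_ld(model, scores, n_lds=model.n_discriminants)
        centers = model.class_centers_ld
        d2 = ((z.to_numpy()[:, None, :] - centers[None]) ** 2).sum(2)
        disc = -0.5 * d2 + np.log(model.priors)
        manual = [model.class_labels[i] for i in np.argmax(disc, axis=1)]
        assert list(pred) == manual

    def test_too_many_lds_rejected(self, rng):
        scores, labels = gaussian_classes(rng, [[-2, 0], [2, 0]], n_per=5)
        model = fit_lda(scores, labels)
        with pytest.raises(HowlIdError):
            project_ld(model, scores, n_lds=2)

    def test_column_mismatch_is_schema_error(self, rng):
        scores, labels = gaussian_classes(rng, [[-2, 0], [2, 0]], n_per=5)
        model = fit_lda(scores, labels)
        bad = scores.rename(columns={"PC1": "PC9"})
        with pytest.raises(SchemaError):
            classify(model, bad)

    def test_serialisation_roundtrip(self, rng, tmp_path):
        scores, labels = gaussian_classes(rng, [[-2, 1], [2, -1], [0, 3]], n_per=6)
        model = fit_lda(scores, labels)
        model.save(tmp_path / "lda.json")
        back = LDAModel.load(tmp_path / "lda.json")
        np.testing.assert_allclose(back.scaling, model.scaling)
        assert back.class_labels == model.class_labels
        pred_a = classify(model, scores)
        pred_b = classify(back, scores)
        assert list(pred_a) == list(pred_b)
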