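"""Anchored LASSO + linear-regression turnover scoring model."""

import numpy as np
import pandas as pd
import pytest

from ecmorph.morphometry import FEATURE_NAMES
from ecmorph.turnover import (
    embed_umap,
    fit_turnover,
    lasso_coefficients,
    lasso_select,
    score,
    standardize,
)


def make_matrix(rng, n=40, informative=True):
    """n samples x 26 features; feature 0 tracks the labels if informative."""
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    if informative:
        X[:, 0] = y + rng.normal(scale=0.05, size=n)
    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    frame.index = [f"s{i}" for i in range(n)]
    return frame, pd.Series(y, index=frame.index)


class TestStandardize:
    def test_calibration_columns_zero_mean_unit_sd(self, rng):
        frame, _ = make_matrix(rng)
        scaled, _ = standardize(frame)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-9)
        assert np.allclose(scaled.std(ddof=0), 1.0, atol=1e-9)

    def test_constant_column_dropped_with_warning(self, rng):
        frame, _ = make_matrix(rng)
        frame[FEATURE_NAMES[3]] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, scaler = standardize(frame)
        assert FEATURE_NAMES[3] not in scaled.columns
        assert scaler.dropped == [FEATURE_NAMES[3]]

    def test_all_constant_rejected(self):
        frame = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            standardize(frame)

    def test_reference_subset_statistics_used(self, rng):
        frame, _ = make_matrix(rng)
        ref = frame.index[:10]
        scaled, _ = standardize(frame, reference_index=ref)
        assert np.allclose(scaled.loc[ref].mean(), 0.0, atol=1e-9)


class TestLasso:
    def test_huge_penalty_nulls_all_coefficients(self, rng):
        frame, y = make_matrix(rng)
        scaled, _ = standardize(frame)
        coef, _ = lasso_coefficients(scaled.to_numpy(), y.to_numpy(), 1e6)
        assert np.allclose(coef, 0.0)

    def test_zero_penalty_matches_normal_equations(self, rng):
        frame, y = make_matrix(rng, n=60)
        scaled, _ = standardize(frame)
        X = scaled.to_numpy()[:, :10]
        coef, icpt = lasso_coefficients(X, y.to_numpy(), 0.0)
        design = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
        assert np.allclose(np.concatenate([[icpt], coef]), beta, atol=1e-6)

    def test_informative_feature_selected(self, rng):
        frame, y = make_matrix(rng, n=60)
        scaled, _ = standardize(frame)
        sel = lasso_select(scaled, y, folds=10, seed=0)
        assert FEATURE_NAMES[0] in sel.selected

    def test_single_class_labels_rejected(self, rng):
        frame, _ = make_matrix(rng)
        scaled, _ = standardize(frame)
        with pytest.raises(ValueError, match="both calibration classes"):
            lasso_select(scaled, np.zeros(len(frame)), folds=5)

    def test_too_few_samples_suggests_smaller_k(self, rng):
        frame, y = make_matrix(rng, n=8)
        scaled, _ = standardize(frame)
        with pytest.raises(ValueError, match="smaller fold count"):
            lasso_select(scaled, y.to_numpy(), folds=10)


class TestFit:
    def test_perfect_feature_reproduces_labels(self, rng):
        frame, y = make_matrix(rng)
        frame[FEATURE_NAMES[0]] = y  # exactly label-predictive
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, [FEATURE_NAMES[0]], scaler)
        assert np.allclose(model.fitted, y, atol=1e-9)

    def test_coefficients_match_normal_equations(self, rng):
        frame, y = make_matrix(rng, n=50)
        scaled, scaler = standardize(frame)
        names = list(FEATURE_NAMES[:5])
        model = fit_turnover(scaled, y, names, scaler)
        X = scaled[names].to_numpy()
        design = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
        assert model.intercept == pytest.approx(beta[0], abs=1e-9)
        assert np.allclose(model.coefficients.to_numpy(), beta[1:], atol=1e-9)

    def test_balanced_labels_mean_fitted_half(self, rng):
        frame, y = make_matrix(rng)
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, list(FEATURE_NAMES[:4]), scaler)
        assert model.fitted.mean() == pytest.approx(0.5, abs=1e-9)

    def test_collinear_column_dropped(self, rng):
        frame, y = make_matrix(rng)
        frame[FEATURE_NAMES[1]] = 2.0 * frame[FEATURE_NAMES[0]]
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, list(FEATURE_NAMES[:2]), scaler)
        assert model.selected == [FEATURE_NAMES[0]]

    def test_empty_selection_intercept_only(self, rng):
        frame, y = make_matrix(rng)
        scaled, scaler = standardize(frame)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fit_turnover(scaled, y, [], scaler)
        assert model.intercept == pytest.approx(y.mean())


class TestScore:
    def test_calibration_sample_reproduces_fitted_value(self, rng):
        frame, y = make_matrix(rng)
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, [FEATURE_NAMES[0]], scaler)
        sid = frame.index[7]
        assert score(model, frame.loc[sid]) == pytest.approx(model.fitted[sid], abs=1e-9)

    def test_identical_vectors_identical_scores(self, rng):
        frame, y = make_matrix(rng)
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, list(FEATURE_NAMES[:3]), scaler)
        v = frame.iloc[0]
        assert score(model, v) == score(model, v.copy())

    def test_missing_feature_named_in_error(self, rng):
        frame, y = make_matrix(rng)
        scaled, scaler = standardize(frame)
        model = fit_turnover(scaled, y, [FEATURE_NAMES[0]], scaler)
        probe = frame.iloc[0].drop(FEATURE_NAMES[0])
        with pytest.raises(KeyError, match=FEATURE_NAMES[0]):
            score(model, probe)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(11)
    centers = rng.normal(scale=8.0, size=(3, len(FEATURE_NAMES)))
    X = np.vstack([c + rng.normal(size=(20, len(FEATURE_NAMES))) for c in centers])
    labels = np.repeat([0, 1, 2], 20)
    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    return frame, labels


class TestEmbedding:
    def test_output_shape(self, blobs):
        frame, _ = blobs
        result = embed_umap(frame, seed=0)
        assert result.coordinates.shape == (len(frame), 2)

    def test_duplicate_rows_embed_near_each_other(self, blobs):
        frame, _ = blobs
        dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        result = embed_umap(dup, seed=0)
        coords = result.coordinates
        d_dup = np.linalg.norm(coords[-1] - coords[0])
        spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
        assert d_dup < 0.25 * spread

    def test_separated_classes_positive_silhouette(self, blobs):
        from sklearn.metrics import silhouette_score

        frame, labels = blobs
        result = embed_umap(frame, seed=0)
        assert silhouette_score(result.coordinates, labels) > 0

    def test_too_few_samples_rejected(self, blobs):
        frame, _ = blobs
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_umap(frame.iloc[:5], n_neighbors=15)
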