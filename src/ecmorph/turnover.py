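"""Anchored ECM turnover scoring model.

The score summarizes collagen turnover on a single axis anchored by two
calibration groups: non-stretched control tissue is assigned 0 and
stretch-induced fibrosis — the gold standard of dense, deposited collagen
— is assigned 1.  Feature selection over the 26 collagen ultrastructure
parameters uses cross-validated LASSO; the selected features then enter an
ordinary least-squares fit of the 0/1 anchor labels.  Scores of new images
are unbounded: values near 0 indicate homeostatic matrix, near 1 fibrotic
deposition, and negative values net collagen degradation.

Standardization statistics come from the calibration samples only, so
scoring held-out groups leaks nothing back into the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "Scaler",
    "LassoSelection",
    "TurnoverModel",
    "EmbeddingResult",
    "standardize",
    "lasso_coefficients",
    "lasso_select",
    "fit_turnover",
    "fit_turnover_model",
    "score",
    "embed_umap",
]

logger = logging.getLogger(__name__)


@dataclass
class Scaler:
    """Per-feature calibration mean/sd; zero-variance columns recorded."""

    mean: pd.Series
    std: pd.Series
    dropped: list[str] = field(default_factory=list)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        kept = self.mean.index
        return (frame[kept] - self.mean) / self.std


@dataclass
class LassoSelection:
    selected: list[str]
    lambda_grid: np.ndarray
    chosen_lambda: float
    cv_mean: np.ndarray
    cv_se: np.ndarray
    coefficients: pd.Series
    folds: int
    seed: int


@dataclass
class TurnoverModel:
    """Fitted anchored scoring model: scaler + selected linear form."""

    scaler: Scaler
    selected: list[str]
    coefficients: pd.Series  # on standardized selected features
    intercept: float
    fitted: pd.Series  # calibration sample id -> fitted score
    metadata: dict = field(default_factory=dict)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # n x 2
    n_neighbors: int
    min_dist: float
    seed: int
    library_version: str = ""


def standardize(
    matrix: pd.DataFrame, reference_index=None
) -> tuple[pd.DataFrame, Scaler]:
    """Z-score each column using statistics of the reference rows.

    ``reference_index`` selects the calibration subset (default: all
    rows).  Columns with zero variance on the reference rows are dropped
    with a warning and recorded on the scaler.
    """
    if matrix.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    ref = matrix if reference_index is None else matrix.loc[reference_index]
    if len(ref) == 0:
        raise ValueError("calibration subset is empty")
    mean = ref.mean(axis=0)
    std = ref.std(axis=0, ddof=0)
    dropped = list(std.index[std == 0])
    if len(dropped) == len(std):
        raise ValueError("all feature columns have zero variance")
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped}",
            stacklevel=2,
        )
        mean = mean.drop(dropped)
        std = std.drop(dropped)
    scaler = Scaler(mean=mean, std=std, dropped=dropped)
    return scaler.transform(matrix), scaler


def lasso_coefficients(
    X: np.ndarray, y: np.ndarray, lam: float, warm: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """L1-penalized least squares, objective (1/2n)||y - Xb||^2 + lam*|b|.

    ``lam = 0`` reduces exactly to ordinary least squares (solved by
    normal equations via lstsq rather than coordinate descent).
    """
    if lam == 0.0:
        Xd = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return beta[1:], float(beta[0])
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=100000, tol=1e-10)
    if warm is not None:
        model.coef_ = warm.copy()
        model.warm_start = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def _lasso_path(X: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """Coefficients and intercepts along a descending penalty grid.

    Uses the compiled coordinate-descent path solver; the intercept is
    recovered from the centred fit as mean(y) - mean(X) @ coef.
    """
    from sklearn.linear_model import lasso_path as _skl_path

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = _skl_path(
            X - x_mean, y - y_mean, alphas=grid, tol=1e-8, max_iter=5000
        )
    icpts = y_mean - x_mean @ coefs
    return coefs, icpts


def _lambda_grid(X: np.ndarray, y: np.ndarray, n: int = 100, decades: float = 4.0) -> np.ndarray:
    lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n)


def lasso_select(
    scaled: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    decades: float = 4.0,
) -> LassoSelection:
    """Cross-validated LASSO feature selection with the one-SE rule.

    The penalty path spans ``decades`` decades down from lambda_max =
    max|X'y|/n (the smallest penalty nulling every coefficient).  K-fold
    CV (seeded shuffle) scores squared error per penalty; the chosen
    penalty is the largest one within one standard error of the CV
    minimum.  Selected features are the nonzero coefficients there — the
    selection may be empty, which downgrades the model to intercept-only
    with a warning.
    """
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels must contain both calibration classes (0 and 1)")
    n = len(y)
    if n < folds:
        raise ValueError(
            f"n={n} samples is fewer than {folds} folds; use a smaller fold count"
        )
    X = scaled.to_numpy(dtype=float)
    grid = _lambda_grid(X, y, n_lambdas, decades)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = np.empty((folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        coefs, icpts = _lasso_path(X[tr], y[tr], grid)
        preds = X[te] @ coefs + icpts  # (n_test, n_lambda)
        errs[f] = ((y[te][:, None] - preds) ** 2).mean(axis=0)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(folds)
    jmin = int(np.argmin(cv_mean))
    within = np.flatnonzero(cv_mean <= cv_mean[jmin] + cv_se[jmin])
    j1se = int(within.min())  # grid is descending: smallest index = largest lambda
    lam = float(grid[j1se])

    full_coefs, _ = _lasso_path(X, y, grid)
    coefs = pd.Series(full_coefs[:, j1se], index=scaled.columns)
    selected = list(coefs.index[coefs != 0])
    if not selected:
        warnings.warn(
            "LASSO selected no features at the one-SE penalty; "
            "the model will be intercept-only",
            stacklevel=2,
        )
    return LassoSelection(
        selected=selected,
        lambda_grid=grid,
        chosen_lambda=lam,
        cv_mean=cv_mean,
        cv_se=cv_se,
        coefficients=coefs,
        folds=folds,
        seed=seed,
    )


def fit_turnover(
    scaled: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    selection: LassoSelection | list[str],
    scaler: Scaler,
    metadata: dict | None = None,
) -> TurnoverModel:
    """OLS of the anchor labels on the standardized selected features.

    Collinear columns in the selected design are dropped (logged) before
    the solve; fitted calibration values are stored on the model so a
    stored sample always reproduces its fitted score.
    """
    selected = selection.selected if isinstance(selection, LassoSelection) else list(selection)
    y = np.asarray(labels, dtype=float)
    meta = dict(metadata or {})
    if isinstance(selection, LassoSelection):
        meta.setdefault("chosen_lambda", selection.chosen_lambda)
        meta.setdefault("folds", selection.folds)
        meta.setdefault("seed", selection.seed)

    if not selected:
        warnings.warn("empty selection: fitting an intercept-only model", stacklevel=2)
        intercept = float(y.mean())
        fitted = pd.Series(np.full(len(y), intercept), index=scaled.index)
        return TurnoverModel(
            scaler=scaler, selected=[], coefficients=pd.Series(dtype=float),
            intercept=intercept, fitted=fitted, metadata=meta,
        )

    # drop columns that do not increase design rank (collinearity)
    kept: list[str] = []
    for name in selected:
        trial = scaled[kept + [name]].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(trial)), trial])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            kept.append(name)
        else:
            logger.info("dropping collinear feature %s from the scoring fit", name)
    X = scaled[kept].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted_vals = design @ beta
    return TurnoverModel(
        scaler=scaler,
        selected=kept,
        coefficients=pd.Series(beta[1:], index=kept),
        intercept=float(beta[0]),
        fitted=pd.Series(fitted_vals, index=scaled.index),
        metadata=meta,
    )


def fit_turnover_model(
    features: pd.DataFrame,
    groups: pd.Series,
    control_group: str = "control",
    fibrosis_group: str = "deposition",
    folds: int = 10,
    seed: int = 0,
) -> TurnoverModel:
    """End-to-end calibration on the two anchor groups.

    Rows of ``features`` whose group label is ``control_group`` get label
    0 and ``fibrosis_group`` label 1; every other group is ignored during
    fitting and can be scored afterwards with :func:`score`.
    """
    groups = groups.reindex(features.index)
    calib = groups.isin([control_group, fibrosis_group])
    if not calib.any():
        raise ValueError("no calibration samples found for the anchor groups")
    calib_idx = features.index[calib]
    y = (groups.loc[calib_idx] == fibrosis_group).astype(float)
    scaled_all, scaler = standardize(features, reference_index=calib_idx)
    scaled = scaled_all.loc[calib_idx]
    selection = lasso_select(scaled, y, folds=folds, seed=seed)
    meta = {"control_group": control_group, "fibrosis_group": fibrosis_group}
    return fit_turnover(scaled, y, selection, scaler, metadata=meta)


def score(model: TurnoverModel, features: pd.Series | pd.DataFrame):
    """Score feature vectors with a fitted model.

    Returns a float for a single vector (Series) or a Series for a frame.
    Raises if any selected feature is absent from the input.
    """
    single = isinstance(features, pd.Series)
    frame = features.to_frame().T if single else features
    missing = [n for n in model.selected if n not in frame.columns]
    if missing:
        raise KeyError(f"feature vector is missing selected feature(s): {missing}")
    if model.selected:
        mu = model.scaler.mean[model.selected]
        sd = model.scaler.std[model.selected]
        z = (frame[model.selected] - mu) / sd
        vals = z.to_numpy(dtype=float) @ model.coefficients.to_numpy() + model.intercept
    else:
        vals = np.full(len(frame), model.intercept)
    if single:
        return float(vals[0])
    return pd.Series(vals, index=frame.index, name="turnover_score")


def embed_umap(
    matrix: pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> EmbeddingResult:
    """2-D UMAP of standardized feature vectors (QC visualization).

    Deterministic for a fixed seed and library version, which is recorded
    on the result.
    """
    if len(matrix) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} samples, got {len(matrix)}"
        )
    import umap

    scaled, _ = standardize(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, min_dist=min_dist, n_components=2,
            random_state=seed,
        )
        coords = reducer.fit_transform(scaled.to_numpy(dtype=float))
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        seed=seed,
        library_version=umap.__version__,
    )
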