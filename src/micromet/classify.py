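"""Random-forest cross-validated classifiers/regressors, covariate-adjusted
ridge regression, AUC, and attribution-vs-ridge concordance.

The classifier protocol: stratified k-fold cross-validation repeated r
times; inside each training fold only, the minority class is upsampled with
replacement to balance the classes; a small hyperparameter grid is scored
by Cohen's kappa (0.5 posterior cut) and the best configuration's per-fold
AUC is recorded; the winning configuration is refit on all data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

from .ev import explained_variance


@dataclass
class CVResult:
    """Per-fold cross-validation metrics (AUC or R2) and the selected model."""

    kind: str
    fold_metrics: np.ndarray
    mean_metric: float
    model_descriptor: dict
    seed: int
    fold_sizes: list = field(default_factory=list)

    @property
    def se_metric(self) -> float:
        return float(self.fold_metrics.std(ddof=1) / np.sqrt(len(self.fold_metrics)))


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney formulation: fraction of (positive, negative)
    pairs correctly ordered, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = s[y == classes[1]]
    neg = s[y == classes[0]]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _upsample(X, y, rng):
    """Balance classes by resampling the minority class with replacement."""
    classes, counts = np.unique(y, return_counts=True)
    nmax = counts.max()
    idx = []
    for c, cnt in zip(classes, counts):
        ci = np.flatnonzero(y == c)
        if cnt < nmax:
            extra = rng.choice(ci, size=nmax - cnt, replace=True)
            ci = np.concatenate([ci, extra])
        idx.append(ci)
    idx = np.concatenate(idx)
    return X[idx], y[idx]


DEFAULT_GRID = ({"max_features": "sqrt"}, {"max_features": 0.33})


def rf_cv_classifier(
    X,
    y,
    n_trees: int = 5000,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    grid=DEFAULT_GRID,
):
    """Repeated stratified CV random forest with in-fold upsampling.

    Model selection across ``grid`` by mean Cohen's kappa (0.5 posterior
    cut); per-fold AUCs of the winning configuration are returned and the
    winner is refit on all data.  Returns (CVResult, fitted model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("y must be binary")
    if counts.min() < folds:
        raise ValueError("both classes must have at least `folds` members")
    rng = np.random.default_rng(seed)
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(splitter.split(X, y))
    results = []
    for gi, params in enumerate(grid):
        aucs, kappas = [], []
        for tr, te in splits:
            Xb, yb = _upsample(X[tr], y[tr], rng)
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed + gi, n_jobs=1, **params
            )
            clf.fit(Xb, yb == classes[1])
            prob = clf.predict_proba(X[te])[:, 1]
            aucs.append(roc_auc(prob, y[te] == classes[1]))
            kappas.append(cohen_kappa_score(y[te] == classes[1], prob >= 0.5))
        results.append((float(np.mean(kappas)), np.array(aucs), params))
    best_kappa, best_aucs, best_params = max(results, key=lambda r: r[0])
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1, **best_params)
    Xb, yb = _upsample(X, y, rng)
    final.fit(Xb, yb == classes[1])
    cv = CVResult(
        "rf_classifier",
        best_aucs,
        float(best_aucs.mean()),
        {"n_trees": n_trees, "kappa": best_kappa, **best_params},
        seed,
        [len(te) for _, te in splits],
    )
    return cv, final


def rf_cv_regressor(
    X,
    y,
    n_trees: int = 5000,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
):
    """Repeated k-fold random-forest regression; mean out-of-sample R2.

    Per-fold R2 is 1 - SSE/SST within the fold; the mean and per-fold
    values are retained.  Returns (CVResult, fitted model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * folds:
        raise ValueError("need n >= 2 * folds samples")
    if np.ptp(y) == 0:
        raise ValueError("constant target")
    splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    r2s = []
    sizes = []
    for tr, te in splitter.split(X):
        reg = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        reg.fit(X[tr], y[tr])
        r2s.append(explained_variance(y[te], reg.predict(X[te])))
        sizes.append(len(te))
    final = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(X, y)
    arr = np.array(r2s)
    cv = CVResult("rf_regressor", arr, float(arr.mean()), {"n_trees": n_trees}, seed, sizes)
    return cv, final


@dataclass
class RidgeResult:
    coefficients: np.ndarray
    covariate_coefficients: np.ndarray
    intercept: float
    penalty: float
    cv_mse: float


def _ridge_solve(X, Z, y, lam):
    """Least squares with penalty lam on X's coefficients only; Z (and the
    intercept) unpenalized.  Returns (beta_x, beta_z, intercept)."""
    n, p = X.shape
    D = np.column_stack([np.ones(n), Z, X])
    q = 1 + Z.shape[1]
    pen = np.zeros(D.shape[1])
    pen[q:] = lam
    A = D.T @ D + np.diag(pen)
    coef = np.linalg.solve(A, D.T @ y)
    return coef[q:], coef[1:q], coef[0]


def ridge_adjusted(
    X,
    y,
    covariates,
    seed: int = 0,
    folds: int = 10,
    n_lambdas: int = 100,
) -> RidgeResult:
    """Ridge on features with unpenalized covariates; penalty by k-fold CV.

    The grid spans six orders of magnitude (100 log-spaced values) around a
    data-driven scale; the penalty minimizing CV squared error is selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = len(y)
    if n <= 10:
        raise ValueError("need n > 10")
    full_cov = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(full_cov) < full_cov.shape[1]:
        raise ValueError("rank-deficient covariates")
    scale = np.trace(X.T @ X) / X.shape[1]
    lams = scale * np.logspace(-3, 3, n_lambdas)
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % folds
    errs = np.zeros(n_lambdas)
    for fi in range(folds):
        te = fold == fi
        tr = ~te
        for li, lam in enumerate(lams):
            bx, bz, b0 = _ridge_solve(X[tr], Z[tr], y[tr], lam)
            pred = b0 + Z[te] @ bz + X[te] @ bx
            errs[li] += np.sum((y[te] - pred) ** 2)
    best = int(np.argmin(errs))
    bx, bz, b0 = _ridge_solve(X, Z, y, lams[best])
    return RidgeResult(bx, bz, float(b0), float(lams[best]), float(errs[best] / n))


def importance_concordance(shap_scores, ridge_coefs) -> dict:
    """Pearson (and Spearman) correlation between per-feature attribution
    scores and ridge coefficients over a matched feature set."""
    a = np.asarray(shap_scores, dtype=float)
    b = np.asarray(ridge_coefs, dtype=float)
    if len(a) != len(b):
        raise ValueError("feature sets must match")
    if len(a) < 5:
        raise ValueError("need at least 5 matched features")
    r, p = stats.pearsonr(a, b)
    rho, sp = stats.spearmanr(a, b)
    return {"pearson_r": float(r), "pearson_p": float(p),
            "spearman_rho": float(rho), "spearman_p": float(sp)}
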