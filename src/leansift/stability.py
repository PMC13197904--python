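"""Bootstrap elastic-net stability selection of protein changes.

The mixing weight α (1 = lasso, 0 = ridge) and penalty λ are tuned jointly
by 10-fold cross-validation minimizing mean squared error, with the fold
assignment shared across the α grid. The tuned model is then refit on
bootstrap resamples of the subjects; a feature counts as selected in one
replicate iff its coefficient is nonzero, and features selected in more
than a frequency threshold (default 60%) of replicates are reported with
the median and IQR of their coefficients.

Conventions follow glmnet: the λ path is log-spaced down from the smallest
λ that zeroes every coefficient, and predictors are standardized before
penalization (recomputed inside each bootstrap replicate), with reported
coefficients back-transformed to the original predictor scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "lambda_path",
    "tune_elastic_net",
    "bootstrap_stability",
    "StabilitySelector",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale_safe, mean, scale_safe


def lambda_path(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                n_lambdas: int = 50, eps: float = 1e-2) -> np.ndarray:
    """glmnet-style log-spaced λ path for standardized X.

    λ_max is the smallest penalty zeroing all coefficients; for near-ridge
    mixes the l1_ratio in the denominator is floored at 0.001 (glmnet's own
    convention, since λ_max diverges as α → 0).
    """
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def tune_elastic_net(X: pd.DataFrame, y, alpha_grid=DEFAULT_ALPHA_GRID,
                     n_lambdas: int = 50, n_folds: int = 10, seed: int = 0):
    """Grid search (α × λ path) minimizing 10-fold CV mean squared error.

    Returns ``(l1_ratio, lam, cv_table)``; *cv_table* has one row per (α, λ)
    with the CV MSE. Fold assignment is fixed by *seed* and shared across α.
    """
    Xv = pd.DataFrame(X).to_numpy(float)
    yv = np.asarray(y, float)
    n = yv.size
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds}-fold CV")
    if n < 30:
        raise ValueError("need n >= 30 to tune")
    Xs, _, _ = _standardize(Xv)
    folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(Xs))
    rows = []
    best = (np.inf, None, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for l1_ratio in alpha_grid:
            lams = lambda_path(Xs, yv, l1_ratio, n_lambdas)
            mse = np.zeros(lams.size)
            for tr, te in folds:
                Xtr, mean, scale = _standardize(Xv[tr])
                Xte = (Xv[te] - mean) / scale
                # warm-start down the path: λ descends, so each solution
                # seeds the next (glmnet's pathwise strategy)
                net = ElasticNet(alpha=lams[0], l1_ratio=l1_ratio,
                                 max_iter=5_000, warm_start=True)
                for i, lam in enumerate(lams):
                    net.set_params(alpha=lam)
                    net.fit(Xtr, yv[tr])
                    pred = net.predict(Xte)
                    mse[i] += np.mean((yv[te] - pred) ** 2)
            mse /= len(folds)
            for lam, m in zip(lams, mse):
                rows.append({"l1_ratio": float(l1_ratio), "lambda": float(lam),
                             "cv_mse": float(m)})
                if m < best[0]:
                    best = (m, float(l1_ratio), float(lam))
    return best[1], best[2], pd.DataFrame(rows)


def bootstrap_stability(X: pd.DataFrame, y, l1_ratio: float, lam: float,
                        B: int = 1000, threshold: float = 0.6,
                        seed: int = 0, coef_summary: str = "all",
                        covariate_names=()) -> pd.DataFrame:
    """Selection frequencies over B bootstrap refits at fixed (α, λ).

    Subjects (rows) are resampled with replacement; standardization is
    recomputed inside each replicate, and coefficients are back-transformed
    to the original predictor scale. ``coef_summary='all'`` computes the
    median/IQR over all replicates including zeros (conservative);
    ``'nonzero'`` restricts to replicates where the feature was selected.

    Returns the full frequency table sorted by frequency; features above
    *threshold* carry ``reported=True``, covariates are tagged.
    """
    if coef_summary not in ("all", "nonzero"):
        raise ValueError("coef_summary must be 'all' or 'nonzero'")
    X = pd.DataFrame(X)
    Xv = X.to_numpy(float)
    yv = np.asarray(y, float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    coefs = np.zeros((B, p))
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        b = 0
        while b < B:
            idx = rng.integers(0, n, n)
            yb = yv[idx]
            if np.ptp(yb) == 0:
                skipped += 1
                if skipped > 10 * B:
                    raise RuntimeError("too many degenerate bootstrap draws")
                continue
            Xb, mean, scale = _standardize(Xv[idx])
            net = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5_000)
            net.fit(Xb, yb)
            coefs[b] = net.coef_ / scale
            b += 1
    selected = coefs != 0
    freq = selected.mean(axis=0)
    med = np.empty(p)
    q1 = np.empty(p)
    q3 = np.empty(p)
    for j in range(p):
        vals = coefs[:, j] if coef_summary == "all" else coefs[selected[:, j], j]
        if vals.size == 0:
            med[j] = q1[j] = q3[j] = 0.0
        else:
            q1[j], med[j], q3[j] = np.percentile(vals, [25, 50, 75])
    out = pd.DataFrame({
        "feature": X.columns, "frequency": freq, "median_beta": med,
        "iqr_lo": q1, "iqr_hi": q3,
        "is_covariate": [c in set(covariate_names) for c in X.columns],
    })
    out["reported"] = out["frequency"] > threshold
    out.attrs.update({"B": B, "threshold": threshold, "l1_ratio": l1_ratio,
                      "lambda": lam, "seed": seed,
                      "skipped_replicates": skipped})
    return out.sort_values("frequency", ascending=False,
                           kind="stable").reset_index(drop=True)


class StabilitySelector(BaseEstimator):
    """Tune-then-bootstrap elastic-net selection as a single estimator.

    After ``fit(X, y)``:

    Attributes
    ----------
    l1_ratio_, lambda_ : float
        CV-chosen mixing weight and penalty.
    stability_ : pandas.DataFrame
        Per-feature selection frequency and coefficient summary.
    selected_ : list
        Features with frequency above the reporting threshold.
    """

    def __init__(self, B: int = 1000, threshold: float = 0.6,
                 alpha_grid=DEFAULT_ALPHA_GRID, n_lambdas: int = 50,
                 n_folds: int = 10, coef_summary: str = "all",
                 covariate_names=(), random_state: int = 0):
        self.B = B
        self.threshold = threshold
        self.alpha_grid = alpha_grid
        self.n_lambdas = n_lambdas
        self.n_folds = n_folds
        self.coef_summary = coef_summary
        self.covariate_names = covariate_names
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        self.l1_ratio_, self.lambda_, self.cv_table_ = tune_elastic_net(
            X, y, alpha_grid=self.alpha_grid, n_lambdas=self.n_lambdas,
            n_folds=self.n_folds, seed=self.random_state)
        self.stability_ = bootstrap_stability(
            X, y, self.l1_ratio_, self.lambda_, B=self.B,
            threshold=self.threshold, seed=self.random_state,
            coef_summary=self.coef_summary,
            covariate_names=self.covariate_names)
        self.selected_ = list(
            self.stability_.loc[self.stability_["reported"], "feature"])
        return self
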