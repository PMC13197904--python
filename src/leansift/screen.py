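"""Residualized-outcome proteomic screen for LST retention.

The change in lean soft tissue is regressed on the change in fat mass; the
residual — LST change not explained by fat change — is the outcome of
interest. Baseline protein levels and six-month protein changes are then
screened as predictors of those residuals in per-protein linear models,
with Benjamini–Hochberg FDR control within each model family, optionally
adjusted for diet, age, height, and race/ethnicity, and stratified by sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ResidualOutcome",
    "compute_residuals",
    "univariate_screen",
    "multivariable_screen",
    "bh_adjust",
    "volcano_table",
    "ProteinScreen",
    "screen_covariates",
]


@dataclass
class ResidualOutcome:
    """Per-subject residualized LST change plus the fitted line."""

    table: pd.DataFrame     # d_lst, d_fm, fitted, residual (indexed by subject)
    slope: float
    intercept: float

    @property
    def residuals(self) -> pd.Series:
        return self.table["residual"]


def compute_residuals(d_lst, d_fm, index=None) -> ResidualOutcome:
    """OLS of ΔLST on ΔFM (with intercept); residuals are the screen outcome."""
    y = np.asarray(d_lst, float)
    x = np.asarray(d_fm, float)
    if y.shape != x.shape:
        raise ValueError("paired arrays must align")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("constant ΔFM: slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    table = pd.DataFrame({"d_lst": y, "d_fm": x, "fitted": fitted,
                          "residual": y - fitted}, index=index)
    return ResidualOutcome(table, slope, intercept)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


def _screen_core(X: np.ndarray, y: np.ndarray, n_fixed_params: int):
    """Per-column slope/SE/t/p of y on each column of X (already partialled).

    ``n_fixed_params`` counts parameters other than the protein slope
    (intercept + covariates) removed from the degrees of freedom.
    """
    n = y.size
    df = n - n_fixed_params - 1
    sxx = np.sum(X ** 2, axis=0)
    ok = sxx > 1e-12 * n
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    beta[ok] = (X[:, ok].T @ y) / sxx[ok]
    syy = float(y @ y)
    rss = syy - beta[ok] ** 2 * sxx[ok]
    rss = np.clip(rss, 0.0, None)
    se[ok] = np.sqrt(rss / df / sxx[ok])
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df, ok


def _screen_frame(proteins: pd.DataFrame, beta, se, t, p, n, family: str,
                  aliased=None) -> pd.DataFrame:
    res = pd.DataFrame({
        "protein": proteins.columns, "family": family, "beta": beta,
        "se": se, "t": t, "p": p, "n": n})
    res["q"] = np.nan
    finite = res["p"].notna()
    if finite.any():
        res.loc[finite, "q"] = bh_adjust(res.loc[finite, "p"])
    if aliased is not None and (~aliased).any():
        res.loc[~aliased, "family"] = family + ":aliased"
    return res


def univariate_screen(proteins: pd.DataFrame, residuals,
                      family: str = "delta:univariate",
                      min_n: int = 10) -> pd.DataFrame:
    """Per-protein OLS of LST residuals on a single protein predictor.

    *proteins* is subjects x proteins (baseline levels or Δ values);
    *residuals* aligns with its index. Complete cases per protein; proteins
    with fewer than *min_n* pairs get NaN results. BH q-values are computed
    within this call (one family).
    """
    y_all = np.asarray(residuals, float)
    P = proteins.to_numpy(float)
    if P.shape[0] != y_all.size:
        raise ValueError("protein matrix and residuals must align")
    if np.isnan(P).any():
        # complete-case per protein
        cols = []
        for j in range(P.shape[1]):
            m = ~np.isnan(P[:, j]) & ~np.isnan(y_all)
            if m.sum() < min_n:
                cols.append((np.nan,) * 4 + (int(m.sum()),))
                continue
            x = P[m, j] - P[m, j].mean()
            y = y_all[m] - y_all[m].mean()
            b, s, t, p, _, _ = _screen_core(x[:, None], y, 1)
            cols.append((b[0], s[0], t[0], p[0], int(m.sum())))
        beta, se, t, p, n = map(np.array, zip(*cols))
        return _screen_frame(proteins, beta, se, t, p, n, family)
    n = y_all.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} subjects")
    Xc = P - P.mean(axis=0)
    yc = y_all - y_all.mean()
    beta, se, t, p, _, _ = _screen_core(Xc, yc, 1)
    return _screen_frame(proteins, beta, se, t, p, n, family)


def multivariable_screen(proteins: pd.DataFrame, residuals,
                         covariates: pd.DataFrame,
                         family: str = "delta:multivariable") -> pd.DataFrame:
    """Per-protein OLS adjusted for covariates (diet, age, height, race/
    ethnicity), one protein at a time.

    Uses Frisch–Waugh–Lovell partialling: outcome and each protein are
    residualized on [1, covariates], giving coefficients, SEs and t-tests
    identical to the full per-protein multiple regression. A protein
    collinear with the covariates raises an error naming it.
    """
    y = np.asarray(residuals, float)
    C = covariates.to_numpy(float)
    if C.shape[0] != y.size or len(proteins) != y.size:
        raise ValueError("proteins, residuals and covariates must align")
    Z = np.column_stack([np.ones(y.size), C])
    q, r = np.linalg.qr(Z)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])))
    if rank < Z.shape[1]:
        diag = np.abs(np.diag(r))
        bad = [covariates.columns[i - 1] for i in range(1, Z.shape[1])
               if diag[i] <= 1e-10 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(
            f"collinear covariates (aliased columns: {bad})")
    P = proteins.to_numpy(float)
    k = Z.shape[1]
    if np.isnan(P).any() or np.isnan(y).any():
        # complete cases per protein (subjects missing that assay drop out)
        cols = []
        for j in range(P.shape[1]):
            m = ~np.isnan(P[:, j]) & ~np.isnan(y)
            if m.sum() < k + 10:
                cols.append((np.nan,) * 4 + (int(m.sum()),))
                continue
            qm, _ = np.linalg.qr(Z[m])
            My = y[m] - qm @ (qm.T @ y[m])
            MX = P[m, j] - qm @ (qm.T @ P[m, j])
            b, s, t, p, _, ok = _screen_core(MX[:, None], My, k)
            if not ok[0]:
                raise np.linalg.LinAlgError(
                    f"protein collinear with covariates: "
                    f"{proteins.columns[j]}")
            cols.append((b[0], s[0], t[0], p[0], int(m.sum())))
        beta, se, t, p, n = map(np.array, zip(*cols))
        return _screen_frame(proteins, beta, se, t, p, n, family)
    My = y - q @ (q.T @ y)
    MX = P - q @ (q.T @ P)
    beta, se, t, p, df, ok = _screen_core(MX, My, k)
    if (~ok).any():
        bad = list(proteins.columns[~ok])
        raise np.linalg.LinAlgError(
            f"protein(s) collinear with covariates: {bad}")
    return _screen_frame(proteins, beta, se, t, p, y.size, family)


def volcano_table(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Per-protein β, −log10 p, and 5%-FDR significance flag for plotting."""
    out = results[["protein", "family", "beta", "p", "q"]].copy()
    out["neg_log10_p"] = -np.log10(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def screen_covariates(subjects: pd.DataFrame,
                      drop_constant: bool = True) -> pd.DataFrame:
    """Adjustment design for multivariable models: diet, age, height, and
    race/ethnicity indicators (White non-Hispanic reference).

    Indicator levels with no observations in this stratum produce constant
    columns; by default they are dropped (they carry no information and
    would otherwise make the design singular).
    """
    from .prediction import design_from_subjects

    out = design_from_subjects(subjects)
    out["diet_hlc"] = (subjects["diet"] == "HLC").astype(float)
    out["age"] = subjects["age"].astype(float)
    out["height_cm"] = subjects["height_cm"].astype(float)
    if drop_constant:
        keep = out.nunique() > 1
        out = out.loc[:, keep]
    return out


class ProteinScreen(BaseEstimator):
    """Sklearn-style wrapper for the per-protein residual screen.

    Parameters
    ----------
    family : str
        Label recorded on every result row, e.g. ``"delta:multivariable"``.
    fdr : float
        FDR level used for the significance flag in ``volcano_``.

    After ``fit(X, y[, covariates])``:

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per protein: beta, se, t, p, q, n.
    volcano_ : pandas.DataFrame
        Plot-ready table with −log10 p and the FDR flag.
    significant_ : list
        Proteins with q < fdr.
    """

    def __init__(self, family: str = "delta:univariate", fdr: float = 0.05):
        self.family = family
        self.fdr = fdr

    def fit(self, X: pd.DataFrame, y, covariates: pd.DataFrame | None = None):
        if covariates is None:
            self.results_ = univariate_screen(X, y, family=self.family)
        else:
            self.results_ = multivariable_screen(X, y, covariates,
                                                 family=self.family)
        self.volcano_ = volcano_table(self.results_, fdr=self.fdr)
        sig = self.results_["q"] < self.fdr
        self.significant_ = list(self.results_.loc[sig, "protein"])
        return self
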