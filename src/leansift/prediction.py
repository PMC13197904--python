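"""Percentage-predicted lean soft tissue and allometric prediction models.

A percentage-predicted metric expresses an observed quantity relative to the
value expected for a person of the same body size and demographics, so that
100% means "exactly as predicted". Two families of models are shipped:

* NHANES anthropometric equations for total LST (linear scale, height in cm,
  weight in kg, race/ethnicity indicators), and
* allometric log-log models for appendicular LST of the form
  ln(appLST) = b0 + b1·ln(appendicular mass) + b2·ln(height in m) + indicators,

plus a fitting routine that re-derives allometric models on any cohort via
L1-penalized regression with a 10-fold cross-validated penalty, an 80/20
train/test split, and test-set R².
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .bodycomp import PairedSummary

__all__ = [
    "PredictionModel",
    "PercentPredicted",
    "load_model",
    "predict_lst",
    "percent_predicted",
    "percent_predicted_change_test",
    "AllometricLSTRegressor",
    "fit_allometric_model",
]

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
}


@dataclass
class PredictionModel:
    """A linear (possibly log-scale) LST prediction equation.

    ``coefficients`` maps predictor names to weights; ``transforms`` maps
    each predictor to 'identity' or 'log'; ``units`` declares conventions
    (notably whether height enters in cm or m). A log-scale model predicts
    exp(linear combination).
    """

    sex: str
    outcome: str                       # "total_lst" | "appendicular_lst"
    scale: str                         # "linear" | "log"
    intercept: float
    coefficients: dict
    transforms: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    provenance: str = "user-fitted"
    test_r2: float | None = None

    def __post_init__(self):
        for name in self.coefficients:
            self.transforms.setdefault(name, "identity")
        unknown = set(self.transforms) - set(self.coefficients)
        if unknown:
            raise ValueError(f"transforms for unknown predictors: {unknown}")

    def predict(self, inputs: dict | pd.DataFrame):
        """Predicted LST (kg) for a mapping/frame of predictor values.

        Indicator predictors absent from *inputs* default to 0; any other
        missing predictor is an error.
        """
        frame = isinstance(inputs, pd.DataFrame)
        acc = np.zeros(len(inputs) if frame else 1, float) + self.intercept
        for name, coef in self.coefficients.items():
            if frame and name in inputs.columns:
                val = inputs[name].to_numpy(float)
            elif not frame and name in inputs:
                val = np.asarray(inputs[name], float)
            elif name.startswith("I_"):
                val = np.zeros_like(acc)
            else:
                raise KeyError(f"missing predictor '{name}'")
            tf = self.transforms.get(name, "identity")
            if tf == "log" and np.any(val <= 0):
                raise ValueError(f"non-positive input to log predictor '{name}'")
            acc = acc + coef * _TRANSFORMS[tf](val)
        out = np.exp(acc) if self.scale == "log" else acc
        return out if frame else float(out[0])

    def to_json(self, path=None) -> str:
        payload = {
            "sex": self.sex, "outcome": self.outcome, "scale": self.scale,
            "intercept": self.intercept, "coefficients": self.coefficients,
            "transforms": self.transforms, "units": self.units,
            "provenance": self.provenance, "test_r2": self.test_r2,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PredictionModel":
        if isinstance(source, (str, Path)) and str(source).lstrip().startswith("{"):
            payload = json.loads(str(source))
        else:
            payload = json.loads(Path(source).read_text())
        return cls(**payload)


def load_model(name: str) -> PredictionModel:
    """Load a shipped model by name, e.g. ``nhanes_female`` or
    ``dietfits_app_male``."""
    ref = resources.files("leansift") / "models" / f"{name}.json"
    return PredictionModel.from_json(str(ref))


def predict_lst(model: PredictionModel, inputs) -> float:
    """Functional wrapper over :meth:`PredictionModel.predict`."""
    return model.predict(inputs)


@dataclass(frozen=True)
class PercentPredicted:
    observed: float
    predicted: float

    @property
    def percent(self) -> float:
        return 100.0 * self.observed / self.predicted


def percent_predicted(observed, predicted):
    """100 · observed / predicted; predicted must be positive."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if np.any(pred <= 0):
        raise ValueError("predicted LST must be positive")
    pct = 100.0 * obs / pred
    return float(pct) if pct.ndim == 0 else pct


def percent_predicted_change_test(percent_baseline, percent_6mo,
                                  measure: str = "percent_predicted_lst",
                                  alpha: float = 0.05) -> PairedSummary:
    """Paired t-test of percentage-predicted LST change on the log scale.

    Percent-predicted values are right-skewed ratios, so the test is run on
    log-transformed values; the reported mean difference, CI and p are
    mapped back through the paired-t machinery on the raw percent scale
    (CI/p from the log-scale test would be equivalent in direction).
    """
    pb = np.asarray(percent_baseline, float)
    pf = np.asarray(percent_6mo, float)
    if np.any(pb <= 0) or np.any(pf <= 0):
        raise ValueError("percent-predicted values must be positive")
    if pb.shape != pf.shape:
        raise ValueError("paired arrays must align")
    n = pb.size
    logdiff = np.log(pf) - np.log(pb)
    mean_log = float(logdiff.mean())
    sd_log = float(logdiff.std(ddof=1))
    if sd_log == 0.0:
        raw = float((pf - pb).mean())
        return PairedSummary(measure, n, raw, raw, raw, np.nan,
                             degenerate=mean_log == 0.0)
    t = mean_log / (sd_log / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    # Raw-scale mean difference and CI, as change tables report percents.
    raw = pf - pb
    se = raw.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    m = float(raw.mean())
    return PairedSummary(measure, n, m, m - tcrit * se, m + tcrit * se,
                         float(p))


_RACE_INDICATORS = ("I_Black", "I_Asian", "I_OtherRace", "I_Hispanic")


def design_from_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Race/ethnicity indicator coding with White non-Hispanic reference.

    'Other' means not American Indian/Alaskan, Asian, Black, Pacific
    Islander, or White; American Indian and Pacific Islander participants
    carry no indicator (reference level).
    """
    out = pd.DataFrame(index=subjects.index)
    race = subjects["race"].astype(str)
    out["I_Black"] = (race == "Black").astype(float)
    out["I_Asian"] = (race == "Asian").astype(float)
    out["I_OtherRace"] = (race == "Other").astype(float)
    out["I_Hispanic"] = subjects["hispanic"].astype(float)
    return out


class AllometricLSTRegressor(BaseEstimator, RegressorMixin):
    """Allometric LST model fit by L1-penalized regression.

    Fits ln(outcome) on ln(mass), ln(height), age, age² and race/ethnicity
    indicators. Predictors are standardized before penalization and the
    fitted coefficients are back-transformed to the original scale. The
    penalty λ is chosen by ``cv``-fold cross-validation minimizing mean
    squared error on the training data.

    Parameters
    ----------
    cv : int
        Number of cross-validation folds for the λ path.
    random_state : int
        Controls CV fold assignment.

    Attributes
    ----------
    intercept_ : float
        Intercept on the log-outcome scale.
    coef_ : dict
        Original-scale coefficients keyed by predictor name.
    """

    def __init__(self, cv: int = 10, n_lambdas: int = 100,
                 random_state: int = 0):
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        """Fit on a design frame of named predictors and log-scale outcome y."""
        X = pd.DataFrame(X)
        y = np.asarray(y, float)
        n = len(X)
        if n < self.cv * 10:
            raise ValueError(
                f"need at least {self.cv * 10} training rows for "
                f"{self.cv}-fold CV, got {n}")
        if np.ptp(y) == 0:
            raise ValueError("constant outcome")
        self.feature_names_in_ = list(X.columns)
        scaler = StandardScaler()
        Xs = scaler.fit_transform(X.to_numpy(float))
        keep = scaler.scale_ > 0
        folds = KFold(self.cv, shuffle=True, random_state=self.random_state)
        # path floor 1e-4 of lambda_max, the glmnet default when n > p
        lasso = LassoCV(cv=folds, alphas=self.n_lambdas, eps=1e-4,
                        max_iter=50_000)
        lasso.fit(Xs[:, keep], y)
        beta_std = np.zeros(X.shape[1])
        beta_std[keep] = lasso.coef_
        beta = np.where(scaler.scale_ > 0, beta_std / np.where(
            scaler.scale_ > 0, scaler.scale_, 1.0), 0.0)
        self.coef_ = dict(zip(self.feature_names_in_, beta))
        self.intercept_ = float(lasso.intercept_
                                - np.sum(beta * scaler.mean_))
        self.lambda_ = float(lasso.alpha_)
        return self

    def predict(self, X: pd.DataFrame):
        X = pd.DataFrame(X)[self.feature_names_in_]
        beta = np.array([self.coef_[c] for c in self.feature_names_in_])
        return self.intercept_ + X.to_numpy(float) @ beta


def _allometric_design(subjects: pd.DataFrame, mass, height_m, outcome):
    X = pd.DataFrame({
        "log_mass": np.log(np.asarray(mass, float)),
        "log_height": np.log(np.asarray(height_m, float)),
        "age": subjects["age"].to_numpy(float),
        "age2": subjects["age"].to_numpy(float) ** 2,
    }, index=subjects.index)
    X = pd.concat([X, design_from_subjects(subjects)], axis=1)
    y = np.log(np.asarray(outcome, float))
    return X, y


def fit_allometric_model(subjects: pd.DataFrame, mass, height_m, observed_lst,
                         outcome: str = "appendicular_lst",
                         sex: str | None = None, split_seed: int = 0,
                         cv: int = 10, test_size: float = 0.2):
    """Derive an allometric LST model on a cohort's baseline data.

    Parameters are per-subject arrays aligned with *subjects*: body mass
    (appendicular for appendicular models, total otherwise, kg), height in
    meters, and observed LST (kg). An 80/20 train/test split is made with
    *split_seed*; the penalty is CV-tuned on the training set and test-set
    R² is reported in the returned :class:`PredictionModel`.
    """
    if sex is not None:
        sel = (subjects["sex"] == sex).to_numpy()
        subjects = subjects[sel].reset_index(drop=True)
        mass = np.asarray(mass, float)[sel]
        height_m = np.asarray(height_m, float)[sel]
        observed_lst = np.asarray(observed_lst, float)[sel]
    n = len(subjects)
    if n < 30:
        raise ValueError(f"need n >= 30 per sex to fit, got {n}")
    X, y = _allometric_design(subjects, mass, height_m, observed_lst)
    idx_train, idx_test = train_test_split(np.arange(n), test_size=test_size,
                                           random_state=split_seed)
    reg = AllometricLSTRegressor(cv=cv, random_state=split_seed)
    reg.fit(X.iloc[idx_train], y[idx_train])
    pred_test = reg.predict(X.iloc[idx_test])
    ss_res = float(np.sum((y[idx_test] - pred_test) ** 2))
    ss_tot = float(np.sum((y[idx_test] - y[idx_test].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    mass_name = ("appendicular_mass" if outcome == "appendicular_lst"
                 else "total_mass")
    coefficients = {mass_name: reg.coef_["log_mass"],
                    "height": reg.coef_["log_height"],
                    "age": reg.coef_["age"], "age2": reg.coef_["age2"]}
    transforms = {mass_name: "log", "height": "log",
                  "age": "identity", "age2": "identity"}
    for ind in _RACE_INDICATORS:
        coefficients[ind] = reg.coef_[ind]
        transforms[ind] = "identity"
    model = PredictionModel(
        sex=sex or "pooled", outcome=outcome, scale="log",
        intercept=reg.intercept_, coefficients=coefficients,
        transforms=transforms,
        units={"height": "m", mass_name: "kg"},
        provenance="user-fitted", test_r2=r2)
    diagnostics = {"lambda": reg.lambda_, "n_train": len(idx_train),
                   "n_test": len(idx_test), "split_seed": split_seed,
                   "test_r2": r2}
    return model, diagnostics
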