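"""Calibration experiments: recovery and error-control checks that the
pipeline is expected to pass on synthetic cohorts with known ground truth.

Each driver runs the relevant stage of the package end to end on freshly
generated data and returns the measured rate or value. They are used by the
test suite and by ``scripts/acceptance.py``; sizes are arguments so callers
can trade Monte-Carlo precision against runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bodycomp import adjust_change
from .cohort import CohortConfig, simulate_cohort, simulate_npx, simulate_screen_dataset
from .npx import NPXMatrix, exclude_failed_samples, filter_proteins_by_lod, \
    impute_lod, resolve_redundant_panels
from .prediction import AllometricLSTRegressor, _allometric_design
from .screen import compute_residuals, multivariable_screen, screen_covariates
from .stability import bootstrap_stability, tune_elastic_net

__all__ = [
    "PUBLISHED_MEAN_CHANGES",
    "ffat_adjusted_mean_changes",
    "qc_protein_count",
    "qc_exclusion_percent",
    "fdr_control_experiment",
    "plant_recovery_top_rate",
    "bootstrap_recovery_rate",
    "allometric_recovery_rate",
]

#: Published six-month mean changes (kg) in the pooled diet-intervention
#: cohort, by sex and region: (ΔLST, ΔFM). Inputs for the linear FFAT
#: adjustment check.
PUBLISHED_MEAN_CHANGES = {
    ("total", "female"): (-1.61, -4.28),
    ("total", "male"): (-2.26, -4.92),
    ("appendicular", "female"): (-0.80, -2.09),
    ("appendicular", "male"): (-1.02, -1.87),
}


def ffat_adjusted_mean_changes(mean_changes=None) -> dict:
    """Apply aLST = LST − 0.176·FM linearly to per-sex mean changes.

    Returns {(region, sex): adjusted mean change rounded to 2 dp}.
    """
    mean_changes = mean_changes or PUBLISHED_MEAN_CHANGES
    return {key: round(float(adjust_change(d_lst, d_fm)), 2)
            for key, (d_lst, d_fm) in mean_changes.items()}


def qc_protein_count(seed: int = 0, n_subjects: int = 120) -> int:
    """Proteins surviving LOD filtering and panel resolution on a panel
    constructed with 276 assays: 24 majority-censored, 10 duplicated."""
    cfg = CohortConfig(n_subjects=n_subjects, n_proteins=266,
                       n_heavy_censored=24, n_duplicated=10,
                       npx_dropout=0, seed=seed)
    _, _, truth = simulate_cohort(cfg)
    matrix = NPXMatrix(simulate_npx(cfg, truth))
    matrix, _ = filter_proteins_by_lod(matrix)
    matrix = impute_lod(matrix)
    matrix, _ = resolve_redundant_panels(matrix)
    return matrix.n_proteins


def qc_exclusion_percent(seed: int = 0) -> float:
    """Percent of cells removed by sample QC on a 242-protein x 708-sample
    matrix carrying 2281 vendor flags."""
    cfg = CohortConfig(n_subjects=354, npx_dropout=0, n_proteins=242,
                       n_heavy_censored=0, n_duplicated=0,
                       qc_fail_cells=2281, n_outlier_samples=0, seed=seed)
    _, _, truth = simulate_cohort(cfg)
    matrix = NPXMatrix(simulate_npx(cfg, truth))
    out, _ = exclude_failed_samples(matrix)
    return 100.0 * out.exclusion_log[-1]["fraction_removed"]


def _null_config(n: int, n_proteins: int = 242) -> CohortConfig:
    return CohortConfig(n_subjects=n, n_proteins=n_proteins,
                        n_heavy_censored=0, n_duplicated=0, npx_dropout=0,
                        planted_effects=[])


def fdr_control_experiment(n_sims: int = 200, n: int = 200,
                           n_proteins: int = 242, fdr: float = 0.05,
                           seed: int = 0) -> float:
    """Mean false-discovery proportion of the Δ-protein screen under the
    global null (no protein associated with the residual)."""
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_sims):
        cfg = _null_config(n, n_proteins)
        _, changes, delta, _ = simulate_screen_dataset(
            cfg, seed=int(rng.integers(2**31)))
        ro = compute_residuals(changes["d_lst"], changes["d_fm"])
        from .screen import univariate_screen
        res = univariate_screen(delta, ro.residuals.to_numpy())
        n_disc = int((res["q"] < fdr).sum())
        fdps.append(n_disc / max(n_disc, 1) if n_disc else 0.0)
    return float(np.mean(fdps))


def _planted_config(n: int, gamma: float = 1.2,
                    n_proteins: int = 242) -> CohortConfig:
    """Single dominant planted protein-change effect (the DLK1-like
    marker), all other proteins null."""
    return CohortConfig(n_subjects=n, n_proteins=n_proteins,
                        n_heavy_censored=0, n_duplicated=0, npx_dropout=0,
                        planted_effects=[(0, gamma)])


def plant_recovery_top_rate(n_seeds: int = 200, n: int = 227,
                            gamma: float = 1.2, seed: int = 0) -> float:
    """Fraction of simulations in which the planted protein has the
    smallest p in the covariate-adjusted Δ-protein screen."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        cfg = _planted_config(n, gamma)
        subjects, changes, delta, _ = simulate_screen_dataset(
            cfg, seed=int(rng.integers(2**31)))
        ro = compute_residuals(changes["d_lst"], changes["d_fm"])
        covs = screen_covariates(subjects.set_index("subject_id"))
        res = multivariable_screen(delta, ro.residuals.to_numpy(), covs)
        hits += res.nsmallest(1, "p")["protein"].item() == "PROT_0000"
    return hits / n_seeds


def bootstrap_recovery_rate(n_seeds: int = 50, n: int = 227, B: int = 200,
                            gamma: float = 1.2, threshold: float = 0.6,
                            seed: int = 0) -> float:
    """Fraction of simulations in which the planted protein exceeds the
    bootstrap selection-frequency threshold at the CV-tuned penalty."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        cfg = _planted_config(n, gamma)
        subjects, changes, delta, _ = simulate_screen_dataset(cfg, seed=s)
        ro = compute_residuals(changes["d_lst"], changes["d_fm"])
        covs = screen_covariates(subjects.set_index("subject_id"))
        X = pd.concat([delta, covs.set_axis(delta.index)], axis=1)
        y = ro.residuals.to_numpy()
        l1, lam, _ = tune_elastic_net(X, y, alpha_grid=(0.5,),
                                      n_lambdas=30, seed=s % 10_000)
        st = bootstrap_stability(X, y, l1, lam, B=B, threshold=threshold,
                                 seed=s % 10_000,
                                 covariate_names=tuple(covs.columns))
        freq = st.set_index("feature").loc["PROT_0000", "frequency"]
        hits += freq > threshold
    return hits / n_seeds


def allometric_recovery_rate(n_seeds: int = 100, n: int = 466,
                             noise_sd: float = 0.02, tol: float = 0.05,
                             seed: int = 0) -> float:
    """Fraction of simulated cohorts for which the penalized allometric fit
    recovers both exponents of a known log-linear law within *tol*.

    Cohorts use an NHANES-like within-sex height spread (SD 7.1 cm) and the
    published female law: ln(appLST) = 0.33 + 0.60·ln(mass) + 1.03·ln(h).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        r = np.random.default_rng(s)
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)], "sex": "female",
            "age": r.uniform(18, 50, n),
            "height_cm": r.normal(164, 7.1, n),
            "race": r.choice(["White", "Black", "Other", "Asian"], n,
                             p=[0.75, 0.04, 0.13, 0.08]),
            "hispanic": r.integers(0, 2, n)})
        mass = np.exp(r.normal(np.log(38), 0.15, n))
        h = subjects["height_cm"].to_numpy() / 100
        ib = (subjects["race"] == "Black").to_numpy(float)
        io = (subjects["race"] == "Other").to_numpy(float)
        lst = np.exp(0.33 + 0.60 * np.log(mass) + 1.03 * np.log(h)
                     + 0.02 * ib + 0.02 * io + r.normal(0, noise_sd, n))
        X, y = _allometric_design(subjects, mass, h, lst)
        reg = AllometricLSTRegressor(random_state=s % 10_000).fit(X, y)
        hits += (abs(reg.coef_["log_mass"] - 0.60) <= tol
                 and abs(reg.coef_["log_height"] - 1.03) <= tol)
    return hits / n_seeds
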