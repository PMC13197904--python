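"""DXA compartment accounting and paired change statistics.

DXA reports three molecular compartments — fat mass (FM), lean soft tissue
(LST) and bone mineral content (BMC) — but LST is not skeletal muscle: it
includes the fat-free fraction of adipose tissue (FFAT, the ~15% of adipose
tissue that is water, protein and mineral). Because DXA books FFAT under
LST, losing adipose tissue deflates measured LST even when no muscle is
lost. The adjusted measure

    aLST = LST − 0.176 · FM

removes that bias (adipose tissue = FM / 0.85, FFAT = adipose − FM ≈
0.176·FM). The adjustment is linear, so it applies equally to levels and to
six-month changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdjustedComp",
    "PairedSummary",
    "FFAT_COEF",
    "ffat_adjust",
    "regional_totals",
    "paired_change_summary",
    "loss_proportions",
    "diet_sensitivity",
    "tee_sensitivity",
    "sex_summary_table",
]

#: FFAT per kg of FM. The exact adipose-composition ratio is
#: 0.15/0.85 = 0.17647…; 0.176 is the rounded operator used throughout.
FFAT_COEF = 0.176
FM_FRACTION_OF_ADIPOSE = 0.85

APPENDICULAR_REGIONS = ("arm_L", "arm_R", "leg_L", "leg_R")


@dataclass(frozen=True)
class AdjustedComp:
    aLST: float
    FFAT: float
    adipose_tissue: float


@dataclass
class PairedSummary:
    measure: str
    n: int
    mean_diff: float
    ci_lo: float
    ci_hi: float
    p: float
    degenerate: bool = False
    median_prop: float | None = None
    iqr_lo: float | None = None
    iqr_hi: float | None = None
    n_excluded: int = 0


def ffat_adjust(lst, fm, coef: float = FFAT_COEF):
    """FFAT-corrected lean soft tissue from DXA LST and FM (kg).

    Accepts scalars or arrays; negative masses are a domain error.
    """
    lst = np.asarray(lst, float)
    fm = np.asarray(fm, float)
    if np.any(lst < 0) or np.any(fm < 0):
        raise ValueError("LST and FM must be non-negative")
    adipose = fm / FM_FRACTION_OF_ADIPOSE
    ffat = adipose - fm
    alst = lst - coef * fm
    if alst.ndim == 0:
        return AdjustedComp(float(alst), float(ffat), float(adipose))
    return AdjustedComp(alst, ffat, adipose)


def adjust_change(d_lst, d_fm, coef: float = FFAT_COEF):
    """Apply the FFAT correction linearly to changes: ΔaLST = ΔLST − coef·ΔFM."""
    return np.asarray(d_lst, float) - coef * np.asarray(d_fm, float)


def regional_totals(scan: pd.DataFrame) -> pd.DataFrame:
    """Total and appendicular (arms+legs only) mass per compartment.

    *scan* is long format with columns region, lst_kg, fm_kg, bmc_kg (one
    subject-timepoint, or grouped by any id columns present).
    """
    comps = ["lst_kg", "fm_kg", "bmc_kg"]
    group_cols = [c for c in ("subject_id", "timepoint") if c in scan.columns]
    app = scan[scan["region"].isin(APPENDICULAR_REGIONS)]
    if group_cols:
        total = scan.groupby(group_cols, sort=True)[comps].sum()
        appendicular = (app.groupby(group_cols, sort=True)[comps].sum()
                        .reindex(total.index, fill_value=0.0))
    else:
        total = scan[comps].sum().to_frame().T
        appendicular = app[comps].sum().to_frame().T
    total = total.add_suffix("_total")
    appendicular = appendicular.add_suffix("_app")
    out = pd.concat([total, appendicular], axis=1)
    out["mass_total"] = out[[c + "_total" for c in comps]].sum(axis=1)
    out["mass_app"] = out[[c + "_app" for c in comps]].sum(axis=1)
    return out.reset_index() if group_cols else out


def paired_change_summary(baseline, followup, measure: str = "",
                          alpha: float = 0.05) -> PairedSummary:
    """Mean paired difference (follow-up − baseline) with Student-t CI and p."""
    baseline = np.asarray(baseline, float)
    followup = np.asarray(followup, float)
    if baseline.shape != followup.shape:
        raise ValueError("baseline and follow-up must be paired (same length)")
    n = baseline.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = followup - baseline
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedSummary(measure, n, mean, mean, mean, np.nan,
                             degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    tstat = mean / se
    p = 2 * stats.t.sf(abs(tstat), n - 1)
    return PairedSummary(measure, n, mean, mean - tcrit * se,
                         mean + tcrit * se, float(p))


def loss_proportions(d_compartment, d_total_mass):
    """Per-subject % of total mass change attributable to a compartment.

    Returns ``(median, (q1, q3), n_excluded)``; subjects with zero total-mass
    change are excluded (the proportion is undefined for them). Quartiles use
    linear interpolation.
    """
    d_comp = np.asarray(d_compartment, float)
    d_tot = np.asarray(d_total_mass, float)
    if d_comp.shape != d_tot.shape:
        raise ValueError("per-subject arrays must align")
    keep = d_tot != 0
    n_excluded = int((~keep).sum())
    props = 100.0 * d_comp[keep] / d_tot[keep]
    if props.size == 0:
        return np.nan, (np.nan, np.nan), n_excluded
    q1, med, q3 = np.percentile(props, [25, 50, 75])
    return float(med), (float(q1), float(q3)), n_excluded


def diet_sensitivity(changes: pd.DataFrame, value_cols=("d_lst",),
                     prop_cols=(), group_col: str = "diet") -> pd.DataFrame:
    """Between-diet comparison: Welch t for absolute changes, Wilcoxon
    rank-sum for loss proportions. One row per measure."""
    groups = sorted(changes[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 diet groups, found {groups}")
    a = changes[changes[group_col] == groups[0]]
    b = changes[changes[group_col] == groups[1]]
    rows = []
    for col in value_cols:
        t, p = stats.ttest_ind(a[col], b[col], equal_var=False)
        rows.append({"measure": col, "test": "welch_t",
                     "group_a": groups[0], "group_b": groups[1],
                     "mean_a": a[col].mean(), "mean_b": b[col].mean(),
                     "stat": float(t), "p": float(p)})
    for col in prop_cols:
        x, y = a[col].dropna(), b[col].dropna()
        method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"measure": col, "test": "wilcoxon_ranksum",
                     "group_a": groups[0], "group_b": groups[1],
                     "mean_a": x.median(), "mean_b": y.median(),
                     "stat": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def tee_sensitivity(d_lst, tee_3mo, tee_6mo, diet) -> pd.DataFrame:
    """OLS of ΔLST on mean(TEE 3-mo, 6-mo) and a diet indicator.

    Returns a coefficient table (term, coef, se, t, p). Rows with missing
    TEE at either visit are dropped.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"d_lst": np.asarray(d_lst, float),
                       "tee_3mo": np.asarray(tee_3mo, float),
                       "tee_6mo": np.asarray(tee_6mo, float),
                       "diet": np.asarray(diet)}).dropna()
    df["tee_mean"] = (df["tee_3mo"] + df["tee_6mo"]) / 2.0
    diet_levels = sorted(df["diet"].unique())
    df["diet_ind"] = (df["diet"] == diet_levels[-1]).astype(float)
    X = sm.add_constant(df[["tee_mean", "diet_ind"]])
    fit = sm.OLS(df["d_lst"], X).fit()
    return pd.DataFrame({"term": X.columns, "coef": fit.params.values,
                         "se": fit.bse.values, "t": fit.tvalues.values,
                         "p": fit.pvalues.values})


def sex_summary_table(subjects: pd.DataFrame, scans: pd.DataFrame,
                      region: str = "total",
                      ffat_coef: float = FFAT_COEF) -> pd.DataFrame:
    """Published-style change table, stratified by sex.

    For ``region='total'`` rows are total mass, FM, LST, aLST; for
    ``region='appendicular'`` the appendicular equivalents. Each row carries
    the paired mean difference (6 mo − baseline), 95% CI, p, and the
    median (IQR) percent of total mass loss.
    """
    totals = regional_totals(scans)
    wide = totals.pivot(index="subject_id", columns="timepoint",
                        values=[c for c in totals.columns
                                if c not in ("subject_id", "timepoint")])
    suffix = "_total" if region == "total" else "_app"
    mass_col = "mass_total" if region == "total" else "mass_app"
    meta = subjects.set_index("subject_id").loc[wide.index]

    rows = []
    for sex in ("female", "male"):
        sel = meta["sex"] == sex
        if not sel.any():
            continue
        sub = wide[sel.to_numpy()]

        def delta(col):
            return (sub[(col, "6mo")] - sub[(col, "baseline")]).to_numpy()

        d_mass = delta(mass_col)
        d_fm = delta("fm_kg" + suffix)
        d_lst = delta("lst_kg" + suffix)
        d_alst = adjust_change(d_lst, d_fm, ffat_coef)
        measures = [("mass", d_mass), ("fm", d_fm), ("lst", d_lst),
                    ("alst", d_alst)]
        for name, d in measures:
            summ = paired_change_summary(np.zeros_like(d), d, measure=name)
            row = {"region": region, "sex": sex, "measure": name,
                   "n": summ.n, "mean_diff": summ.mean_diff,
                   "ci_lo": summ.ci_lo, "ci_hi": summ.ci_hi, "p": summ.p}
            # Proportions are always of *total* mass loss, including for the
            # appendicular-mass row; the total-mass row itself has none.
            if not (region == "total" and name == "mass"):
                med, (q1, q3), nex = loss_proportions(d, delta("mass_total"))
                row.update({"median_prop": med, "iqr_lo": q1, "iqr_hi": q3,
                            "n_prop_excluded": nex})
            rows.append(row)
    return pd.DataFrame(rows)
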