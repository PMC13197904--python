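"""Synthetic DIETFITS-like cohorts for testing the lean-soft-tissue pipeline.

The generator emulates the data structure of a two-arm diet-based weight-loss
trial: per-participant demographics, paired (baseline / 6-mo) regional DXA
scans, and an Olink-style NPX proteomic matrix with limit-of-detection
censoring, cross-panel assay redundancy, QC failures, outlier samples, and
planted protein–residual associations with known ground truth.

Sex-specific defaults reproduce the published cohort margins: for example
female total lean soft tissue 49.0 ± 6.1 kg, fat mass 35.4 ± 6.8 kg, and a
mean six-month total-mass change of −5.9 kg (females) / −7.18 kg (males).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_npx",
    "simulate_screen_dataset",
    "write_cohort",
]

APPENDICULAR_REGIONS = ("arm_L", "arm_R", "leg_L", "leg_R")
REGIONS = APPENDICULAR_REGIONS + ("trunk", "head")

PANELS = ("Cardiovascular_II", "Cardiovascular_III", "Inflammation")

# Within-appendicular split: arms carry ~27% of limb mass, legs ~73%,
# shared equally between left and right.
_ARM_SHARE = 0.27
# Head share of the non-appendicular compartment (rough anthropometry;
# the head is never involved in any downstream statistic).
_HEAD_LST_SHARE = 0.12
_HEAD_FM_SHARE = 0.03
_HEAD_BMC_SHARE = 0.20


def _sex_dict(female: float, male: float) -> dict[str, float]:
    return {"female": female, "male": male}


@dataclass
class CohortConfig:
    """Tunable description of the simulated trial population.

    All masses are kg, heights cm, ages years, NPX values log2 relative
    abundance. Per-sex parameters are ``{"female": ..., "male": ...}`` maps.
    """

    n_subjects: int = 374
    female_fraction: float = 0.607
    age_mean: float = 39.4
    age_sd: float = 6.7
    age_range: tuple[float, float] = (18.0, 50.0)
    bmi_mean: dict = field(default_factory=lambda: _sex_dict(32.1, 32.5))
    bmi_sd: dict = field(default_factory=lambda: _sex_dict(3.2, 3.3))
    bmi_range: tuple[float, float] = (28.0, 40.0)
    height_mean: dict = field(default_factory=lambda: _sex_dict(164.4, 176.8))
    height_sd: dict = field(default_factory=lambda: _sex_dict(6.4, 6.9))
    bodyfat_mean: dict = field(default_factory=lambda: _sex_dict(40.6, 30.1))
    bodyfat_sd: dict = field(default_factory=lambda: _sex_dict(4.0, 4.8))
    race_probs: dict = field(default_factory=lambda: {
        "White": 0.733, "Other": 0.127, "Asian": 0.092, "Black": 0.038,
        "AmericanIndian": 0.005, "PacificIslander": 0.005,
    })
    hispanic_prob: float = 0.215
    diet_hlc_prob: float = 0.519
    mass_change_mean: dict = field(default_factory=lambda: _sex_dict(-5.9, -7.18))
    mass_change_sd: dict = field(default_factory=lambda: _sex_dict(4.7, 6.3))
    fm_fraction_of_loss: dict = field(default_factory=lambda: _sex_dict(0.725, 0.685))
    fm_noise_sd: float = 0.4
    bmc_change_sd: float = 0.05
    residual_sd: float = 0.7
    # Baseline appendicular fractions of each compartment (published margins:
    # female LST 21.1/49.0, FM 17.1/35.4; male LST 30.6/67.8, FM 12.1/30.8).
    app_lst_fraction: dict = field(default_factory=lambda: _sex_dict(21.1 / 49.0, 30.6 / 67.8))
    app_fm_fraction: dict = field(default_factory=lambda: _sex_dict(17.1 / 35.4, 12.1 / 30.8))
    app_fraction_sd: float = 0.02
    # Fraction of each compartment's six-month change occurring in the limbs.
    app_change_fraction_lst: dict = field(default_factory=lambda: _sex_dict(0.497, 0.451))
    app_change_fraction_fm: dict = field(default_factory=lambda: _sex_dict(0.488, 0.380))
    tee_mean: float = 35.0
    tee_sd: float = 6.0
    # --- proteomics ---
    n_proteins: int = 266
    n_heavy_censored: int = 24
    n_duplicated: int = 10
    planted_effects: list = field(default_factory=lambda: [
        (0, 1.2), (1, 0.6), (2, 0.5), (3, 0.4), (4, 0.3),
    ])
    delta_sd: float = 0.3
    lod_quantile: float = 0.05
    heavy_lod_quantile: float = 0.7
    qc_fail_prob: float = 0.013
    qc_fail_cells: int | None = None
    n_outlier_samples: int = 2
    outlier_shift: float = 2.5
    npx_dropout: int = 20
    dup_noise_sd: float = 0.15
    max_resamples: int = 1000
    seed: int = 0

    @property
    def n_planted(self) -> int:
        return len(self.planted_effects)

    def validate(self) -> None:
        for name in ("female_fraction", "hispanic_prob", "diet_hlc_prob",
                     "lod_quantile", "heavy_lod_quantile", "qc_fail_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("age_sd", "delta_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.n_planted > self.n_proteins:
            raise ValueError("more planted effects than proteins")
        for idx, _ in self.planted_effects:
            if not 0 <= idx < self.n_proteins:
                raise ValueError(f"planted protein index {idx} out of range")
        if self.n_heavy_censored + self.n_duplicated + self.n_planted > self.n_proteins:
            raise ValueError("heavy-censored + duplicated + planted exceed n_proteins")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-6:
            raise ValueError("race_probs must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        d["bmi_range"] = list(d["bmi_range"])
        d["planted_effects"] = [list(t) for t in d["planted_effects"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "bmi_range" in d:
            d["bmi_range"] = tuple(d["bmi_range"])
        if "planted_effects" in d:
            d["planted_effects"] = [tuple(t) for t in d["planted_effects"]]
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    per_subject: pd.DataFrame          # d_total, d_fm, d_lst, d_bmc, eps, u
    gamma: np.ndarray                  # planted effect sizes (kg per NPX unit)
    planted_proteins: list             # assay ids of the planted proteins
    planted_deltas: pd.DataFrame       # subjects x planted proteins
    heavy_censored: list = field(default_factory=list)
    duplicated: list = field(default_factory=list)
    qc_failed: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "per_subject": self.per_subject.to_dict(orient="list"),
            "gamma": self.gamma.tolist(),
            "planted_proteins": self.planted_proteins,
            "planted_deltas": self.planted_deltas.to_dict(orient="list"),
            "heavy_censored": self.heavy_censored,
            "duplicated": self.duplicated,
            "qc_failed": self.qc_failed,
            "outlier_samples": self.outlier_samples,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class DegenerateConfigError(RuntimeError):
    """A compartment could not be kept positive within max_resamples."""


def _truncated_normal(rng, mean, sd, lo, hi, size, max_tries=1000):
    """Rejection-sampled truncated normal (exact for these mild truncations)."""
    mean = np.broadcast_to(np.asarray(mean, float), (size,))
    sd = np.broadcast_to(np.asarray(sd, float), (size,))
    out = rng.normal(mean, sd)
    for _ in range(max_tries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean[bad], sd[bad])
    raise DegenerateConfigError("truncated-normal rejection did not converge")


def _per_sex(cfg_map, sexes: np.ndarray) -> np.ndarray:
    return np.where(sexes == "female", cfg_map["female"], cfg_map["male"]).astype(float)


def simulate_cohort(config: CohortConfig):
    """Simulate subjects, paired regional DXA scans, and ground truth.

    Returns ``(subjects, scans, truth)`` where *subjects* is one row per
    participant, *scans* is long format (subject x timepoint x region with
    LST/FM/BMC in kg), and *truth* records the protein-driven LST residual
    component each subject carries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    if n == 0:
        subjects = pd.DataFrame(columns=[
            "subject_id", "sex", "age", "height_cm", "race", "hispanic",
            "diet", "tee_3mo", "tee_6mo"])
        scans = pd.DataFrame(columns=[
            "subject_id", "timepoint", "region", "lst_kg", "fm_kg", "bmc_kg"])
        truth = SyntheticTruth(
            per_subject=pd.DataFrame(columns=["subject_id", "d_total", "d_fm",
                                              "d_lst", "d_bmc", "eps", "u"]),
            gamma=np.array([g for _, g in config.planted_effects], float),
            planted_proteins=[], planted_deltas=pd.DataFrame())
        return subjects, scans, truth

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_range, n)
    bmi = _truncated_normal(rng, _per_sex(config.bmi_mean, sex),
                            _per_sex(config.bmi_sd, sex), *config.bmi_range, n)
    height = rng.normal(_per_sex(config.height_mean, sex),
                        _per_sex(config.height_sd, sex))
    weight = bmi * (height / 100.0) ** 2
    bodyfat = _truncated_normal(rng, _per_sex(config.bodyfat_mean, sex),
                                _per_sex(config.bodyfat_sd, sex), 15.0, 55.0, n)

    fm0 = bodyfat / 100.0 * weight
    bmc0 = 0.04 * weight * (1.0 + rng.normal(0.0, 0.05, n))
    lst0 = weight - fm0 - bmc0

    race = rng.choice(list(config.race_probs), size=n,
                      p=list(config.race_probs.values()))
    hispanic = rng.random(n) < config.hispanic_prob
    diet = np.where(rng.random(n) < config.diet_hlc_prob, "HLC", "HLF")
    tee3 = rng.normal(config.tee_mean, config.tee_sd, n)
    tee6 = tee3 + rng.normal(0.0, 2.0, n)

    # Six-month changes. A core mass change drives a fat-dominated loss;
    # the protein-driven deviation u (planted signal + noise) lands in LST.
    gamma = np.array([g for _, g in config.planted_effects], float)
    planted = rng.normal(0.0, config.delta_sd, (n, config.n_planted))
    eps = rng.normal(0.0, config.residual_sd, n)
    u = planted @ gamma + eps if config.n_planted else eps.copy()

    d_fm = np.empty(n)
    d_lst = np.empty(n)
    d_bmc = np.empty(n)
    pending = np.arange(n)
    for _ in range(config.max_resamples):
        m = pending.size
        if m == 0:
            break
        core = rng.normal(_per_sex(config.mass_change_mean, sex[pending]),
                          _per_sex(config.mass_change_sd, sex[pending]))
        dfm = (_per_sex(config.fm_fraction_of_loss, sex[pending]) * core
               + rng.normal(0.0, config.fm_noise_sd, m))
        dbmc = rng.normal(0.0, config.bmc_change_sd, m)
        dlst = core - dfm - dbmc + u[pending]
        ok = ((fm0[pending] + dfm > 0.5) & (lst0[pending] + dlst > 0.5)
              & (bmc0[pending] + dbmc > 0.1))
        idx = pending[ok]
        d_fm[idx], d_lst[idx], d_bmc[idx] = dfm[ok], dlst[ok], dbmc[ok]
        pending = pending[~ok]
    if pending.size:
        raise DegenerateConfigError(
            f"{pending.size} subjects violated compartment positivity after "
            f"{config.max_resamples} resampling rounds")
    d_total = d_fm + d_lst + d_bmc  # conservation holds exactly

    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    subjects = pd.DataFrame({
        "subject_id": subject_id, "sex": sex, "age": age, "height_cm": height,
        "race": race, "hispanic": hispanic.astype(int), "diet": diet,
        "tee_3mo": tee3, "tee_6mo": tee6,
    })

    # Regional allocation. Appendicular fractions per sex + noise, arms/legs
    # split fixed, head share of the non-appendicular remainder fixed.
    app_lst = lst0 * np.clip(_per_sex(config.app_lst_fraction, sex)
                             + rng.normal(0, config.app_fraction_sd, n), 0.05, 0.9)
    app_fm = fm0 * np.clip(_per_sex(config.app_fm_fraction, sex)
                           + rng.normal(0, config.app_fraction_sd, n), 0.05, 0.9)
    app_bmc = 0.45 * bmc0

    d_app_lst = _per_sex(config.app_change_fraction_lst, sex) * d_lst
    d_app_fm = _per_sex(config.app_change_fraction_fm, sex) * d_fm

    def region_frames(lst, fm, bmc, a_lst, a_fm, a_bmc, timepoint):
        rows = []
        rest_lst, rest_fm, rest_bmc = lst - a_lst, fm - a_fm, bmc - a_bmc
        head = (_HEAD_LST_SHARE * rest_lst, _HEAD_FM_SHARE * rest_fm,
                _HEAD_BMC_SHARE * rest_bmc)
        trunk = (rest_lst - head[0], rest_fm - head[1], rest_bmc - head[2])
        shares = {"arm_L": _ARM_SHARE / 2, "arm_R": _ARM_SHARE / 2,
                  "leg_L": (1 - _ARM_SHARE) / 2, "leg_R": (1 - _ARM_SHARE) / 2}
        for region, s in shares.items():
            rows.append(pd.DataFrame({
                "subject_id": subject_id, "timepoint": timepoint,
                "region": region, "lst_kg": s * a_lst, "fm_kg": s * a_fm,
                "bmc_kg": s * a_bmc}))
        for region, vals in (("trunk", trunk), ("head", head)):
            rows.append(pd.DataFrame({
                "subject_id": subject_id, "timepoint": timepoint,
                "region": region, "lst_kg": vals[0], "fm_kg": vals[1],
                "bmc_kg": vals[2]}))
        return rows

    frames = region_frames(lst0, fm0, bmc0, app_lst, app_fm, app_bmc, "baseline")
    frames += region_frames(lst0 + d_lst, fm0 + d_fm, bmc0 + d_bmc,
                            app_lst + d_app_lst, app_fm + d_app_fm,
                            app_bmc, "6mo")
    scans = (pd.concat(frames, ignore_index=True)
             .sort_values(["subject_id", "timepoint", "region"])
             .reset_index(drop=True))

    planted_ids = [f"PROT_{idx:04d}" for idx, _ in config.planted_effects]
    truth = SyntheticTruth(
        per_subject=pd.DataFrame({
            "subject_id": subject_id, "d_total": d_total, "d_fm": d_fm,
            "d_lst": d_lst, "d_bmc": d_bmc, "eps": eps, "u": u}),
        gamma=gamma,
        planted_proteins=planted_ids,
        planted_deltas=pd.DataFrame(planted, columns=planted_ids,
                                    index=subject_id),
    )
    return subjects, scans, truth


def _protein_catalog(config: CohortConfig):
    """Assay catalog: ids, synthetic UniProt accessions, panel assignment."""
    p = config.n_proteins
    ids = [f"PROT_{i:04d}" for i in range(p)]
    uniprot = [f"SYNP{i:04d}" for i in range(p)]
    panel = [PANELS[i % 3] for i in range(p)]
    # Heavy-censored and duplicated blocks occupy the tail of the catalog,
    # away from the planted indices at the head.
    heavy = list(range(p - config.n_heavy_censored, p))
    dup = list(range(p - config.n_heavy_censored - config.n_duplicated,
                     p - config.n_heavy_censored))
    return ids, uniprot, panel, heavy, dup


def simulate_npx(config: CohortConfig, truth: SyntheticTruth,
                 subjects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate an Olink-style long NPX table consistent with *truth*.

    Columns: SampleID, SubjectID, Timepoint, OlinkID, Assay, UniProt, Panel,
    NPX, LOD, QC_Warning. Values are log2-scale relative abundances; each
    protein's LOD is its ``lod_quantile`` empirical quantile, heavy-censored
    proteins use ``heavy_lod_quantile`` (>50%, so the LOD filter drops them).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    subject_id = truth.per_subject["subject_id"].to_numpy()
    n = subject_id.size
    p = config.n_proteins
    ids, uniprot, panel, heavy, dup = _protein_catalog(config)

    mu = rng.uniform(1.0, 9.0, p)
    base = mu + rng.normal(0.0, 1.0, (n, p))
    delta = rng.normal(0.0, config.delta_sd, (n, p))
    for j, (idx, _) in enumerate(config.planted_effects):
        delta[:, idx] = truth.planted_deltas.iloc[:, j].to_numpy()
    follow = base + delta

    # Subjects without a 6-mo blood draw.
    dropout = rng.choice(n, size=min(config.npx_dropout, n), replace=False)
    has_6mo = np.ones(n, bool)
    has_6mo[dropout] = False

    # Outlier samples: follow-up samples globally shifted on every protein.
    candidates = np.flatnonzero(has_6mo)
    outliers = rng.choice(candidates,
                          size=min(config.n_outlier_samples, candidates.size),
                          replace=False)
    follow[outliers] += config.outlier_shift
    truth.outlier_samples = [f"{subject_id[i]}_6mo" for i in outliers]
    truth.heavy_censored = [ids[i] for i in heavy]
    truth.duplicated = [ids[i] for i in dup]

    frames = []
    for tp, mat, keep in (("baseline", base, np.ones(n, bool)),
                          ("6mo", follow, has_6mo)):
        sid = np.array([f"{s}_{tp}" for s in subject_id])[keep]
        frames.append(pd.DataFrame({
            "SampleID": np.repeat(sid, p),
            "SubjectID": np.repeat(subject_id[keep], p),
            "Timepoint": tp,
            "OlinkID": np.tile(ids, keep.sum()),
            "Assay": np.tile(ids, keep.sum()),
            "UniProt": np.tile(uniprot, keep.sum()),
            "Panel": np.tile(panel, keep.sum()),
            "NPX": mat[keep].ravel(),
        }))
        # Redundant copies on a second panel with correlated noise.
        if dup:
            dup_panel = [PANELS[(PANELS.index(panel[i]) + 1) % 3] for i in dup]
            dvals = (mat[keep][:, dup]
                     + rng.normal(0.0, config.dup_noise_sd,
                                  (int(keep.sum()), len(dup))))
            frames.append(pd.DataFrame({
                "SampleID": np.repeat(sid, len(dup)),
                "SubjectID": np.repeat(subject_id[keep], len(dup)),
                "Timepoint": tp,
                "OlinkID": np.tile([ids[i] + "_dup" for i in dup], keep.sum()),
                "Assay": np.tile([ids[i] for i in dup], keep.sum()),
                "UniProt": np.tile([uniprot[i] for i in dup], keep.sum()),
                "Panel": np.tile(dup_panel, keep.sum()),
                "NPX": dvals.ravel(),
            }))
    npx = pd.concat(frames, ignore_index=True)

    # Per-assay LOD at the configured quantile of that assay's values.
    heavy_ids = set(truth.heavy_censored)
    lod_map = {}
    for oid, vals in npx.groupby("OlinkID")["NPX"]:
        qq = (config.heavy_lod_quantile if oid in heavy_ids
              else config.lod_quantile)
        lod_map[oid] = float(np.quantile(vals, qq))
    npx["LOD"] = npx["OlinkID"].map(lod_map)

    npx["QC_Warning"] = "Pass"
    if config.qc_fail_cells is not None:
        flagged = rng.choice(len(npx), size=min(config.qc_fail_cells, len(npx)),
                             replace=False)
        npx.loc[npx.index[flagged], "QC_Warning"] = "Warning"
        truth.qc_failed = sorted(
            npx.loc[npx.index[flagged], "SampleID"].unique().tolist())
    elif config.qc_fail_prob > 0:
        sp = npx[["SampleID", "Panel"]].drop_duplicates()
        fail = sp[rng.random(len(sp)) < config.qc_fail_prob]
        if len(fail):
            key = npx["SampleID"] + "|" + npx["Panel"]
            bad = set(fail["SampleID"] + "|" + fail["Panel"])
            npx.loc[key.isin(bad), "QC_Warning"] = "Warning"
            truth.qc_failed = sorted(set(fail["SampleID"]))
    return npx


def simulate_screen_dataset(config: CohortConfig, seed: int | None = None):
    """Compact generator for screen/selection experiments.

    Produces the post-QC objects the proteomic stages consume — a subjects
    table, per-subject DXA changes, and a wide ΔNPX matrix — without the
    long-format Olink plumbing. Shares the generative model of
    :func:`simulate_cohort` / :func:`simulate_npx` exactly for the planted
    contract: LST residual about its regression on ΔFM ≈ Σ γ_p ΔProtein_p + ε.

    Returns ``(subjects, changes, delta, truth)`` where *changes* has columns
    d_lst / d_fm and *delta* is subjects x proteins.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    subjects, _, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = len(subjects)
    p = config.n_proteins
    ids = [f"PROT_{i:04d}" for i in range(p)]
    delta = rng.normal(0.0, config.delta_sd, (n, p))
    for j, (idx, _) in enumerate(config.planted_effects):
        delta[:, idx] = truth.planted_deltas.iloc[:, j].to_numpy()
    delta = pd.DataFrame(delta, columns=ids,
                         index=subjects["subject_id"].to_numpy())
    changes = truth.per_subject.set_index("subject_id")[["d_lst", "d_fm"]]
    return subjects, changes, delta, truth


def write_cohort(out_dir, subjects: pd.DataFrame, scans: pd.DataFrame,
                 truth: SyntheticTruth, npx: pd.DataFrame | None = None) -> None:
    """Write cohort CSV, scans CSV, NPX long TSV and truth JSON to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "cohort.csv", index=False)
    scans.to_csv(out / "scans.csv", index=False)
    truth.to_json(out / "truth.json")
    if npx is not None:
        npx.to_csv(out / "npx.tsv", sep="\t", index=False)
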