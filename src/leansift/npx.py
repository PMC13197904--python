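"""Olink-style NPX ingestion and quality control.

NPX (normalized protein expression) is a relative log2-scale abundance.
The QC pipeline applies, in a fixed and logged order:

1. drop proteins with >50% of values below their limit of detection (LOD);
2. replace remaining below-LOD values with that protein's LOD;
3. resolve proteins measured on more than one panel to a single copy;
4. exclude sample x panel observations flagged by vendor QC;
5. remove samples whose PC1 score lies >3 SD from the mean.

Every removal is appended to an exclusion log sufficient to reconstruct it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NPXMatrix",
    "filter_proteins_by_lod",
    "impute_lod",
    "resolve_redundant_panels",
    "exclude_failed_samples",
    "pca_outlier_removal",
    "run_qc",
]

REQUIRED_COLUMNS = ("SampleID", "OlinkID", "Assay", "UniProt", "Panel",
                    "NPX", "LOD")


class NPXMatrix:
    """Long-format NPX table plus an exclusion log.

    One row per (sample, assay, panel) observation. A ``BelowLOD`` flag is
    derived on construction and preserved through imputation so downstream
    stages can sensitivity-test censored values.
    """

    def __init__(self, data: pd.DataFrame, exclusion_log: list | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"NPX table missing columns: {missing}")
        data = data.copy()
        if data.duplicated(["SampleID", "OlinkID", "Panel"]).any():
            raise ValueError("duplicate (sample, assay, panel) observations")
        if "QC_Warning" not in data.columns:
            data["QC_Warning"] = "Pass"
        if "BelowLOD" not in data.columns:
            data["BelowLOD"] = data["NPX"] < data["LOD"]
        self.data = data
        self.exclusion_log = list(exclusion_log or [])

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "NPXMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def write_log(self, path) -> None:
        Path(path).write_text(json.dumps(self.exclusion_log, indent=1))

    # -- views -------------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.data["UniProt"].nunique()

    @property
    def n_samples(self) -> int:
        return self.data["SampleID"].nunique()

    def wide(self, value: str = "NPX") -> pd.DataFrame:
        """Samples x proteins matrix (NaN where unobserved)."""
        return self.data.pivot_table(index="SampleID", columns="UniProt",
                                     values=value, aggfunc="mean")

    def delta_wide(self) -> pd.DataFrame:
        """Per-subject 6mo − baseline NPX, complete pairs only."""
        if "SubjectID" not in self.data.columns or "Timepoint" not in self.data.columns:
            raise ValueError("delta requires SubjectID and Timepoint columns")
        piv = self.data.pivot_table(index=["SubjectID", "Timepoint"],
                                    columns="UniProt", values="NPX",
                                    aggfunc="mean")
        base = piv.xs("baseline", level="Timepoint")
        follow = piv.xs("6mo", level="Timepoint")
        common = base.index.intersection(follow.index)
        return follow.loc[common] - base.loc[common]

    def baseline_wide(self) -> pd.DataFrame:
        sel = self.data[self.data["Timepoint"] == "baseline"]
        return sel.pivot_table(index="SubjectID", columns="UniProt",
                               values="NPX", aggfunc="mean")

    def _with(self, data: pd.DataFrame, entry: dict) -> "NPXMatrix":
        out = NPXMatrix.__new__(NPXMatrix)
        out.data = data
        out.exclusion_log = self.exclusion_log + [entry]
        return out


def filter_proteins_by_lod(matrix: NPXMatrix):
    """Drop assays with strictly more than 50% of non-missing values below LOD.

    Returns ``(matrix, dropped)`` where *dropped* lists (OlinkID, Panel)
    pairs. Idempotent: surviving assays are at most 50% censored.
    """
    d = matrix.data
    frac = d.groupby(["OlinkID", "Panel"], sort=False)["BelowLOD"].mean()
    dropped = frac[frac > 0.5]
    keys = d["OlinkID"] + "|" + d["Panel"]
    bad = {f"{o}|{p}" for o, p in dropped.index}
    out = d[~keys.isin(bad)].reset_index(drop=True)
    entry = {"step": "filter_proteins_by_lod", "rule": ">50% below LOD",
             "dropped": [{"OlinkID": o, "Panel": p,
                          "frac_below_lod": float(f)}
                         for (o, p), f in dropped.items()]}
    return matrix._with(out, entry), list(dropped.index)


def impute_lod(matrix: NPXMatrix) -> NPXMatrix:
    """Replace below-LOD values with that protein's LOD; flags retained."""
    d = matrix.data.copy()
    mask = d["BelowLOD"].to_numpy(bool)
    d.loc[mask, "NPX"] = d.loc[mask, "LOD"]
    entry = {"step": "impute_lod", "n_imputed": int(mask.sum())}
    return matrix._with(d, entry)


def resolve_redundant_panels(matrix: NPXMatrix,
                             policy: str = "fewest_missing"):
    """Keep one panel per protein measured on several panels.

    Default policy retains the copy with fewer below-LOD/missing values,
    tie-broken by higher LOD; ``policy='higher_lod'`` swaps the priority.
    Returns ``(matrix, resolution_log)``.
    """
    if policy not in ("fewest_missing", "higher_lod"):
        raise ValueError(f"unknown policy '{policy}'")
    d = matrix.data
    stats = (d.groupby(["UniProt", "OlinkID", "Panel"], sort=False)
             .agg(n_below=("BelowLOD", "sum"),
                  n_missing=("NPX", lambda s: int(s.isna().sum())),
                  lod=("LOD", "mean"))
             .reset_index())
    stats["n_bad"] = stats["n_below"] + stats["n_missing"]
    resolutions = []
    drop_keys = set()
    for uniprot, grp in stats.groupby("UniProt", sort=False):
        if len(grp) == 1:
            continue
        if policy == "fewest_missing":
            order = grp.sort_values(["n_bad", "lod"],
                                    ascending=[True, False])
        else:
            order = grp.sort_values(["lod", "n_bad"],
                                    ascending=[False, True])
        keep = order.iloc[0]
        for _, row in order.iloc[1:].iterrows():
            drop_keys.add((row["OlinkID"], row["Panel"]))
        resolutions.append({
            "UniProt": uniprot,
            "kept": {"OlinkID": keep["OlinkID"], "Panel": keep["Panel"],
                     "n_bad": int(keep["n_bad"]), "lod": float(keep["lod"])},
            "dropped": [{"OlinkID": r["OlinkID"], "Panel": r["Panel"],
                         "n_bad": int(r["n_bad"]), "lod": float(r["lod"])}
                        for _, r in order.iloc[1:].iterrows()],
        })
    keys = list(zip(d["OlinkID"], d["Panel"]))
    mask = np.array([k in drop_keys for k in keys])
    out = d[~mask].reset_index(drop=True)
    entry = {"step": "resolve_redundant_panels", "policy": policy,
             "resolutions": resolutions}
    return matrix._with(out, entry), resolutions


def exclude_failed_samples(matrix: NPXMatrix):
    """Remove observations flagged by vendor QC (QC_Warning != 'Pass').

    The flag is consumed as given; the internal-control computation behind
    it is upstream at the vendor. Returns ``(matrix, n_removed)``.
    """
    d = matrix.data
    bad = d["QC_Warning"].astype(str) != "Pass"
    out = d[~bad].reset_index(drop=True)
    entry = {"step": "exclude_failed_samples",
             "n_cells_removed": int(bad.sum()),
             "n_cells_total": int(len(d)),
             "fraction_removed": float(bad.mean()) if len(d) else 0.0,
             "samples_touched": sorted(d.loc[bad, "SampleID"].unique().tolist())}
    return matrix._with(out, entry), int(bad.sum())


def pca_outlier_removal(matrix: NPXMatrix, sd_threshold: float = 3.0):
    """Remove samples whose PC1 score is > *sd_threshold* SD from the mean.

    Single pass (no iteration). The PCA pools all samples across
    timepoints, centers per protein, and is unscaled; remaining missing
    cells are mean-imputed for score computation only.
    Returns ``(matrix, outlier_sample_ids)``.
    """
    d = matrix.data
    wide = matrix.wide()
    X = wide.to_numpy(float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    if np.isfinite(sd_threshold) and min(X.shape) >= 2:
        # PC1 via SVD; scores are the first left singular vector scaled.
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        z = (pc1 - pc1.mean()) / pc1.std(ddof=1)
        outliers = list(wide.index[np.abs(z) > sd_threshold])
        scores = dict(zip(wide.index, pc1))
    else:
        outliers, scores = [], {}
    out = d[~d["SampleID"].isin(outliers)].reset_index(drop=True)
    entry = {"step": "pca_outlier_removal", "sd_threshold": sd_threshold,
             "outliers": [{"SampleID": s, "pc1_score": float(scores[s])}
                          for s in outliers]}
    return matrix._with(out, entry), outliers


def run_qc(matrix: NPXMatrix, sd_threshold: float = 3.0,
           panel_policy: str = "fewest_missing") -> NPXMatrix:
    """Full QC pipeline in the fixed order; see module docstring."""
    matrix, _ = filter_proteins_by_lod(matrix)
    matrix = impute_lod(matrix)
    matrix, _ = resolve_redundant_panels(matrix, policy=panel_policy)
    matrix, _ = exclude_failed_samples(matrix)
    matrix, _ = pca_outlier_removal(matrix, sd_threshold=sd_threshold)
    return matrix
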