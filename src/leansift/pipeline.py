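"""End-to-end orchestration: simulate → QC → tables → screens → structure.

A single run configuration (YAML/dict) drives the fixed stage order

    simulate, qc, bodycomp, percent_predicted, screen, stability, structure

writing plain TSV/JSON outputs plus a reproducibility manifest that hashes
every stage's inputs and outputs. Reruns resume from cached stage outputs
when the stage's configuration (including seeds) is unchanged; changing one
stage's seed therefore shows up in the manifest diff of that stage and its
downstream dependents only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bodycomp, npx, prediction, screen, stability, structure
from .cohort import CohortConfig, simulate_cohort, simulate_npx, write_cohort

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "manifest_diff"]

STAGES = ("simulate", "qc", "bodycomp", "percent_predicted", "screen",
          "stability", "structure")

DEFAULT_CONFIG = {
    "simulate": {},               # CohortConfig overrides
    "qc": {"pc_sd_threshold": 3.0, "panel_policy": "fewest_missing"},
    "screen": {"fdr": 0.05},
    "stability": {"B": 200, "threshold": 0.6,
                  "alpha_grid": [0.0, 0.25, 0.5, 0.75, 1.0],
                  "n_lambdas": 30},
    "structure": {"n_perm": 2000, "var_target": 0.6, "max_components": 10},
    "seeds": {"simulate": 0, "screen": 1, "stability": 2, "structure": 3},
    "sexes": ["female", "male"],
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}))
        else:
            out[k] = override.get(k, v)
    for k, v in override.items():
        out.setdefault(k, v)
    return out


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cfg_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages = {}
        if path.exists():
            self.previous = json.loads(path.read_text())
        else:
            self.previous = {}

    def can_skip(self, stage: str, cfg_hash: str, outputs: list[Path]) -> bool:
        prev = self.previous.get(stage)
        if not prev or prev.get("config_hash") != cfg_hash:
            return False
        if not all(p.exists() for p in outputs):
            return False
        return all(_sha(p) == prev["outputs"].get(p.name)
                   for p in outputs)

    def record(self, stage: str, cfg_hash: str, inputs: list[Path],
               outputs: list[Path], cached: bool = False) -> None:
        self.stages[stage] = {
            "config_hash": cfg_hash,
            "cached": cached,
            "inputs": {p.name: _sha(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha(p) for p in outputs if p.exists()},
        }

    def write(self, config: dict) -> None:
        payload = {"config": config, **self.stages}
        self.path.write_text(json.dumps(payload, indent=1, default=str))


def manifest_diff(a: dict, b: dict) -> dict:
    """Stages whose output hashes differ between two manifest payloads."""
    changed = {}
    for stage in STAGES:
        oa = a.get(stage, {}).get("outputs", {})
        ob = b.get(stage, {}).get("outputs", {})
        files = sorted(set(oa) | set(ob))
        diff = [f for f in files if oa.get(f) != ob.get(f)]
        if diff:
            changed[stage] = diff
    return changed


def _subject_changes(subjects: pd.DataFrame, scans: pd.DataFrame):
    totals = bodycomp.regional_totals(scans)
    wide = totals.pivot(index="subject_id", columns="timepoint",
                        values=[c for c in totals.columns
                                if c not in ("subject_id", "timepoint")])
    d = pd.DataFrame(index=wide.index)
    for col in ("lst_kg_total", "fm_kg_total", "mass_total",
                "lst_kg_app", "fm_kg_app", "mass_app"):
        d["d_" + col] = wide[(col, "6mo")] - wide[(col, "baseline")]
    for col in ("lst_kg_app", "mass_app"):
        d[col + "_baseline"] = wide[(col, "baseline")]
        d[col + "_6mo"] = wide[(col, "6mo")]
    return d.join(subjects.set_index("subject_id"))


def run_pipeline(config: dict | None = None, out_dir="leansift_run"):
    """Execute all stages; returns the output directory as a Path."""
    config = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    seeds = config["seeds"]

    # ---- simulate -------------------------------------------------------
    sim_cfg = CohortConfig.from_dict(
        {**config["simulate"], "seed": seeds["simulate"]})
    sim_hash = _cfg_hash(sim_cfg.to_dict())
    sim_out = [out / f for f in ("cohort.csv", "scans.csv", "npx.tsv",
                                 "truth.json", "uniprot2gene.tsv",
                                 "gene_sets.gmt")]
    if manifest.can_skip("simulate", sim_hash, sim_out):
        manifest.record("simulate", sim_hash, [], sim_out, cached=True)
    else:
        subjects, scans, truth = simulate_cohort(sim_cfg)
        npx_long = simulate_npx(sim_cfg, truth)
        write_cohort(out, subjects, scans, truth, npx_long)
        rng = np.random.default_rng(np.random.SeedSequence(
            [seeds["simulate"], 99]))
        uni = sorted(npx_long["UniProt"].unique())
        genes = [u.replace("SYNP", "GENE") for u in uni]
        pd.DataFrame({"UniProt": uni, "Gene": genes}).to_csv(
            out / "uniprot2gene.tsv", sep="\t", index=False)
        sets = {f"SET_{i:02d}": list(rng.choice(genes,
                                                rng.integers(10, 40),
                                                replace=False))
                for i in range(50)}
        structure.write_gmt(sets, out / "gene_sets.gmt")
        manifest.record("simulate", sim_hash, [], sim_out)

    subjects = pd.read_csv(out / "cohort.csv")
    scans = pd.read_csv(out / "scans.csv")

    # ---- qc -------------------------------------------------------------
    qc_cfg = config["qc"]
    qc_hash = _cfg_hash([qc_cfg, sim_hash])
    qc_out = [out / "clean_npx.tsv", out / "qc_log.json"]
    if manifest.can_skip("qc", qc_hash, qc_out):
        manifest.record("qc", qc_hash, [out / "npx.tsv"], qc_out, cached=True)
    else:
        matrix = npx.NPXMatrix.from_tsv(out / "npx.tsv")
        clean = npx.run_qc(matrix, sd_threshold=qc_cfg["pc_sd_threshold"],
                           panel_policy=qc_cfg["panel_policy"])
        clean.to_tsv(out / "clean_npx.tsv")
        clean.write_log(out / "qc_log.json")
        manifest.record("qc", qc_hash, [out / "npx.tsv"], qc_out)
    clean = npx.NPXMatrix.from_tsv(out / "clean_npx.tsv")

    changes = _subject_changes(subjects, scans)

    # ---- bodycomp -------------------------------------------------------
    bc_hash = _cfg_hash([sim_hash])
    bc_out = [out / "table_total.tsv", out / "table_appendicular.tsv",
              out / "diet_sensitivity.tsv", out / "tee_sensitivity.tsv"]
    if manifest.can_skip("bodycomp", bc_hash, bc_out):
        manifest.record("bodycomp", bc_hash, [], bc_out, cached=True)
    else:
        bodycomp.sex_summary_table(subjects, scans, "total").to_csv(
            out / "table_total.tsv", sep="\t", index=False)
        bodycomp.sex_summary_table(subjects, scans, "appendicular").to_csv(
            out / "table_appendicular.tsv", sep="\t", index=False)
        diet_rows = []
        for sex in config["sexes"]:
            sub = changes[changes["sex"] == sex].copy()
            sub["prop_lst"] = 100 * sub["d_lst_kg_total"] / sub["d_mass_total"]
            tab = bodycomp.diet_sensitivity(
                sub, value_cols=("d_lst_kg_total", "d_lst_kg_app",
                                 "d_mass_total"),
                prop_cols=("prop_lst",))
            tab.insert(0, "sex", sex)
            diet_rows.append(tab)
        pd.concat(diet_rows).to_csv(out / "diet_sensitivity.tsv", sep="\t",
                                    index=False)
        tee_rows = []
        for sex in config["sexes"]:
            sub = changes[changes["sex"] == sex]
            tab = bodycomp.tee_sensitivity(sub["d_lst_kg_total"],
                                           sub["tee_3mo"], sub["tee_6mo"],
                                           sub["diet"])
            tab.insert(0, "sex", sex)
            tee_rows.append(tab)
        pd.concat(tee_rows).to_csv(out / "tee_sensitivity.tsv", sep="\t",
                                   index=False)
        manifest.record("bodycomp", bc_hash, [], bc_out)

    # ---- percent predicted ---------------------------------------------
    pp_hash = _cfg_hash([sim_hash])
    pp_out = [out / "table_percent_predicted.tsv"]
    if manifest.can_skip("percent_predicted", pp_hash, pp_out):
        manifest.record("percent_predicted", pp_hash, [], pp_out, cached=True)
    else:
        rows = []
        for sex in config["sexes"]:
            model = prediction.load_model(f"dietfits_app_{sex}")
            sub = changes[changes["sex"] == sex]
            ind = prediction.design_from_subjects(sub)
            height_m = sub["height_cm"].to_numpy(float) / 100.0
            pps = {}
            for tp in ("baseline", "6mo"):
                inputs = pd.DataFrame({
                    "appendicular_mass": sub[f"mass_app_{tp}"].to_numpy(float),
                    "height": height_m,
                    "I_Black": ind["I_Black"].to_numpy(),
                    "I_Asian": ind["I_Asian"].to_numpy(),
                    "I_OtherRace": ind["I_OtherRace"].to_numpy(),
                })
                pred = model.predict(inputs)
                pps[tp] = prediction.percent_predicted(
                    sub[f"lst_kg_app_{tp}"].to_numpy(float), pred)
            summ = prediction.percent_predicted_change_test(
                pps["baseline"], pps["6mo"])
            rows.append({"measure": "percent_predicted_app_lst", "sex": sex,
                         "n": summ.n,
                         "mean_baseline": float(np.mean(pps["baseline"])),
                         "sd_baseline": float(np.std(pps["baseline"], ddof=1)),
                         "mean_6mo": float(np.mean(pps["6mo"])),
                         "sd_6mo": float(np.std(pps["6mo"], ddof=1)),
                         "mean_diff": summ.mean_diff, "ci_lo": summ.ci_lo,
                         "ci_hi": summ.ci_hi, "p": summ.p})
        pd.DataFrame(rows).to_csv(out / "table_percent_predicted.tsv",
                                  sep="\t", index=False)
        manifest.record("percent_predicted", pp_hash, [], pp_out)

    # ---- screen ---------------------------------------------------------
    sc_cfg = config["screen"]
    sc_hash = _cfg_hash([sc_cfg, qc_hash, seeds["screen"]])
    sc_out = [out / "screen_results.tsv", out / "volcano.tsv",
              out / "residuals.tsv"]
    delta = clean.delta_wide()
    if manifest.can_skip("screen", sc_hash, sc_out):
        manifest.record("screen", sc_hash, [out / "clean_npx.tsv"], sc_out,
                        cached=True)
    else:
        res_rows, screen_rows, volcano_rows = [], [], []
        for sex in config["sexes"]:
            sub = changes[changes["sex"] == sex]
            ro = screen.compute_residuals(sub["d_lst_kg_total"],
                                          sub["d_fm_kg_total"],
                                          index=sub.index)
            rtab = ro.table.copy()
            rtab.insert(0, "sex", sex)
            rtab.insert(0, "subject_id", sub.index)
            res_rows.append(rtab)
            paired = delta.index.intersection(sub.index)
            covs = screen.screen_covariates(sub.loc[paired])
            resid = ro.residuals.loc[paired]
            for family, X in (("baseline", clean.baseline_wide()
                               .loc[paired]),
                              ("delta", delta.loc[paired])):
                for kind in ("univariate", "multivariable"):
                    est = screen.ProteinScreen(
                        family=f"{family}:{kind}", fdr=sc_cfg["fdr"])
                    est.fit(X, resid.to_numpy(),
                            covariates=covs if kind == "multivariable"
                            else None)
                    r = est.results_.copy()
                    r.insert(0, "sex", sex)
                    screen_rows.append(r)
                    v = est.volcano_.copy()
                    v.insert(0, "sex", sex)
                    volcano_rows.append(v)
        pd.concat(res_rows).to_csv(out / "residuals.tsv", sep="\t",
                                   index=False)
        pd.concat(screen_rows).to_csv(out / "screen_results.tsv", sep="\t",
                                      index=False)
        pd.concat(volcano_rows).to_csv(out / "volcano.tsv", sep="\t",
                                       index=False)
        manifest.record("screen", sc_hash, [out / "clean_npx.tsv"], sc_out)

    screen_results = pd.read_csv(out / "screen_results.tsv", sep="\t")
    residuals_tab = pd.read_csv(out / "residuals.tsv", sep="\t")

    # ---- stability ------------------------------------------------------
    st_cfg = config["stability"]
    st_hash = _cfg_hash([st_cfg, sc_hash, seeds["stability"]])
    st_out = [out / "stability.tsv", out / "stability_params.json"]
    if manifest.can_skip("stability", st_hash, st_out):
        manifest.record("stability", st_hash, [], st_out, cached=True)
    else:
        st_rows, st_params = [], {}
        for sex in config["sexes"]:
            sub = changes[changes["sex"] == sex]
            rsub = residuals_tab[residuals_tab["sex"] == sex]
            rser = pd.Series(rsub["residual"].to_numpy(),
                             index=rsub["subject_id"])
            # complete cases: subjects with a full Delta-NPX vector
            paired = delta.loc[delta.index.intersection(rser.index)].dropna().index
            covs = screen.screen_covariates(sub.loc[paired])
            X = pd.concat([delta.loc[paired], covs], axis=1)
            sel = stability.StabilitySelector(
                B=st_cfg["B"], threshold=st_cfg["threshold"],
                alpha_grid=st_cfg["alpha_grid"],
                n_lambdas=st_cfg["n_lambdas"],
                covariate_names=tuple(covs.columns),
                random_state=seeds["stability"])
            sel.fit(X, rser.loc[paired].to_numpy())
            tab = sel.stability_.copy()
            tab.insert(0, "sex", sex)
            st_rows.append(tab)
            st_params[sex] = {"l1_ratio": sel.l1_ratio_,
                              "lambda": sel.lambda_, "B": st_cfg["B"],
                              "threshold": st_cfg["threshold"],
                              "seed": seeds["stability"]}
        pd.concat(st_rows).to_csv(out / "stability.tsv", sep="\t",
                                  index=False)
        (out / "stability_params.json").write_text(
            json.dumps(st_params, indent=1))
        manifest.record("stability", st_hash, [], st_out)

    # ---- structure ------------------------------------------------------
    tr_cfg = config["structure"]
    tr_hash = _cfg_hash([tr_cfg, sc_hash, seeds["structure"]])
    tr_out = [out / "enrichment.tsv", out / "pc_regression.json",
              out / "pc_loadings.tsv"]
    if manifest.can_skip("structure", tr_hash, tr_out):
        manifest.record("structure", tr_hash, [], tr_out, cached=True)
    else:
        mapping = pd.read_csv(out / "uniprot2gene.tsv", sep="\t")
        sets = structure.read_gmt(out / "gene_sets.gmt")
        enr_rows, pc_report = [], {}
        load_rows = []
        for sex in config["sexes"]:
            stats_sex = screen_results[
                (screen_results["sex"] == sex)
                & (screen_results["family"] == "delta:multivariable")]
            ranked, n_unmapped = structure.map_proteins_to_genes(
                stats_sex, mapping)
            enr = structure.preranked_gsea(ranked, sets,
                                           n_perm=tr_cfg["n_perm"],
                                           seed=seeds["structure"])
            enr.insert(0, "sex", sex)
            enr["n_unmapped"] = n_unmapped
            enr_rows.append(enr)

            sub = changes[changes["sex"] == sex]
            rsub = residuals_tab[residuals_tab["sex"] == sex]
            rser = pd.Series(rsub["residual"].to_numpy(),
                             index=rsub["subject_id"])
            paired = delta.loc[delta.index.intersection(rser.index)].dropna().index
            model = structure.pc_regression(
                delta.loc[paired], rser.loc[paired].to_numpy(),
                var_target=tr_cfg["var_target"],
                max_components=tr_cfg["max_components"])
            pc_report[sex] = {
                "n_components": model.n_components,
                "explained_variance_ratio":
                    model.explained_variance_ratio.tolist(),
                "regression": model.regression.to_dict(orient="records"),
                "top_loadings": model.top_loadings,
            }
            lt = model.loadings.reset_index().rename(
                columns={"index": "protein", "UniProt": "protein"})
            lt.insert(0, "sex", sex)
            load_rows.append(lt)
        pd.concat(enr_rows).to_csv(out / "enrichment.tsv", sep="\t",
                                   index=False)
        (out / "pc_regression.json").write_text(
            json.dumps(pc_report, indent=1))
        pd.concat(load_rows).to_csv(out / "pc_loadings.tsv", sep="\t",
                                    index=False)
        manifest.record("structure", tr_hash, [], tr_out)

    manifest.write(config)
    return out
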