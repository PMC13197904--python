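"""NPX quality-control rules on constructed fixtures with known answers."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_npx_frame
from leansift.cohort import CohortConfig, simulate_cohort, simulate_npx
from leansift.npx import (NPXMatrix, exclude_failed_samples,
                          filter_proteins_by_lod, impute_lod,
                          pca_outlier_removal, resolve_redundant_panels,
                          run_qc)


class TestLODFilter:
    def test_majority_censored_dropped(self):
        # 6 of 10 values below LOD 5.0 -> >50% -> dropped
        vals = {"A": [1, 2, 3, 4, 4.5, 4.9, 6, 7, 8, 9],
                "B": [6, 7, 8, 9, 6, 7, 8, 9, 6, 7]}
        m = NPXMatrix(make_npx_frame(vals, {"A": 5.0, "B": 5.0}))
        out, dropped = filter_proteins_by_lod(m)
        assert [o for o, _ in dropped] == ["A"]
        assert out.n_proteins == 1

    def test_exactly_half_retained(self):
        # the rule is strictly >50%
        vals = {"A": [1, 2, 3, 4, 4.5, 6, 7, 8, 9, 10]}
        m = NPXMatrix(make_npx_frame(vals, {"A": 5.0}))
        out, dropped = filter_proteins_by_lod(m)
        assert dropped == [] and out.n_proteins == 1

    def test_no_censoring_noop(self):
        vals = {"A": [6.0, 7.0], "B": [8.0, 9.0]}
        m = NPXMatrix(make_npx_frame(vals, {"A": 5.0, "B": 5.0}))
        out, dropped = filter_proteins_by_lod(m)
        assert dropped == [] and len(out.data) == len(m.data)

    def test_idempotent(self, small_npx):
        m = NPXMatrix(small_npx)
        once, d1 = filter_proteins_by_lod(m)
        twice, d2 = filter_proteins_by_lod(once)
        assert len(d1) == 24 and d2 == []
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestImputeLOD:
    def test_count_oracle(self):
        vals = {"A": [1.2, 2.5, 3.0, 1.9], "B": [6.0, 7.0, 8.0, 9.0]}
        m = NPXMatrix(make_npx_frame(vals, {"A": 2.0, "B": 5.0}))
        k = int((m.data["NPX"] < m.data["LOD"]).sum())
        out = impute_lod(m)
        changed = (out.data["NPX"] != m.data["NPX"]).sum()
        assert changed == k == 2
        # below-LOD cells now sit exactly at LOD; flags preserved
        assert (out.data.loc[out.data["BelowLOD"], "NPX"]
                == out.data.loc[out.data["BelowLOD"], "LOD"]).all()

    def test_at_lod_unchanged(self):
        m = NPXMatrix(make_npx_frame({"A": [2.0, 3.0]}, {"A": 2.0}))
        out = impute_lod(m)
        pd.testing.assert_series_equal(out.data["NPX"], m.data["NPX"])


class TestPanelResolution:
    def _dup_matrix(self, n_bad_p1, n_bad_p2, lod_p1=1.5, lod_p2=2.0, n=10):
        def vals(n_bad, lod):
            return [lod - 1] * n_bad + [lod + 3] * (n - n_bad)
        frame = pd.concat([
            make_npx_frame({"U1@a": vals(n_bad_p1, lod_p1)}, {"U1@a": lod_p1},
                           panels={"U1@a": "P1"}),
            make_npx_frame({"U1@b": vals(n_bad_p2, lod_p2)}, {"U1@b": lod_p2},
                           panels={"U1@b": "P2"}),
        ])
        return NPXMatrix(frame.reset_index(drop=True))

    def test_fewer_missing_wins(self):
        m = self._dup_matrix(n_bad_p1=3, n_bad_p2=7)
        out, log = resolve_redundant_panels(m)
        assert out.data["Panel"].unique().tolist() == ["P1"]
        assert log[0]["kept"]["n_bad"] == 3

    def test_tie_broken_by_higher_lod(self):
        m = self._dup_matrix(n_bad_p1=3, n_bad_p2=3, lod_p1=1.5, lod_p2=2.0)
        out, log = resolve_redundant_panels(m)
        assert out.data["Panel"].unique().tolist() == ["P2"]
        assert log[0]["kept"]["lod"] == 2.0

    def test_unique_proteins_untouched(self):
        m = NPXMatrix(make_npx_frame({"A": [6.0, 7.0], "B": [5.0, 6.0]},
                                     {"A": 2.0, "B": 2.0}))
        out, log = resolve_redundant_panels(m)
        assert log == [] and len(out.data) == len(m.data)


class TestSampleQC:
    def test_no_flags_identity(self):
        m = NPXMatrix(make_npx_frame({"A": [6.0, 7.0]}, {"A": 2.0}))
        out, n = exclude_failed_samples(m)
        assert n == 0 and len(out.data) == 2

    def test_flagged_panel_removed(self):
        qc = {("X0", "P1"): "Warning"}
        m = NPXMatrix(make_npx_frame({"A": [6.0, 7.0], "B": [5.0, 6.0]},
                                     {"A": 2.0, "B": 2.0}, qc=qc))
        out, n = exclude_failed_samples(m)
        assert n == 2                      # both assays of sample X0
        assert "X0" not in set(out.data["SampleID"])

    def test_exclusion_fraction_on_cohort_shape(self):
        """242 proteins x 708 samples with 2281 flagged cells -> ~1.3%."""
        cfg = CohortConfig(n_subjects=354, npx_dropout=0, n_proteins=242,
                           n_heavy_censored=0, n_duplicated=0,
                           qc_fail_cells=2281, n_outlier_samples=0, seed=8)
        _, _, truth = simulate_cohort(cfg)
        npx = simulate_npx(cfg, truth)
        assert len(npx) == 242 * 708
        m = NPXMatrix(npx)
        out, n = exclude_failed_samples(m)
        frac = out.exclusion_log[-1]["fraction_removed"]
        assert n == 2281
        assert round(100 * frac, 1) == 1.3


class TestPCAOutliers:
    def test_planted_outliers_recovered(self, small_config, small_npx):
        _, _, truth = simulate_cohort(small_config)
        simulate_npx(small_config, truth)    # populates truth.outlier_samples
        m = impute_lod(filter_proteins_by_lod(NPXMatrix(small_npx))[0])
        out, flagged = pca_outlier_removal(m)
        assert set(flagged) == set(truth.outlier_samples)

    def test_homogeneous_matrix_few_outliers(self, rng):
        n, p = 80, 40
        df = make_npx_frame(
            {f"A{j}": rng.normal(5, 1, n) for j in range(p)},
            {f"A{j}": 0.0 for j in range(p)})
        out, flagged = pca_outlier_removal(NPXMatrix(df))
        assert len(flagged) <= 3             # small tail fraction at 3 SD

    def test_infinite_threshold_noop(self, small_npx):
        m = NPXMatrix(small_npx)
        out, flagged = pca_outlier_removal(m, sd_threshold=np.inf)
        assert flagged == [] and len(out.data) == len(m.data)


class TestPipelineOrderAndAudit:
    def test_dietfits_shape_yields_242(self, small_npx):
        """276 assays, 24 heavily censored, 10 duplicated -> 242 proteins."""
        m = NPXMatrix(small_npx)
        assert m.data.groupby(["OlinkID", "Panel"]).ngroups == 276
        m, dropped = filter_proteins_by_lod(m)
        assert len(dropped) == 24
        m = impute_lod(m)
        m, res = resolve_redundant_panels(m)
        assert len(res) == 10
        assert m.n_proteins == 242

    def test_full_qc_order_logged(self, small_npx):
        clean = run_qc(NPXMatrix(small_npx))
        steps = [e["step"] for e in clean.exclusion_log]
        assert steps == ["filter_proteins_by_lod", "impute_lod",
                         "resolve_redundant_panels", "exclude_failed_samples",
                         "pca_outlier_removal"]

    def test_audit_reconstructs_removals(self, small_npx):
        """Replaying the exclusion log on the raw table reproduces the clean
        table's assay set and row count exactly."""
        m = NPXMatrix(small_npx)
        clean = run_qc(m)
        log = {e["step"]: e for e in clean.exclusion_log}
        d = m.data.copy()
        drop_assays = {(r["OlinkID"], r["Panel"])
                       for r in log["filter_proteins_by_lod"]["dropped"]}
        drop_assays |= {(r["OlinkID"], r["Panel"])
                        for res in log["resolve_redundant_panels"]["resolutions"]
                        for r in res["dropped"]}
        keys = list(zip(d["OlinkID"], d["Panel"]))
        d = d[[k not in drop_assays for k in keys]]
        d = d[d["QC_Warning"] == "Pass"]
        outliers = {o["SampleID"]
                    for o in log["pca_outlier_removal"]["outliers"]}
        d = d[~d["SampleID"].isin(outliers)]
        assert len(d) == len(clean.data)
        assert set(zip(d["OlinkID"], d["Panel"])) == \
            set(zip(clean.data["OlinkID"], clean.data["Panel"]))

    def test_duplicate_observation_rejected(self):
        df = make_npx_frame({"A": [6.0, 7.0]}, {"A": 2.0})
        dup = pd.concat([df, df.iloc[[0]]]).reset_index(drop=True)
        with pytest.raises(ValueError, match="duplicate"):
            NPXMatrix(dup)
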