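"""Gene-set enrichment and rotated PC regression."""

import numpy as np
import pandas as pd
import pytest

from leansift.structure import (RotatedPCRegression, enrichment_score,
                                map_proteins_to_genes, pc_regression,
                                preranked_gsea, read_gmt, write_gmt)


@pytest.fixture()
def ranked5():
    return pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                     index=["g1", "g2", "g3", "g4", "g5"])


class TestMapping:
    def _results(self, proteins, ts):
        return pd.DataFrame({"protein": proteins, "t": ts})

    def test_all_mapped(self):
        res = self._results(["U1", "U2"], [2.0, -1.0])
        mapping = pd.DataFrame({"u": ["U1", "U2"], "g": ["A", "B"]})
        ranked, n_unmapped = map_proteins_to_genes(res, mapping)
        assert n_unmapped == 0 and len(ranked) == 2
        assert list(ranked.index) == ["A", "B"]     # sorted by t desc

    def test_unmapped_dropped(self):
        res = self._results(["U1", "U9"], [2.0, 1.0])
        mapping = pd.DataFrame({"u": ["U1"], "g": ["A"]})
        ranked, n_unmapped = map_proteins_to_genes(res, mapping)
        assert n_unmapped == 1 and list(ranked.index) == ["A"]

    def test_duplicate_gene_max_abs_t(self):
        res = self._results(["U1", "U2"], [1.0, -3.0])
        mapping = pd.DataFrame({"u": ["U1", "U2"], "g": ["A", "A"]})
        ranked, _ = map_proteins_to_genes(res, mapping)
        assert len(ranked) == 1 and ranked["A"] == -3.0


class TestEnrichmentScore:
    def test_hand_oracle(self, ranked5):
        # hits g1 (+3/5), g5 (+2/5); misses −1/3 each; max |run| = 0.6
        assert enrichment_score(ranked5, {"g1", "g5"}) == pytest.approx(0.6)

    def test_whole_list_degenerate(self, ranked5):
        with pytest.raises(ValueError):
            enrichment_score(ranked5, set(ranked5.index))

    def test_sign_symmetry(self, ranked5):
        """Reversing the ranking (stats negated) flips the signed ES: the
        running sum totals zero, so the reversed partial sums are the
        negated originals."""
        for members in ({"g1"}, {"g1", "g5"}, {"g2", "g3"}):
            es = enrichment_score(ranked5, members)
            mirrored = pd.Series(-ranked5.to_numpy()[::-1],
                                 index=ranked5.index[::-1])
            assert enrichment_score(mirrored, members) == pytest.approx(-es)


class TestGSEA:
    def test_p_never_zero(self, rng):
        genes = [f"G{i}" for i in range(60)]
        ranked = pd.Series(np.linspace(3, -3, 60), index=genes)
        # set identical to the extreme top: p floored at 1/(n_perm+1)
        sets = {"TOP": genes[:5]}
        out = preranked_gsea(ranked, sets, n_perm=200, seed=0)
        assert out["p"].item() >= 1 / 201

    def test_equal_stats_uniform_p(self, rng):
        genes = [f"G{i}" for i in range(100)]
        ranked = pd.Series(np.ones(100), index=genes)
        sets = {f"S{i}": list(rng.choice(genes, 10, replace=False))
                for i in range(30)}
        out = preranked_gsea(ranked, sets, n_perm=300, seed=1)
        from scipy import stats
        assert stats.kstest(out["p"], "uniform").pvalue > 0.005

    def test_small_sets_skipped(self, ranked5):
        genes = [f"G{i}" for i in range(20)]
        ranked = pd.Series(np.linspace(2, -2, 20), index=genes)
        out = preranked_gsea(ranked, {"tiny": genes[:2],
                                      "absent": ["zz", "yy"]},
                             n_perm=100, seed=0)
        assert out["skipped"].all()

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"A": ["g1", "g2", "g3"], "B": ["g4", "g5", "g6", "g7"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_seed_determinism(self, rng):
        genes = [f"G{i}" for i in range(80)]
        ranked = pd.Series(rng.normal(0, 1, 80), index=genes).sort_values(
            ascending=False)
        sets = {"S": genes[3:15]}
        a = preranked_gsea(ranked, sets, n_perm=500, seed=7)
        b = preranked_gsea(ranked, sets, n_perm=500, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestPCRegression:
    def test_rank1_recovery(self, rng):
        n, p = 150, 30
        f = rng.normal(0, 1, n)
        load = rng.uniform(0.5, 1.5, p)
        X = pd.DataFrame(np.outer(f, load) + rng.normal(0, 0.05, (n, p)),
                         columns=[f"P{i}" for i in range(p)])
        model = pc_regression(X, rng.normal(0, 1, n))
        assert model.n_components == 1
        # loadings proportional to the true factor pattern (up to sign)
        lvec = model.loadings.iloc[:, 0].to_numpy()
        corr = np.corrcoef(np.abs(lvec), load)[0, 1]
        assert corr > 0.9

    def test_k1_varimax_identity(self, rng):
        n, p = 100, 10
        f = rng.normal(0, 1, n)
        X = pd.DataFrame(np.outer(f, np.ones(p)) + rng.normal(0, 0.05, (n, p)))
        X.columns = [f"P{i}" for i in range(p)]
        model = pc_regression(X, rng.normal(0, 1, n))
        assert model.n_components == 1
        assert model.rotation.shape == (1, 1)
        assert abs(abs(model.rotation[0, 0]) - 1.0) < 1e-12

    def test_two_factor_plant_and_recover(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 200, 40
            f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
            l1 = np.r_[np.ones(20), np.zeros(20)]
            l2 = np.r_[np.zeros(20), np.ones(20)]
            X = pd.DataFrame(np.outer(f1, l1) + np.outer(f2, l2)
                             + rng.normal(0, 0.5, (n, p)),
                             columns=[f"P{i}" for i in range(p)])
            y = 1.5 * f1 + rng.normal(0, 1, n)
            model = pc_regression(X, y)
            reg = model.regression.set_index("component")
            comps = [c for c in reg.index if c != "intercept"]
            # which rotated component carries factor 1? the one whose top
            # loadings are in the first block
            sig = [c for c in comps if reg.loc[c, "p"] < 0.05]
            f1_comp = model.loadings.iloc[:20].abs().sum().idxmax()
            f2_comp = model.loadings.iloc[20:].abs().sum().idxmax()
            if f1_comp in sig and f2_comp not in sig:
                hits += 1
        assert hits >= 9

    def test_communalities_preserved(self, rng):
        n, p = 120, 25
        X = pd.DataFrame(rng.normal(0, 1, (n, p)) +
                         np.outer(rng.normal(0, 1, n), rng.uniform(0, 1, p)),
                         columns=[f"P{i}" for i in range(p)])
        est = RotatedPCRegression(var_target=0.5, max_components=5)
        est.fit(X, rng.normal(0, 1, n))
        model = est.model_
        k = model.n_components
        # unrotated loadings from scratch
        Z = (X - X.mean()) / X.std(ddof=0)
        u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        L = vt[:k].T * (s[:k] / np.sqrt(n - 1))
        np.testing.assert_allclose(
            (model.loadings.to_numpy() ** 2).sum(axis=1),
            (L ** 2).sum(axis=1), atol=1e-8)
        # rotation orthonormal
        np.testing.assert_allclose(model.rotation @ model.rotation.T,
                                   np.eye(k), atol=1e-8)

    def test_scores_orthogonal_prerotation(self, rng):
        n, p = 100, 15
        X = pd.DataFrame(rng.normal(0, 1, (n, p)),
                         columns=[f"P{i}" for i in range(p)])
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        scores = u[:, :5] * s[:5]
        gram = scores.T @ scores
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (50, 5)),
                         columns=[f"P{i}" for i in range(5)])
        X["P0"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            pc_regression(X, rng.normal(0, 1, 50))
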