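"""Higher-order pattern analyses over screen statistics.

Two complementary views of the protein results:

* preranked gene-set enrichment: proteins are mapped to gene symbols,
  ranked by their multivariable t-statistic, and each gene set is scored by
  the weighted Kolmogorov–Smirnov running-sum enrichment score (weight
  exponent 1 on |t|). Significance comes from gene-label permutation —
  random same-size sets — with BH correction across sets.
* varimax-rotated principal-component regression: standardized protein
  changes are decomposed, a deterministic retention rule keeps the smallest
  k components explaining >= 60% cumulative variance (capped at 10), the
  retained loadings are varimax-rotated, and the rotated scores are used as
  predictors of the LST residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "read_gmt",
    "map_proteins_to_genes",
    "enrichment_score",
    "preranked_gsea",
    "RotatedPCRegression",
    "pc_regression",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, members = parts[0], [g for g in parts[2:] if g]
            seen = dict.fromkeys(members)     # dedupe, keep order
            if seen:
                sets[name] = list(seen)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def map_proteins_to_genes(results: pd.DataFrame, mapping: pd.DataFrame):
    """Ranked gene list from per-protein t-statistics.

    *results* needs columns ``protein`` (UniProt accession) and ``t``;
    *mapping* is two columns (UniProt accession, gene symbol). Unmapped
    proteins are dropped (count returned); genes hit by several proteins
    collapse to the entry with the largest |t|.

    Returns ``(ranked, n_unmapped)`` with *ranked* a Series of t-statistics
    indexed by gene, sorted descending.
    """
    mapping = mapping.iloc[:, :2].copy()
    mapping.columns = ["protein", "gene"]
    merged = results.merge(mapping, on="protein", how="left")
    n_unmapped = int(merged["gene"].isna().sum())
    merged = merged.dropna(subset=["gene", "t"])
    merged = (merged.reindex(merged["t"].abs()
                             .sort_values(ascending=False).index)
              .drop_duplicates("gene", keep="first"))
    ranked = (merged.set_index("gene")["t"]
              .sort_values(ascending=False))
    return ranked, n_unmapped


def enrichment_score(ranked: pd.Series, members, weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score of *members* in *ranked*.

    Hits increment by |t|^weight / Σ|t|^weight over the set; misses
    decrement by 1/(N − s). The ES is the running-sum value of largest
    absolute deviation from zero.
    """
    genes = ranked.index.to_numpy()
    t = ranked.to_numpy(float)
    hit = np.isin(genes, list(members))
    s = int(hit.sum())
    N = genes.size
    if s == 0 or s == N:
        raise ValueError("set is empty or spans the whole ranked list")
    w = np.abs(t) ** weight
    denom = w[hit].sum()
    steps = np.where(hit, np.where(denom > 0, w / max(denom, 1e-300), 0.0),
                     -1.0 / (N - s))
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def _es_null(t_abs_w: np.ndarray, size: int, n_perm: int, rng) -> np.ndarray:
    """Null ES distribution from random same-size gene sets, vectorized."""
    N = t_abs_w.size
    # random subsets as the top-`size` entries of random keys per permutation
    keys = rng.random((n_perm, N))
    hit_idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    hits = np.zeros((n_perm, N), bool)
    hits[np.arange(n_perm)[:, None], hit_idx] = True
    denom = np.where(hits, t_abs_w, 0.0).sum(axis=1, keepdims=True)
    steps = np.where(hits, t_abs_w / np.clip(denom, 1e-300, None),
                     -1.0 / (N - size))
    run = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), idx]


def preranked_gsea(ranked: pd.Series, gene_sets: dict, n_perm: int = 10_000,
                   seed: int = 0, min_size: int = 3,
                   weight: float = 1.0) -> pd.DataFrame:
    """Permutation preranked GSEA over a ranked gene list.

    Each set is intersected with the list (sets smaller than *min_size*
    after intersection, or spanning the whole list, are skipped with a
    ``skipped`` reason). Two-tailed permutation p uses |ES| against random
    gene-label sets of matching size, with the +1 correction so p is never
    exactly zero; q is BH across scored sets.
    """
    if len(ranked) < 10:
        raise ValueError("ranked list needs at least 10 genes")
    from .screen import bh_adjust

    rng = np.random.default_rng(seed)
    t_abs_w = np.abs(ranked.to_numpy(float)) ** weight
    genes = set(ranked.index)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        inter = [g for g in members if g in genes]
        size = len(inter)
        if size < min_size or size >= len(ranked):
            rows.append({"set": name, "size": size, "es": np.nan,
                         "p": np.nan, "skipped": True})
            continue
        es = enrichment_score(ranked, inter, weight=weight)
        if size not in null_cache:
            null_cache[size] = _es_null(t_abs_w, size, n_perm, rng)
        null = null_cache[size]
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
        rows.append({"set": name, "size": size, "es": es, "p": float(p),
                     "skipped": False})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    scored = ~out["skipped"]
    if scored.any():
        out.loc[scored, "q"] = bh_adjust(out.loc[scored, "p"])
    return out


@dataclass
class RotatedPCModel:
    n_components: int
    loadings: pd.DataFrame              # proteins x components (rotated)
    rotation: np.ndarray
    scores: pd.DataFrame                # subjects x components (rotated)
    regression: pd.DataFrame            # per-component beta/se/t/p
    explained_variance_ratio: np.ndarray
    top_loadings: dict = field(default_factory=dict)


class RotatedPCRegression(BaseEstimator):
    """Varimax-rotated PC regression of protein changes on LST residuals.

    Columns of X are standardized (correlation-scale PCA); the smallest k
    components reaching ``var_target`` cumulative explained variance are
    retained (capped at ``max_components``), varimax-rotated, and the
    rotated scores regressed against y by OLS. Components with p < 0.05
    are reported with their top-loading proteins. Each rotated component is
    oriented so its largest-|loading| protein loads positively.
    """

    def __init__(self, var_target: float = 0.6, max_components: int = 10,
                 n_top: int = 10, alpha: float = 0.05):
        self.var_target = var_target
        self.max_components = max_components
        self.n_top = n_top
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, float)
        n, p = X.shape
        Xv = X.to_numpy(float)
        sd = Xv.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant protein column(s); drop before PCA")
        Z = (Xv - Xv.mean(axis=0)) / sd
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        eig = s ** 2 / (n - 1)
        evr = eig / eig.sum()
        k = int(np.searchsorted(np.cumsum(evr), self.var_target) + 1)
        k = min(k, self.max_components, p, n - 2)
        if k >= n:
            raise ValueError("cannot retain k >= n components")
        loadings = vt[:k].T * np.sqrt(eig[:k])     # variable-component corr
        if k > 1:
            rotated, rotation = rotate_factors(loadings, "varimax")
        else:
            rotated, rotation = loadings.copy(), np.eye(1)
        # standardized unrotated scores, then rotate
        scores_std = u[:, :k] * np.sqrt(n - 1)
        scores = scores_std @ rotation
        # orientation: largest-|loading| protein positive per component
        for j in range(k):
            lead = np.argmax(np.abs(rotated[:, j]))
            if rotated[lead, j] < 0:
                rotated[:, j] *= -1
                rotation[:, j] *= -1
                scores[:, j] *= -1

        comp_names = [f"RC{j + 1}" for j in range(k)]
        D = np.column_stack([np.ones(n), scores])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        dfree = n - k - 1
        sigma2 = resid @ resid / dfree
        cov = sigma2 * np.linalg.inv(D.T @ D)
        se = np.sqrt(np.diag(cov))
        tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), dfree)
        reg = pd.DataFrame({"component": ["intercept"] + comp_names,
                            "beta": beta, "se": se, "t": tstat, "p": pvals})

        load_df = pd.DataFrame(rotated, index=X.columns, columns=comp_names)
        top = {}
        for j, name in enumerate(comp_names):
            if pvals[j + 1] < self.alpha:
                order = load_df[name].abs().sort_values(ascending=False)
                top[name] = list(order.index[: self.n_top])
        self.model_ = RotatedPCModel(
            n_components=k, loadings=load_df, rotation=rotation,
            scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
            regression=reg, explained_variance_ratio=evr[:k],
            top_loadings=top)
        self.n_components_ = k
        return self


def pc_regression(delta: pd.DataFrame, residuals, var_target: float = 0.6,
                  max_components: int = 10) -> RotatedPCModel:
    """Functional wrapper over :class:`RotatedPCRegression`."""
    est = RotatedPCRegression(var_target=var_target,
                              max_components=max_components)
    est.fit(delta, residuals)
    return est.model_
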