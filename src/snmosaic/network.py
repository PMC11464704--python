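"""Weighted co-expression networks for single-nucleus data.

Sparse single-cell profiles are aggregated into metacells (small
nearest-neighbor groups in PC space averaged within sample x cell type), a
signed adjacency a_ij = ((1 + cor_ij)/2)^beta is raised to the smallest
integer power giving an approximately scale-free degree distribution, genes
are clustered on topological overlap, and each module is summarized by its
eigengene (sign-oriented first principal component). Hub genes are ranked by
kME (gene-eigengene correlation), module activity per cell by a rank-based
score, and module-trait relations by Pearson correlation of per-sample mean
eigengenes with FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .deg import bh_adjust

#: module label palette, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
UNASSIGNED = "grey"


@dataclass
class NetworkConfig:
    min_expressed_fraction: float = 0.05
    network_type: str = "signed"
    soft_power: int | str = "auto"
    scale_free_r2_threshold: float = 0.8
    min_module_size: int = 30
    metacell_k: int = 25
    cut_height: float = 0.99


@dataclass
class ModuleResult:
    labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    hubs: dict = field(default_factory=dict)
    soft_power: int = 0
    scale_free_r2: float = np.nan
    trait_correlations: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_network_genes(counts, min_fraction: float = 0.05) -> np.ndarray:
    """Keep genes detected (count > 0) in at least ``min_fraction`` of cells.
    ``counts`` is genes x cells; returns a boolean gene mask."""
    frac = np.asarray((counts > 0).mean(axis=1)).ravel()
    return frac >= min_fraction


def make_metacells(expr: pd.DataFrame, metadata: pd.DataFrame, k: int = 25,
                   strata_cols=("animal_id", "cell_type"), n_pcs: int = 20,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Average k-nearest-neighbor cell groups into metacells per stratum.

    ``expr`` is cells x genes (normalized). Within each stratum, cells are
    greedily partitioned: an unassigned seed cell absorbs its k-1 nearest
    unassigned neighbors in ``n_pcs``-dimensional PC space. A stratum with
    fewer than k cells is pooled into one metacell with a warning. Returns
    (metacell x gene matrix carrying stratum metadata in .attrs, mapping
    cell -> metacell id); the mapping partitions the cells.
    """
    from sklearn.decomposition import PCA
    rng = np.random.default_rng(seed)
    rows, meta_rows, mapping = [], [], {}
    mc_id = 0
    strata = metadata.groupby(list(strata_cols), observed=True, sort=True)
    for key, sub in strata:
        cells = sub.index.to_numpy()
        X = expr.loc[cells].to_numpy()
        if len(cells) < k:
            warnings.warn(f"stratum {key} has {len(cells)} < k={k} cells; "
                          "pooled into one metacell", stacklevel=2)
            groups = [np.arange(len(cells))]
        elif k == 1:
            groups = [np.array([i]) for i in range(len(cells))]
        else:
            comps = min(n_pcs, len(cells) - 1, X.shape[1])
            pcs = PCA(n_components=comps,
                      random_state=int(rng.integers(2**31))).fit_transform(X)
            groups = _greedy_knn_partition(pcs, k)
        for g in groups:
            name = f"mc{mc_id}"
            rows.append(pd.Series(X[g].mean(axis=0), index=expr.columns, name=name))
            rec = sub.iloc[0].to_dict()
            rec["n_cells"] = len(g)
            meta_rows.append(pd.Series(rec, name=name))
            for c in cells[g]:
                mapping[c] = name
            mc_id += 1
    mat = pd.DataFrame(rows)
    mat.attrs["metadata"] = pd.DataFrame(meta_rows)
    return mat, pd.Series(mapping, name="metacell")


def _greedy_knn_partition(pcs: np.ndarray, k: int) -> list[np.ndarray]:
    n = len(pcs)
    unassigned = np.ones(n, dtype=bool)
    groups = []
    d2 = ((pcs[:, None, :] - pcs[None, :, :]) ** 2).sum(axis=2)
    while unassigned.sum() >= k:
        seed_idx = int(np.argmax(unassigned))  # first unassigned cell
        cand = np.where(unassigned)[0]
        order = cand[np.argsort(d2[seed_idx, cand], kind="mergesort")]
        grp = order[:k]
        groups.append(grp)
        unassigned[grp] = False
    leftover = np.where(unassigned)[0]
    if leftover.size:
        groups[-1] = np.concatenate([groups[-1], leftover])
    return groups


# ---------------------------------------------------------------------------
# network construction

def _signed_adjacency(expr: np.ndarray, beta: float) -> np.ndarray:
    r = np.corrcoef(expr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return ((1.0 + r) / 2.0) ** beta


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (negative when the
    slope is positive, i.e. anti-scale-free)."""
    k = adjacency.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < n_bins or k.max() <= k.min():
        return -1.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean() + 1e-9))
    if len(xs) < 3:
        return -1.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_power(expr: pd.DataFrame, threshold: float = 0.8,
                    powers=range(1, 21)) -> tuple[int, float, bool]:
    """Smallest integer power whose signed adjacency reaches the scale-free
    fit threshold; falls back to the argmax with ``reached=False``."""
    X = expr.to_numpy()
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all genes constant")
    X = X[:, keep]
    if X.shape[1] < 50:
        raise ValueError("need at least 50 variable genes")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    base = (1.0 + r) / 2.0
    best_beta, best_r2 = None, -np.inf
    for beta in powers:
        r2 = scale_free_fit(base ** beta)
        if r2 >= threshold:
            return int(beta), float(r2), True
    # second pass records the best fit
    for beta in powers:
        r2 = scale_free_fit(base ** beta)
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), float(r2)
    return best_beta, best_r2, False


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(expr: pd.DataFrame, config: NetworkConfig | None = None,
                   ) -> ModuleResult:
    """Cluster genes on topological-overlap dissimilarity into color modules.

    Average-linkage hierarchical clustering of 1 - TOM, cut at a static
    height; clusters below ``min_module_size`` fall into the grey
    (unassigned) module. Labels are palette colors by decreasing size.
    """
    config = config or NetworkConfig()
    genes = expr.columns
    X = expr.to_numpy()
    variable = X.std(axis=0) > 0
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    if variable.sum() < config.min_module_size:
        result = ModuleResult(labels=labels)
        return result
    Xv = X[:, variable]
    if config.soft_power == "auto":
        beta, r2, reached = pick_soft_power(
            expr.loc[:, variable], threshold=config.scale_free_r2_threshold)
        if not reached:
            warnings.warn(f"no soft power reached scale-free R2 >= "
                          f"{config.scale_free_r2_threshold}; using beta={beta} "
                          f"(R2={r2:.2f})", stacklevel=2)
    else:
        beta = int(config.soft_power)
        r2 = np.nan
    A = _signed_adjacency(Xv, beta)
    tom = topological_overlap(A)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=config.cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= config.min_module_size].index
    order = sizes.loc[keep].sort_values(ascending=False).index
    color_of = {cl: MODULE_COLORS[i % len(MODULE_COLORS)]
                for i, cl in enumerate(order)}
    var_genes = genes[variable]
    for cl, color in color_of.items():
        labels.loc[var_genes[raw == cl]] = color
    return ModuleResult(labels=labels, soft_power=int(beta),
                        scale_free_r2=float(r2))


# ---------------------------------------------------------------------------
# eigengenes, kME, hubs

def compute_kme_hubs(expr: pd.DataFrame, labels: pd.Series,
                     n_hubs: int = 10) -> ModuleResult:
    """Eigengenes (sign-oriented PC1 per module), the full kME matrix and the
    top-``n_hubs`` genes per module by within-module kME."""
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no non-grey modules")
    # stable order: by size desc then name
    modules = sorted(modules, key=lambda m: (-(labels == m).sum(), m))
    eig = {}
    for m in modules:
        genes = labels.index[labels == m]
        sub = expr[genes].to_numpy()
        Z = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0,
                                                sub.std(axis=0), 1.0)
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        r = np.array([np.corrcoef(pc1, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        if np.nanmean(r) < 0:
            pc1 = -pc1
        eig[m] = pc1
    eigengenes = pd.DataFrame(eig, index=expr.index)
    Xz = (expr - expr.mean()) / expr.std().replace(0, 1.0)
    Ez = (eigengenes - eigengenes.mean()) / eigengenes.std()
    kme = (Xz.T @ Ez) / (len(expr) - 1)   # ddof=1 matches pandas std
    hubs = {}
    for m in modules:
        members = labels.index[labels == m]
        ranked = kme.loc[members, m].sort_values(ascending=False)
        if len(members) < n_hubs:
            warnings.warn(f"module {m} has fewer than {n_hubs} genes; "
                          "all returned as hubs", stacklevel=2)
        hubs[m] = ranked.head(n_hubs).index.tolist()
    return ModuleResult(labels=labels, eigengenes=eigengenes, kme=kme, hubs=hubs)


def trait_correlation(eigengenes: pd.DataFrame, metadata: pd.DataFrame,
                      traits: list[str], sample_col: str = "animal_id",
                      stratify_col: str | None = None) -> pd.DataFrame:
    """Pearson correlation of per-sample mean eigengenes with traits.

    Eigengenes are averaged per sample (and per stratum when stratified),
    binary traits are coded 0/1, p-values are BH-adjusted over the whole
    module x trait (x stratum) grid, and stars mark adj_p <= .05/.01/.001.
    """
    meta = metadata.loc[eigengenes.index]
    strata = ([("all", slice(None))] if stratify_col is None
              else [(s, meta[stratify_col] == s)
                    for s in sorted(meta[stratify_col].unique())])
    rows = []
    for stratum, mask in strata:
        eg = eigengenes.loc[mask] if not isinstance(mask, slice) else eigengenes
        md = meta.loc[eg.index]
        per_sample = eg.groupby(md[sample_col], observed=True).mean()
        if len(per_sample) < 3:
            warnings.warn(f"stratum {stratum}: fewer than 3 samples", stacklevel=2)
            continue
        trait_vals = md.groupby(sample_col, observed=True)[traits].first()
        trait_vals = trait_vals.loc[per_sample.index]
        for trait in traits:
            t = trait_vals[trait]
            if t.dtype == object or t.dtype.name in ("category", "bool"):
                codes = pd.factorize(t, sort=True)[0].astype(float)
            else:
                codes = t.astype(float).to_numpy()
            for m in eigengenes.columns:
                x = per_sample[m].to_numpy()
                if np.std(codes) == 0 or np.std(x) == 0:
                    rows.append((m, trait, stratum, np.nan, np.nan))
                    continue
                r, p = stats.pearsonr(x, codes)
                rows.append((m, trait, stratum, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["module", "trait", "stratum", "r", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["stars"] = out["adj_p"].map(
        lambda q: "***" if q <= 0.001 else "**" if q <= 0.01
        else "*" if q <= 0.05 else "")
    return out


def module_score(expr: pd.DataFrame, gene_set, rank_cap: int = 1500,
                 ) -> pd.Series:
    """Rank-based per-cell activity score of a gene set, in [0, 1].

    Genes are ranked per cell by decreasing expression (ties get the average
    rank; ranks beyond ``rank_cap`` are set to rank_cap + 1); the score is
    1 - (mean set rank - (|set|+1)/2) / rank_cap, clipped to [0, 1].
    """
    genes = [g for g in gene_set if g in expr.columns]
    if not genes:
        return pd.Series(np.nan, index=expr.index, name="score")
    ranks = expr.rank(axis=1, ascending=False, method="average")
    ranks = ranks.clip(upper=rank_cap + 1)
    mean_rank = ranks[genes].mean(axis=1)
    score = 1.0 - (mean_rank - (len(genes) + 1) / 2.0) / rank_cap
    return score.clip(0.0, 1.0).rename("score")
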