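"""Quality-control filtering, normalization, cell-type assignment and
composition testing.

Cells pass QC when their mitochondrial fraction, detected-gene count and UMI
count all lie strictly inside the configured bounds. Typing is a
nearest-centroid correlation classifier over a marker panel — a deliberately
transparent stand-in for reference label transfer, adequate for data whose
marker structure is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from .simulate import BROAD_CLASS


@dataclass
class QCThresholds:
    """All five bounds are strict inequalities."""
    max_mito_fraction: float = 0.07
    min_genes: int = 200
    max_genes: int = 5625
    min_umi: int = 208
    max_umi: int = 16300

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0,1]")
        if self.min_genes >= self.max_genes or self.min_umi >= self.max_umi:
            raise ValueError("each min threshold must be below its max")


def compute_qc_metrics(adata: AnnData, mito_genes=None,
                       mito_prefixes=("mt-", "MT-")) -> AnnData:
    """Attach n_umi, n_genes and mito_fraction (on raw counts) to .obs."""
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    if mito_genes is not None:
        mito_mask = adata.var_names.isin(mito_genes)
    else:
        mito_mask = adata.var_names.str.startswith(mito_prefixes)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    adata.obs["n_umi"] = n_umi
    adata.obs["n_genes"] = n_genes
    adata.obs["mito_fraction"] = np.divide(
        mito, n_umi, out=np.zeros_like(mito, dtype=float), where=n_umi > 0)
    return adata


def qc_filter(adata: AnnData, thresholds: QCThresholds | None = None,
              mito_genes=None, mito_prefixes=("mt-", "MT-"),
              ) -> tuple[AnnData, dict]:
    """Keep cells strictly inside every bound; report removals per criterion."""
    t = thresholds or QCThresholds()
    if not {"n_umi", "n_genes", "mito_fraction"} <= set(adata.obs.columns):
        adata = compute_qc_metrics(adata, mito_genes, mito_prefixes)
    obs = adata.obs
    fail_mito = ~(obs["mito_fraction"] < t.max_mito_fraction)
    fail_genes = ~((obs["n_genes"] > t.min_genes) & (obs["n_genes"] < t.max_genes))
    fail_umi = ~((obs["n_umi"] > t.min_umi) & (obs["n_umi"] < t.max_umi))
    keep = ~(fail_mito | fail_genes | fail_umi)
    report = {
        "n_input": adata.n_obs,
        "n_kept": int(keep.sum()),
        "removed_mito": int(fail_mito.sum()),
        "removed_genes": int(fail_genes.sum()),
        "removed_umi": int(fail_umi.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    return adata[keep.to_numpy()].copy(), report


def log_normalize(adata: AnnData, scale: float = 1e4,
                  layer: str = "lognorm") -> AnnData:
    """ln(1 + count / library_size * scale) per cell; zero-library cells are
    flagged in .obs['zero_library'] and excluded."""
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    lib = np.asarray(X.sum(axis=1)).ravel()
    zero = lib == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} cells with zero library size",
                      stacklevel=2)
        adata = adata[~zero].copy()
        X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
        lib = lib[~zero]
    norm = X.astype(float).tocsr(copy=True)
    norm.data = norm.data * np.repeat(scale / lib, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    adata.layers[layer] = norm
    adata.obs["library_size"] = lib
    return adata


def assign_cell_types(adata: AnnData, panel, layer: str = "lognorm",
                      min_correlation: float = 0.1) -> pd.DataFrame:
    """Nearest-centroid Pearson classifier over the panel genes.

    Returns a frame with cell_type, broad_class and confidence (top minus
    second correlation); cells whose best correlation is below
    ``min_correlation`` — including all-zero cells — are 'unassigned'.
    """
    genes = [g for g in panel.centroids.columns if g in adata.var_names]
    if len(genes) < 10:
        raise ValueError(
            f"only {len(genes)} panel genes present in the matrix (need >= 10)")
    X = adata.layers.get(layer, adata.X)
    sub = X[:, adata.var_names.get_indexer(genes)]
    if sparse.issparse(sub):
        sub = np.asarray(sub.todense())
    C = panel.centroids[genes].to_numpy()
    r = _rowwise_pearson(sub, C)
    order = np.argsort(r, axis=1)
    top, second = order[:, -1], order[:, -2]
    best = r[np.arange(len(r)), top]
    conf = best - r[np.arange(len(r)), second]
    labels = panel.centroids.index.to_numpy()[top].astype(object)
    labels[~(best >= min_correlation)] = "unassigned"
    out = pd.DataFrame({
        "cell_type": labels,
        "confidence": np.where(best >= min_correlation, conf, 0.0),
        "best_correlation": best,
    }, index=adata.obs_names)
    out["broad_class"] = out["cell_type"].map(
        lambda t: BROAD_CLASS.get(t, "non_neuronal" if t != "unassigned" else "unassigned"))
    return out


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of A with every row of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(A, axis=1)
    sb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A @ B.T) / np.outer(sa, sb)
    return np.nan_to_num(r, nan=-np.inf)


def summarize_markers(adata: AnnData, labels: pd.Series, markers: dict,
                      layer: str = "lognorm") -> pd.DataFrame:
    """Per (cell type, marker): mean log-normalized expression and percent of
    cells with a nonzero raw count."""
    rows = []
    X = adata.layers.get(layer, adata.X)
    raw = adata.X
    for ct in sorted(labels.unique()):
        mask = (labels == ct).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"cell type {ct} has zero cells; row omitted", stacklevel=2)
            continue
        for marker_type, genes in markers.items():
            for g in genes:
                if g not in adata.var_names:
                    continue
                j = adata.var_names.get_loc(g)
                col = X[mask, j]
                rawcol = raw[mask, j]
                mean = float(col.mean())
                pct = float(np.asarray((rawcol > 0).sum()) / mask.sum() * 100.0)
                rows.append((ct, marker_type, g, mean, pct))
    return pd.DataFrame(rows, columns=[
        "cell_type", "marker_of", "gene", "mean_expression", "percent_expressed"])


def composition_test(metadata: pd.DataFrame, type_col: str = "cell_type",
                     time_col: str = "timepoint", genotype_col: str | None = None,
                     seed: int = 0) -> dict:
    """Chi-square homogeneity test of cell-type composition across timepoints.

    When more than 20% of expected counts fall below 5, the p-value is
    replaced by a permutation null (labels shuffled across cells).
    """
    if metadata[time_col].nunique() < 2:
        raise ValueError("composition test needs at least two timepoints")
    results = {}
    strata = ([("all", metadata)] if genotype_col is None
              else list(metadata.groupby(genotype_col, observed=True)))
    for name, df in strata:
        table = pd.crosstab(df[type_col], df[time_col])
        chi2, p, dof, expected = stats.chi2_contingency(table)
        method = "chi2"
        if (expected < 5).mean() > 0.2:
            method = "permutation"
            rng = np.random.default_rng(seed)
            perm_stats = np.empty(999)
            types = df[type_col].to_numpy()
            times = df[time_col].to_numpy()
            for i in range(999):
                perm = pd.crosstab(pd.Series(rng.permutation(types)), pd.Series(times))
                perm_stats[i] = stats.chi2_contingency(perm)[0]
            p = float((1 + (perm_stats >= chi2).sum()) / 1000)
            warnings.warn("sparse contingency table: using permutation null",
                          stacklevel=2)
        results[name] = {"table": table,
                         "proportions": table / table.sum(axis=0),
                         "chi2": float(chi2), "p": float(p), "dof": int(dof),
                         "method": method}
    return results
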