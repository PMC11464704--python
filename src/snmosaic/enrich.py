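"""Gene-set enrichment, cross-list overlap, ortholog mapping, direction
concordance and the gene-length trend test.

Enrichment is one-sided Fisher over-representation: for a DEG list of size n
drawn from a universe of size N, the probability of seeing k or more list
members in a term of size K is the hypergeometric upper tail. The same
machinery tests the overlap of two DEG lists (e.g. across species after
ortholog mapping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust


@dataclass
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def fisher_enrichment(deg_genes, gene_sets: list[GeneSet], universe,
                      ) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper tail) over-representation per
    term, BH-adjusted across terms. Sets are intersected with the universe;
    the sample odds ratio of the 2x2 table is reported."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_genes) & universe
    N, n = len(universe), len(deg)
    rows = []
    for gs in gene_sets:
        members = gs.genes & universe
        K = len(members)
        k = len(members & deg)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((gs.name, k, K, n, N, odds, p))
    out = pd.DataFrame(rows, columns=["term", "k_overlap", "set_size",
                                      "list_size", "universe_size",
                                      "odds_ratio", "p"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def overlap_significance(list_a, list_b, universe) -> dict:
    """Fisher one-sided test of the overlap of two gene lists, plus Jaccard
    index and sample odds ratio."""
    universe = set(universe)
    a, b = set(list_a) & universe, set(list_b) & universe
    if not a or not b:
        warnings.warn("empty gene list: overlap p fixed at 1", stacklevel=2)
        return {"p": 1.0, "jaccard": 0.0, "odds_ratio": 0.0,
                "k_overlap": 0, "n_a": len(a), "n_b": len(b)}
    k = len(a & b)
    N = len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, len(a), len(b)))
    tl = k
    tr = len(b) - k
    bl = len(a) - k
    br = N - len(a) - len(b) + k
    odds = (tl * br) / (tr * bl) if tr * bl > 0 else np.inf
    return {"p": p, "jaccard": k / len(a | b), "odds_ratio": odds,
            "k_overlap": k, "n_a": len(a), "n_b": len(b)}


# ---------------------------------------------------------------------------
# ortholog mapping and cross-species concordance

def map_orthologs(symbols, table: pd.DataFrame, case_fallback: bool = True,
                  ) -> tuple[dict, list]:
    """Map symbols via a two-column ortholog table (source, target).

    Exact match first; then the cross-species case convention (mouse
    Title-case <-> human UPPER) as a fallback. Many-to-many rows are kept
    (first match wins) and flagged in the unmapped report as duplicates.
    Returns (mapping, unmapped symbols).
    """
    src, dst = table.columns[:2]
    lut: dict[str, str] = {}
    duplicated = set()
    for s, d in zip(table[src], table[dst]):
        if s in lut and lut[s] != d:
            duplicated.add(s)
            continue
        lut[s] = d
    if duplicated:
        warnings.warn(f"{len(duplicated)} many-to-many ortholog rows; "
                      "first mapping kept", stacklevel=2)
    mapping, unmapped = {}, []
    for sym in symbols:
        if sym in lut:
            mapping[sym] = lut[sym]
        elif case_fallback and sym.upper() in lut:
            mapping[sym] = lut[sym.upper()]
        elif case_fallback and sym.capitalize() in lut:
            mapping[sym] = lut[sym.capitalize()]
        elif case_fallback:
            # bare case-convention flip when no table row exists
            flipped = sym.upper() if sym != sym.upper() else sym.capitalize()
            if flipped != sym:
                mapping[sym] = flipped
            else:
                unmapped.append(sym)
        else:
            unmapped.append(sym)
    return mapping, unmapped


def top_direction_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                              ortholog_map: dict | None = None, k: int = 20,
                              alpha: float = 0.05,
                              exclude_unmapped: bool = False) -> dict:
    """Directional agreement of the top-k DEGs of A with their orthologs in B.

    Top-k per direction is chosen by |log2fc| among A's significant rows
    (adj_p <= alpha); a gene counts as concordant when its mapped ortholog is
    significant in B with the same fold-change sign.
    """
    sig_a = table_a[table_a["adj_p"] <= alpha]
    sig_b = table_b[table_b["adj_p"] <= alpha]
    b_sign = dict(zip(sig_b["gene"], np.sign(sig_b["log2fc"])))
    out = {}
    for direction, sign in (("up", 1), ("down", -1)):
        cand = sig_a[np.sign(sig_a["log2fc"]) == sign]
        top = cand.reindex(cand["log2fc"].abs().sort_values(ascending=False).index)
        top = top.head(k)
        n_conc = n_unmapped = 0
        for g in top["gene"]:
            mapped = ortholog_map.get(g, g) if ortholog_map else g
            if ortholog_map is not None and g not in ortholog_map:
                n_unmapped += 1
                if exclude_unmapped:
                    continue
            if b_sign.get(mapped, 0) == sign:
                n_conc += 1
        denom = len(top) - (n_unmapped if exclude_unmapped else 0)
        out[direction] = {"concordant": n_conc, "k": int(denom),
                          "unmapped": n_unmapped}
    return out


# ---------------------------------------------------------------------------
# gene-length trend

def gene_length_trend(deg_table: pd.DataFrame, gene_lengths: pd.Series,
                      alpha: float = 0.05) -> dict:
    """Is fold change related to gene length (long-gene repression)?

    Reports the Spearman correlation of log2fc with log10 length over all
    tested genes, and a two-sample KS test comparing significant-DEG lengths
    against the background. Genes without a length are excluded and counted.
    """
    merged = deg_table.merge(gene_lengths.rename("length"), left_on="gene",
                             right_index=True, how="left")
    missing = int(merged["length"].isna().sum())
    have = merged.dropna(subset=["length"])
    if len(have) < 0.8 * len(deg_table):
        warnings.warn(f"lengths available for only {len(have)}/{len(deg_table)} genes",
                      stacklevel=2)
    if have["log2fc"].nunique() <= 1 or len(have) < 3:
        rho, rho_p = 0.0, 1.0
    else:
        rho, rho_p = stats.spearmanr(np.log10(have["length"]), have["log2fc"])
    sig = have[have["adj_p"] <= alpha]
    if len(sig) >= 2 and len(have) > len(sig):
        ks, ks_p = stats.ks_2samp(sig["length"], have["length"])
    else:
        ks, ks_p = np.nan, np.nan
    return {"spearman_rho": float(rho), "spearman_p": float(rho_p),
            "ks_stat": float(ks), "ks_p": float(ks_p),
            "n_genes": len(have), "n_missing_length": missing,
            "n_significant": len(sig)}
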