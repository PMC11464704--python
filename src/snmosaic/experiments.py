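"""The five-contrast design separating cell-autonomous from
non-cell-autonomous effects.

Experiments 1-2 compare mutant to wild-type animals within each sex.
Experiments 3-5 exploit X-inactivation mosaicism in heterozygous females:
(3) WT-allele cells of het females vs WT females — any signal here is
non-cell-autonomous, since the cells themselves express the WT allele;
(4) MUT-allele cells of het females vs WT females — cell-autonomous plus
environmental signal; (5) MUT- vs WT-allele cells *within* het females —
cell-autonomous signal with the animal environment held constant.
Cross-experiment significance membership then classifies each gene's
effect mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg import differential_expression

BROAD_CLASSES = ("glutamatergic", "GABAergic", "non_neuronal")
MALE_TIMEPOINTS = ("P30", "P60", "P120")
FEMALE_TIMEPOINTS = ("P30", "P60", "P150")


@dataclass
class ContrastSpec:
    experiment_id: int
    name: str
    group_a: dict            # metadata-field -> required value(s)
    group_b: dict
    timepoints: tuple[str, ...]
    cell_classes: tuple[str, ...] = BROAD_CLASSES

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast selectors must be disjoint")


def build_contrasts(significance_cutoff: float = 0.05) -> list[ContrastSpec]:
    """The default suite of five experiments.

    1: null males vs WT males (allele call ignored), male timepoints.
    2: het females vs WT females (all cells), female timepoints.
    3: WT-allele cells of het females vs WT-allele cells of WT females.
    4: MUT-allele cells of het females vs WT-allele cells of WT females.
    5: MUT- vs WT-allele cells within het females.
    3-5 run on the neuronal broad classes only.
    """
    neuronal = ("glutamatergic", "GABAergic")
    return [
        ContrastSpec(1, "male_null_vs_wt",
                     {"genotype": "null_male"}, {"genotype": "wt_male"},
                     MALE_TIMEPOINTS, BROAD_CLASSES),
        ContrastSpec(2, "female_het_vs_wt",
                     {"genotype": "het_female"}, {"genotype": "wt_female"},
                     FEMALE_TIMEPOINTS, BROAD_CLASSES),
        ContrastSpec(3, "female_wtcell_het_vs_wt",
                     {"genotype": "het_female", "allele_call": "WT"},
                     {"genotype": "wt_female", "allele_call": "WT"},
                     FEMALE_TIMEPOINTS, neuronal),
        ContrastSpec(4, "female_mutcell_het_vs_wt",
                     {"genotype": "het_female", "allele_call": "MUT"},
                     {"genotype": "wt_female", "allele_call": "WT"},
                     FEMALE_TIMEPOINTS, neuronal),
        ContrastSpec(5, "female_mutcell_vs_wtcell_within_het",
                     {"genotype": "het_female", "allele_call": "MUT"},
                     {"genotype": "het_female", "allele_call": "WT"},
                     FEMALE_TIMEPOINTS, neuronal),
    ]


def _select(meta: pd.DataFrame, selector: dict) -> np.ndarray:
    mask = np.ones(len(meta), dtype=bool)
    for key, val in selector.items():
        col = meta[key].to_numpy()
        if isinstance(val, (list, tuple, set, frozenset)):
            mask &= np.isin(col, list(val))
        else:
            mask &= col == val
    return mask


@dataclass
class SuiteResult:
    deg_tables: dict = field(default_factory=dict)   # (exp, class, tp) -> DataFrame
    low_tables: dict = field(default_factory=dict)   # lower-confidence ZINB calls
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped: list = field(default_factory=list)


def run_suite(counts: np.ndarray, meta: pd.DataFrame,
              contrasts: list[ContrastSpec] | None = None,
              genes: list[str] | None = None,
              lib_sizes: np.ndarray | None = None,
              alpha: float = 0.05, seed: int = 0,
              class_col: str = "broad_class",
              run_zinb: bool = False,
              min_cells_per_group: int = 20) -> SuiteResult:
    """Run every contrast per cell class x timepoint and summarize DEG counts.

    ``counts`` is genes x cells aligned with ``meta`` rows. Significant-gene
    counts use BH-adjusted p <= alpha on the high-detection (moderated GLS)
    tables only; ZINB calls on the low-detection partition, when requested,
    go to a separate lower-confidence table.
    """
    if contrasts is None:
        contrasts = build_contrasts()
    counts = np.asarray(counts) if not hasattr(counts, "toarray") else counts.toarray()
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    result = SuiteResult()
    rows = []
    for spec in contrasts:
        zinb_here = run_zinb and spec.experiment_id in (1, 2)
        for cls in spec.cell_classes:
            for tp in spec.timepoints:
                stratum = (meta[class_col] == cls) & (meta["timepoint"] == tp)
                mask_a = _select(meta, spec.group_a) & stratum.to_numpy()
                mask_b = _select(meta, spec.group_b) & stratum.to_numpy()
                if mask_a.sum() < min_cells_per_group or mask_b.sum() < min_cells_per_group:
                    result.skipped.append((spec.experiment_id, cls, tp,
                                           int(mask_a.sum()), int(mask_b.sum())))
                    continue
                idx = np.where(mask_a | mask_b)[0]
                group = np.where(mask_a[idx], "A", "B")
                import zlib
                sub_seed = (seed * 131 + spec.experiment_id * 17
                            + zlib.crc32(f"{cls}:{tp}".encode()) % 1000) % (2**31)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    high, low_tab, info = differential_expression(
                        counts[:, idx], np.asarray(lib_sizes)[idx],
                        group, meta["animal_id"].to_numpy()[idx],
                        genes, seed=sub_seed, run_zinb=zinb_here)
                key = (spec.experiment_id, cls, tp)
                if len(high):
                    # group "A" is the mutant side and sorts first, so log2fc
                    # is already mutant minus control
                    high = high.copy()
                    high["experiment_id"] = spec.experiment_id
                    high["cell_class"] = cls
                    high["timepoint"] = tp
                    result.deg_tables[key] = high
                if len(low_tab):
                    low_tab = low_tab.copy()
                    low_tab["experiment_id"] = spec.experiment_id
                    low_tab["cell_class"] = cls
                    low_tab["timepoint"] = tp
                    low_tab["confidence"] = "lower"
                    result.low_tables[key] = low_tab
                sig = high[high["adj_p"] <= alpha] if len(high) else pd.DataFrame()
                n_up = int((sig["log2fc"] > 0).sum()) if len(sig) else 0
                n_down = int((sig["log2fc"] < 0).sum()) if len(sig) else 0
                n_animals = int(meta["animal_id"].iloc[idx].nunique())
                rows.append((spec.experiment_id, cls, tp, n_up, n_down,
                             n_up + n_down, n_animals))
    result.summary = pd.DataFrame(rows, columns=[
        "experiment_id", "cell_class", "timepoint", "n_up", "n_down",
        "n_total_significant", "n_animals"])
    return result


def classify_effect_mode(tables: dict, alpha: float = 0.05,
                         cell_class: str | None = None,
                         timepoint: str | None = None) -> pd.DataFrame:
    """Classify genes by significance membership across experiments 3, 4, 5.

    Significant in 3 and not 5 -> non_cell_autonomous (the WT-allele cells
    changed, so the environment did it). Significant in 5 (with 4 concurring)
    and not 3 -> cell_autonomous. Significant in both 3 and 5 -> mixed.
    Anything else -> none.
    """
    def _table(exp):
        matches = [v for (e, c, t), v in tables.items()
                   if e == exp
                   and (cell_class is None or c == cell_class)
                   and (timepoint is None or t == timepoint)]
        if not matches:
            raise KeyError(f"missing DEG table for experiment {exp}")
        return pd.concat(matches, ignore_index=True)

    t3, t4, t5 = _table(3), _table(4), _table(5)
    sig = {e: set(t.loc[t["adj_p"] <= alpha, "gene"])
           for e, t in ((3, t3), (4, t4), (5, t5))}
    genes = sorted(set(t3["gene"]) | set(t4["gene"]) | set(t5["gene"]))
    rows = []
    for g in genes:
        in3, in4, in5 = g in sig[3], g in sig[4], g in sig[5]
        if in3 and in5:
            mode = "mixed"
        elif in3:
            mode = "non_cell_autonomous"
        elif in5 and in4:
            mode = "cell_autonomous"
        else:
            mode = "none"
        rows.append((g, mode, in3, in4, in5))
    return pd.DataFrame(rows, columns=["gene", "mode", "sig_exp3", "sig_exp4",
                                       "sig_exp5"])
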