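"""Synthetic cohorts, counts, reads and panels with known ground truth.

The generator emulates a longitudinal single-nucleus study of an X-linked
mutation: heterozygous females are random-XCI mosaics of WT-expressing and
mutant-expressing cells, hemizygous males are single-allele, and planted
transcriptional effects are either cell-autonomous (present only in
mutant-allele cells) or non-cell-autonomous (present in every cell of a
mutant animal, including its WT-allele cells).

Counts are negative binomial with mean = library size x relative abundance,
an animal-level random intercept on the log2 mean calibrated to a target
intra-animal correlation, and cell-type marker structure so that
nearest-centroid labeling is well posed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

SEXES = ("M", "F")
GENOTYPES = ("het_female", "wt_female", "null_male", "wt_male")
TIMEPOINTS = ("P30", "P60", "P120", "P150")
MUTANT_GENOTYPES = frozenset({"het_female", "null_male"})

#: 14-type cortical taxonomy: 4 excitatory layers, 5 inhibitory subclasses,
#: 5 non-neuronal types.
DEFAULT_TAXONOMY = (
    "L2/3", "L4", "L5", "L6",
    "Pvalb", "Vip", "Sst", "Sncg", "Lamp5",
    "Astro", "Oligo", "Endo", "Peri", "Micro",
)

BROAD_CLASS = {
    "L2/3": "glutamatergic", "L4": "glutamatergic",
    "L5": "glutamatergic", "L6": "glutamatergic",
    "Pvalb": "GABAergic", "Vip": "GABAergic", "Sst": "GABAergic",
    "Sncg": "GABAergic", "Lamp5": "GABAergic",
    "Astro": "non_neuronal", "Oligo": "non_neuronal", "Endo": "non_neuronal",
    "Peri": "non_neuronal", "Micro": "non_neuronal",
}

N_MITO_GENES = 13
LN2SQ = np.log(2.0) ** 2


def default_cohort_layout() -> list[tuple[str, str, str, int]]:
    """Default cohort: 2 males/genotype at P30/P60/P120, 2 females/genotype
    at P30/P60 and 4 at the late female timepoint P150 — 28 animals."""
    layout: list[tuple[str, str, str, int]] = []
    for tp in ("P30", "P60", "P120"):
        for gt in ("null_male", "wt_male"):
            layout.append(("M", gt, tp, 2))
    for tp in ("P30", "P60"):
        for gt in ("het_female", "wt_female"):
            layout.append(("F", gt, tp, 2))
    for gt in ("het_female", "wt_female"):
        layout.append(("F", gt, "P150", 4))
    return layout


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    seed: int = 0
    cohort_layout: list[tuple[str, str, str, int]] | None = None
    cells_per_animal: int = 100
    n_genes: int = 1000
    n_cell_types: int = 14
    xci_skew: float = 0.5          # P(het-female cell expresses the WT allele)
    frac_ca: float = 0.0           # fraction of genes with cell-autonomous effects
    frac_nca: float = 0.0          # fraction with non-cell-autonomous effects
    effect_log2fc: float = 1.0
    icc: float = 0.0               # target intra-animal correlation of log-expression
    libsize_meanlog: float = float(np.log(5000.0))
    libsize_sdlog: float = 0.3
    nb_dispersion: float = 0.1     # NB variance = mu + dispersion * mu^2
    read_error_rate: float = 0.0
    umis_per_mecp2_cell_mean: float = 3.0
    decoy_fraction: float = 0.2    # off-target reads as a fraction of all reads
    marker_log2fc: float = 2.0
    markers_per_type: int = 10

    def __post_init__(self) -> None:
        if self.cohort_layout is None:
            self.cohort_layout = default_cohort_layout()
        if not 0.0 < self.xci_skew < 1.0:
            raise ConfigurationError(f"xci_skew must be in (0,1), got {self.xci_skew}")
        if self.frac_ca < 0 or self.frac_nca < 0 or self.frac_ca + self.frac_nca > 1:
            raise ConfigurationError(
                f"frac_ca + frac_nca must lie in [0,1]: {self.frac_ca} + {self.frac_nca}"
            )
        if not 0.0 <= self.icc < 1.0:
            raise ConfigurationError(f"icc must be in [0,1), got {self.icc}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0.0 <= self.read_error_rate < 0.5:
            raise ConfigurationError(
                f"read_error_rate must be in [0,0.5), got {self.read_error_rate}"
            )
        for name in ("cells_per_animal", "n_genes", "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_cell_types > self.n_genes:
            raise ConfigurationError("more cell types than genes")


@dataclass
class Animal:
    animal_id: str
    sex: str
    genotype: str
    timepoint: str
    body_weight: float
    disease_score: int


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator.

    gene_effects: per-gene effect class and signed log2 fold change.
    cell_allele: barcode -> expressed allele (WT / MUT; NA outside mosaic logic
    never occurs here: males carry their hemizygous allele).
    gene_module: optional gene -> module id for co-expression simulations.
    module_traits: optional module -> {trait: coupling} map.
    """
    gene_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "effect_class", "log2fc"])
    )
    cell_allele: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    gene_module: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    module_traits: dict[str, dict[str, float]] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationTruth):
            return NotImplemented
        return (
            self.gene_effects.reset_index(drop=True).equals(
                other.gene_effects.reset_index(drop=True))
            and self.cell_allele.equals(other.cell_allele)
            and self.gene_module.equals(other.gene_module)
            and self.module_traits == other.module_traits
        )


# ---------------------------------------------------------------------------
# cohort

_SEVERITY = {"null_male": 2.0, "het_female": 1.2, "wt_male": 0.0, "wt_female": 0.0}
_STAGE_BASELINE = {"P30": 1.0, "P60": 2.0, "P120": 3.5, "P150": 3.5}
_BASE_WEIGHT = {"P30": 14.0, "P60": 20.0, "P120": 26.0, "P150": 26.0}


def _disease_score(genotype: str, timepoint: str) -> int:
    return int(min(7, round(_STAGE_BASELINE[timepoint] * _SEVERITY[genotype])))


def simulate_cohort(config: SimulationConfig) -> tuple[list[Animal], pd.DataFrame]:
    """Build the animal roster and a per-cell metadata skeleton.

    Each het-female cell draws its expressed allele Bernoulli(xci_skew) (WT
    with probability ``xci_skew``); male and homozygous cells carry the single
    allele implied by the animal genotype. Cell types are drawn uniformly.
    """
    rng = np.random.default_rng(_substream(config.seed, "cohort"))
    animals: list[Animal] = []
    for entry in config.cohort_layout:
        sex, genotype, timepoint, n = entry
        if sex not in SEXES or genotype not in GENOTYPES or timepoint not in TIMEPOINTS:
            raise ConfigurationError(f"unknown sex/genotype/timepoint in layout entry {entry!r}")
        if (sex == "M") != (genotype in ("null_male", "wt_male")):
            raise ConfigurationError(f"sex/genotype mismatch in layout entry {entry!r}")
        for _ in range(int(n)):
            idx = len(animals) + 1
            score = _disease_score(genotype, timepoint)
            weight = _BASE_WEIGHT[timepoint] * (1.0 if sex == "M" else 0.85)
            weight *= 1.0 - 0.04 * score
            weight += rng.normal(0.0, 0.8)
            animals.append(Animal(
                animal_id=f"A{idx:03d}", sex=sex, genotype=genotype,
                timepoint=timepoint, body_weight=round(float(weight), 2),
                disease_score=score,
            ))

    types = list(DEFAULT_TAXONOMY[: config.n_cell_types]) if config.n_cell_types <= len(
        DEFAULT_TAXONOMY) else [f"T{i}" for i in range(config.n_cell_types)]
    rows = []
    for a in animals:
        n_cells = config.cells_per_animal
        cell_types = rng.choice(types, size=n_cells)
        if a.genotype == "het_female":
            allele = np.where(rng.random(n_cells) < config.xci_skew, "WT", "MUT")
        elif a.genotype == "null_male":
            allele = np.repeat("MUT", n_cells)
        else:
            allele = np.repeat("WT", n_cells)
        barcodes = _random_barcodes(rng, n_cells, prefix=a.animal_id)
        for bc, ct, al in zip(barcodes, cell_types, allele):
            rows.append((bc, a.animal_id, a.sex, a.genotype, a.timepoint, ct, al,
                         a.body_weight, a.disease_score))
    cells = pd.DataFrame(rows, columns=[
        "barcode", "animal_id", "sex", "genotype", "timepoint",
        "cell_type", "true_allele", "body_weight", "disease_score"])
    cells["broad_class"] = cells["cell_type"].map(
        lambda t: BROAD_CLASS.get(t, "non_neuronal"))
    return animals, cells


def _random_barcodes(rng: np.random.Generator, n: int, prefix: str = "") -> list[str]:
    alphabet = np.array(list("ACGT"))
    seqs = rng.choice(alphabet, size=(n, 16))
    tags = ["".join(s) for s in seqs]
    # prefix guarantees uniqueness across animals
    return [f"{prefix}:{t}" if prefix else t for t in tags]


def _substream(seed: int, label: str) -> np.random.SeedSequence:
    # zlib.crc32 is stable across processes (str hash() is salted)
    import zlib
    return np.random.SeedSequence(entropy=seed,
                                  spawn_key=(zlib.crc32(label.encode()),))


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    animals: list[Animal],
    cells: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[sparse.csr_matrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """NB counts with marker structure, animal intercepts and planted effects.

    Returns (counts cells x genes CSR, gene table, cell metadata, truth).
    The animal random intercept acts on the log2 mean; its per-gene variance is
    solved so that the intra-animal correlation of log expression matches
    ``config.icc`` (a delta-method within-cell variance (1/mu + dispersion) /
    ln(2)^2 is inverted analytically).
    """
    rng = np.random.default_rng(_substream(config.seed, "counts"))
    n_genes, n_cells = config.n_genes, len(cells)

    gene_names = _gene_names(n_genes)
    is_mito = np.array([g.startswith("mt-") for g in gene_names])

    # relative abundances: lognormal, mito genes set to realistic modest share
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base[is_mito] = np.exp(rng.normal(1.0, 0.3, is_mito.sum()))
    q = base / base.sum()

    # marker layout mirrors simulate_marker_panel (shared deterministic rule)
    types = sorted(cells["cell_type"].unique())
    marker_of = _marker_assignment(gene_names, types, config.markers_per_type, is_mito)

    # planted effects on non-marker, non-mito genes
    eligible = np.where(~is_mito & (marker_of == ""))[0]
    n_ca = int(round(config.frac_ca * n_genes))
    n_nca = int(round(config.frac_nca * n_genes))
    if n_ca + n_nca > eligible.size:
        raise ConfigurationError("not enough non-marker genes for planted effects")
    chosen = rng.choice(eligible, size=n_ca + n_nca, replace=False)
    ca_idx, nca_idx = chosen[:n_ca], chosen[n_ca:]
    signs = rng.choice([-1.0, 1.0], size=n_ca + n_nca)
    effect = np.zeros(n_genes)
    effect[ca_idx] = signs[:n_ca] * config.effect_log2fc
    effect[nca_idx] = signs[n_ca:] * config.effect_log2fc
    effect_class = np.repeat("none", n_genes).astype(object)
    effect_class[ca_idx] = "cell_autonomous"
    effect_class[nca_idx] = "non_cell_autonomous"

    lib = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, n_cells)

    # per-gene animal intercept sd calibrated to the target icc on log scale
    theta = 1.0 / config.nb_dispersion
    mu_typical = np.exp(config.libsize_meanlog) * q
    if config.icc > 0:
        sd_animal = _solve_intercept_sd(mu_typical, config.nb_dispersion,
                                        config.icc, config.libsize_sdlog)
    else:
        sd_animal = np.zeros(n_genes)

    animal_ids = [a.animal_id for a in animals]
    intercepts = {aid: rng.normal(0.0, 1.0, n_genes) * sd_animal for aid in animal_ids}

    type_index = {t: i for i, t in enumerate(types)}
    marker_boost = np.zeros((len(types), n_genes))
    for g, owner in enumerate(marker_of):
        if owner:
            marker_boost[type_index[owner], g] = config.marker_log2fc

    is_mut_allele = (cells["true_allele"] == "MUT").to_numpy()
    is_mut_animal = cells["genotype"].isin(MUTANT_GENOTYPES).to_numpy()

    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    cell_animal = cells["animal_id"].to_numpy()
    cell_type_i = cells["cell_type"].map(type_index).to_numpy()
    for c in range(n_cells):
        eta = marker_boost[cell_type_i[c]] + intercepts[cell_animal[c]]
        eta = eta + np.where(is_mut_allele[c], effect * (effect_class == "cell_autonomous"), 0.0)
        eta = eta + np.where(is_mut_animal[c], effect * (effect_class == "non_cell_autonomous"), 0.0)
        # mean = library size x relative abundance; eta perturbs abundance
        # per gene (genes stay independent, so no per-cell renormalization)
        mu = lib[c] * q * np.exp2(eta)
        counts[c] = rng.negative_binomial(theta, theta / (theta + mu))

    X = sparse.csr_matrix(counts)
    genes = pd.DataFrame({"gene": gene_names, "is_mito": is_mito,
                          "marker_of": marker_of, "relative_abundance": q})
    meta = cells.copy()
    meta["n_umi"] = np.asarray(X.sum(axis=1)).ravel()
    meta["n_genes"] = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
    meta["mito_fraction"] = np.divide(
        mito_counts, meta["n_umi"], out=np.zeros(len(meta)), where=meta["n_umi"] > 0)

    truth = SimulationTruth(
        gene_effects=pd.DataFrame({
            "gene": gene_names, "effect_class": effect_class, "log2fc": effect}),
        cell_allele=pd.Series(cells["true_allele"].to_numpy(),
                              index=cells["barcode"], name="true_allele"),
    )
    return X, genes, meta, truth


def _log2_nb_moment_tables(dispersion: float):
    """Interpolants x = log2(mu) -> (E[log2(count+0.5)], Var[log2(count+0.5)])
    for NB counts (variance = mu + dispersion mu^2), exact via pmf summation
    at low means and second-order delta beyond."""
    from scipy import stats as _st
    x_grid = np.linspace(-10.0, 14.0, 200)
    mu = np.exp2(x_grid)
    mean = np.log2(mu + 0.5)
    var = (1.0 / mu + dispersion) / LN2SQ
    theta = 1.0 / dispersion
    small = np.where(mu <= 300)[0]
    ms = mu[small]
    sd = np.sqrt(ms + dispersion * ms * ms)
    K = int(min(8000, max(50, (ms + 12 * sd).max())))
    k = np.arange(K + 1)
    pmf = _st.nbinom.pmf(k[None, :], theta, (theta / (theta + ms))[:, None])
    pmf = pmf / pmf.sum(axis=1, keepdims=True)
    xv = np.log2(k + 0.5)
    ex = pmf @ xv
    vv = (pmf * (xv[None, :] - ex[:, None]) ** 2).sum(axis=1)
    mean[small], var[small] = ex, vv

    def m_of(log2mu):
        return np.interp(log2mu, x_grid, mean)

    def v_of(log2mu):
        return np.interp(log2mu, x_grid, var)

    return m_of, v_of


def _solve_intercept_sd(mu_typical: np.ndarray, dispersion: float, icc: float,
                        libsize_sdlog: float) -> np.ndarray:
    """Per-gene animal-intercept sd (log2 scale) hitting the target
    intra-animal correlation of log expression.

    The intercept enters the NB mean, but log expression responds with slope
    below one at low counts (the +0.5 floor compresses), and the within-cell
    variance itself depends on the shifted mean. For each gene the sd is
    solved by bisection so that the realized between-animal variance of
    E[log2(count+0.5)] equals icc/(1-icc) times the realized mean within-cell
    variance, both taken over the intercept and library-size distributions by
    Gauss-Hermite quadrature."""
    ratio = icc / (1.0 - icc)
    lib_var = (libsize_sdlog / np.log(2.0)) ** 2
    m_of, v_of = _log2_nb_moment_tables(dispersion)
    nodes, wts = np.polynomial.hermite_e.hermegauss(9)
    wts = wts / wts.sum()
    x0 = np.log2(np.maximum(mu_typical, 1e-8))

    def imbalance(sigma):
        # between-animal variance of the conditional mean, and mean within var
        st = np.sqrt(sigma ** 2 + lib_var)
        mm = np.stack([m_of(x0 + z * sigma) for z in nodes])
        e_m = wts @ mm
        between = wts @ (mm - e_m) ** 2
        within = wts @ np.stack([v_of(x0 + z * st) for z in nodes])
        return between - ratio * within

    lo = np.zeros_like(x0)
    hi = np.full_like(x0, 12.0)
    unsolvable = imbalance(hi) < 0  # slope too flat: cap at hi
    for _ in range(40):
        mid = (lo + hi) / 2.0
        high = imbalance(mid) > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    sd = (lo + hi) / 2.0
    return np.where(unsolvable, 12.0, sd)


def _gene_names(n_genes: int) -> list[str]:
    n_mt = min(N_MITO_GENES, max(0, n_genes - 50))
    names = [f"mt-Gene{i + 1}" for i in range(n_mt)]
    names += [f"Gene{i + 1:05d}" for i in range(n_genes - n_mt)]
    return names


def _marker_assignment(gene_names, types, markers_per_type, is_mito) -> np.ndarray:
    """Deterministically reserve the first non-mito genes as type markers."""
    marker_of = np.repeat("", len(gene_names)).astype(object)
    non_mito = [i for i in range(len(gene_names)) if not is_mito[i]]
    pos = 0
    for t in types:
        for _ in range(markers_per_type):
            if pos >= len(non_mito):
                raise ConfigurationError("not enough genes for marker panel")
            marker_of[non_mito[pos]] = t
            pos += 1
    return marker_of


# ---------------------------------------------------------------------------
# marker panel

@dataclass
class MarkerPanel:
    """Cell-type centroid profiles over a panel of marker genes."""
    genes: list[str]
    centroids: pd.DataFrame  # cell types x panel genes, log-normalized scale
    markers: dict[str, list[str]]


def simulate_marker_panel(config: SimulationConfig,
                          genes: pd.DataFrame | None = None) -> MarkerPanel:
    """Centroid panel consistent with ``simulate_counts`` marker structure.

    Centroids are expected log-normalized expression: baseline abundance with
    a ``marker_log2fc`` boost on the owning type's markers; pairwise
    distinguishable by construction when the boost is positive.
    """
    if config.n_cell_types < 2:
        raise ConfigurationError("n_cell_types must be >= 2 for a marker panel")
    if genes is None:
        names = _gene_names(config.n_genes)
        is_mito = np.array([g.startswith("mt-") for g in names])
        types = sorted(DEFAULT_TAXONOMY[: config.n_cell_types]) if (
            config.n_cell_types <= len(DEFAULT_TAXONOMY)
        ) else sorted([f"T{i}" for i in range(config.n_cell_types)])
        marker_of = _marker_assignment(names, types, config.markers_per_type, is_mito)
        rng = np.random.default_rng(_substream(config.seed, "counts"))
        base = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
        base[is_mito] = np.exp(rng.normal(1.0, 0.3, is_mito.sum()))
        q = base / base.sum()
        genes = pd.DataFrame({"gene": names, "is_mito": is_mito,
                              "marker_of": marker_of, "relative_abundance": q})
    types = sorted({m for m in genes["marker_of"] if m})
    panel_mask = genes["marker_of"] != ""
    panel_genes = genes.loc[panel_mask, "gene"].tolist()
    q = genes.loc[panel_mask, "relative_abundance"].to_numpy()
    owner = genes.loc[panel_mask, "marker_of"].to_numpy()
    scale = 1e4
    rows = {}
    for t in types:
        boost = np.where(owner == t, config.marker_log2fc, 0.0)
        rows[t] = np.log1p(q * np.exp2(boost) * scale)
    centroids = pd.DataFrame(rows, index=panel_genes).T
    markers = {t: genes.loc[genes["marker_of"] == t, "gene"].tolist() for t in types}
    return MarkerPanel(genes=panel_genes, centroids=centroids, markers=markers)


# ---------------------------------------------------------------------------
# allele reads

READ_LENGTH = 91


def default_gene_sequence(length: int = 160, codon_position: int = 60,
                          seed: int = 20240901) -> tuple[str, int]:
    """Synthetic stand-in gene sequence with an ATG at ``codon_position``.

    A fixed-seed random sequence (not a real genomic locus) used as the
    start-codon window for read simulation and genotyping tests.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    seq[codon_position:codon_position + 3] = list("ATG")
    return "".join(seq), codon_position


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class FastqRecord:
    name: str
    sequence: str
    quality: str


def simulate_mecp2_reads(
    cells: pd.DataFrame,
    wt_window: str,
    codon_offset: int,
    config: SimulationConfig,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Emit barcoded/UMI-tagged reads from each cell's expressed-allele window.

    Each expressing cell draws Poisson(umis_per_mecp2_cell_mean) UMIs; every
    UMI emits >= 1 read from the cell's allele sequence (WT window, or the
    same window with TTG substituted at the codon) with i.i.d. substitution
    errors, on a random strand. Decoy reads from unrelated random sequence
    make up ``decoy_fraction`` of the output. Returns the records plus a
    per-cell truth table (barcode, true_allele, n_umi).
    """
    rng = np.random.default_rng(_substream(config.seed, "reads"))
    mut_window = (wt_window[:codon_offset] + "TTG" + wt_window[codon_offset + 3:])
    records: list[FastqRecord] = []
    truth_rows = []
    rid = 0
    for barcode, allele in zip(cells["barcode"], cells["true_allele"]):
        if allele not in ("WT", "MUT"):
            truth_rows.append((barcode, allele, 0))
            continue
        n_umi = rng.poisson(config.umis_per_mecp2_cell_mean)
        truth_rows.append((barcode, allele, int(n_umi)))
        window = wt_window if allele == "WT" else mut_window
        for _ in range(n_umi):
            umi = "".join(rng.choice(list("ACGT"), size=10))
            n_reads = 1 + rng.poisson(0.3)
            for _ in range(n_reads):
                rid += 1
                records.append(_emit_read(rng, rid, barcode, umi, window,
                                          codon_offset, config.read_error_rate))
    n_on_target = len(records)
    if config.decoy_fraction > 0 and n_on_target > 0:
        n_decoy = int(round(n_on_target * config.decoy_fraction
                            / (1.0 - config.decoy_fraction)))
        barcodes = cells["barcode"].to_numpy()
        for _ in range(n_decoy):
            rid += 1
            seq = "".join(rng.choice(list("ACGT"), size=READ_LENGTH))
            bc = barcodes[rng.integers(len(barcodes))]
            umi = "".join(rng.choice(list("ACGT"), size=10))
            # decoy names carry a 'd' prefix so truth-aware tests can split them
            records.append(FastqRecord(
                name=f"d{rid}_CB:{bc}_UMI:{umi}", sequence=seq,
                quality="I" * len(seq)))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["barcode", "true_allele", "n_umi"])
    return records, truth


def _emit_read(rng, rid, barcode, umi, window, codon_offset, error_rate) -> FastqRecord:
    lo = max(0, codon_offset + 3 - READ_LENGTH)
    hi = min(codon_offset, len(window) - READ_LENGTH)
    start = int(rng.integers(lo, hi + 1))
    seq = np.array(list(window[start:start + READ_LENGTH]))
    if error_rate > 0:
        err = rng.random(seq.size) < error_rate
        if err.any():
            bases = np.array(list("ACGT"))
            for i in np.where(err)[0]:
                choices = bases[bases != seq[i]]
                seq[i] = choices[rng.integers(3)]
    s = "".join(seq)
    if rng.random() < 0.5:
        s = _revcomp(s)
    return FastqRecord(name=f"r{rid}_CB:{barcode}_UMI:{umi}", sequence=s,
                       quality="I" * len(s))


def write_fastq(records: list[FastqRecord], path) -> None:
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# co-expression ground truth

def simulate_module_expression(
    n_modules: int = 3,
    genes_per_module: int = 80,
    n_background: int = 60,
    n_metacells: int = 300,
    loading: float = 0.8,
    seed: int = 0,
    animals: list[Animal] | None = None,
    trait_coupling: float = 0.0,
    coupled_module: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Latent-factor expression for module-recovery benchmarks.

    Each module is one latent factor; member genes load on it with the given
    loading (unit total variance). Background genes are independent noise.
    When ``animals`` is given, metacells are spread over the cohort and the
    coupled module's factor tracks the animals' disease score with strength
    ``trait_coupling`` (correlation scale).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_modules * genes_per_module + n_background
    gene_names = [f"Gene{i + 1:05d}" for i in range(n_genes)]
    meta_rows = []
    if animals is not None:
        per = int(np.ceil(n_metacells / len(animals)))
        assign = np.repeat([a.animal_id for a in animals], per)[:n_metacells]
        by_id = {a.animal_id: a for a in animals}
        score = pd.Series({a.animal_id: a.disease_score for a in animals})
        z = (score - score.mean()) / (score.std() if score.std() > 0 else 1.0)
        animal_factor = {aid: trait_coupling * z[aid]
                         + np.sqrt(max(0.0, 1 - trait_coupling**2)) * rng.normal()
                         for aid in by_id}
        for i, aid in enumerate(assign):
            a = by_id[aid]
            meta_rows.append((f"mc{i}", aid, a.sex, a.genotype, a.timepoint,
                              a.body_weight, a.disease_score))
    else:
        assign = None
        for i in range(n_metacells):
            meta_rows.append((f"mc{i}", f"A{i % 8:03d}", "F", "wt_female", "P30",
                              20.0, 0))
    meta = pd.DataFrame(meta_rows, columns=[
        "metacell", "animal_id", "sex", "genotype", "timepoint",
        "body_weight", "disease_score"]).set_index("metacell")

    expr = np.empty((n_metacells, n_genes))
    module_ids = np.repeat("", n_genes).astype(object)
    resid = np.sqrt(1.0 - loading**2)
    for m in range(n_modules):
        if animals is not None and m == coupled_module and trait_coupling != 0:
            base = np.array([animal_factor[aid] for aid in assign])
            factor = 0.9 * base + np.sqrt(1 - 0.9**2) * rng.normal(size=n_metacells)
        else:
            factor = rng.normal(size=n_metacells)
        sl = slice(m * genes_per_module, (m + 1) * genes_per_module)
        expr[:, sl] = (loading * factor[:, None]
                       + resid * rng.normal(size=(n_metacells, genes_per_module)))
        module_ids[sl] = f"M{m + 1}"
    expr[:, n_modules * genes_per_module:] = rng.normal(
        size=(n_metacells, n_background))
    df = pd.DataFrame(expr, index=meta.index, columns=gene_names)
    truth = SimulationTruth(
        gene_module=pd.Series(module_ids, index=gene_names, name="module"),
        module_traits={f"M{coupled_module + 1}": {"disease_score": trait_coupling}}
        if trait_coupling else {},
    )
    return df, meta, truth


# ---------------------------------------------------------------------------
# truth serialization

class TruthParseError(ValueError):
    pass


def export_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "gene_effects": truth.gene_effects.to_dict(orient="list"),
        "cell_allele": {"index": truth.cell_allele.index.tolist(),
                        "values": truth.cell_allele.tolist()},
        "gene_module": {"index": truth.gene_module.index.tolist(),
                        "values": truth.gene_module.tolist()},
        "module_traits": truth.module_traits,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_truth(path) -> SimulationTruth:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TruthParseError(
                f"cannot parse truth file {path}: line {exc.lineno}: {exc.msg}"
            ) from exc
    ge = pd.DataFrame(payload["gene_effects"])
    if ge.empty:
        ge = pd.DataFrame(columns=["gene", "effect_class", "log2fc"])
    return SimulationTruth(
        gene_effects=ge,
        cell_allele=pd.Series(payload["cell_allele"]["values"],
                              index=payload["cell_allele"]["index"],
                              name="true_allele", dtype=object),
        gene_module=pd.Series(payload["gene_module"]["values"],
                              index=payload["gene_module"]["index"],
                              name="module", dtype=object),
        module_traits=payload["module_traits"],
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
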