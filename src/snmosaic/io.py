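"""Readers, writers, configuration and the end-to-end pipeline.

Count matrices travel as Matrix-Market triplets (matrix.mtx + features.tsv +
barcodes.tsv, optionally gzipped); every derived table is TSV with a header
comment carrying the package version, seed and a configuration hash, and a
manifest records checksums so reruns are verifiable byte for byte.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from . import __version__
from .enrich import GeneSet

log = logging.getLogger("snmosaic")


def _maybe(path: Path) -> Path:
    """Resolve a file that may or may not carry a .gz suffix."""
    if path.exists():
        return path
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(f"missing file: {path} (or {gz.name})")


def _open_text(path: Path, mode: str = "rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_counts_dir(path) -> AnnData:
    """Load matrix.mtx / features.tsv / barcodes.tsv into an AnnData
    (cells x genes; the on-disk matrix is genes x cells by convention)."""
    path = Path(path)
    mtx = _maybe(path / "matrix.mtx")
    features = _maybe(path / "features.tsv")
    barcodes = _maybe(path / "barcodes.tsv")
    with _open_text(mtx, "rb") as fh:
        M = spio.mmread(fh).tocsr()
    feat = pd.read_csv(features, sep="\t", header=None)
    bc = pd.read_csv(barcodes, sep="\t", header=None)
    if M.shape[0] != len(feat) or M.shape[1] != len(bc):
        raise ValueError(
            f"dimension mismatch: matrix is {M.shape[0]}x{M.shape[1]} but "
            f"features.tsv has {len(feat)} rows and barcodes.tsv {len(bc)}")
    var = pd.DataFrame(index=pd.Index(feat[0].astype(str), name="gene"))
    if feat.shape[1] > 1:
        var["symbol"] = feat[1].to_numpy()
    return AnnData(X=M.T.tocsr(), var=var,
                   obs=pd.DataFrame(index=pd.Index(bc[0].astype(str),
                                                   name="barcode")))


def write_counts_dir(adata: AnnData, path, compress: bool = False) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    with _open_text(path / f"matrix.mtx{suffix}", "wb") as fh:
        spio.mmwrite(fh, X.T.tocoo())
    with _open_text(path / f"features.tsv{suffix}", "wt") as fh:
        for g in adata.var_names:
            fh.write(f"{g}\t{g}\n")
    with _open_text(path / f"barcodes.tsv{suffix}", "wt") as fh:
        for b in adata.obs_names:
            fh.write(f"{b}\n")


def read_gene_sets(path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ... per line."""
    sets = []
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, "
                                 f"got {len(parts)}")
            genes = list(dict.fromkeys(parts[2:]))
            if len(genes) < len(parts) - 2:
                log.warning("%s:%d: duplicate genes in set %s deduplicated",
                            path, lineno, parts[0])
            sets.append(GeneSet(name=parts[0], genes=frozenset(genes)))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# table output with provenance

def config_hash(config) -> str:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tables(results: dict[str, pd.DataFrame], outdir, seed: int,
                 config=None) -> dict:
    """Write each frame as TSV with a provenance header; return the manifest
    (also written as manifest.json) mapping file -> sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config or {})
    header = f"# snmosaic v{__version__} seed={seed} config={chash}\n"
    manifest = {}
    for name, df in results.items():
        fp = outdir / f"{name}.tsv"
        with open(fp, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        manifest[fp.name] = hashlib.sha256(fp.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "config": chash, "files": manifest}, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration

@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "snmosaic_out"
    counts_dir: str | None = None        # consume existing counts, else simulate
    fastq: str | None = None
    gene_sets: str | None = None         # GMT path
    deg_alpha: float = 0.05
    enrichment_input: str = "raw_p"      # 'raw_p' or 'adj_p'
    enrichment_cutoff: float = 0.05
    run_zinb: bool = False
    simulation: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthetic end-to-end run: simulate -> genotype -> QC/annotate ->
    five-experiment DEG suite -> effect modes -> enrichment -> modules.

    Returns a report dict; tables and the report land in ``config.outdir``.
    """
    from . import allele, deg, enrich, experiments, network, qc, simulate

    logging.basicConfig(level=config.log_level)
    report: dict = {"seed": config.seed}
    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)

    log.info("stage simulate: cohort + counts + reads")
    animals, cells = simulate.simulate_cohort(sim_cfg)
    X, genes_tab, meta, truth = simulate.simulate_counts(animals, cells, sim_cfg)
    panel = simulate.simulate_marker_panel(sim_cfg, genes_tab)
    gene_seq, codon_pos = simulate.default_gene_sequence()
    reads, read_truth = simulate.simulate_mecp2_reads(meta, *_window(gene_seq, codon_pos),
                                                      sim_cfg)
    report["n_animals"] = len(animals)
    report["n_cells_simulated"] = len(meta)

    log.info("stage genotype: %d reads", len(reads))
    ref = allele.build_mini_reference(gene_seq, codon_pos)
    tagged = (allele.TaggedRead(*_parse_name(r.name), r.sequence, r.quality)
              for r in reads)
    counts_per_bc, stats = allele.count_alleles(tagged, ref)
    geno = allele.genotype_table(counts_per_bc).set_index("barcode")
    meta = meta.set_index("barcode")
    meta["allele_call"] = geno["call"].reindex(meta.index).fillna("NONE")
    report["n_cells_genotyped"] = int((meta["allele_call"].isin(["WT", "MUT"])).sum())

    log.info("stage qc + annotate")
    adata = AnnData(X=X, obs=meta,
                    var=genes_tab.set_index("gene"))
    adata, qc_report = qc.qc_filter(adata)
    report["qc"] = qc_report
    adata = qc.log_normalize(adata)
    labels = qc.assign_cell_types(adata, panel)
    adata.obs["assigned_type"] = labels["cell_type"]
    adata.obs["assigned_class"] = labels["broad_class"]
    comp = qc.composition_test(adata.obs, type_col="assigned_type")
    report["composition_p"] = comp["all"]["p"]

    log.info("stage experiments: DEG suite")
    counts_dense = np.asarray(adata.X.todense()).T  # genes x cells
    suite = experiments.run_suite(
        counts_dense, adata.obs.reset_index(), genes=list(adata.var_names),
        alpha=config.deg_alpha, seed=config.seed, class_col="assigned_class",
        run_zinb=config.run_zinb)
    report["deg_summary_rows"] = len(suite.summary)
    report["n_deg_total"] = int(suite.summary["n_total_significant"].sum())
    try:
        modes = experiments.classify_effect_mode(suite.deg_tables,
                                                 alpha=config.deg_alpha)
        report["effect_modes"] = modes["mode"].value_counts().to_dict()
    except KeyError:
        modes = pd.DataFrame()
        report["effect_modes"] = {}

    log.info("stage enrichment")
    if config.gene_sets:
        gene_sets = read_gene_sets(config.gene_sets)
    else:
        gene_sets = _synthetic_gene_sets(truth, list(adata.var_names), config.seed)
    enr_rows = []
    for (exp, cls, tp), tab in suite.deg_tables.items():
        col = "p" if config.enrichment_input == "raw_p" else "adj_p"
        hits = tab.loc[tab[col] <= config.enrichment_cutoff, "gene"]
        res = enrich.fisher_enrichment(hits, gene_sets, tab["gene"])
        res.insert(0, "experiment_id", exp)
        res.insert(1, "cell_class", cls)
        res.insert(2, "timepoint", tp)
        enr_rows.append(res)
    enrichment = (pd.concat(enr_rows, ignore_index=True)
                  if enr_rows else pd.DataFrame())

    log.info("stage co-expression modules")
    net_cfg = network.NetworkConfig(**config.network)
    lognorm = pd.DataFrame(np.asarray(adata.layers["lognorm"].todense()),
                           index=adata.obs_names, columns=adata.var_names)
    keep = network.select_network_genes(counts_dense, net_cfg.min_expressed_fraction)
    obs = adata.obs.copy()
    obs["cell_type"] = obs["assigned_type"]
    mc, mapping = make_metacells_safe(lognorm.loc[:, keep], obs, net_cfg.metacell_k,
                                      seed=config.seed)
    mods = network.detect_modules(mc, net_cfg)
    n_modules = mods.labels[mods.labels != network.UNASSIGNED].nunique()
    report["n_modules"] = int(n_modules)
    trait_tab = pd.DataFrame()
    if n_modules:
        kme = network.compute_kme_hubs(mc, mods.labels)
        trait_tab = network.trait_correlation(
            kme.eigengenes, mc.attrs["metadata"],
            traits=["body_weight", "disease_score"])
        report["n_trait_hits"] = int((trait_tab["adj_p"] <= 0.05).sum())

    tables = {"deg_summary": suite.summary, "effect_modes": modes,
              "enrichment": enrichment, "module_traits": trait_tab,
              "genotype_calls": geno.reset_index(),
              "qc_metadata": adata.obs.reset_index()}
    tables = {k: v for k, v in tables.items() if len(v)}
    write_tables(tables, config.outdir, config.seed,
                 dataclasses.asdict(config))
    with open(Path(config.outdir) / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    log.info("pipeline done: %s", report)
    return report


def make_metacells_safe(expr, obs, k, seed):
    import warnings as _w

    from .network import make_metacells
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return make_metacells(expr, obs, k=k, seed=seed)


def _window(gene_seq: str, codon_pos: int):
    from .allele import FLANK
    return (gene_seq[codon_pos - FLANK:codon_pos + FLANK], FLANK)


def _parse_name(name: str):
    from .allele import _NAME_RE
    m = _NAME_RE.search(name)
    return (m.group("cb"), m.group("umi")) if m else (None, None)


def _synthetic_gene_sets(truth, universe: list[str], seed: int,
                         n_random: int = 5) -> list[GeneSet]:
    """Gene sets for a self-contained run: one set seeded with planted
    effect genes (if any) plus random sets."""
    rng = np.random.default_rng(seed)
    sets = []
    ge = truth.gene_effects
    planted = ge.loc[ge["effect_class"] != "none", "gene"]
    planted = [g for g in planted if g in set(universe)]
    if len(planted) >= 3:
        sets.append(GeneSet("planted_effects", frozenset(planted)))
    for i in range(n_random):
        size = int(rng.integers(20, 60))
        sets.append(GeneSet(f"random_set_{i + 1}",
                            frozenset(rng.choice(universe, size, replace=False))))
    return sets
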