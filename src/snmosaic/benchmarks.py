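"""Self-contained validation benchmarks with known ground truth.

Each function simulates its own inputs, runs the relevant pipeline stage and
returns the measured quantities. They are used both by the test suite and by
scripts/acceptance.py; every number they report is computed at call time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import allele, deg, enrich, experiments, network
from . import simulate as sim


def _sub(seed: int, offset: int) -> int:
    return int((seed * 9973 + offset) % (2**31))


def design_conformance() -> dict:
    """Structural defaults: reference window, cohort, taxonomy, contrasts."""
    seq, pos = sim.default_gene_sequence()
    ref = allele.build_mini_reference(seq, pos)
    animals, _ = sim.simulate_cohort(sim.SimulationConfig(seed=0))
    panel = sim.simulate_marker_panel(sim.SimulationConfig(seed=0))
    contrasts = experiments.build_contrasts()
    return {
        "miniref_window_length": len(ref.sequence),
        "cohort_n_samples": len(animals),
        "taxonomy_n_cell_types": len(panel.markers),
        "contrast_suite_n_experiments": len({c.experiment_id for c in contrasts}),
    }


def allele_recovery(seed: int, read_error_rate: float = 0.01,
                    n_cells: int = 500, min_umis: int = 3) -> dict:
    """Genotype synthetic mosaic cells and compare calls with truth.

    Accuracy is reported over WT/MUT-called cells whose true UMI depth is at
    least ``min_umis``; a noiseless replicate checks exact recovery, and the
    decoy (off-target) reads are genotyped alone to confirm they never call.
    """
    out = {}
    seq, pos = sim.default_gene_sequence()
    ref = allele.build_mini_reference(seq, pos)
    window = seq[pos - allele.FLANK:pos + allele.FLANK]
    for label, err in (("noisy", read_error_rate), ("noiseless", 0.0)):
        cfg = sim.SimulationConfig(
            seed=_sub(seed, 1), cohort_layout=[("F", "het_female", "P30", 2)],
            cells_per_animal=(n_cells + 1) // 2, read_error_rate=err,
            umis_per_mecp2_cell_mean=5.0, decoy_fraction=0.2)
        _, cells = sim.simulate_cohort(cfg)
        reads, truth = sim.simulate_mecp2_reads(cells, window, allele.FLANK, cfg)
        tagged = [allele.TaggedRead(*_tags(r.name), r.sequence, r.quality)
                  for r in reads]
        counts, stats_ = allele.count_alleles(tagged, ref)
        table = allele.genotype_table(counts).set_index("barcode")
        merged = table.join(truth.set_index("barcode"), how="right")
        called = merged[merged.call.isin(["WT", "MUT"])]
        if label == "noisy":
            deep = called[called.n_umi >= min_umis]
            out["call_accuracy_pct"] = float(
                (deep.call == deep.true_allele).mean() * 100.0)
            out["n_cells_called"] = int(len(called))
            decoys = [t for t, r in zip(tagged, reads) if r.name.startswith("d")]
            decoy_counts, decoy_stats = allele.count_alleles(decoys, ref)
            out["decoy_false_calls"] = int(sum(
                c.n_wt_umi + c.n_mut_umi > 0 for c in decoy_counts))
        else:
            informative = merged[merged.n_umi >= 1]
            out["noiseless_accuracy_pct"] = float(
                (informative.call == informative.true_allele).mean() * 100.0)
    return out


def null_calibration(seed: int, n_genes: int = 2000) -> dict:
    """Global-null DEG run: 2 genotype groups x 4 animals x 50 cells,
    intra-animal correlation 0.2, no planted effects."""
    cfg = sim.SimulationConfig(
        seed=_sub(seed, 2),
        cohort_layout=[("F", "het_female", "P30", 4),
                       ("F", "wt_female", "P30", 4)],
        cells_per_animal=50, n_genes=n_genes, n_cell_types=2,
        markers_per_type=0, icc=0.2)
    animals, cells = sim.simulate_cohort(cfg)
    X, genes, meta, _ = sim.simulate_counts(animals, cells, cfg)
    counts = X.toarray().T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        high, _, info = deg.differential_expression(
            counts, counts.sum(axis=0),
            np.where(meta.genotype == "het_female", "het", "wt"),
            meta.animal_id.to_numpy(), list(genes.gene), seed=_sub(seed, 3))
    return {
        "bh_positive_fraction": float((high.adj_p <= 0.05).mean()),
        "ks_uniformity_p": float(stats.kstest(high.p, "uniform").pvalue),
        "rho_consensus": float(info["rho_consensus"]),
        "n_genes_tested": int(len(high)),
    }


def oracle_equivalence(seed: int) -> dict:
    """Closed-form cross-checks: GLS-vs-OLS, Fisher-vs-hypergeometric tail,
    BH-vs-direct formula."""
    rng = np.random.default_rng(_sub(seed, 4))
    worst_t = worst_p = 0.0
    for _ in range(50):
        n = int(rng.integers(8, 16))
        G = int(rng.integers(5, 20))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(G, n))
        vf = deg.VoomFit(logcpm=Y, weights=np.ones_like(Y),
                         lib_sizes=np.ones(n), trend_x=np.array([0.0, 1.0]),
                         trend_y=np.array([1.0, 1.0]))
        tab = deg.fit_moderated(vf, X, np.array([0.0, 1.0]), rho=0.0,
                                prior_df=0)
        for g in range(G):
            b, res, *_ = np.linalg.lstsq(X, Y[g], rcond=None)
            s2 = res[0] / (n - 2)
            t = b[1] / np.sqrt(np.linalg.inv(X.T @ X)[1, 1] * s2)
            p = 2 * stats.t.sf(abs(t), n - 2)
            worst_t = max(worst_t, abs(t - tab.moderated_t[g]))
            worst_p = max(worst_p, abs(p - tab.p[g]))

    from scipy.special import comb
    worst_fisher = 0.0
    for _ in range(100):
        N = int(rng.integers(20, 120))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        universe = [f"g{i}" for i in range(N)]
        term = set(rng.choice(universe, K, replace=False))
        hits = set(rng.choice(universe, n, replace=False))
        res = enrich.fisher_enrichment(
            hits, [enrich.GeneSet("t", frozenset(term))], universe)
        k = len(term & hits)
        total = comb(N, n, exact=True)
        tail = sum(comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
                   for j in range(k, min(K, n) + 1)) / total
        worst_fisher = max(worst_fisher, abs(res.p[0] - tail))

    worst_bh = 0.0
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 150)))
        m = len(p)
        order = np.argsort(p)
        direct = np.minimum(1.0, np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1])
        ours = deg.bh_adjust(p)[order]
        worst_bh = max(worst_bh, float(np.abs(ours - direct).max()))
    return {"max_ols_t_diff": worst_t, "max_ols_p_diff": worst_p,
            "max_fisher_p_diff": worst_fisher, "max_bh_diff": worst_bh}


def icc_recovery(seed: int, icc_values=(0.0, 0.1, 0.3)) -> dict:
    """Consensus-correlation recovery of simulated intra-animal correlation
    (200 genes, 8 animals x 50 cells)."""
    out = {}
    for i, icc in enumerate(icc_values):
        cfg = sim.SimulationConfig(
            seed=_sub(seed, 10 + i),
            cohort_layout=[("F", "wt_female", "P30", 8)],
            cells_per_animal=50, n_genes=200, n_cell_types=2,
            markers_per_type=0, icc=icc)
        animals, cells = sim.simulate_cohort(cfg)
        X, genes, meta, _ = sim.simulate_counts(animals, cells, cfg)
        counts = X.toarray().T
        design = np.ones((counts.shape[1], 1))
        vf = deg.voom_transform(counts, design, counts.sum(axis=0))
        cc = deg.consensus_correlation(vf, design, meta.animal_id.to_numpy())
        out[f"consensus_at_icc_{icc}"] = float(cc.rho_consensus)
        out[f"icc_error_{icc}"] = float(abs(cc.rho_consensus - icc))
    return out


def effect_discrimination(seed: int) -> dict:
    """Planted cell-autonomous / non-cell-autonomous genes (|log2FC| = 1)
    through experiments 3-5, with allele calls taken from truth."""
    cfg = sim.SimulationConfig(
        seed=_sub(seed, 20),
        cohort_layout=[("F", "het_female", "P30", 4),
                       ("F", "wt_female", "P30", 4)],
        cells_per_animal=300, n_genes=600, n_cell_types=2, markers_per_type=0,
        frac_ca=0.1, frac_nca=0.1, effect_log2fc=1.0, icc=0.05)
    animals, cells = sim.simulate_cohort(cfg)
    X, genes, meta, truth = sim.simulate_counts(animals, cells, cfg)
    meta = meta.copy()
    meta["allele_call"] = meta["true_allele"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = experiments.run_suite(
            X.toarray().T, meta,
            contrasts=[c for c in experiments.build_contrasts()
                       if c.experiment_id >= 3],
            genes=list(genes.gene), seed=_sub(seed, 21))
    ge = truth.gene_effects.set_index("gene")
    nca = set(ge.index[ge.effect_class == "non_cell_autonomous"])
    ca = set(ge.index[ge.effect_class == "cell_autonomous"])
    sig = {}
    for e in (3, 4, 5):
        tab = pd.concat([v for (ee, *_), v in res.deg_tables.items() if ee == e])
        sig[e] = set(tab.loc[tab.adj_p <= 0.05, "gene"])
    modes = experiments.classify_effect_mode(res.deg_tables).set_index("gene")
    hits = total = 0
    for g, row in modes[modes["mode"] != "none"].iterrows():
        want = ge.effect_class.get(g, "none")
        if want == "none":
            continue
        total += 1
        hits += (row["mode"] == want
                 or (row["mode"] == "mixed" and want == "non_cell_autonomous"))
    return {
        "exp3_nca_power": len(sig[3] & nca) / len(nca),
        "exp5_nca_flag_rate": len(sig[5] & nca) / len(nca),
        "exp5_ca_power": len(sig[5] & ca) / len(ca),
        "effect_mode_accuracy": hits / max(total, 1),
        "n_modes_classified": total,
    }


def module_recovery(seed: int) -> dict:
    """Planted-module benchmark: ARI, hub-vs-periphery kME ranking, and the
    disease-score coupling on the default 28-animal cohort."""
    from sklearn.metrics import adjusted_rand_score
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, _, truth = sim.simulate_module_expression(seed=_sub(seed, 30))
        res = network.detect_modules(expr)
        mask = truth.gene_module != ""
        ari = adjusted_rand_score(truth.gene_module[mask], res.labels[mask])

        rng = np.random.default_rng(_sub(seed, 31))
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            f = rng.normal(size=200)
            cols = {"hub": 0.9 * f + np.sqrt(1 - 0.81) * rng.normal(size=200),
                    "per": 0.4 * f + np.sqrt(1 - 0.16) * rng.normal(size=200)}
            for i in range(30):
                cols[f"g{i}"] = 0.7 * f + np.sqrt(0.51) * rng.normal(size=200)
            Xh = pd.DataFrame(cols)
            kme = network.compute_kme_hubs(
                Xh, pd.Series("turquoise", index=Xh.columns))
            wins += bool(kme.kme.loc["hub", "turquoise"]
                         > kme.kme.loc["per", "turquoise"])

        animals, _ = sim.simulate_cohort(sim.SimulationConfig(seed=_sub(seed, 32)))
        c_expr, c_meta, c_truth = sim.simulate_module_expression(
            seed=_sub(seed, 33), animals=animals, trait_coupling=0.8)
        c_res = network.detect_modules(c_expr)
        kme = network.compute_kme_hubs(c_expr, c_res.labels)
        tc = network.trait_correlation(kme.eigengenes, c_meta,
                                       ["body_weight", "disease_score"])
        coupled_genes = c_truth.gene_module.index[c_truth.gene_module == "M1"]
        color = c_res.labels[coupled_genes].mode().iat[0]
        row = tc[(tc.module == color) & (tc.trait == "disease_score")].iloc[0]
    return {"module_recovery_ari": float(ari),
            "hub_outranks_periphery_rate": wins / n_rep,
            "trait_coupling_r": float(row.r),
            "trait_coupling_adj_p": float(row.adj_p),
            "trait_coupling_sign_correct": bool(row.r > 0)}


def zinb_performance(seed: int) -> dict:
    """ZINB LRT null behavior, model recovery and power at a 4-fold effect."""
    rng = np.random.default_rng(_sub(seed, 40))
    null_ps = []
    for _ in range(25):
        y = rng.negative_binomial(2.0, 2.0 / 2.5, size=400)
        null_ps.append(deg.zinb_lrt(y, np.repeat(["a", "b"], 200))["p"])
    pis = [deg.fit_zinb(rng.negative_binomial(2.0, 2.0 / 3.0, size=200)).pi
           for _ in range(15)]
    hits = 0
    n_rep = 25
    for _ in range(n_rep):
        ya = rng.negative_binomial(1.0, 1.0 / 1.45, size=200)
        yb = rng.negative_binomial(1.0, 1.0 / 2.8, size=200)
        row = deg.zinb_lrt(np.concatenate([ya, yb]), np.repeat(["a", "b"], 200))
        hits += bool(row["p"] <= 0.05)
    return {"zinb_null_median_p": float(np.median(null_ps)),
            "zinb_mean_pi_pure_nb": float(np.mean(pis)),
            "zinb_power_4fold": hits / n_rep}


def _tags(name: str):
    m = allele._NAME_RE.search(name)
    return (m.group("cb"), m.group("umi")) if m else (None, None)
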