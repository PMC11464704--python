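"""Co-expression: gene filtering, metacells, soft power, module detection,
eigengenes/kME/hubs, trait correlation, rank-based module scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from snmosaic import network
from snmosaic import simulate as sim
from snmosaic.network import (NetworkConfig, UNASSIGNED, compute_kme_hubs,
                              detect_modules, make_metacells, module_score,
                              pick_soft_power, select_network_genes,
                              trait_correlation)


class TestSelectGenes:
    def test_five_percent_boundary_inclusive(self):
        counts = np.zeros((3, 1000))
        counts[0, :49] = 1   # 4.9% -> excluded
        counts[1, :50] = 1   # 5.0% -> included
        counts[2, :] = 1
        keep = select_network_genes(counts, 0.05)
        assert list(keep) == [False, True, True]

    def test_zero_threshold_keeps_all(self):
        counts = np.zeros((4, 10))
        assert select_network_genes(counts, 0.0).all()


@pytest.fixture(scope="module")
def planted_modules():
    return sim.simulate_module_expression(seed=4)


class TestMetacells:
    def _stratum(self, n=60, genes=25, seed=0):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(size=(n, genes)),
                            index=[f"c{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(genes)])
        meta = pd.DataFrame({"animal_id": "A1", "cell_type": "T"},
                            index=expr.index)
        return expr, meta

    def test_k1_is_identity(self):
        expr, meta = self._stratum()
        mc, mapping = make_metacells(expr, meta, k=1)
        assert mc.shape == expr.shape
        np.testing.assert_allclose(np.sort(mc.to_numpy(), axis=0),
                                   np.sort(expr.to_numpy(), axis=0))

    def test_mapping_is_partition(self):
        expr, meta = self._stratum()
        mc, mapping = make_metacells(expr, meta, k=7)
        assert set(mapping.index) == set(expr.index)
        sizes = mapping.value_counts()
        assert sizes.sum() == len(expr)

    def test_metacell_approaches_stratum_mean(self):
        expr, meta = self._stratum(n=100)
        center = expr.mean()
        d_small = np.linalg.norm(
            make_metacells(expr, meta, k=5)[0] - center, axis=1).mean()
        d_large = np.linalg.norm(
            make_metacells(expr, meta, k=25)[0] - center, axis=1).mean()
        assert d_large < d_small

    def test_small_stratum_pooled_with_warning(self):
        expr, meta = self._stratum(n=8)
        with pytest.warns(UserWarning, match="pooled"):
            mc, mapping = make_metacells(expr, meta, k=25)
        assert len(mc) == 1


class TestSoftPower:
    def _structured(self, seed=0):
        rng = np.random.default_rng(seed)
        cols = []
        for size in (60, 50, 40, 30, 25):
            f = rng.normal(size=300)
            load = rng.uniform(0.3, 0.95, size)
            cols.append(load * f[:, None]
                        + np.sqrt(1 - load ** 2) * rng.normal(size=(300, size)))
        cols.append(rng.normal(size=(300, 50)))
        X = pd.DataFrame(np.hstack(cols))
        X.columns = [f"g{i}" for i in range(X.shape[1])]
        return X

    def test_structured_data_reaches_threshold(self):
        beta, r2, reached = pick_soft_power(self._structured())
        assert reached and r2 >= 0.8 and beta <= 12

    def test_noise_never_reaches_threshold(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(250, 120)),
                         columns=[f"g{i}" for i in range(120)])
        beta, r2, reached = pick_soft_power(X)
        assert not reached

    def test_deterministic(self):
        X = self._structured(seed=3)
        assert pick_soft_power(X) == pick_soft_power(X)

    def test_all_constant_rejected(self):
        X = pd.DataFrame(np.ones((50, 60)))
        with pytest.raises(ValueError):
            pick_soft_power(X)


class TestDetectModules:
    def test_planted_blocks_recovered(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        mask = truth.gene_module != ""
        ari = adjusted_rand_score(truth.gene_module[mask], res.labels[mask])
        assert ari >= 0.8
        assert res.labels[mask].nunique() >= 3

    def test_background_lands_in_grey(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        bg = truth.gene_module == ""
        assert (res.labels[bg] == UNASSIGNED).mean() >= 0.8

    def test_single_global_factor_gives_one_module(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=250)
        X = pd.DataFrame(0.8 * f[:, None]
                         + 0.6 * rng.normal(size=(250, 90)),
                         columns=[f"g{i}" for i in range(90)])
        res = detect_modules(X)
        non_grey = res.labels[res.labels != UNASSIGNED]
        assert non_grey.nunique() == 1
        assert len(non_grey) >= 80

    def test_pure_noise_is_mostly_grey(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 150)),
                         columns=[f"g{i}" for i in range(150)])
        res = detect_modules(X)
        assert (res.labels == UNASSIGNED).mean() >= 0.5

    def test_gene_order_invariance(self, planted_modules):
        expr, meta, truth = planted_modules
        rng = np.random.default_rng(4)
        perm = rng.permutation(expr.columns)
        a = detect_modules(expr).labels
        b = detect_modules(expr[perm]).labels
        # same partition up to color names
        assert adjusted_rand_score(a[perm], b[perm]) == 1.0


class TestKmeHubs:
    def test_gene_equal_to_eigengene_has_kme_one(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        kme = compute_kme_hubs(expr, res.labels)
        probe = expr.copy()
        m = kme.eigengenes.columns[0]
        probe["probe"] = kme.eigengenes[m]
        labels = pd.concat([res.labels, pd.Series({"probe": m})])
        kme2 = compute_kme_hubs(probe, labels)
        assert kme2.kme.loc["probe", m] == pytest.approx(1.0, abs=1e-9)

    def test_eigengene_orientation_positive_mean_kme(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        kme = compute_kme_hubs(expr, res.labels)
        for m in kme.eigengenes.columns:
            members = res.labels.index[res.labels == m]
            assert kme.kme.loc[members, m].mean() > 0

    def test_noise_gene_has_small_kme(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        kme = compute_kme_hubs(expr, res.labels)
        bg = truth.gene_module.index[truth.gene_module == ""]
        frac_small = (kme.kme.loc[bg].abs() <= 0.2).to_numpy().mean()
        assert frac_small >= 0.9

    def test_planted_hub_outranks_periphery(self):
        rng = np.random.default_rng(5)
        wins = 0
        for rep in range(30):
            f = rng.normal(size=200)
            cols = {"hub": 0.9 * f + np.sqrt(1 - 0.81) * rng.normal(size=200),
                    "per": 0.4 * f + np.sqrt(1 - 0.16) * rng.normal(size=200)}
            for i in range(30):
                cols[f"g{i}"] = 0.7 * f + np.sqrt(0.51) * rng.normal(size=200)
            X = pd.DataFrame(cols)
            labels = pd.Series("turquoise", index=X.columns)
            kme = compute_kme_hubs(X, labels)
            wins += (kme.kme.loc["hub", "turquoise"]
                     > kme.kme.loc["per", "turquoise"])
        assert wins / 30 >= 0.95

    def test_top10_hubs_per_module(self, planted_modules):
        expr, meta, truth = planted_modules
        res = detect_modules(expr)
        kme = compute_kme_hubs(expr, res.labels)
        for m, hubs in kme.hubs.items():
            assert len(hubs) == 10
            members = res.labels.index[res.labels == m]
            ranked = kme.kme.loc[members, m].sort_values(ascending=False)
            assert set(hubs) == set(ranked.index[:10])


class TestTraitCorrelation:
    def test_eigengene_equal_to_trait_gives_r_one(self):
        meta = pd.DataFrame({
            "animal_id": [f"A{i}" for i in range(12)],
            "disease_score": np.arange(12.0)},
            index=[f"mc{i}" for i in range(12)])
        eig = pd.DataFrame({"turquoise": np.arange(12.0)}, index=meta.index)
        out = trait_correlation(eig, meta, ["disease_score"])
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_constant_trait_reported_na(self):
        meta = pd.DataFrame({
            "animal_id": [f"A{i}" for i in range(8)],
            "flat": 1.0}, index=[f"mc{i}" for i in range(8)])
        eig = pd.DataFrame({"blue": np.arange(8.0)}, index=meta.index)
        out = trait_correlation(eig, meta, ["flat"])
        assert out.r.isna().all()

    def test_permuted_trait_rarely_significant(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(30):
            meta = pd.DataFrame({
                "animal_id": [f"A{i}" for i in range(20)],
                "score": rng.permutation(np.arange(20.0))},
                index=[f"mc{i}" for i in range(20)])
            eig = pd.DataFrame({"m": rng.normal(size=20)}, index=meta.index)
            out = trait_correlation(eig, meta, ["score"])
            hits += out.p.iloc[0] <= 0.05
        assert hits <= 5

    def test_planted_coupling_on_default_cohort(self):
        cfg = sim.SimulationConfig(seed=1)
        animals, _ = sim.simulate_cohort(cfg)
        expr, meta, truth = sim.simulate_module_expression(
            seed=9, animals=animals, trait_coupling=0.8)
        res = detect_modules(expr)
        kme = compute_kme_hubs(expr, res.labels)
        out = trait_correlation(kme.eigengenes, meta,
                                ["body_weight", "disease_score"])
        coupled_genes = truth.gene_module.index[truth.gene_module == "M1"]
        coupled_color = res.labels[coupled_genes].mode().iat[0]
        row = out[(out.module == coupled_color)
                  & (out.trait == "disease_score")].iloc[0]
        assert row.adj_p <= 0.05
        assert row.r > 0


class TestModuleScore:
    def test_top_ranked_set_scores_near_one(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random(size=(20, 200)),
                         columns=[f"g{i}" for i in range(200)])
        X.iloc[:, :10] += 10.0  # set genes dominate every cell
        score = module_score(X, [f"g{i}" for i in range(10)], rank_cap=150)
        assert (score > 0.95).all()

    def test_undetected_set_scores_near_zero(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.random(size=(15, 2000)) + 1.0,
                         columns=[f"g{i}" for i in range(2000)])
        X.iloc[:, -5:] = 0.0
        score = module_score(X, [f"g{i}" for i in range(1995, 2000)],
                             rank_cap=100)
        assert (score < 0.05).all()

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.random(size=(10, 50)),
                         columns=[f"g{i}" for i in range(50)])
        genes = [f"g{i}" for i in range(8)]
        a = module_score(X, genes, rank_cap=40)
        b = module_score(np.exp(X * 3), genes, rank_cap=40)
        np.testing.assert_allclose(a, b)

    def test_empty_intersection_gives_na(self):
        X = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        assert module_score(X, ["zz"]).isna().all()

    def test_scores_within_unit_interval(self, planted_modules):
        expr, meta, truth = planted_modules
        genes = truth.gene_module.index[truth.gene_module == "M1"]
        s = module_score(expr, list(genes), rank_cap=100)
        assert s.between(0, 1).all()
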