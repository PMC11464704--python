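"""Differential-expression engine: partitioning, voom weights, consensus
correlation, moderated GLS against a closed-form OLS oracle, BH, and the
zero-inflated NB likelihood-ratio test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from snmosaic import deg
from snmosaic import simulate as sim
from snmosaic.deg import (VoomFit, bh_adjust, consensus_correlation,
                          downsample_balance, fit_moderated,
                          partition_by_fraction, voom_transform, zinb_lrt)


def _unit_voomfit(Y):
    return VoomFit(logcpm=Y, weights=np.ones_like(Y),
                   lib_sizes=np.ones(Y.shape[1]),
                   trend_x=np.array([0.0, 1.0]), trend_y=np.array([1.0, 1.0]))


class TestPartition:
    def test_strictly_less_than_threshold(self):
        n = 1000
        counts = np.zeros((3, n))
        counts[0, :249] = 1   # 24.9% -> low
        counts[1, :250] = 1   # exactly 25% -> high
        counts[2, :] = 1      # everywhere -> high
        high, low = partition_by_fraction(counts, 0.25)
        assert low[0] and high[1] and high[2]
        assert (high ^ low).all()


class TestDownsample:
    def test_min_rule_and_determinism(self):
        groups = {"a": np.arange(100), "b": np.arange(100, 140)}
        out1 = downsample_balance(groups, seed=3)
        out2 = downsample_balance(groups, seed=3)
        assert len(out1["a"]) == len(out1["b"]) == 40
        assert np.array_equal(out1["a"], out2["a"])
        assert np.array_equal(out1["b"], groups["b"])  # already minimal

    def test_equal_groups_unchanged(self):
        groups = {"a": np.arange(10), "b": np.arange(10, 20)}
        out = downsample_balance(groups, seed=0)
        assert np.array_equal(out["a"], groups["a"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            downsample_balance({"a": np.arange(5), "b": np.array([])}, seed=0)


class TestVoom:
    def test_logcpm_of_zero_count_at_million_libsize(self):
        counts = np.array([[0.0, 5.0], [3.0, 2.0]])
        lib = np.array([1e6, 1e6])
        design = np.ones((2, 1))
        vf = voom_transform(counts, design, lib)
        assert vf.logcpm[0, 0] == pytest.approx(-1.0, abs=1e-4)

    def test_weights_are_inverse_fourth_power_of_trend(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(60, 30)).astype(float)
        vf = voom_transform(counts, np.ones((30, 1)), np.full(30, 1e4))
        assert (vf.weights > 0).all()
        # homoscedastic data: flat trend, weights within a 2-fold band
        w = vf.weights.ravel()
        assert w.max() / w.min() < 2.0

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            voom_transform(np.ones((5, 10)), X, np.full(10, 100.0))


class TestConsensusCorrelation:
    def _gaussian_blocks(self, icc, G=150, nb=8, k=40, seed=0):
        rng = np.random.default_rng(seed)
        blocks = np.repeat(np.arange(nb), k)
        a = rng.normal(size=(G, nb)) * np.sqrt(icc)
        Y = a[:, blocks] + rng.normal(size=(G, nb * k)) * np.sqrt(1 - icc)
        return Y, blocks

    @pytest.mark.parametrize("icc", [0.0, 0.3])
    def test_recovery_on_gaussian_blocks(self, icc):
        Y, blocks = self._gaussian_blocks(icc)
        cc = consensus_correlation(_unit_voomfit(Y), np.ones((Y.shape[1], 1)),
                                   blocks)
        assert abs(cc.rho_consensus - icc) < 0.05

    def test_permuting_blocks_destroys_correlation(self):
        Y, blocks = self._gaussian_blocks(0.3)
        rng = np.random.default_rng(1)
        cc = consensus_correlation(_unit_voomfit(Y), np.ones((Y.shape[1], 1)),
                                   rng.permutation(blocks))
        assert abs(cc.rho_consensus) < 0.05

    def test_gene_order_invariance(self):
        Y, blocks = self._gaussian_blocks(0.2, G=60)
        design = np.ones((Y.shape[1], 1))
        a = consensus_correlation(_unit_voomfit(Y), design, blocks)
        b = consensus_correlation(_unit_voomfit(Y[::-1]), design, blocks)
        assert a.rho_consensus == pytest.approx(b.rho_consensus, abs=1e-10)

    def test_singleton_blocks_rejected(self):
        Y = np.random.default_rng(0).normal(size=(10, 6))
        with pytest.raises(ValueError, match="replication"):
            consensus_correlation(_unit_voomfit(Y), np.ones((6, 1)),
                                  np.arange(6))


class TestModeratedFit:
    def test_matches_ols_oracle_to_1e8(self):
        """rho=0, unit weights, no moderation == textbook OLS t and p."""
        rng = np.random.default_rng(4)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(8, 16))
            G = int(rng.integers(5, 25))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            Y = rng.normal(size=(G, n))
            tab = fit_moderated(_unit_voomfit(Y), X, np.array([0.0, 1.0]),
                                rho=0.0, prior_df=0)
            for g in range(G):
                b, res, *_ = np.linalg.lstsq(X, Y[g], rcond=None)
                s2 = res[0] / (n - 2)
                t = b[1] / np.sqrt(np.linalg.inv(X.T @ X)[1, 1] * s2)
                p = 2 * stats.t.sf(abs(t), n - 2)
                worst = max(worst, abs(t - tab.moderated_t[g]),
                            abs(p - tab.p[g]))
        assert worst < 1e-8

    def test_infinite_prior_df_gives_common_variance(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(40, 12))
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        tab = fit_moderated(_unit_voomfit(Y), X, np.array([0.0, 1.0]),
                            prior_df=np.inf)
        assert tab.posterior_s2.nunique() == 1

    def test_moderation_shrinks_toward_prior(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(80, 10))
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        tab = fit_moderated(_unit_voomfit(Y), X, np.array([0.0, 1.0]))
        spread_raw = np.log(tab.s2).std()
        spread_post = np.log(tab.posterior_s2).std()
        assert spread_post < spread_raw

    def test_ignoring_true_correlation_inflates_positives(self):
        """Forcing rho=0 on correlated data yields more (false) positives
        than the consensus-correlation fit."""
        rng = np.random.default_rng(7)
        nb, k, G = 8, 40, 300
        blocks = np.repeat(np.arange(nb), k)
        group = (blocks >= nb // 2).astype(float)
        a = rng.normal(size=(G, nb)) * np.sqrt(0.3)
        Y = a[:, blocks] + rng.normal(size=(G, nb * k)) * np.sqrt(0.7)
        X = np.column_stack([np.ones(nb * k), group])
        vf = _unit_voomfit(Y)
        naive = fit_moderated(vf, X, np.array([0.0, 1.0]), rho=0.0)
        rho = consensus_correlation(vf, X, blocks).rho_consensus
        corrected = fit_moderated(vf, X, np.array([0.0, 1.0]), rho=rho,
                                  blocks=blocks)
        assert (naive.p <= 0.05).sum() > (corrected.p <= 0.05).sum()
        assert (corrected.p <= 0.05).mean() < 0.12

    def test_saturated_design_rejected(self):
        Y = np.random.default_rng(0).normal(size=(5, 2))
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        with pytest.raises(ValueError, match="saturated"):
            fit_moderated(_unit_voomfit(Y), X, np.array([0.0, 1.0]))


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 200)))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            out = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    def test_adjusted_at_least_raw_and_bounded(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # monotone in the p-value ranking
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestZINB:
    def test_null_split_gives_large_p(self, rng):
        ps = []
        for rep in range(20):
            y = rng.negative_binomial(2.0, 2.0 / 2.5, size=400)
            ps.append(zinb_lrt(y, np.repeat(["a", "b"], 200))["p"])
        assert np.median(ps) >= 0.3

    def test_pure_nb_fits_small_pi(self, rng):
        pis = [deg.fit_zinb(rng.negative_binomial(2.0, 2.0 / 3.0, size=200)).pi
               for _ in range(15)]
        assert np.mean(pis) <= 0.05

    def test_recovers_planted_zero_inflation(self, rng):
        y = np.where(rng.random(800) < 0.35, 0,
                     rng.negative_binomial(2.0, 2.0 / 4.0, size=800))
        fit = deg.fit_zinb(y)
        assert 0.2 <= fit.pi <= 0.5

    def test_power_for_fourfold_difference(self, rng):
        hits = 0
        for rep in range(15):
            ya = rng.negative_binomial(1.0, 1.0 / 1.45, size=200)
            yb = rng.negative_binomial(1.0, 1.0 / 2.8, size=200)
            row = zinb_lrt(np.concatenate([ya, yb]), np.repeat(["a", "b"], 200))
            hits += row["p"] <= 0.05
        assert hits / 15 >= 0.8

    def test_log2fc_sign_follows_group_means(self, rng):
        ya = rng.negative_binomial(2.0, 2.0 / 6.0, size=200)   # mean 4
        yb = rng.negative_binomial(2.0, 2.0 / 3.0, size=200)   # mean 1
        row = zinb_lrt(np.concatenate([ya, yb]), np.repeat(["a", "b"], 200))
        assert row["log2fc"] > 0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="20"):
            zinb_lrt(np.zeros(30), np.repeat(["a", "b"], 15))


class TestPipelineProperties:
    def test_planted_up_genes_have_positive_log2fc(self):
        cfg = sim.SimulationConfig(
            seed=17, cohort_layout=[("F", "het_female", "P30", 3),
                                    ("F", "wt_female", "P30", 3)],
            cells_per_animal=150, n_genes=300, n_cell_types=2,
            markers_per_type=0, frac_nca=0.15, effect_log2fc=1.0)
        animals, cells = sim.simulate_cohort(cfg)
        X, genes, meta, truth = sim.simulate_counts(animals, cells, cfg)
        high, low, info = deg.differential_expression(
            X.toarray().T, np.asarray(X.sum(axis=1)).ravel(),
            np.where(meta.genotype == "het_female", "het", "wt"),
            meta.animal_id.to_numpy(), list(genes.gene), seed=0)
        ge = truth.gene_effects.set_index("gene")
        merged = high.set_index("gene").join(ge, rsuffix="_true")
        up = merged[(merged.effect_class == "non_cell_autonomous")
                    & (merged.log2fc_true > 0) & (merged.adj_p <= 0.05)]
        assert len(up) >= 10
        assert (up.log2fc > 0).mean() >= 0.95
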