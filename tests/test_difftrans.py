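import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboscreen.difftrans import (LOW_ABUNDANCE, ModeratedS2B, NBDifferential,
                                  TranslationEfficiency, bh_adjust,
                                  estimate_dispersions, size_factors,
                                  squeeze_variances)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = np.tile(np.array([[3], [10], [50]]), (1, 4))
        np.testing.assert_allclose(size_factors(mat), np.ones(4))

    def test_doubled_column_scales_factor(self):
        a = np.array([[3.0], [10.0], [50.0]])
        mat = np.hstack([a, 2 * a])
        sf = size_factors(mat)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        mat = np.array([[4, 8, 2], [10, 30, 5], [100, 90, 80]], dtype=float)
        # oracle: per-gene geometric-mean reference, per-sample median ratio
        ref = np.exp(np.mean(np.log(mat), axis=1))
        expect = np.median(mat / ref[:, None], axis=0)
        np.testing.assert_allclose(size_factors(mat), expect)

    def test_all_zero_row_fallback(self, caplog):
        mat = np.array([[0, 1], [2, 0]], dtype=float)
        sf = size_factors(mat)
        assert (sf > 0).all()


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_adjusted_never_below_raw_and_nan_passthrough(self):
        p = np.array([0.001, np.nan, 0.5, 0.04])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        ok = ~np.isnan(p)
        assert (adj[ok] >= p[ok] - 1e-15).all()


def _nb_counts(rng, mean, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestNBDifferential:
    def test_statsmodels_glm_cross_check(self):
        """The vectorized group-mean Newton fit is the same NB GLM that
        statsmodels fits with a log link and offset."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        sf = np.array([0.9, 1.1, 1.0, 1.05, 0.85, 1.2])
        cond = np.array(["A", "A", "A", "B", "B", "B"])
        counts = pd.DataFrame(
            _nb_counts(rng, 200 * sf[None, :], 0.05, (20, 6)),
            index=[f"g{i}" for i in range(20)])
        model = NBDifferential(counts, cond, ("B", "A"), size_factors_=sf,
                               min_mean_count=0)
        res = model.fit()
        alpha = res.params["dispersion"]
        X = np.column_stack([np.ones(6), (cond == "B").astype(float)])
        for i in range(20):
            glm = sm.GLM(counts.iloc[i].to_numpy(), X,
                         family=sm.families.NegativeBinomial(alpha=alpha[i]),
                         offset=np.log(sf)).fit()
            lfc = glm.params[1] / np.log(2)
            se = glm.bse[1] / np.log(2)
            assert res.table["log2FC"].iloc[i] == pytest.approx(lfc, abs=1e-5)
            assert res.table["se"].iloc[i] == pytest.approx(se, rel=1e-3)

    def test_single_gene_recovery_200_simulations(self):
        """True log2FC 2 at mean 500, n=3: estimate within +-0.5 in >=90%."""
        rng = np.random.default_rng(11)
        a = _nb_counts(rng, 500.0, 0.02, (200, 3))
        b = _nb_counts(rng, 2000.0, 0.02, (200, 3))
        counts = pd.DataFrame(np.hstack([a, b]))
        res = NBDifferential(counts, ["A"] * 3 + ["B"] * 3, ("B", "A"),
                             size_factors_=np.ones(6)).fit()
        hits = np.abs(res.table["log2FC"] - 2.0) <= 0.5
        assert hits.mean() >= 0.90

    def test_all_zero_gene_skipped_low_abundance(self):
        counts = pd.DataFrame(np.vstack([np.zeros(6, dtype=int),
                                         np.full(6, 100)]),
                              index=["gz", "gok"])
        res = NBDifferential(counts, ["A"] * 3 + ["B"] * 3).fit()
        row = res.table.set_index("gene_id").loc["gz"]
        assert not row["tested"] and row["reason"] == LOW_ABUNDANCE
        assert np.isnan(row["p"])

    def test_requires_two_conditions_with_replicates(self):
        counts = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            NBDifferential(counts, ["A", "A", "B"])

    def test_wald_rank_orders_match_exact_permutation_test(self):
        """Across a 50-gene panel at n=3 vs 3, NB Wald p agrees in rank
        ordering with an exact condition-label permutation test.

        Effects are kept moderate so the 20-split permutation p (resolution
        1/10) does not saturate at its floor for most genes.
        """
        from itertools import combinations
        rng = np.random.default_rng(7)
        lfcs = rng.uniform(-0.8, 0.8, 50)
        counts = np.hstack([
            _nb_counts(rng, 300.0, 0.02, (50, 3)),
            _nb_counts(rng, 300.0 * 2 ** lfcs[:, None], 0.02, (50, 3))])
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(50)])
        res = NBDifferential(df, ["A"] * 3 + ["B"] * 3,
                             size_factors_=np.ones(6)).fit()
        y = np.log1p(counts)
        perm_p = []
        splits = [np.array(c) for c in combinations(range(6), 3)]
        for i in range(50):
            obs = abs(y[i, 3:].mean() - y[i, :3].mean())
            null = [abs(y[i, list(set(range(6)) - set(s))].mean()
                        - y[i, s].mean()) for s in splits]
            perm_p.append(np.mean([n >= obs - 1e-12 for n in null]))
        rho = stats.spearmanr(res.table["p"], perm_p).statistic
        assert rho >= 0.9


class TestTranslationEfficiency:
    def _paired(self, rng, rna_mean_b_factor, rpf_mean_b_factor, n_genes=60):
        rna = np.hstack([_nb_counts(rng, 300.0, 0.02, (n_genes, 3)),
                         _nb_counts(rng, 300.0 * rna_mean_b_factor, 0.02,
                                    (n_genes, 3))])
        rpf = np.hstack([_nb_counts(rng, 300.0, 0.02, (n_genes, 3)),
                         _nb_counts(rng, 300.0 * rpf_mean_b_factor, 0.02,
                                    (n_genes, 3))])
        idx = [f"g{i}" for i in range(n_genes)]
        cond = ["A"] * 3 + ["B"] * 3
        return (pd.DataFrame(rna, index=idx), pd.DataFrame(rpf, index=idx),
                cond)

    def test_parallel_doubling_gives_null_te(self):
        rna, rpf, cond = self._paired(np.random.default_rng(0), 2.0, 2.0)
        res = TranslationEfficiency(rna, rpf, cond, cond, ("B", "A")).fit()
        assert abs(res.table["log2FC"].mean()) < 0.1
        assert (res.table["p"] < 0.01).mean() < 0.05

    def test_rpf_only_doubling_of_subset_gives_unit_te_lfc(self):
        # doubling footprints of a 10-gene subset (so normalization has a
        # stable background) shifts those genes' TE log2FC to ~1
        rng = np.random.default_rng(1)
        rna, rpf, cond = self._paired(rng, 1.0, 1.0)
        spiked = rpf.index[:10]
        rpf.loc[spiked, rpf.columns[3:]] *= 2
        res = TranslationEfficiency(rna, rpf, cond, cond, ("B", "A")).fit()
        t = res.table.set_index("gene_id")
        # normalization absorbs a small part of a subset-only shift, so the
        # recovered interaction sits slightly under the generative value
        assert t.loc[spiked, "log2FC"].mean() == pytest.approx(1.0, abs=0.2)
        assert abs(t.drop(spiked)["log2FC"].mean()) < 0.1

    def test_gene_missing_in_one_assay_skipped_with_reason(self):
        rna, rpf, cond = self._paired(np.random.default_rng(2), 1.0, 1.0, 10)
        res = TranslationEfficiency(rna.iloc[:8], rpf, cond, cond).fit()
        t = res.table.set_index("gene_id")
        assert (t.loc[["g8", "g9"], "reason"] == "MISSING_ASSAY").all()
        assert not t.loc["g8", "tested"]


class TestModeratedS2B:
    def test_identical_values_give_p_one(self):
        vals = pd.DataFrame(np.full((30, 6), 90.0))
        res = ModeratedS2B(vals, ["A"] * 3 + ["B"] * 3).fit()
        assert (res.table["p"] == 1.0).all()
        assert (res.table["log2FC"] == 0.0).all()

    def test_zero_prior_weight_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(np.exp(rng.normal(4.5, 0.3, (40, 6))))
        cond = ["A"] * 3 + ["B"] * 3
        res0 = ModeratedS2B(vals, cond, prior_weight=0).fit()
        logv = np.log2(vals.to_numpy())
        for i in range(40):
            t, p = stats.ttest_ind(logv[i, 3:], logv[i, :3], equal_var=True)
            assert res0.table["p"].iloc[i] == pytest.approx(p, rel=1e-9)

    def test_too_few_finite_values_skipped(self):
        vals = pd.DataFrame(np.full((5, 6), 90.0))
        vals.iloc[0, [0, 1]] = np.nan
        res = ModeratedS2B(vals, ["A"] * 3 + ["B"] * 3).fit()
        assert not res.table["tested"].iloc[0]
        assert res.table["reason"].iloc[0] == "TOO_FEW_VALUES"

    def test_infinite_sentinels_treated_as_missing(self):
        vals = pd.DataFrame(np.full((5, 6), 90.0)
                            + np.random.default_rng(1).normal(0, 1, (5, 6)))
        vals.iloc[1, 0] = np.inf
        res = ModeratedS2B(vals, ["A"] * 3 + ["B"] * 3).fit()
        assert res.table["tested"].iloc[1]  # still 2 finite per condition

    def test_squeeze_variances_shrinks_toward_prior(self):
        rng = np.random.default_rng(5)
        df = np.full(400, 4.0)
        true_var = np.exp(rng.normal(np.log(0.25), 0.6, 400))
        s2 = true_var * stats.chi2.rvs(4, size=400, random_state=rng) / 4
        post, d0, s0 = squeeze_variances(s2, df)
        assert 0 < d0 < np.inf
        assert s0 == pytest.approx(0.25, rel=0.5)
        # posterior lies between the raw variance and the prior
        lo = np.minimum(s2, s0) - 1e-12
        hi = np.maximum(s2, s0) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()

    def test_squeeze_variances_homogeneous_gives_heavy_prior(self):
        # when all true variances are equal, the fitted prior df is large
        # (often infinite) and posteriors collapse toward the prior
        rng = np.random.default_rng(6)
        s2 = 0.25 * stats.chi2.rvs(4, size=300, random_state=rng) / 4
        post, d0, s0 = squeeze_variances(s2, np.full(300, 4.0))
        assert d0 > 8
        assert np.abs(post / s0 - 1).max() < 0.6

    def test_limma_cross_check_via_rscript(self, tmp_path):
        """Moderated t statistics match the reference empirical-Bayes
        implementation in the limma R package on a complete matrix."""
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(2.0 ** rng.normal(6.5, 0.4, (60, 6)),
                            index=[f"g{i}" for i in range(60)])
        cond = ["A"] * 3 + ["B"] * 3
        res = ModeratedS2B(vals, cond, ("B", "A")).fit()
        mat_path = tmp_path / "m.tsv"
        np.log2(vals).to_csv(mat_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mat_path}", row.names=1))
            design <- cbind(1, c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(m, design))
            write.table(data.frame(p=fit$p.value[,2], t=fit$t[,2]),
                        "{out_path}", sep="\t", quote=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        np.testing.assert_allclose(res.table.set_index("gene_id")["p"],
                                   ref["p"], rtol=1e-4)


def test_dispersion_estimates_recover_truth_scale():
    rng = np.random.default_rng(2)
    mean = rng.lognormal(np.log(300), 1.0, 1500)
    counts = _nb_counts(rng, mean[:, None], 0.05, (1500, 6))
    alpha = estimate_dispersions(counts.astype(float), np.ones(6),
                                 [np.arange(3), np.arange(3, 6)])
    assert np.median(alpha) == pytest.approx(0.05, rel=0.3)
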