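"""Phenotype adjustment, mixed-model scan, LD pruning, top-SNP selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genopred import assoc
from genopred.grm import GRM, build_grm
from genopred.simdata import SimConfig, simulate_population
from genopred.varcomp import reml_fit

from conftest import make_genotypes


class TestAdjustPhenotype:
    def test_intercept_only_centers_the_trait(self):
        df = pd.DataFrame({"id": list("abcd"), "trait": [1.0, 2.0, 3.0, 10.0]})
        resid = assoc.adjust_phenotype(df, "trait", model=())
        np.testing.assert_allclose(resid, df["trait"] - 4.0, atol=1e-12)

    def test_binary_factor_residuals_by_hand(self):
        # groups: x -> mean 2, y -> mean 7; residuals by subtraction
        df = pd.DataFrame(
            {"id": list("abcdef"),
             "trait": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0],
             "grp": ["x", "x", "x", "y", "y", "y"]}
        )
        resid = assoc.adjust_phenotype(df, "trait", model=["grp"])
        np.testing.assert_allclose(resid, [-1, 0, 1, -1, 0, 1], atol=1e-12)

    def test_interaction_term_is_combined_factor(self):
        df = pd.DataFrame(
            {"id": list("abcdefgh"),
             "trait": [1.0, 2, 3, 4, 10, 11, 20, 21],
             "a": ["u", "u", "u", "u", "v", "v", "v", "v"],
             "b": ["p", "p", "q", "q", "p", "p", "q", "q"]}
        )
        resid = assoc.adjust_phenotype(df, "trait", model=[("a", "b")])
        # four cells with means (1.5, 3.5, 10.5, 20.5)
        np.testing.assert_allclose(resid, [-0.5, 0.5] * 4, atol=1e-12)

    def test_saturated_factor_is_an_error(self):
        df = pd.DataFrame({"id": list("abc"), "trait": [1.0, 2, 3],
                           "f": ["x", "y", "z"]})
        with pytest.raises(assoc.SaturatedModelError):
            assoc.adjust_phenotype(df, "trait", model=["f"])

    def test_pure_noise_factor_barely_changes_residual_variance(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({"id": np.arange(n).astype(str),
                           "trait": rng.standard_normal(n),
                           "real": rng.choice(["a", "b", "c"], n),
                           "noise": rng.choice(list("abcdefgh"), n)})
        v1 = np.var(assoc.adjust_phenotype(df, "trait", model=["real"]))
        v2 = np.var(assoc.adjust_phenotype(df, "trait", model=["real", "noise"]))
        assert abs(v1 - v2) / v1 < 0.01


class TestGwasScan:
    def test_zero_grm_reduces_to_per_snp_ols(self):
        """Brute-force oracle: with G = 0, GLS collapses to plain OLS."""
        rng = np.random.default_rng(1)
        n, m = 50, 100
        g = make_genotypes(rng.integers(0, 3, size=(n, m)).astype(np.int8))
        y = rng.standard_normal(n)
        G0 = GRM(matrix=np.zeros((n, n)), sample_ids=g.sample_ids,
                 snp_ids_used=g.snp_ids)
        res = assoc.gwas_scan(g, y, G0, sigma2_a=1.0, sigma2_e=1.0)
        x = g.values.astype(float)
        for j in rng.choice(m, 12, replace=False):
            X = np.column_stack([np.ones(n), x[:, j]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            assert res.table["alpha"].iloc[j] == pytest.approx(beta[1], abs=1e-8)

    def test_planted_qtl_is_top_hit(self):
        cfg = SimConfig(n_individuals=600, n_snps=800, n_chromosomes=2,
                        n_families=1, ld_decay=0.0, n_qtl=1,
                        architecture="oligogenic", h2=0.05, seed=17)
        out = simulate_population(cfg)
        y = out.phenotypes - out.phenotypes.mean()
        G = build_grm(out.genotypes)
        vc = reml_fit(y, [G])
        res = assoc.gwas_scan(out.genotypes, y, G, vc.sigma2_a[0], vc.sigma2_e)
        (qtl, _), = out.true_qtl
        assert res.table["p"].idxmin() == qtl

    def test_allele_relabeling_flips_effect_sign(self):
        rng = np.random.default_rng(2)
        n = 80
        vals = rng.integers(0, 3, size=(n, 5)).astype(np.int8)
        g1 = make_genotypes(vals)
        g2 = make_genotypes(2 - vals)
        y = rng.standard_normal(n)
        G0 = GRM(matrix=np.eye(n) * 0.0, sample_ids=g1.sample_ids,
                 snp_ids_used=g1.snp_ids)
        r1 = assoc.gwas_scan(g1, y, G0, 0.5, 1.0)
        r2 = assoc.gwas_scan(g2, y, G0, 0.5, 1.0)
        np.testing.assert_allclose(r1.table["alpha"], -r2.table["alpha"], atol=1e-10)
        np.testing.assert_allclose(r1.table["p"], r2.table["p"], atol=1e-10)

    def test_permuted_phenotype_destroys_signal(self, small_population):
        out = small_population
        rng = np.random.default_rng(3)
        y = rng.permutation(out.phenotypes)
        G = build_grm(out.genotypes)
        res = assoc.gwas_scan(out.genotypes, y - y.mean(), G, 0.1, 0.9)
        truth = np.zeros(out.genotypes.n_snps)
        for idx, eff in out.true_qtl:
            truth[idx] = eff
        r = np.corrcoef(res.table["alpha"], truth)[0, 1]
        assert abs(r) < 0.1


def test_variance_share_closed_forms():
    assert assoc.variance_share(0.5, 0.0, 50.0) == 0.0
    assert assoc.variance_share(0.5, 1.0, 50.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        assoc.variance_share(0.5, 1.0, 0.0)


def test_variance_share_single_qtl_is_total_genetic_variance():
    cfg = SimConfig(n_individuals=2000, n_snps=100, n_chromosomes=1,
                    n_families=1, n_qtl=1, architecture="oligogenic",
                    h2=0.4, seed=13)
    out = simulate_population(cfg)
    (idx, eff), = out.true_qtl
    p = out.genotypes.allele_freq()[idx]
    sigma2_a = float(np.var(out.true_breeding_values))
    share = assoc.variance_share(p, eff, sigma2_a)
    # 2p(1-p)a^2 is the HWE variance of the QTL; sampling error only
    assert share == pytest.approx(100.0, abs=5.0)


class TestPruneLd:
    def _toy_panel(self):
        """6 SNPs with hand-set LD: s0=s1 (r2=1), s3=s4 (r2=1), rest free."""
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        vals = np.column_stack(
            [base[:, 0], base[:, 0], base[:, 1], base[:, 2], base[:, 2], base[:, 3]]
        ).astype(np.int8)
        return make_genotypes(vals)

    def test_duplicated_snp_keeps_only_the_more_significant(self):
        g = self._toy_panel()
        # significance order: s1 best, then s0 (its duplicate), then others
        sel = assoc.prune_ld(g, ["s1", "s0", "s2", "s3", "s4", "s5"],
                             r2_max=0.95, window=6, step=2)
        assert "s1" in sel.snp_ids and "s0" not in sel.snp_ids

    def test_hand_enumerated_retained_set(self):
        """Window walk enumerated by hand.

        Duplicate pairs (s0,s1) and (s3,s4); rank s3 > s0 > s1 > s4 > s2
        > s5. Windows of 3 shifted by 1:
        [s0,s1,s2] best s0 -> drop s1; [s2,s3] best s3 -> keep s2;
        [s2,s3,s4] best s3 -> drop s4; [s3,s5] best s3 -> keep s5.
        Retained, genomic order: s0, s2, s3, s5.
        """
        g = self._toy_panel()
        ranked = ["s3", "s0", "s1", "s4", "s2", "s5"]
        sel = assoc.prune_ld(g, ranked, r2_max=0.95, window=3, step=1)
        # windows (size 3, step 1): [s0,s1,s2] best s0 -> drop s1;
        # [s2,s3,s4] best s3 -> drop s4; [s4(gone),s5] nothing.
        assert list(sel.snp_ids) == ["s0", "s2", "s3", "s5"]

    def test_all_distinct_with_r2max_one_is_identity(self):
        rng = np.random.default_rng(8)
        g = make_genotypes(rng.integers(0, 3, size=(50, 6)).astype(np.int8))
        ranked = [f"s{j}" for j in range(6)]
        sel = assoc.prune_ld(g, ranked, r2_max=1.0, window=6, step=2)
        assert list(sel.snp_ids) == ranked

    def test_redundant_additions_do_not_change_retained_set(self):
        g = self._toy_panel()
        sel_small = assoc.prune_ld(g, ["s0", "s2", "s5"], r2_max=0.95,
                                   window=6, step=2)
        sel_big = assoc.prune_ld(g, ["s0", "s1", "s2", "s5"], r2_max=0.95,
                                 window=6, step=2)
        assert list(sel_small.snp_ids) == [s for s in sel_big.snp_ids if s != "s1"]
        assert "s1" not in sel_big.snp_ids

    def test_invalid_window_is_an_error(self):
        g = self._toy_panel()
        with pytest.raises(ValueError):
            assoc.prune_ld(g, ["s0"], window=0)


class TestSelectTopSnps:
    def _result(self, pvals):
        m = len(pvals)
        table = pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(m)],
             "chrom": "chr1", "bp": 1 + 100 * np.arange(m),
             "freq": 0.3, "alpha": 0.1, "se": 0.05,
             "p": pvals, "neglog10p": -np.log10(pvals),
             "var_share_pct": 1.0}
        )
        return assoc.GwasResult(table=table, sigma2_a=1.0, sigma2_e=1.0)

    def test_threshold_counts_by_hand(self):
        res = self._result([1e-3, 1e-2, 0.5])
        g = make_genotypes(np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1],
                                     [0, 2, 1]], dtype=np.int8))
        sel = assoc.select_top_snps(res, g, threshold_neglog10p=2.5, prune=None)
        assert list(sel.snp_ids) == ["s0"]  # only p=1e-3 passes p<0.0032

    def test_infinite_threshold_gives_empty_flagged_selection(self):
        res = self._result([1e-3, 1e-2, 0.5])
        g = make_genotypes(np.zeros((4, 3), dtype=np.int8))
        sel = assoc.select_top_snps(res, g, threshold_neglog10p=np.inf)
        assert sel.empty and len(sel.snp_ids) == 0

    def test_threshold_2_5_is_p_0_0032(self):
        assert 10 ** (-2.5) == pytest.approx(0.0032, abs=5e-5)
        res = self._result([0.0031, 0.0033])
        g = make_genotypes(np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8))
        sel = assoc.select_top_snps(res, g, threshold_neglog10p=2.5, prune=None)
        assert list(sel.snp_ids) == ["s0"]


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=20))
def test_neglog10p_consistency_property(pvals):
    """The stored -log10(p) always matches the p column."""
    table = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(len(pvals))],
         "chrom": "chr1", "bp": np.arange(len(pvals)),
         "freq": 0.5, "alpha": 0.0, "se": 1.0,
         "p": pvals, "neglog10p": -np.log10(pvals), "var_share_pct": 0.0}
    )
    res = assoc.GwasResult(table=table, sigma2_a=1.0, sigma2_e=1.0)
    np.testing.assert_allclose(res.table["neglog10p"],
                               -np.log10(res.table["p"]), atol=1e-9)
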