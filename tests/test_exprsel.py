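"""Expression-based SNP prioritization: GSA, harvesting, eQTL scans."""

import numpy as np
import pandas as pd
import pytest

from genopred import exprsel
from genopred.simdata import (SimConfig, make_gene_map,
                              simulate_expression_panel, simulate_population)

from conftest import make_genotypes


@pytest.fixture(scope="module")
def expression_setup():
    cfg = SimConfig(n_individuals=250, n_snps=500, n_chromosomes=2,
                    n_families=15, n_qtl=20, h2=0.3, seed=77)
    out = simulate_population(cfg)
    gmap = make_gene_map(out.genotypes, 40, seed=5)
    panel, truth = simulate_expression_panel(
        out.genotypes, 45, 40, gmap, cfg, ages_months=(8, 12, 30),
        n_eqtl_genes=2, eqtl_effect_sd=2.0,
        n_gsa_genes=2, gsa_effect=1.2, phenotypes=out.phenotypes)
    y_by_animal = dict(zip(out.genotypes.sample_ids,
                           out.phenotypes - out.phenotypes.mean()))
    return out, panel, truth, y_by_animal


class TestGsa:
    def test_planted_gsa_genes_are_flagged(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        res = exprsel.gsa_scan(panel, y_by)
        planted = set(truth.loc[truth.kind == "gsa", "gene_id"])
        flagged = set(res.loc[res.gsa, "gene_id"])
        assert planted <= flagged

    def test_permuted_phenotype_null_calibration(self, expression_setup):
        """Hit rate at p<0.0032 stays near nominal under permutation."""
        out, panel, truth, y_by = expression_setup
        rng = np.random.default_rng(1)
        counts = 0
        reps = 30
        vals = np.fromiter(y_by.values(), dtype=float)
        keys = list(y_by)
        for _ in range(reps):
            perm = dict(zip(keys, rng.permutation(vals)))
            res = exprsel.gsa_scan(panel, perm)
            counts += int(res["gsa"].sum())
        rate = counts / (reps * len(res))
        # nominal 0.0032; binomial 99.9% upper bound ~ 0.0032+3.3*sqrt(pq/n)
        n_tests = reps * len(res)
        bound = 0.0032 + 3.3 * np.sqrt(0.0032 * 0.9968 / n_tests)
        assert rate < bound

    def test_missing_phenotype_raises(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        partial = dict(list(y_by.items())[:3])
        with pytest.raises(KeyError):
            exprsel.gsa_scan(panel, partial)


class TestHarvest:
    def _toy(self):
        g = make_genotypes(np.array([[0, 1, 2, 1], [1, 2, 0, 0],
                                     [2, 0, 1, 2]], dtype=np.int8),
                           bp=[650, 720, 1500, 2500])
        gmap = pd.DataFrame({"gene_id": ["gA"], "chrom": ["chr1"],
                             "start": [1000], "end": [2000], "strand": ["+"]})
        return g, gmap

    def test_plus_strand_promoter_interval(self):
        """Gene 1000-2000 (+): harvested window [700, 2000] catches
        SNPs at 720 and 1500, not 650 or 2500."""
        g, gmap = self._toy()
        sel, skipped = exprsel.harvest_gene_snps(["gA"], gmap, g)
        assert sorted(sel.snp_ids) == ["s1", "s2"]
        assert skipped == []

    def test_minus_strand_promoter_is_downstream(self):
        """Gene 1000-2000 (-): promoter [2001, 2300]; window [1000, 2300]."""
        g, gmap = self._toy()
        gmap["strand"] = "-"
        lo, hi = exprsel.gene_interval(gmap.iloc[0])
        assert (lo, hi) == (1000, 2300)
        sel, _ = exprsel.harvest_gene_snps(["gA"], gmap, g)
        assert sorted(sel.snp_ids) == ["s2"]  # 1500 only; 2500 outside

    def test_gene_without_snps_contributes_none_and_missing_gene_skipped(self):
        g, gmap = self._toy()
        gmap2 = pd.concat([gmap, pd.DataFrame(
            {"gene_id": ["gB"], "chrom": ["chr1"], "start": [5000],
             "end": [6000], "strand": ["+"]})], ignore_index=True)
        sel, skipped = exprsel.harvest_gene_snps(["gA", "gB", "gC"], gmap2, g)
        assert sorted(sel.snp_ids) == ["s1", "s2"]
        assert skipped == ["gC"]

    def test_harvest_invariant_to_gene_order(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        genes = list(panel.gene_map["gene_id"][:10])
        a, _ = exprsel.harvest_gene_snps(genes, panel.gene_map, out.genotypes)
        b, _ = exprsel.harvest_gene_snps(genes[::-1], panel.gene_map,
                                         out.genotypes)
        assert list(a.snp_ids) == list(b.snp_ids)


class TestEqtl:
    def test_planted_pair_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_individuals=120, n_snps=200, n_chromosomes=1,
                            n_families=1, n_qtl=5, seed=500 + seed)
            out = simulate_population(cfg)
            gmap = make_gene_map(out.genotypes, 10, seed=seed)
            panel, truth = simulate_expression_panel(
                out.genotypes, 45, 10, gmap, cfg, ages_months=(8,),
                n_eqtl_genes=1, eqtl_effect_sd=2.0)
            if truth.empty:
                continue
            res = exprsel.eqtl_scan(panel, out.genotypes, 8)
            planted = truth.iloc[0]
            found = ((res.gene_id == planted.gene_id)
                     & (res.snp_id == planted.snp_id)).any()
            hits += int(found)
        assert hits >= 8

    def test_permutation_null_rate(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        rng = np.random.default_rng(2)
        counts = panel.counts.copy()
        idx8 = panel.samples_at_age(8)
        perm = rng.permutation(idx8)
        shuffled = counts.to_numpy().copy()
        shuffled[:, idx8] = shuffled[:, perm]
        panel2 = exprsel.ExpressionPanel(
            counts=pd.DataFrame(shuffled, index=counts.index,
                                columns=counts.columns),
            covariates=panel.covariates, gene_map=panel.gene_map)
        res = exprsel.eqtl_scan(panel2, out.genotypes, 8)
        n_tests = len(panel.counts) * out.genotypes.n_snps
        rate = len(res) / n_tests
        bound = 0.0032 + 3.3 * np.sqrt(0.0032 * 0.9968 / n_tests)
        assert rate < bound

    def test_same_seed_identical_hits(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        a = exprsel.eqtl_scan(panel, out.genotypes, 12)
        b = exprsel.eqtl_scan(panel, out.genotypes, 12)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_age_is_an_error(self, expression_setup):
        out, panel, *_ = expression_setup
        with pytest.raises(ValueError, match="age"):
            exprsel.eqtl_scan(panel, out.genotypes, 99)


class TestCombineAges:
    def test_single_age_equals_its_pruned_list(self, expression_setup):
        out, panel, truth, y_by = expression_setup
        h8 = exprsel.eqtl_scan(panel, out.genotypes, 8)
        combined = exprsel.combine_eqtl_ages([h8], out.genotypes,
                                             prune=(0.95, 100, 20))
        from genopred.assoc import prune_ld
        ranked = h8.groupby("snp_id", sort=False)["p"].min().sort_values(
            kind="mergesort").index.to_list()
        direct = prune_ld(out.genotypes, ranked, 0.95, 100, 20)
        assert list(combined.snp_ids) == list(direct.snp_ids)

    def test_union_of_disjoint_hits(self, expression_setup):
        out, *_ = expression_setup
        mk = lambda rows: pd.DataFrame(
            rows, columns=["snp_id", "gene_id", "age_months", "beta", "p",
                           "cis_flag"])
        ids = out.genotypes.snp_ids
        h1 = mk([(ids[0], "g1", 8, 1.0, 1e-4, True),
                 (ids[5], "g2", 8, 1.0, 1e-5, False)])
        h2 = mk([(ids[9], "g1", 12, 1.0, 1e-3, True)])
        sel = exprsel.combine_eqtl_ages([h1, h2], out.genotypes,
                                        prune=(0.95, 50, 10))
        assert set(sel.snp_ids) == {ids[0], ids[5], ids[9]}

    def test_duplicate_snp_across_ages_counted_once(self, expression_setup):
        out, *_ = expression_setup
        ids = out.genotypes.snp_ids
        mk = lambda rows: pd.DataFrame(
            rows, columns=["snp_id", "gene_id", "age_months", "beta", "p",
                           "cis_flag"])
        h1 = mk([(ids[0], "g1", 8, 1.0, 1e-4, True)])
        h2 = mk([(ids[0], "g1", 12, 1.0, 1e-6, True)])
        sel = exprsel.combine_eqtl_ages([h1, h2], out.genotypes,
                                        prune=(0.95, 50, 10))
        assert list(sel.snp_ids) == [ids[0]]
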