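"""Simulate the study population and write its on-disk artifacts.

Outputs under results/sim/: PLINK bed/bim/fam genotypes, a phenotype +
covariate table, the expression panel with its gene map, and the truth
records (QTL, planted expression signals) used later for sanity checks.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from genopred.genio import write_plink
from genopred.simdata import (make_gene_map, simulate_expression_panel,
                              simulate_population)


def main():
    common.SIM_DIR.mkdir(parents=True, exist_ok=True)
    out = simulate_population(common.POPULATION)
    write_plink(out.genotypes, common.SIM_DIR / "geno")

    pheno = out.phenotype_table()
    pheno["family"] = out.family_ids
    pheno.to_csv(common.SIM_DIR / "phenotypes.tsv", sep="\t", index=False)

    truth = pd.DataFrame(out.true_qtl, columns=["snp_index", "effect"])
    truth["snp_id"] = out.genotypes.snp_ids[truth["snp_index"]]
    truth.to_csv(common.SIM_DIR / "true_qtl.tsv", sep="\t", index=False)

    gmap = make_gene_map(out.genotypes, common.N_GENES,
                         seed=common.MASTER_SEED)
    panel, expr_truth = simulate_expression_panel(
        out.genotypes, common.N_EXPR_ANIMALS, common.N_GENES, gmap,
        common.POPULATION, ages_months=common.EXPR_AGES,
        n_eqtl_genes=common.N_EQTL_GENES, n_gsa_genes=common.N_GSA_GENES,
        phenotypes=out.phenotypes)
    panel.counts.to_csv(common.SIM_DIR / "expression.tsv", sep="\t")
    panel.covariates.to_csv(common.SIM_DIR / "expression_covariates.tsv",
                            sep="\t", index=False)
    gmap.to_csv(common.SIM_DIR / "gene_map.tsv", sep="\t", index=False)
    expr_truth.to_csv(common.SIM_DIR / "expression_truth.tsv", sep="\t",
                      index=False)

    h2_real = np.var(out.true_breeding_values) / (
        np.var(out.true_breeding_values)
        + np.var(out.phenotypes - out.true_breeding_values
                 - (out.phenotypes - out.true_breeding_values).mean()))
    print(f"simulated {out.genotypes.n_individuals} animals x "
          f"{out.genotypes.n_snps} SNPs, {len(truth)} QTL")
    print(f"realized var(TBV) = {np.var(out.true_breeding_values):.3f} "
          f"(target h2 {common.POPULATION.h2})")
    print(f"expression panel: {panel.counts.shape[0]} genes x "
          f"{panel.counts.shape[1]} samples over ages {common.EXPR_AGES}")


if __name__ == "__main__":
    main()
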