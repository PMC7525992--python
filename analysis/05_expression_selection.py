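"""Expression-based SNP pre-selection: GSA gene harvest and eQTL scans.

GSA: genes whose expression tracks the adjusted phenotype (diet and sire
as fixed effects, p < 0.0032); SNPs harvested from 300 bp upstream of
the TSS (strand-aware) through the gene end. eQTL: per-age all-pairs
scans at the same threshold, combined across ages and LD-pruned. Writes
results/selection_gsa.txt and results/selection_eqtl.txt.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from genopred.exprsel import (ExpressionPanel, combine_eqtl_ages, eqtl_scan,
                              gsa_scan, harvest_gene_snps)
from genopred.genio import read_plink


def main():
    g = read_plink(common.SIM_DIR / "geno")
    counts = pd.read_csv(common.SIM_DIR / "expression.tsv", sep="\t",
                         index_col=0)
    cov = pd.read_csv(common.SIM_DIR / "expression_covariates.tsv", sep="\t",
                      dtype={"animal_id": str, "sample": str})
    gmap = pd.read_csv(common.SIM_DIR / "gene_map.tsv", sep="\t")
    panel = ExpressionPanel(counts=counts, covariates=cov, gene_map=gmap)

    pheno = pd.read_csv(common.SIM_DIR / "phenotypes_adjusted.tsv", sep="\t",
                        dtype={"id": str})
    y_by_animal = dict(zip(pheno["id"], pheno["trait_adjusted"]))

    gsa = gsa_scan(panel, y_by_animal)
    gsa_genes = gsa.loc[gsa.gsa, "gene_id"].tolist()
    sel_gsa, skipped = harvest_gene_snps(gsa_genes, gmap, g,
                                         prune=common.PRUNE)
    (common.RESULTS / "selection_gsa.txt").write_text(
        "\n".join(sel_gsa.snp_ids) + ("\n" if len(sel_gsa.snp_ids) else ""))
    truth = pd.read_csv(common.SIM_DIR / "expression_truth.tsv", sep="\t")
    planted_gsa = set(truth.loc[truth.kind == "gsa", "gene_id"])
    print(f"GSA: {len(gsa_genes)} significant genes "
          f"({len(planted_gsa & set(gsa_genes))} of {len(planted_gsa)} "
          f"planted recovered) -> {len(sel_gsa.snp_ids)} SNPs harvested")

    per_age = []
    for age in common.EXPR_AGES:
        hits = eqtl_scan(panel, g, age)
        per_age.append(hits)
        print(f"eQTL at {age:2d} months: {len(hits)} hits "
              f"({int(hits.cis_flag.sum())} cis)")
    sel_eqtl = combine_eqtl_ages(per_age, g, prune=common.PRUNE)
    (common.RESULTS / "selection_eqtl.txt").write_text(
        "\n".join(sel_eqtl.snp_ids) + ("\n" if len(sel_eqtl.snp_ids) else ""))
    print(f"combined across ages and pruned: {len(sel_eqtl.snp_ids)} "
          f"unique eQTL SNPs")


if __name__ == "__main__":
    main()
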