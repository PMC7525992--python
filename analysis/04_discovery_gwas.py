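"""Mixed-model GWAS on the discovery animals and top-SNP selection.

Variance components are fitted once on the discovery set (no per-SNP
refit); each SNP is then tested by GLS under V = G sigma2_a + I sigma2_e.
SNPs passing -log10(p) >= 2.5 (p < 0.0032) are LD-pruned (r2 >= 0.95
against the window's most significant SNP). Writes results/gwas.tsv and
results/selection_gwas.txt.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from genopred.assoc import gwas_scan, select_top_snps
from genopred.genio import read_plink
from genopred.grm import build_grm
from genopred.varcomp import reml_fit


def main():
    g = read_plink(common.SIM_DIR / "geno")
    pheno = pd.read_csv(common.SIM_DIR / "phenotypes_adjusted.tsv", sep="\t",
                        dtype={"id": str})
    design = pd.read_csv(common.RESULTS / "fold_design_random.tsv", sep="\t",
                         dtype=str)
    disc_ids = set(design.loc[design.role == "discovery", "id"])
    mask = np.array([s in disc_ids for s in g.sample_ids])
    gd = g.subset_samples(np.where(mask)[0])
    y = pheno.set_index("id").loc[gd.sample_ids, "trait_adjusted"].to_numpy()
    y = y - y.mean()

    Gd = build_grm(gd)
    vc = reml_fit(y, [Gd])
    print(f"discovery REML: h2 = {vc.h2:.3f} "
          f"(sigma2_a {vc.sigma2_a[0]:.3f}, sigma2_e {vc.sigma2_e:.3f})")

    res = gwas_scan(gd, y, Gd, vc.sigma2_a[0], vc.sigma2_e)
    res.table.to_csv(common.RESULTS / "gwas.tsv", sep="\t", index=False)

    sel = select_top_snps(res, gd, threshold_neglog10p=common.THRESHOLD,
                          prune=common.PRUNE)
    Path(common.RESULTS / "selection_gwas.txt").write_text(
        "\n".join(sel.snp_ids) + ("\n" if len(sel.snp_ids) else ""))

    truth = pd.read_csv(common.SIM_DIR / "true_qtl.tsv", sep="\t")
    hits_near_qtl = sum(
        any(abs(res.table.set_index("snp_id").loc[s, "bp"] - row.bp) <= 5000
            and res.table.set_index("snp_id").loc[s, "chrom"] == row.chrom
            for s in sel.snp_ids)
        for row in truth.assign(
            bp=res.table.set_index("snp_id").reindex(truth.snp_id)["bp"].to_numpy(),
            chrom=res.table.set_index("snp_id").reindex(truth.snp_id)["chrom"].to_numpy(),
        ).itertuples())
    n_sig = int((res.table.neglog10p >= common.THRESHOLD).sum())
    print(f"{n_sig} SNPs pass -log10(p) >= {common.THRESHOLD}; "
          f"{len(sel.snp_ids)} remain after pruning")
    print(f"{hits_near_qtl} of {len(truth)} true QTL have a selected SNP "
          f"within 5 kb")
    top = res.table.nsmallest(3, "p")[["snp_id", "p", "var_share_pct"]]
    print("top hits:\n" + top.to_string(index=False))


if __name__ == "__main__":
    main()
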