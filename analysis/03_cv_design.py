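"""Pick the GWAS discovery set and build the cross-validation folds.

The discovery set is the most diverse of 100 random draws under the
average co-ancestry criterion x'Gx/2 and is disjoint from every CV
animal. The remaining animals are split into 10 folds twice: at random
and by k-means on GRM principal components (keeping relatives together).
Writes results/fold_design_{random,kmeans}.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from genopred.cvdesign import (FoldDesign, kmeans_folds,
                               mean_fold_cross_relationship, random_folds,
                               select_discovery)
from genopred.genio import read_plink
from genopred.grm import GRM
from genopred.pipeline import stage_seed


def main():
    g = read_plink(common.SIM_DIR / "geno")
    gdf = pd.read_csv(common.RESULTS / "grm.tsv", sep="\t", index_col=0)
    G = GRM(matrix=gdf.to_numpy(), sample_ids=gdf.index.to_numpy(dtype=object),
            snp_ids_used=g.snp_ids)

    disc, scores = select_discovery(G, common.N_DISCOVERY,
                                    seed=stage_seed(common.MASTER_SEED,
                                                    "discovery"))
    print(f"discovery set: {len(disc)} animals; criterion "
          f"{scores.min():.1f} (best) vs {np.median(scores):.1f} (median "
          f"of 100 candidates)")
    rest = np.array([s for s in G.sample_ids if s not in set(disc)],
                    dtype=object)

    rd = random_folds(rest, n_folds=common.N_FOLDS,
                      seed=stage_seed(common.MASTER_SEED, "random_folds"))
    km = kmeans_folds(G, rest, n_clusters=common.N_CLUSTERS,
                      n_starts=common.N_STARTS, n_folds=common.N_FOLDS,
                      n_pcs=common.N_PCS,
                      seed=stage_seed(common.MASTER_SEED, "kmeans_folds"))
    for name, folds in (("random", rd), ("kmeans", km)):
        design = FoldDesign(discovery_ids=disc,
                            fold_assignment=folds.fold_assignment,
                            strategy=name, seed=folds.seed)
        design.to_frame().to_csv(
            common.RESULTS / f"fold_design_{name}.tsv", sep="\t", index=False)
        rel = mean_fold_cross_relationship(G, design)
        print(f"{name:7s} folds: mean fold-to-complement relationship "
              f"{rel:+.4f}")
    print("k-means folds should show the lower cross-fold relatedness: "
          "validation animals have fewer close relatives in training")


if __name__ == "__main__":
    main()
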