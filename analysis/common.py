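"""Shared configuration for the analysis drivers.

The stated world: a herd-structured beef-cattle-like population with a
moderately heritable carcass trait (h2 = 0.25), a mid-density SNP array
with LD blocks, an oligogenic-leaning architecture so SNP pre-selection
has signal to find, categorical fixed effects, and a 45-animal
expression panel measured at five ages under a two-level diet with sire
groups. Sizes are desk-scale stand-ins for the original design (which
used ~13,700 animals and ~59,000 array SNPs).
"""

from pathlib import Path

from genopred.simdata import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"

MASTER_SEED = 20240915

POPULATION = SimConfig(
    n_individuals=1500,
    n_snps=3000,
    n_chromosomes=5,
    n_families=75,          # half-sib families of ~20, sibs only
    ld_decay=0.7,
    maf_range=(0.05, 0.5),
    architecture="oligogenic",
    n_qtl=20,
    h2=0.25,
    fixed_effects=[("herd", 8, 0.5), ("year", 4, 0.3), ("sex", 2, 0.2)],
    seed=MASTER_SEED,
)

N_EXPR_ANIMALS = 45
N_GENES = 200
EXPR_AGES = (8, 12, 18, 24, 30)
N_EQTL_GENES = 6
N_GSA_GENES = 6

N_DISCOVERY = 500
N_FOLDS = 10
N_CLUSTERS = 60          # scaled from 100 to suit n ~ 1000 CV animals
N_STARTS = 50
N_PCS = 20

THRESHOLD = 2.5
PRUNE = (0.95, 500, 100)  # r2 ceiling and window scaled to the panel size

# The standard "array" is every 2nd simulated SNP; the full simulated panel
# plays the role of imputed sequence, so GWAS/eQTL/GSA can pre-select SNPs
# the array does not carry (as the original design does).
ARRAY_STRIDE = 2


def array_panel(genotypes):
    return genotypes.snp_ids[::ARRAY_STRIDE]
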