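"""Synthetic populations for genomic-prediction benchmarking.

Genotypes come from a haplotype model with first-order-Markov linkage
disequilibrium: each haplotype is a latent Gaussian AR(1) process along
the chromosome, thresholded per SNP at the quantile of its allele
frequency. Adjacent-SNP genotype correlation therefore decays
geometrically with the ``ld_decay`` parameter. Families are half-sib:
all offspring of a sire receive one gamete recombined from the sire's
two haplotypes and one gamete drawn fresh from the population, which is
the relatedness pattern of commercial slaughter populations (sib
relationships present, no sire-son pairs).

Traits are additive: a chosen set of QTL receives effects drawn from a
normal (polygenic / oligogenic) or a four-class scale mixture of normals,
rescaled so the realized genetic variance hits the heritability target
on a unit-phenotypic-variance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import ConfigError, GenotypeMatrix, _snp_meta
from .exprsel import ExpressionPanel

#: relative per-effect variances of the four mixture classes (null first)
MIXTURE_CLASS_VARIANCES = (0.0, 1e-4, 1e-3, 1e-2)

ARCHITECTURES = ("polygenic", "oligogenic", "mixture")


@dataclass
class SimConfig:
    """Stated world for one synthetic population.

    ``h2`` is narrow-sense heritability on the fixed-effect-adjusted
    scale: var(breeding values) / (var(breeding values) + var(residual)).
    ``n_families <= 1`` means an unrelated base population (no shared
    sire gametes).
    """

    n_individuals: int = 1000
    n_snps: int = 5000
    n_chromosomes: int = 5
    n_families: int = 50
    ld_decay: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    architecture: str = "polygenic"
    n_qtl: int = 500
    qtl_variance_profile: tuple = (0.0, 0.1, 0.3, 0.6)
    h2: float = 0.25
    fixed_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ConfigError("h2 must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl exceeds n_snps")
        if not (0 <= self.ld_decay < 1):
            raise ConfigError("ld_decay must lie in [0, 1)")
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"architecture must be one of {ARCHITECTURES}")
        prof = np.asarray(self.qtl_variance_profile, dtype=float)
        if (prof < 0).any() or not np.isclose(prof.sum(), 1.0):
            raise ConfigError("qtl_variance_profile must be nonnegative and sum to 1")
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_chromosomes < 1:
            raise ConfigError("n_individuals, n_snps, n_chromosomes must be positive")


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    true_qtl: list  # (snp_index, effect) pairs on the allele-count scale
    true_breeding_values: np.ndarray
    phenotypes: np.ndarray
    covariates: pd.DataFrame
    family_ids: np.ndarray

    def phenotype_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.genotypes.sample_ids, "trait": self.phenotypes})
        for col in self.covariates.columns:
            out[col] = self.covariates[col].to_numpy()
        return out


def _chromosome_sizes(n_snps: int, n_chromosomes: int) -> np.ndarray:
    base = n_snps // n_chromosomes
    sizes = np.full(n_chromosomes, base, dtype=int)
    sizes[: n_snps - base * n_chromosomes] += 1
    return sizes


def _draw_haplotypes(rng, n_hap, thresholds, rho, sizes) -> np.ndarray:
    """n_hap haplotypes; AR(1) latent field per chromosome, thresholded."""
    m = thresholds.size
    z = np.empty((n_hap, m))
    start = 0
    innov_sd = np.sqrt(1.0 - rho * rho)
    for size in sizes:
        z[:, start] = rng.standard_normal(n_hap)
        for j in range(start + 1, start + size):
            z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n_hap)
        start += size
    return (z < thresholds).astype(np.int8)


def _recombine(rng, hap_a, hap_b, sizes, switch_prob=0.02) -> np.ndarray:
    """One gamete per row pair, switching source haplotype along the map."""
    n, m = hap_a.shape
    out = np.empty((n, m), dtype=np.int8)
    start = 0
    for size in sizes:
        state = rng.integers(0, 2, size=n)
        for j in range(start, start + size):
            flip = rng.random(n) < switch_prob
            state = np.where(flip, 1 - state, state)
            col = np.where(state == 0, hap_a[:, j], hap_b[:, j])
            out[:, j] = col
        start += size
    return out


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate the genotype matrix; returns (genotypes, family_ids)."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    sizes = _chromosome_sizes(m, config.n_chromosomes)

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = norm.ppf(freqs)
    rho = config.ld_decay

    if config.n_families <= 1:
        family_ids = np.array([f"F{i:05d}" for i in range(n)], dtype=object)
        hap1 = _draw_haplotypes(rng, n, thresholds, rho, sizes)
        hap2 = _draw_haplotypes(rng, n, thresholds, rho, sizes)
    else:
        fam_index = np.arange(n) % config.n_families
        family_ids = np.array([f"F{i:05d}" for i in fam_index], dtype=object)
        sire_h1 = _draw_haplotypes(rng, config.n_families, thresholds, rho, sizes)
        sire_h2 = _draw_haplotypes(rng, config.n_families, thresholds, rho, sizes)
        hap1 = _recombine(rng, sire_h1[fam_index], sire_h2[fam_index], sizes)
        hap2 = _draw_haplotypes(rng, n, thresholds, rho, sizes)

    values = (hap1 + hap2).astype(np.int8)

    chrom = np.concatenate(
        [np.full(s, f"chr{c + 1}", dtype=object) for c, s in enumerate(sizes)]
    )
    bp = np.concatenate([1 + 1000 * np.arange(s, dtype=np.int64) for s in sizes])
    ids = np.array(
        [f"{c}_{p}" for c, p in zip(chrom, bp)], dtype=object
    )
    gm = GenotypeMatrix(
        values=values,
        snp_meta=_snp_meta(ids, chrom, bp, ["A"] * m, ["B"] * m, np.full(m, np.nan)),
        sample_ids=np.array([f"ID{i:06d}" for i in range(n)], dtype=object),
    ).with_recomputed_freq()
    return gm, family_ids


def _qtl_effects(rng, config: SimConfig) -> np.ndarray:
    """Unscaled per-QTL allele-substitution effects for the architecture."""
    k = config.n_qtl
    if config.architecture in ("polygenic", "oligogenic"):
        return rng.standard_normal(k)
    probs = np.asarray(config.qtl_variance_profile, dtype=float)
    classes = rng.choice(len(MIXTURE_CLASS_VARIANCES), size=k, p=probs)
    sds = np.sqrt(np.asarray(MIXTURE_CLASS_VARIANCES))[classes]
    return rng.standard_normal(k) * sds


def simulate_trait(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    family_ids: np.ndarray | None = None,
) -> SimOutput:
    """Attach a trait to a simulated genotype panel.

    Breeding values are exactly (2p-centered genotypes) x effect vector;
    effects are rescaled so var(bv) = h2 and residual variance is 1 - h2,
    putting the adjusted phenotype on a unit-variance scale. Fixed-effect
    contributions are added on top and recorded in ``covariates``.
    """
    if config.n_qtl > genotypes.n_snps:
        raise ConfigError("n_qtl exceeds the panel's SNP count")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, m = genotypes.values.shape

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    alpha = _qtl_effects(rng, config)

    p = genotypes.allele_freq()
    z_qtl = genotypes.values[:, qtl_idx].astype(float) - 2.0 * p[qtl_idx]
    g_raw = z_qtl @ alpha
    var_raw = float(np.var(g_raw))
    if config.h2 == 0 or var_raw == 0 or not np.any(alpha):
        alpha = np.zeros_like(alpha)
        tbv = np.zeros(n)
    else:
        alpha = alpha * np.sqrt(config.h2 / var_raw)
        tbv = z_qtl @ alpha

    resid = rng.standard_normal(n) * np.sqrt(max(1.0 - config.h2, 0.0))

    covariates = pd.DataFrame(index=np.arange(n))
    fixed_part = np.zeros(n)
    for name, n_levels, effect_sd in config.fixed_effects:
        levels = rng.integers(0, n_levels, size=n)
        effects = rng.standard_normal(n_levels) * effect_sd
        covariates[name] = np.array([f"{name}{l}" for l in levels], dtype=object)
        fixed_part += effects[levels]

    phenotypes = fixed_part + tbv + resid
    if family_ids is None:
        family_ids = np.array([f"F{i:05d}" for i in range(n)], dtype=object)
    return SimOutput(
        genotypes=genotypes,
        true_qtl=list(zip(qtl_idx.tolist(), alpha.tolist())),
        true_breeding_values=tbv,
        phenotypes=phenotypes,
        covariates=covariates,
        family_ids=family_ids,
    )


def simulate_population(config: SimConfig) -> SimOutput:
    """Convenience wrapper: genotypes + trait from one config."""
    gm, fam = simulate_genotypes(config)
    return simulate_trait(gm, config, family_ids=fam)


def make_gene_map(
    genotypes: GenotypeMatrix, n_genes: int, seed: int = 0, gene_span_bp: int = 5000
) -> pd.DataFrame:
    """Random gene coordinates on the simulated chromosomes.

    Genes are intervals of ``gene_span_bp`` anchored at SNP positions so a
    typical gene body covers a handful of markers; strand is random.
    """
    rng = np.random.default_rng(seed)
    meta = genotypes.snp_meta
    rows = []
    anchors = rng.choice(len(meta), size=n_genes, replace=n_genes > len(meta))
    for g, a in enumerate(np.sort(anchors)):
        chrom = meta["chrom"].iloc[a]
        start = int(meta["bp"].iloc[a])
        rows.append(
            {
                "gene_id": f"gene{g:05d}",
                "chrom": chrom,
                "start": start,
                "end": start + gene_span_bp,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    return pd.DataFrame(rows)


def simulate_expression_panel(
    genotypes: GenotypeMatrix,
    n_samples: int,
    n_genes: int,
    gene_map: pd.DataFrame,
    config: SimConfig,
    ages_months: tuple = (8, 12, 18, 24, 30),
    n_eqtl_genes: int = 0,
    eqtl_effect_sd: float = 2.0,
    n_gsa_genes: int = 0,
    gsa_effect: float = 1.0,
    phenotypes: np.ndarray | None = None,
    n_sires: int = 5,
    noise_sd: float = 1.0,
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Simulate a small RNA-seq panel over repeated ages.

    ``n_samples`` animals (default design is 45: 23 high- / 22 low-energy
    diet) are drawn from the genotyped population and measured at each age.
    The first ``n_eqtl_genes`` genes get expression driven additively by a
    cis SNP inside their harvested interval with effect ``eqtl_effect_sd``
    (in units of the expression noise sd); the next ``n_gsa_genes`` genes
    track the animal's phenotype with slope ``gsa_effect``. Counts are
    exponentiated log-scale signals, so they are nonnegative.

    Returns (panel, truth table of planted signals).
    """
    if n_samples > genotypes.n_individuals:
        raise ConfigError("n_samples exceeds the number of genotyped individuals")
    if len(gene_map) < n_genes:
        raise ConfigError("gene_map has fewer genes than n_genes")
    chroms = set(genotypes.snp_meta["chrom"])
    bad = gene_map.loc[~gene_map["chrom"].isin(chroms), "gene_id"]
    if len(bad):
        raise ConfigError(f"gene_map chromosomes outside panel: {list(bad)[:3]}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    animal_idx = np.sort(rng.choice(genotypes.n_individuals, n_samples, replace=False))
    animal_ids = genotypes.sample_ids[animal_idx]
    diet_levels = np.array(["high"] * ((n_samples + 1) // 2) + ["low"] * (n_samples // 2))
    diet = diet_levels[rng.permutation(n_samples)]
    sire = np.array([f"sire{s}" for s in rng.integers(0, n_sires, n_samples)], dtype=object)

    meta = genotypes.snp_meta
    truth_rows = []
    gene_signals = np.zeros((n_genes, n_samples))
    pheno_animal = None
    if phenotypes is not None:
        pheno_animal = np.asarray(phenotypes)[animal_idx]

    for gi in range(n_eqtl_genes):
        row = gene_map.iloc[gi]
        lo, hi = (row.start - 300, row.end) if row.strand == "+" else (row.start, row.end + 300)
        in_gene = np.where(
            (meta["chrom"] == row.chrom) & (meta["bp"] >= lo) & (meta["bp"] <= hi)
        )[0]
        if in_gene.size == 0:
            continue
        snp = int(rng.choice(in_gene))
        dose = genotypes.values[animal_idx, snp].astype(float)
        if np.std(dose) == 0:
            continue
        gene_signals[gi] += eqtl_effect_sd * noise_sd * (dose - dose.mean())
        truth_rows.append(
            {"gene_id": row.gene_id, "kind": "eqtl", "snp_id": meta["id"].iloc[snp]}
        )

    if n_gsa_genes and pheno_animal is not None:
        ph_std = (pheno_animal - pheno_animal.mean()) / (pheno_animal.std() or 1.0)
        for gi in range(n_eqtl_genes, n_eqtl_genes + n_gsa_genes):
            gene_signals[gi] += gsa_effect * noise_sd * ph_std
            truth_rows.append(
                {"gene_id": gene_map["gene_id"].iloc[gi], "kind": "gsa", "snp_id": ""}
            )

    diet_shift = np.where(diet == "high", 0.3, 0.0)
    sire_effects = {s: e for s, e in zip(np.unique(sire), rng.standard_normal(n_sires) * 0.2)}
    sire_shift = np.array([sire_effects[s] for s in sire])

    frames, cov_rows = [], []
    base_level = rng.normal(3.0, 0.5, size=n_genes)
    for age in ages_months:
        log_expr = (
            base_level[:, None]
            + gene_signals
            + diet_shift[None, :]
            + sire_shift[None, :]
            + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
        )
        counts = np.exp(log_expr)
        sample_names = [f"{a}_m{age}" for a in animal_ids]
        frames.append(
            pd.DataFrame(counts, index=gene_map["gene_id"].iloc[:n_genes], columns=sample_names)
        )
        cov_rows.append(
            pd.DataFrame(
                {
                    "sample": sample_names,
                    "animal_id": animal_ids,
                    "diet": diet,
                    "sire": sire,
                    "age_months": age,
                }
            )
        )
    counts_df = pd.concat(frames, axis=1)
    covariates = pd.concat(cov_rows, ignore_index=True)
    panel = ExpressionPanel(
        counts=counts_df,
        covariates=covariates,
        gene_map=gene_map.iloc[:n_genes].reset_index(drop=True),
    )
    return panel, pd.DataFrame(truth_rows, columns=["gene_id", "kind", "snp_id"])
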