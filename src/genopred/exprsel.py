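"""Expression-based SNP prioritization: trait-associated genes and eQTL.

Two routes feed SNPs into prediction models from a small RNA-seq panel:

* gene-trait association (GSA): per gene, regression of expression on the
  adjusted phenotype with diet and sire fitted as fixed effects; SNPs are
  then harvested from each significant gene's promoter (300 bp upstream
  of the transcription start site, strand-aware) through the gene end.
* eQTL: per (SNP, gene) pair and age, regression of expression on allele
  count with the same covariates; hits across ages are combined and
  LD-pruned.

Both use the fixed nominal threshold p < 0.0032 (i.e. -log10 p = 2.5);
no multiplicity correction is applied, matching the pre-selection role:
the cost of a false positive here is only a slightly larger SNP panel.
Expression enters on a log(count+1) scale by default (variance
stabilization); ``log_transform=False`` gives the raw-count regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genio import GenotypeMatrix, mean_impute

logger = logging.getLogger(__name__)

GSA_P_THRESHOLD = 0.0032
EQTL_P_THRESHOLD = 0.0032
PROMOTER_BP = 300


@dataclass
class ExpressionPanel:
    counts: pd.DataFrame  # genes x samples
    covariates: pd.DataFrame  # sample, animal_id, diet, sire, age_months
    gene_map: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("expression counts must be nonnegative")
        needed = {"sample", "animal_id", "diet", "sire", "age_months"}
        missing = needed - set(self.covariates.columns)
        if missing:
            raise ValueError(f"covariate columns missing: {sorted(missing)}")
        if list(self.counts.columns) != list(self.covariates["sample"]):
            raise ValueError("counts columns and covariate rows must align")
        if self.covariates[["diet", "sire"]].isna().any().any():
            raise ValueError("every sample needs diet and sire")

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.covariates["age_months"].unique())

    def samples_at_age(self, age) -> np.ndarray:
        return np.where((self.covariates["age_months"] == age).to_numpy())[0]


@dataclass
class EqtlHit:
    snp_id: str
    gene_id: str
    age_months: int
    beta: float
    p: float
    cis_flag: bool


def _covariate_design(cov: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Full-dummy design (intercept + diet + sire) and its nominal rank.

    The full-dummy coding is structurally rank-deficient (one redundant
    baseline per factor); that is handled by QR and is not confounding.
    """
    parts = [np.ones((len(cov), 1))]
    nominal_rank = 1
    for col in ("diet", "sire"):
        dummies = pd.get_dummies(cov[col].astype(str), dtype=float)
        parts.append(dummies.to_numpy())
        nominal_rank += dummies.shape[1] - 1
    return np.hstack(parts), nominal_rank


def _residualizer(X: np.ndarray, nominal_rank: int | None = None):
    """(project-out function, effective rank) for covariate matrix X."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    rank = int(keep.sum())
    if nominal_rank is not None and rank < nominal_rank:
        logger.warning("confounded covariate design: rank %d < expected %d; "
                       "falling back to pseudoinverse fit", rank, nominal_rank)
    q = q[:, keep]

    def project_out(v):
        return v - q @ (q.T @ v)

    return project_out, rank


def _regression_pvals(E_resid: np.ndarray, x_resid: np.ndarray, df: int):
    """Slope and p of each row of E_resid on x_resid (both residualized)."""
    sxx = float(x_resid @ x_resid)
    if sxx <= 0 or df <= 0:
        k = E_resid.shape[0]
        return np.zeros(k), np.ones(k)
    beta = E_resid @ x_resid / sxx
    rss = np.einsum("ij,ij->i", E_resid, E_resid) - beta**2 * sxx
    rss = np.clip(rss, 0.0, None)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * t_dist.sf(np.abs(tval), df), np.finfo(float).tiny, 1.0)
    return beta, p


def _expression_matrix(panel: ExpressionPanel, sample_idx, log_transform: bool):
    e = panel.counts.to_numpy(dtype=float)[:, sample_idx]
    return np.log1p(e) if log_transform else e


def gsa_scan(
    panel: ExpressionPanel,
    y_adj_by_animal: dict,
    p_threshold: float = GSA_P_THRESHOLD,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Gene-trait association over the panel's animals.

    Repeated ages are collapsed to the per-animal mean (log-scale) before
    the regression, so each animal contributes one observation. Returns a
    per-gene table with ``beta``, ``p``, and the ``gsa`` flag at the
    nominal threshold.
    """
    cov = panel.covariates
    animals = cov["animal_id"].unique()
    missing = [a for a in animals if a not in y_adj_by_animal]
    if missing:
        raise KeyError(f"no adjusted phenotype for animals: {missing[:5]}")

    e_all = _expression_matrix(panel, np.arange(len(cov)), log_transform)
    # per-animal mean expression across ages
    groups = [np.where((cov["animal_id"] == a).to_numpy())[0] for a in animals]
    e_mean = np.column_stack([e_all[:, gidx].mean(axis=1) for gidx in groups])
    first_row = [g[0] for g in groups]
    cov_animal = cov.iloc[first_row]

    X, nominal = _covariate_design(cov_animal)
    project_out, rank = _residualizer(X, nominal)
    y = np.array([y_adj_by_animal[a] for a in animals], dtype=float)
    y_r = project_out(y)
    e_r = project_out(e_mean.T).T
    df = len(animals) - rank - 1
    beta, p = _regression_pvals(e_r, y_r, df)
    genes = panel.counts.index.to_numpy()
    return pd.DataFrame(
        {"gene_id": genes, "beta": beta, "p": p, "gsa": p < p_threshold}
    )


def gene_interval(row, promoter_bp: int = PROMOTER_BP) -> tuple[int, int]:
    """Strand-aware harvested interval: promoter start through gene end."""
    if row["strand"] == "-":
        return int(row["start"]), int(row["end"]) + promoter_bp
    return int(row["start"]) - promoter_bp, int(row["end"])


def harvest_gene_snps(
    gsa_genes,
    gene_map: pd.DataFrame,
    g: GenotypeMatrix,
    promoter_bp: int = PROMOTER_BP,
    prune: tuple | None = None,
):
    """SNPs inside the harvested interval of each gene, unioned and deduplicated.

    Genes absent from the map are reported, not fatal. If ``prune`` is
    given as (r2_max, window, step), the union is LD-pruned in genomic
    rank order. Returns (SnpSelection, skipped-genes list).
    """
    from .assoc import SnpSelection, prune_ld

    meta = g.snp_meta
    gm = gene_map.set_index("gene_id")
    hits: set = set()
    skipped = []
    for gene in gsa_genes:
        if gene not in gm.index:
            skipped.append(gene)
            continue
        row = gm.loc[gene]
        lo, hi = gene_interval(row, promoter_bp)
        mask = (meta["chrom"] == row["chrom"]) & (meta["bp"] >= lo) & (meta["bp"] <= hi)
        hits.update(meta.loc[mask, "id"])
    ordered = meta.loc[meta["id"].isin(hits), "id"].to_numpy()
    if skipped:
        logger.warning("harvest skipped %d genes absent from map", len(skipped))
    if prune is not None and len(ordered) > 1:
        sel = prune_ld(g, list(ordered), *prune)
        ids = sel.snp_ids
    else:
        ids = ordered
    return (
        SnpSelection(snp_ids=ids, source="gsa", pruning_params=prune),
        skipped,
    )


def eqtl_scan(
    panel: ExpressionPanel,
    g: GenotypeMatrix,
    age,
    p_threshold: float = EQTL_P_THRESHOLD,
    log_transform: bool = True,
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """All-pairs (SNP, gene) additive-linear scan at one age.

    Expression is regressed on allele count with diet and sire as fixed
    effects; pairs with p below the nominal threshold are returned with
    their cis/trans annotation (cis = SNP inside the gene's harvested
    interval). SNPs monomorphic in the subsample are skipped.
    """
    sample_idx = panel.samples_at_age(age)
    if sample_idx.size == 0:
        raise ValueError(f"no expression samples at age {age}")
    cov = panel.covariates.iloc[sample_idx]
    animal_ids = cov["animal_id"].to_numpy()
    pos = {s: i for i, s in enumerate(g.sample_ids)}
    try:
        geno_rows = np.array([pos[a] for a in animal_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"panel animal {exc.args[0]!r} not genotyped") from exc

    x = mean_impute(g)[geno_rows]
    sds = x.std(axis=0)
    usable = sds > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("eQTL scan at age %s skipped %d monomorphic SNPs", age, n_skipped)

    e = _expression_matrix(panel, sample_idx, log_transform)
    X, nominal = _covariate_design(cov)
    project_out, rank = _residualizer(X, nominal)
    df = len(sample_idx) - rank - 1
    e_r = project_out(e.T).T
    x_r = project_out(x[:, usable])

    # correlation-based all-pairs test (equivalent to per-pair OLS slope t)
    e_norm = e_r / np.maximum(np.linalg.norm(e_r, axis=1, keepdims=True), 1e-300)
    x_norm = x_r / np.maximum(np.linalg.norm(x_r, axis=0, keepdims=True), 1e-300)
    r = e_norm @ x_norm
    r = np.clip(r, -0.999999999, 0.999999999)
    tval = r * np.sqrt(df / (1.0 - r * r))
    p = np.clip(2.0 * t_dist.sf(np.abs(tval), df), np.finfo(float).tiny, 1.0)

    sxx = np.einsum("ij,ij->j", x_r, x_r)
    betas = (e_r @ x_r) / sxx

    gene_ids = panel.counts.index.to_numpy()
    snp_ids = g.snp_ids[usable]
    gi, si = np.where(p < p_threshold)

    gm = panel.gene_map.set_index("gene_id")
    meta = g.snp_meta.set_index("id")
    rows = []
    for a, b in zip(gi, si):
        gene = gene_ids[a]
        snp = snp_ids[b]
        cis = False
        if gene in gm.index:
            grow = gm.loc[gene]
            lo, hi = gene_interval(grow, promoter_bp)
            srow = meta.loc[snp]
            cis = bool(srow["chrom"] == grow["chrom"] and lo <= srow["bp"] <= hi)
        rows.append(
            {"snp_id": snp, "gene_id": gene, "age_months": age,
             "beta": float(betas[a, b]), "p": float(p[a, b]), "cis_flag": cis}
        )
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "age_months",
                                       "beta", "p", "cis_flag"])


def combine_eqtl_ages(hits_per_age, g: GenotypeMatrix, prune: tuple | None = None):
    """Union of eQTL SNPs across ages, ranked by best p, then LD-pruned.

    ``hits_per_age`` is an iterable of eqtl_scan tables. Returns a
    SnpSelection (source "eqtl").
    """
    from .assoc import DEFAULT_PRUNE_PARAMS, SnpSelection, prune_ld

    frames = [h for h in hits_per_age if len(h)]
    if not frames:
        return SnpSelection(snp_ids=np.array([], dtype=object), source="eqtl",
                            pruning_params=prune)
    allhits = pd.concat(frames, ignore_index=True)
    best = allhits.groupby("snp_id", sort=False)["p"].min()
    ranked = best.sort_values(kind="mergesort").index.to_numpy()
    params = prune if prune is not None else DEFAULT_PRUNE_PARAMS
    if len(ranked) > 1:
        sel = prune_ld(g, list(ranked), *params)
        ids = sel.snp_ids
    else:
        ids = ranked
    return SnpSelection(snp_ids=np.asarray(ids, dtype=object), source="eqtl",
                        threshold_neglog10p=-np.log10(EQTL_P_THRESHOLD),
                        pruning_params=params)
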