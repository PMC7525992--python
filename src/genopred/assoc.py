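"""Mixed-model single-SNP association, LD pruning, and top-SNP selection.

The scan fits, for each SNP i, y = 1*mu + x_i*alpha_i + a + e with
var(a) = G*sigma2_a and var(e) = I*sigma2_e, holding the variance
components at their null-model (no-SNP) estimates — the P3D/EMMAX
approximation. One eigendecomposition of G whitens the model, after
which every SNP is an ordinary two-column regression, so the whole scan
is a couple of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import norm

from .genio import GenotypeMatrix, PhenotypeTable, mean_impute
from .grm import GRM

#: operating significance threshold on the -log10(p) scale (p < 0.0032)
DEFAULT_THRESHOLD_NEGLOG10P = 2.5
#: pruning defaults: r2 ceiling, window length (SNPs), window shift (SNPs)
DEFAULT_PRUNE_PARAMS = (0.95, 5000, 100)


@dataclass
class GwasResult:
    """Per-SNP effects, tests, and genetic-variance shares from one scan."""

    table: pd.DataFrame  # snp_id, chrom, bp, freq, alpha, se, p, neglog10p, var_share_pct
    sigma2_a: float
    sigma2_e: float

    def ranked_ids(self) -> np.ndarray:
        """SNP ids ordered most-significant first (ties: genomic order)."""
        t = self.table.sort_values(["p", "chrom", "bp"], kind="mergesort")
        return t["snp_id"].to_numpy()


@dataclass
class SnpSelection:
    snp_ids: np.ndarray
    source: str = "gwas"
    threshold_neglog10p: float | None = None
    pruning_params: tuple | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("selection contains duplicate SNP ids")
        self.empty = len(self.snp_ids) == 0


class SaturatedModelError(ValueError):
    pass


def _design_from_factors(data: pd.DataFrame, model) -> np.ndarray:
    """Full-dummy design (intercept + one column per level per term).

    ``model`` is a list of factor names or tuples of names; a tuple is an
    interaction fitted as the combined factor. Rank deficiency is fine:
    the fit uses a pseudoinverse.
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    for term in model:
        if isinstance(term, (tuple, list)):
            combined = data[list(term)].astype(str).agg(":".join, axis=1)
            name = ":".join(term)
        else:
            combined = data[term].astype(str)
            name = term
        if combined.nunique() >= n:
            raise SaturatedModelError(
                f"factor {name!r} has as many levels as observations"
            )
        cols.append(pd.get_dummies(combined, dtype=float).to_numpy())
    return np.hstack(cols)


def adjust_phenotype(
    pheno: PhenotypeTable | pd.DataFrame, trait: str = "trait", model=()
) -> np.ndarray:
    """Residuals of the trait after OLS on categorical fixed effects.

    This is the two-stage pre-adjustment: downstream mixed models see
    only these residuals, never the raw trait. With an empty model the
    residuals are the centered trait.
    """
    data = pheno.data if isinstance(pheno, PhenotypeTable) else pheno
    y = data[trait].to_numpy(dtype=float)
    X = _design_from_factors(data, list(model))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid - resid.mean()  # exact zero mean despite pseudoinverse roundoff


def gwas_scan(
    g: GenotypeMatrix,
    y_adj: np.ndarray,
    G: GRM,
    sigma2_a: float,
    sigma2_e: float,
) -> GwasResult:
    """Mixed-model scan at fixed null-model variance components.

    Wald two-sided p-values from the normal approximation. The per-SNP
    variance share is 2 p (1-p) alpha^2 / sigma2_a * 100.
    """
    y = np.asarray(y_adj, dtype=float)
    n = y.size
    if G.n != n or g.n_individuals != n:
        raise ValueError("genotypes, phenotype, and GRM must share samples")
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")

    evals, evecs = scipy.linalg.eigh(G.matrix)
    d = sigma2_a * np.clip(evals, 0.0, None) + sigma2_e
    if np.min(d) <= 0 or np.max(d) / np.min(d) > 1e12:
        raise np.linalg.LinAlgError(
            f"V singular or ill-conditioned (condition {np.max(d)/np.min(d):.2e})"
        )
    w = 1.0 / np.sqrt(d)

    x = mean_impute(g)
    yt = w * (evecs.T @ y)
    onet = w * evecs.sum(axis=0)  # U' 1, whitened
    xt = w[:, None] * (evecs.T @ x)

    a = onet @ onet
    b = onet @ xt
    c = np.einsum("ij,ij->j", xt, xt)
    u = onet @ yt
    v = yt @ xt
    det = a * c - b * b
    ok = det > 1e-12 * max(a, 1.0)
    alpha = np.where(ok, (a * v - b * u) / np.where(ok, det, 1.0), 0.0)
    se = np.where(ok, np.sqrt(a / np.where(ok, det, 1.0)), np.inf)
    z = np.where(se > 0, alpha / se, 0.0)
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    freq = g.allele_freq()
    share = np.where(
        ok, variance_share(freq, alpha, sigma2_a) if sigma2_a > 0 else 0.0, 0.0
    )
    table = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.snp_meta["chrom"].to_numpy(),
            "bp": g.snp_meta["bp"].to_numpy(),
            "freq": freq,
            "alpha": alpha,
            "se": se,
            "p": p,
            "neglog10p": -np.log10(p),
        }
    )
    table["var_share_pct"] = share
    return GwasResult(table=table, sigma2_a=sigma2_a, sigma2_e=sigma2_e)


def variance_share(p, alpha, sigma2_a) -> np.ndarray:
    """Percent of additive genetic variance from a SNP: 2p(1-p)a^2/s2a*100."""
    if np.ndim(sigma2_a) == 0 and sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return 2.0 * p * (1.0 - p) * alpha**2 / sigma2_a * 100.0


def _r2_with(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Squared genotype correlation of each column of x with ref."""
    xc = x - x.mean(axis=0)
    rc = ref - ref.mean()
    denom = np.einsum("ij,ij->j", xc, xc) * (rc @ rc)
    num = (rc @ xc) ** 2
    out = np.zeros(x.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def prune_ld(
    g: GenotypeMatrix,
    ranked_snps,
    r2_max: float = DEFAULT_PRUNE_PARAMS[0],
    window: int = DEFAULT_PRUNE_PARAMS[1],
    step: int = DEFAULT_PRUNE_PARAMS[2],
) -> SnpSelection:
    """Windowed LD pruning of a significance-ranked SNP list.

    Within each window (``window`` SNPs long, advanced by ``step``, in
    genomic index order within chromosome), every SNP whose squared
    genotype correlation with the window's most significant retained SNP
    is >= ``r2_max`` is removed; the most significant SNP is always kept.
    Ties in rank break toward the smaller genomic coordinate. Output
    preserves genomic order. Cross-chromosome r2 is never computed.
    """
    ranked = list(ranked_snps)
    if not ranked:
        raise ValueError("ranked_snps is empty")
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")

    rank = {sid: k for k, sid in enumerate(ranked)}
    meta = g.snp_meta
    in_sel = meta["id"].isin(rank).to_numpy()
    sel_idx = np.where(in_sel)[0]  # genomic order by construction
    x = mean_impute(g)

    removed: set = set()
    for chrom in meta["chrom"].iloc[sel_idx].unique():
        chrom_idx = sel_idx[(meta["chrom"].iloc[sel_idx] == chrom).to_numpy()]
        m = len(chrom_idx)
        for start in range(0, m, step):
            win = [j for j in chrom_idx[start : start + window] if j not in removed]
            if len(win) < 2:
                if start + window >= m:
                    break
                continue
            best = min(win, key=lambda j: (rank[meta["id"].iloc[j]], meta["bp"].iloc[j]))
            others = [j for j in win if j != best]
            r2 = _r2_with(x[:, others], x[:, best])
            for j, r in zip(others, r2):
                if r >= r2_max:
                    removed.add(j)
            if start + window >= m:
                break

    kept = [meta["id"].iloc[j] for j in sel_idx if j not in removed]
    return SnpSelection(
        snp_ids=np.array(kept, dtype=object),
        source="pruned",
        pruning_params=(r2_max, window, step),
    )


def select_top_snps(
    res: GwasResult,
    g: GenotypeMatrix,
    threshold_neglog10p: float = DEFAULT_THRESHOLD_NEGLOG10P,
    prune: tuple | None = DEFAULT_PRUNE_PARAMS,
) -> SnpSelection:
    """Significance-threshold selection followed by LD pruning.

    SNPs with -log10(p) >= threshold survive; an empty survivor set is a
    valid (flagged) selection.
    """
    if threshold_neglog10p <= 0:
        raise ValueError("threshold must be positive")
    t = res.table
    hits = t.loc[t["neglog10p"] >= threshold_neglog10p]
    if hits.empty:
        return SnpSelection(
            snp_ids=np.array([], dtype=object),
            source="gwas",
            threshold_neglog10p=threshold_neglog10p,
            pruning_params=prune,
        )
    ranked = hits.sort_values(["p", "chrom", "bp"], kind="mergesort")["snp_id"].to_numpy()
    if prune is not None and len(ranked) > 1:
        sel = prune_ld(g, ranked, *prune)
        ids = sel.snp_ids
    else:
        order = t.loc[t["snp_id"].isin(set(ranked))]["snp_id"].to_numpy()
        ids = order
    return SnpSelection(
        snp_ids=ids,
        source="gwas",
        threshold_neglog10p=threshold_neglog10p,
        pruning_params=prune,
    )
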