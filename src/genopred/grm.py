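"""Genomic relationship matrices (VanRaden method 1) and variants.

G = Z_c diag(w) Z_c' / sum_j 2 p_j (1-p_j) w_j, with Z_c the genotype
matrix centered at twice the observed allele frequency, w per-SNP weights
(all ones in the unweighted case). Also provides the top-SNP-removed
base-panel matrix used alongside a top-SNP matrix in two-component
models, and PCA of a GRM for population-structure work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .genio import GenotypeMatrix, mean_impute

logger = logging.getLogger(__name__)

#: diagonal ridge guaranteeing positive semidefiniteness after imputation
GRM_RIDGE = 1e-6


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: np.ndarray
    snp_ids_used: np.ndarray
    weights: np.ndarray | None = None
    scale: float = np.nan
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if self.matrix.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"GRM asymmetric by {asym:.2e}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def ridged(self, ridge: float = GRM_RIDGE) -> np.ndarray:
        return self.matrix + ridge * np.eye(self.n)


def build_grm(
    g: GenotypeMatrix,
    snp_subset=None,
    weights=None,
) -> GRM:
    """Build a (possibly weighted) genomic relationship matrix.

    Monomorphic SNPs contribute zero variance and are excluded with a
    warning. ``weights`` must align with the SNP set actually used (after
    subsetting), and must be positive.
    """
    panel = g if snp_subset is None else g.subset_snps(snp_subset)
    if panel.n_snps == 0:
        raise ValueError("empty SNP panel for GRM")
    x = mean_impute(panel)
    p = panel.allele_freq()

    if weights is None:
        w = np.ones(panel.n_snps)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (panel.n_snps,):
            raise ValueError(f"weights length {w.size} != panel size {panel.n_snps}")
        if (w <= 0).any():
            raise ValueError("weights must be positive")

    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("excluding %d monomorphic SNPs from GRM", int((~poly).sum()))
        x, p, w = x[:, poly], p[poly], w[poly]
    if p.size == 0:
        raise ValueError("no polymorphic SNPs left for GRM")

    zc = x - 2.0 * p
    scale = float(np.sum(2.0 * p * (1.0 - p) * w))
    mat = (zc * w) @ zc.T / scale
    mat = 0.5 * (mat + mat.T)
    return GRM(
        matrix=mat,
        sample_ids=panel.sample_ids,
        snp_ids_used=panel.snp_ids[poly] if not poly.all() else panel.snp_ids,
        weights=w if weights is not None else None,
        scale=scale,
        provenance={
            "method": "vanraden1",
            "n_snps": int(p.size),
            "weighted": weights is not None,
            "freq_source": "observed",
        },
    )


def adjust_grm_remove(
    g: GenotypeMatrix, base_panel, top_snps
) -> tuple[GRM, GRM, int]:
    """Base-panel GRM with overlapping top SNPs removed, plus the top-SNP GRM.

    Returns (G_base_adjusted, G_top, overlap_count). This is the
    two-matrix construction for the second GBLUP model: the first random
    effect uses the array panel minus any SNP also in the pre-selected
    set, the second uses the pre-selected SNPs themselves.
    """
    base = list(dict.fromkeys(base_panel))
    top = list(dict.fromkeys(top_snps))
    if not base or not top:
        raise ValueError("base_panel and top_snps must be nonempty")
    top_set = set(top)
    kept = [s for s in base if s not in top_set]
    overlap = len(base) - len(kept)
    if not kept:
        raise ValueError("top_snps cover the whole base panel: empty adjusted GRM")
    g_adj = build_grm(g, snp_subset=kept)
    g_adj.provenance["adjustment"] = {"removed_overlap": overlap}
    g_top = build_grm(g, snp_subset=top)
    return g_adj, g_top, overlap


def grm_pca(G: GRM, n_components: int) -> np.ndarray:
    """Principal-component scores of a GRM (n x n_components).

    Scores are eigenvectors scaled by sqrt(eigenvalue), ordered by
    descending eigenvalue, with the deterministic sign convention that
    each component's largest-magnitude loading is positive.
    """
    if n_components > G.n:
        raise ValueError("n_components exceeds matrix order")
    evals, evecs = scipy.linalg.eigh(G.matrix)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] < -1e-6 * max(1.0, evals[0]):
        raise np.linalg.LinAlgError(
            f"GRM not PSD beyond ridge tolerance (min eigenvalue {evals[-1]:.3e})"
        )
    evals = np.clip(evals, 0.0, None)
    k = n_components
    vec = evecs[:, :k]
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    vec = vec * flip
    return vec * np.sqrt(evals[:k])
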