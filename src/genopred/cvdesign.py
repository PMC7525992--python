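"""Discovery-set selection and cross-validation fold design under relatedness.

The GWAS discovery set must be genetically diverse and disjoint from the
animals used to train and validate prediction. It is chosen as the best
of ``n_candidates`` random subsets under the average co-ancestry
criterion sum x'Gx/2 (x the 0/1 indicator of the subset) — smaller is
more diverse. The remaining animals are split into 10 folds either at
random or by k-means on principal components of the GRM; k-means folds
keep relatives together, so validation animals have fewer close
relatives in training, which lowers apparent accuracy but makes it a
fairer estimate for unrelated selection candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grm import GRM, grm_pca

logger = logging.getLogger(__name__)

N_FOLDS_DEFAULT = 10
N_CLUSTERS_DEFAULT = 100
N_STARTS_DEFAULT = 50
N_CANDIDATES_DEFAULT = 100
N_PCS_DEFAULT = 20


@dataclass
class FoldDesign:
    discovery_ids: np.ndarray
    fold_assignment: dict  # id -> fold number in 1..n_folds
    strategy: str
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.discovery_ids) & set(self.fold_assignment)
        if overlap:
            raise ValueError(f"discovery and CV sets overlap: {sorted(overlap)[:5]}")

    @property
    def n_folds(self) -> int:
        return max(self.fold_assignment.values()) if self.fold_assignment else 0

    def fold_ids(self, fold: int) -> np.ndarray:
        return np.array(
            [i for i, f in self.fold_assignment.items() if f == fold], dtype=object
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "role": "discovery"} for i in self.discovery_ids]
        rows += [{"id": i, "role": f"fold_{f}"} for i, f in self.fold_assignment.items()]
        return pd.DataFrame(rows)


def coancestry_criterion(G: GRM, ids) -> float:
    """Average co-ancestry x'Gx/2 of an id subset."""
    idx = _indices_of(G, ids)
    x = np.zeros(G.n)
    x[idx] = 1.0
    return float(x @ G.matrix @ x) / 2.0


def _indices_of(G: GRM, ids) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(G.sample_ids)}
    try:
        return np.array([lookup[s] for s in ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"sample id {exc.args[0]!r} not in GRM") from exc


def select_discovery(
    G: GRM,
    n_discovery: int,
    n_candidates: int = N_CANDIDATES_DEFAULT,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Most diverse of ``n_candidates`` random subsets of size ``n_discovery``.

    Returns (chosen ids, criterion value per candidate examined). Ties
    break toward the earlier-drawn candidate, so the result is
    deterministic under the seed.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if not 0 < n_discovery < G.n:
        raise ValueError("n_discovery must be in (0, n)")
    rng = np.random.default_rng(seed)
    best_ids, best_score = None, np.inf
    scores = np.empty(n_candidates)
    for c in range(n_candidates):
        idx = rng.choice(G.n, size=n_discovery, replace=False)
        x = np.zeros(G.n)
        x[idx] = 1.0
        score = float(x @ G.matrix @ x) / 2.0
        scores[c] = score
        if score < best_score:
            best_score, best_ids = score, G.sample_ids[np.sort(idx)]
    return best_ids, scores


def random_folds(ids, n_folds: int = N_FOLDS_DEFAULT, seed: int = 0) -> FoldDesign:
    """Uniform random split into near-equal folds (sizes differ by <= 1)."""
    ids = np.asarray(ids, dtype=object)
    if len(ids) < n_folds:
        raise ValueError("fewer ids than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[j]: (k % n_folds) + 1 for k, j in enumerate(perm)}
    return FoldDesign(
        discovery_ids=np.array([], dtype=object),
        fold_assignment=assignment,
        strategy="random",
        seed=seed,
    )


def kmeans_folds(
    G: GRM,
    ids=None,
    n_clusters: int = N_CLUSTERS_DEFAULT,
    n_starts: int = N_STARTS_DEFAULT,
    n_folds: int = N_FOLDS_DEFAULT,
    n_pcs: int = N_PCS_DEFAULT,
    seed: int = 0,
) -> FoldDesign:
    """k-means folds: cluster GRM principal components, pack clusters whole.

    k-means (best of ``n_starts`` random initializations by within-cluster
    sum of squares) runs on the top ``n_pcs`` principal-component scores of
    the GRM restricted to ``ids``. Clusters are then packed greedily —
    largest first into the currently smallest fold — so no cluster is ever
    split across folds.
    """
    ids = G.sample_ids if ids is None else np.asarray(ids, dtype=object)
    idx = _indices_of(G, ids)
    if not (n_folds <= n_clusters <= len(ids)):
        raise ValueError("need n_folds <= n_clusters <= n ids")
    sub = GRM(matrix=G.matrix[np.ix_(idx, idx)], sample_ids=ids,
              snp_ids_used=G.snp_ids_used)
    scores = grm_pca(sub, min(n_pcs, len(ids)))
    km = KMeans(n_clusters=n_clusters, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(scores)

    clusters = [np.where(labels == c)[0] for c in range(n_clusters)]
    clusters = [c for c in clusters if c.size > 0]
    clusters.sort(key=lambda c: (-c.size, int(c[0])))
    fold_sizes = np.zeros(n_folds, dtype=int)
    assignment = {}
    for members in clusters:
        fold = int(np.argmin(fold_sizes))
        fold_sizes[fold] += members.size
        for j in members:
            assignment[ids[j]] = fold + 1
    design = FoldDesign(
        discovery_ids=np.array([], dtype=object),
        fold_assignment=assignment,
        strategy="kmeans",
        seed=seed,
        diagnostics={"fold_sizes": fold_sizes.tolist(),
                     "inertia": float(km.inertia_)},
    )
    design.diagnostics["mean_cross_relationship"] = mean_fold_cross_relationship(G, design)
    return design


def mean_fold_cross_relationship(G: GRM, design: FoldDesign) -> float:
    """Mean GRM entry between each fold and its complement, averaged."""
    lookup = {s: i for i, s in enumerate(G.sample_ids)}
    cv_ids = list(design.fold_assignment)
    cv_idx = np.array([lookup[i] for i in cv_ids], dtype=int)
    folds = np.array([design.fold_assignment[i] for i in cv_ids], dtype=int)
    vals = []
    for f in np.unique(folds):
        a = cv_idx[folds == f]
        b = cv_idx[folds != f]
        vals.append(float(np.mean(G.matrix[np.ix_(a, b)])))
    return float(np.mean(vals))
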