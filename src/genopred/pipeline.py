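"""End-to-end prediction strategies and design sweeps.

Eight strategies compare SNP pre-selection sources and models:

====================  =======================  ==========================
name                  SNP sources              model
====================  =======================  ==========================
GBLUP-50k             base array               one-GRM GBLUP
GBLUP-GWAS            base + GWAS top SNPs     two-GRM GBLUP (G50adj, G2)
GBLUP-eQTL            base + eQTL SNPs         two-GRM GBLUP (G50adj, G2)
GBLUP-GSA             base + GSA-gene SNPs     two-GRM GBLUP (G50adj, G2)
wGBLUP-50k            base array               iterative weighted GBLUP
wGBLUP-GWAS           base UNION top SNPs      iterative weighted GBLUP
BayesR-50k            base array               BayesR mixture
BayesR-GWAS           base UNION top SNPs      BayesR mixture
====================  =======================  ==========================

In two-GRM strategies the pre-selected SNPs form their own relationship
matrix G2 and are removed from the base-array matrix (G50adj), so no SNP
is counted twice. Every run starts with a leakage audit: the GWAS
discovery animals must be disjoint from the cross-validation animals,
and validation phenotypes never enter training.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evalmetrics
from .assoc import (DEFAULT_PRUNE_PARAMS, DEFAULT_THRESHOLD_NEGLOG10P,
                    GwasResult, SnpSelection, select_top_snps)
from .bayesr import BayesRConfig, bayesr_fit, bayesr_predict
from .cvdesign import FoldDesign, random_folds
from .genio import GenotypeMatrix
from .grm import adjust_grm_remove, build_grm, GRM
from .varcomp import gblup_predict, reml_fit
from .wgblup import run_wgblup

logger = logging.getLogger(__name__)

THRESHOLD_SWEEP_DEFAULT = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0)

STRATEGIES = {
    "GBLUP-50k": ("base", "eq2"),
    "GBLUP-GWAS": ("gwas", "eq3"),
    "GBLUP-eQTL": ("eqtl", "eq3"),
    "GBLUP-GSA": ("gsa", "eq3"),
    "wGBLUP-50k": ("base", "wgblup"),
    "wGBLUP-GWAS": ("gwas", "wgblup"),
    "BayesR-50k": ("base", "bayesr"),
    "BayesR-GWAS": ("gwas", "bayesr"),
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class StrategySpec:
    name: str
    snp_source: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; "
                             f"choose from {sorted(STRATEGIES)}")
        src, model = STRATEGIES[self.name]
        if self.snp_source and self.snp_source != src:
            raise ValueError(f"{self.name} implies snp_source={src!r}")
        if self.model and self.model != model:
            raise ValueError(f"{self.name} implies model={model!r}")
        self.snp_source, self.model = src, model


@dataclass
class DataBundle:
    """Everything a strategy needs: genotypes, adjusted trait, panels."""

    genotypes: GenotypeMatrix
    y_adj: np.ndarray
    base_panel: np.ndarray  # SNP ids of the standard array
    selections: dict = field(default_factory=dict)  # source -> SnpSelection

    def __post_init__(self) -> None:
        self.y_adj = np.asarray(self.y_adj, dtype=float)
        if self.y_adj.size != self.genotypes.n_individuals:
            raise ValueError("y_adj does not match genotype rows")
        self.base_panel = np.asarray(self.base_panel, dtype=object)


def _leakage_audit(bundle: DataBundle, design: FoldDesign) -> None:
    overlap = set(design.discovery_ids) & set(design.fold_assignment)
    if overlap:
        raise RuntimeError(
            f"leakage: {len(overlap)} discovery animals inside CV folds"
        )


def _cv_view(bundle: DataBundle, design: FoldDesign):
    pos = {s: i for i, s in enumerate(bundle.genotypes.sample_ids)}
    cv_ids = list(design.fold_assignment)
    idx = np.array([pos[i] for i in cv_ids], dtype=int)
    folds = np.array([design.fold_assignment[i] for i in cv_ids], dtype=int)
    return bundle.genotypes.subset_samples(idx), bundle.y_adj[idx], folds


def _union_panel(bundle: DataBundle, selection: SnpSelection) -> np.ndarray:
    extra = [s for s in selection.snp_ids if s not in set(bundle.base_panel)]
    return np.concatenate([bundle.base_panel, np.array(extra, dtype=object)])


def _eval_gblup(g_cv, y_cv, folds, grms, strategy) -> evalmetrics.EvalResult:
    rows, h2s = [], []
    for f in np.unique(folds):
        ref = folds != f
        sub = [GRM(matrix=G.matrix[np.ix_(ref, ref)],
                   sample_ids=g_cv.sample_ids[ref], snp_ids_used=G.snp_ids_used)
               for G in grms]
        vc = reml_fit(y_cv[ref], sub)
        gbv = gblup_predict(y_cv, grms, vc, ref, sample_ids=g_cv.sample_ids)
        val = ~ref
        h2 = max(vc.h2, 1e-6)
        rows.append((int(f), int(val.sum()),
                     evalmetrics.fold_accuracy(y_cv[val], gbv.gbv[val], h2),
                     evalmetrics.prediction_bias(y_cv[val], gbv.gbv[val])))
        h2s.append(vc.h2)
    return evalmetrics.summarize_folds(rows, h2_used=float(np.mean(h2s)),
                                       strategy=strategy)


def _eval_bayesr(g_cv, y_cv, folds, panel_ids, strategy,
                 config: BayesRConfig) -> evalmetrics.EvalResult:
    rows, h2s = [], []
    panel = g_cv.subset_snps(panel_ids)
    for f in np.unique(folds):
        ref = folds != f
        post = bayesr_fit(panel.subset_samples(np.where(ref)[0]), y_cv[ref],
                          config=config)
        gbv = bayesr_predict(panel, post)
        val = ~ref
        h2 = post.sigma2_g_mean / (post.sigma2_g_mean + post.sigma2_e_mean)
        h2 = min(max(h2, 1e-6), 1.0)
        rows.append((int(f), int(val.sum()),
                     evalmetrics.fold_accuracy(y_cv[val], gbv[val], h2),
                     evalmetrics.prediction_bias(y_cv[val], gbv[val])))
        h2s.append(h2)
    return evalmetrics.summarize_folds(rows, h2_used=float(np.mean(h2s)),
                                       strategy=strategy)


def run_strategy(
    spec,
    bundle: DataBundle,
    design: FoldDesign,
    bayesr_config: BayesRConfig | None = None,
    wgblup_iterations: int = 5,
    wgblup_report_iteration: int = 2,
) -> evalmetrics.EvalResult:
    """Cross-validated evaluation of one prediction strategy.

    For weighted GBLUP the headline numbers come from
    ``wgblup_report_iteration`` (default 2, the first weighted round);
    the full per-iteration trajectory is available through
    :func:`genopred.wgblup.run_wgblup` directly.
    """
    if isinstance(spec, str):
        spec = StrategySpec(name=spec)
    _leakage_audit(bundle, design)
    g_cv, y_cv, folds = _cv_view(bundle, design)

    if spec.model in ("eq2", "eq3"):
        if spec.model == "eq2":
            grms = [build_grm(g_cv, snp_subset=bundle.base_panel)]
        else:
            sel = bundle.selections.get(spec.snp_source)
            if sel is None:
                raise KeyError(f"strategy {spec.name} needs a {spec.snp_source!r} selection")
            if sel.empty:
                logger.warning("%s: empty selection, degenerating to GBLUP-50k",
                               spec.name)
                grms = [build_grm(g_cv, snp_subset=bundle.base_panel)]
            else:
                panel_ids = [s for s in sel.snp_ids
                             if s in set(g_cv.snp_meta["id"])]
                g_adj, g_top, overlap = adjust_grm_remove(
                    g_cv, list(bundle.base_panel), list(panel_ids))
                logger.info("%s: %d top SNPs, overlap with base %d",
                            spec.name, len(panel_ids), overlap)
                grms = [g_adj, g_top]
        return _eval_gblup(g_cv, y_cv, folds, grms, spec.name)

    if spec.model == "wgblup":
        if spec.snp_source == "base":
            panel_ids = bundle.base_panel
        else:
            sel = bundle.selections.get(spec.snp_source)
            if sel is None:
                raise KeyError(f"strategy {spec.name} needs a {spec.snp_source!r} selection")
            panel_ids = _union_panel(bundle, sel)
        design_cv = FoldDesign(discovery_ids=np.array([], dtype=object),
                               fold_assignment=design.fold_assignment,
                               strategy=design.strategy, seed=design.seed)
        out = run_wgblup(bundle.genotypes, bundle.y_adj, design_cv,
                         n_iterations=wgblup_iterations, snp_panel=panel_ids)
        t = min(wgblup_report_iteration, wgblup_iterations)
        res = out["per_iteration"][t - 1]
        res.strategy = spec.name
        return res

    if spec.model == "bayesr":
        if spec.snp_source == "base":
            panel_ids = bundle.base_panel
        else:
            sel = bundle.selections.get(spec.snp_source)
            if sel is None:
                raise KeyError(f"strategy {spec.name} needs a {spec.snp_source!r} selection")
            panel_ids = _union_panel(bundle, sel)
        return _eval_bayesr(g_cv, y_cv, folds, panel_ids, spec.name,
                            bayesr_config or BayesRConfig())

    raise AssertionError(f"unhandled model {spec.model}")  # pragma: no cover


def threshold_sweep(
    gwas_result: GwasResult,
    bundle: DataBundle,
    design: FoldDesign,
    thresholds=THRESHOLD_SWEEP_DEFAULT,
    prune: tuple = DEFAULT_PRUNE_PARAMS,
) -> pd.DataFrame:
    """GBLUP-GWAS accuracy at each -log10(p) selection threshold.

    Selections are nested before pruning, so the number of selected SNPs
    is nonincreasing in the threshold.
    """
    rows = []
    for thr in thresholds:
        sel = select_top_snps(gwas_result, bundle.genotypes,
                              threshold_neglog10p=thr, prune=prune)
        b = DataBundle(genotypes=bundle.genotypes, y_adj=bundle.y_adj,
                       base_panel=bundle.base_panel, selections={"gwas": sel})
        res = run_strategy("GBLUP-GWAS", b, design)
        rows.append({"threshold": thr, "n_snps_selected": len(sel.snp_ids),
                     "accuracy": res.mean_accuracy, "se": res.empirical_se,
                     "bias_slope": res.mean_bias_slope})
    return pd.DataFrame(rows)


def reference_size_sweep(
    bundle: DataBundle,
    design: FoldDesign,
    sizes,
    strategy: str = "GBLUP-50k",
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy as a function of the reference-validation set size.

    Each size draws a random subset of the design's CV animals, splits it
    into random folds, and evaluates ``strategy``. Deterministic under
    ``seed``.
    """
    cv_ids = np.asarray(list(design.fold_assignment), dtype=object)
    rows = []
    for k, size in enumerate(sizes):
        if size > len(cv_ids):
            raise ValueError(f"size {size} exceeds available CV animals")
        rng = np.random.default_rng(stage_seed(seed, f"rvsize:{size}:{k}"))
        chosen = rng.choice(cv_ids, size=size, replace=False)
        sub_design = random_folds(chosen, n_folds=n_folds,
                                  seed=stage_seed(seed, f"folds:{size}"))
        sub_design = FoldDesign(discovery_ids=design.discovery_ids,
                                fold_assignment=sub_design.fold_assignment,
                                strategy="random", seed=seed)
        res = run_strategy(strategy, bundle, sub_design)
        rows.append({"rv_size": size, "accuracy": res.mean_accuracy,
                     "se": res.empirical_se})
    return pd.DataFrame(rows)
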