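"""Accuracy, empirical standard error, and bias of genomic prediction.

Accuracy of a fold is the Pearson correlation between validation
adjusted phenotypes and their GBVs divided by the square root of the
heritability (so it estimates the correlation with true breeding value).
The empirical SE over a 10-fold CV is sd(fold accuracies)/sqrt(10).
Bias is the OLS slope b of phenotype on GBV; unbiased prediction gives
b = 1, and the reported deviation is b - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EvalResult:
    per_fold: pd.DataFrame  # fold, n_val, accuracy, bias_slope
    mean_accuracy: float
    empirical_se: float
    mean_bias_slope: float
    h2_used: float
    strategy: str = ""

    @property
    def bias_deviation(self) -> float:
        return self.mean_bias_slope - 1.0


def fold_accuracy(y_adj_val, gbv_val, h2: float) -> float:
    """Pearson r(y, GBV) / sqrt(h2); NaN if the GBVs are constant."""
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    y = np.asarray(y_adj_val, dtype=float)
    g = np.asarray(gbv_val, dtype=float)
    if np.std(g) == 0 or np.std(y) == 0:
        return np.nan
    r = float(np.corrcoef(y, g)[0, 1])
    return r / np.sqrt(h2)


def empirical_se(fold_accuracies) -> float:
    """sd of the fold accuracies divided by sqrt(number of folds)."""
    acc = np.asarray(fold_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 folds for an empirical SE")
    return float(np.std(acc, ddof=1) / np.sqrt(acc.size))


def prediction_bias(y_adj_val, gbv_val) -> float:
    """OLS slope of phenotype on GBV (1 = unbiased)."""
    y = np.asarray(y_adj_val, dtype=float)
    g = np.asarray(gbv_val, dtype=float)
    vg = np.var(g)
    if vg == 0:
        return np.nan
    return float(np.cov(y, g, ddof=0)[0, 1] / vg)


def summarize_folds(fold_rows, h2_used: float, strategy: str = "") -> EvalResult:
    """Pool per-fold (fold, n_val, accuracy, bias_slope) records.

    Bias is averaged per fold then pooled, matching the accuracy
    treatment; pooled-regression bias is available by concatenating the
    folds upstream instead.
    """
    per_fold = pd.DataFrame(fold_rows, columns=["fold", "n_val", "accuracy", "bias_slope"])
    acc = per_fold["accuracy"].to_numpy(dtype=float)
    ok = np.isfinite(acc)
    return EvalResult(
        per_fold=per_fold,
        mean_accuracy=float(np.mean(acc[ok])) if ok.any() else np.nan,
        empirical_se=empirical_se(acc[ok]) if ok.sum() >= 2 else np.nan,
        mean_bias_slope=float(np.nanmean(per_fold["bias_slope"])),
        h2_used=h2_used,
        strategy=strategy,
    )
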