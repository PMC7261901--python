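"""Two-group differential expression on count matrices.

Normalization uses median-of-ratios size factors. The test is Welch's t on
log2(normalized + 1); fold changes are ratios of group means of normalized
counts with a pseudocount. Calls use strict fold-change bounds (default
> 1.2 up, < 0.83 down) gated by the raw p-value; BH FDR is reported
alongside but does not gate the call.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONDITION, CONTROL, ExpressionStudy

__all__ = [
    "estimate_size_factors",
    "normalize_counts",
    "de_table",
    "de_test",
    "apply_de_filter",
    "benjamini_hochberg",
    "ddct_relative_expression",
    "de_feature_ids",
]

DE_COLUMNS = ["feature", "feature_class", "base_mean", "fold_change",
              "log2fc", "p_value", "fdr", "call"]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    Uses only features with strictly positive counts in every sample so the
    per-feature geometric mean is finite; raises if none exist (pre-filter
    low-count features in that case).
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; "
            "pre-filter the matrix before estimating size factors")
    log_counts = np.log(arr[positive])
    log_geo_mean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     size_factors: Optional[pd.Series] = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts.div(size_factors, axis=1)


def benjamini_hochberg(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def _welch_p(cond: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Two-sided Welch-t p-values row-wise; degenerate rows handled explicitly."""
    res = stats.ttest_ind(cond, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        # zero variance in both groups: p = 1 if means agree, else 0
        diff = cond.mean(axis=1) - ctrl.mean(axis=1)
        p[bad] = np.where(np.isclose(diff[bad], 0.0), 1.0, 0.0)
    return p


def _call(fold_change: np.ndarray, p: np.ndarray,
          up: float, down: float, alpha: float) -> np.ndarray:
    call = np.full(fold_change.shape, "ns", dtype=object)
    sig = p < alpha
    call[sig & (fold_change > up)] = "up"
    call[sig & (fold_change < down)] = "down"
    return call


def de_table(counts: pd.DataFrame, condition_samples: list[str],
             control_samples: list[str], feature_class: str = "mRNA", *,
             size_factors: Optional[pd.Series] = None, pseudocount: float = 1.0,
             up: float = 1.2, down: float = 0.83,
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature DE table for an explicit sample split."""
    if len(condition_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined)")
    norm = normalize_counts(counts, size_factors)
    log_norm = np.log2(norm.to_numpy(dtype=float) + 1.0)
    idx = {s: i for i, s in enumerate(norm.columns)}
    cond_ix = [idx[s] for s in condition_samples]
    ctrl_ix = [idx[s] for s in control_samples]

    cond_norm = norm.iloc[:, cond_ix].to_numpy(dtype=float)
    ctrl_norm = norm.iloc[:, ctrl_ix].to_numpy(dtype=float)
    fold = (cond_norm.mean(axis=1) + pseudocount) / (ctrl_norm.mean(axis=1) + pseudocount)
    p = _welch_p(log_norm[:, cond_ix], log_norm[:, ctrl_ix])
    table = pd.DataFrame({
        "feature": counts.index,
        "feature_class": feature_class,
        "base_mean": norm.mean(axis=1).to_numpy(),
        "fold_change": fold,
        "log2fc": np.log2(fold),
        "p_value": p,
        "fdr": benjamini_hochberg(p),
        "call": _call(fold, p, up, down, alpha),
    })
    return table.reset_index(drop=True)


def de_test(study: ExpressionStudy, feature_class: str = "mrna",
            method: str = "welch-t", **kwargs) -> pd.DataFrame:
    """DE table for one feature class of a study (condition vs control)."""
    if method != "welch-t":
        raise ValueError(f"unknown DE method {method!r}")
    label = {"mrna": "mRNA", "lncrna": "lncRNA", "mirna": "miRNA"}[feature_class]
    return de_table(study.counts[feature_class],
                    study.samples_of(CONDITION), study.samples_of(CONTROL),
                    feature_class=label, **kwargs)


def apply_de_filter(table: pd.DataFrame, up: float = 1.2, down: float = 0.83,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Recompute calls at the given strict thresholds and keep survivors."""
    if not down < 1.0 < up:
        raise ValueError("thresholds must satisfy down < 1 < up")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    out = table.copy()
    out["call"] = _call(out["fold_change"].to_numpy(dtype=float),
                        out["p_value"].to_numpy(dtype=float), up, down, alpha)
    return out[out["call"] != "ns"].reset_index(drop=True)


def de_feature_ids(table: pd.DataFrame) -> list[str]:
    """Features called up or down, in table order."""
    return list(table.loc[table["call"] != "ns", "feature"])


def ddct_relative_expression(ct_target_cond: float, ct_ref_cond: float,
                             ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the delta-delta-Ct method, 2**(-ddCt)."""
    values = (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(values)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
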