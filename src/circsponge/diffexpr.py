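"""Differential expression: paired tumor/normal and unpaired knockdown tests.

The tumor-vs-normal contrast uses a two-sided paired t-test on per-subject
differences of log2(CPM + 1); the knockdown contrast (small unpaired designs,
3 vs 3 by default) uses Welch's t on log2(CPM + 1). Fold changes are
log2((mean CPM_A + c) / (mean CPM_B + c)) with pseudocount c = 1 CPM.
Multiple testing is Benjamini-Hochberg. Filter defaults reproduce the study
thresholds: |fold change| >= 2 with p < 0.05 and FDR < 0.001 for circRNAs,
|fold change| >= 1.5 with p < 0.05 (no FDR filter) for knockdown genes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, PipelineError
from .annotate import cpm_normalize

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-8  # variance floor for degenerate (zero-spread) tests


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def log2fc(matrix: ExpressionMatrix, group_a, group_b, feature: str,
           pseudocount: float = 1.0) -> float:
    """log2 of the (pseudocounted) mean-CPM ratio of group A over group B."""
    if feature not in matrix.counts.index:
        raise PipelineError(f"unknown feature {feature!r}")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise PipelineError("log2fc: empty group")
    if set(group_a) & set(group_b):
        raise PipelineError("log2fc: groups overlap")
    cpm = cpm_normalize(matrix)
    mean_a = cpm.loc[feature, group_a].mean()
    mean_b = cpm.loc[feature, group_b].mean()
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def paired_t_from_diffs(diffs, var_floor: float = VAR_FLOOR) -> float:
    """Two-sided paired t-test p-value from per-pair differences.

    All-zero differences give p = 1; zero spread around a non-zero mean is
    handled with a variance floor so the test stays defined.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise PipelineError(f"paired test needs >= 3 pairs, got {n}")
    if np.all(d == 0):
        return 1.0
    var = d.var(ddof=1)
    var = max(var, var_floor)
    t = d.mean() / np.sqrt(var / n)
    return float(2.0 * stats.t.sf(abs(t), n - 1))


def paired_test(matrix: ExpressionMatrix, feature: str,
                cond_a: str = "tumor", cond_b: str = "normal",
                pseudocount: float = 1.0) -> float:
    """Paired t-test on per-subject differences of log2(CPM + pseudocount)."""
    if feature not in matrix.counts.index:
        raise PipelineError(f"unknown feature {feature!r}")
    pairs = matrix.pairs(cond_a, cond_b)
    if len(pairs) < 3:
        raise PipelineError(f"paired test needs >= 3 complete pairs, got {len(pairs)}")
    logcpm = np.log2(cpm_normalize(matrix) + pseudocount)
    diffs = [logcpm.loc[feature, a] - logcpm.loc[feature, b] for a, b in pairs]
    return paired_t_from_diffs(diffs)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise PipelineError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Whole-matrix DE tables
# ---------------------------------------------------------------------------

def _drop_all_zero(matrix: ExpressionMatrix) -> ExpressionMatrix:
    keep = matrix.counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d feature(s) with zero counts in all samples", n_dropped)
    return ExpressionMatrix(matrix.counts.loc[keep], matrix.sample_meta)


def _fold_changes(matrix, samples_a, samples_b, pseudocount):
    cpm = cpm_normalize(matrix)
    mean_a = cpm[samples_a].mean(axis=1)
    mean_b = cpm[samples_b].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def _as_table(features, lfc, p) -> pd.DataFrame:
    padj = bh_adjust(p)
    return pd.DataFrame({
        "feature_id": features,
        "log2fc": np.asarray(lfc, dtype=float),
        "p": np.asarray(p, dtype=float),
        "padj": padj,
        "direction": np.where(np.asarray(lfc) > 0, "up", "down"),
    }).set_index("feature_id")


def de_paired(matrix: ExpressionMatrix, cond_a: str = "tumor", cond_b: str = "normal",
              pseudocount: float = 1.0) -> pd.DataFrame:
    """Paired DE over every (non-all-zero) feature: log2fc, p, BH padj, direction."""
    matrix = _drop_all_zero(matrix)
    pairs = matrix.pairs(cond_a, cond_b)
    if len(pairs) < 3:
        raise PipelineError(f"paired design needs >= 3 complete pairs, got {len(pairs)}")
    samples_a = [a for a, _ in pairs]
    samples_b = [b for _, b in pairs]
    logcpm = np.log2(cpm_normalize(matrix) + pseudocount)
    diffs = logcpm[samples_a].to_numpy() - logcpm[samples_b].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    var = np.maximum(diffs.var(axis=1, ddof=1), VAR_FLOOR)
    t = mean / np.sqrt(var / n)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p[np.all(diffs == 0, axis=1)] = 1.0
    lfc = _fold_changes(matrix, samples_a, samples_b, pseudocount)
    return _as_table(matrix.feature_ids, lfc, p)


def de_unpaired(matrix: ExpressionMatrix, cond_a: str = "knockdown",
                cond_b: str = "control", pseudocount: float = 1.0) -> pd.DataFrame:
    """Welch's t on log2(CPM + pseudocount); for small unpaired designs."""
    matrix = _drop_all_zero(matrix)
    samples_a = matrix.samples_in(cond_a)
    samples_b = matrix.samples_in(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise PipelineError("unpaired test needs >= 2 samples per group")
    logcpm = np.log2(cpm_normalize(matrix) + pseudocount)
    xa = logcpm[samples_a].to_numpy()
    xb = logcpm[samples_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    va = np.maximum(xa.var(axis=1, ddof=1), VAR_FLOOR)
    vb = np.maximum(xb.var(axis=1, ddof=1), VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    same = np.all(xa == xa[:, :1], axis=1) & np.all(xb == xb[:, :1], axis=1) \
        & (xa[:, 0] == xb[:, 0])
    p[same] = 1.0
    lfc = _fold_changes(matrix, samples_a, samples_b, pseudocount)
    return _as_table(matrix.feature_ids, lfc, p)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def call_dec(results: pd.DataFrame, min_fold_change: float = 2.0,
             max_p: float = 0.05, max_padj: float = 0.001) -> pd.DataFrame:
    """Differentially expressed circRNAs: |FC| >= 2, p < 0.05, FDR < 0.001."""
    min_abs_lfc = np.log2(min_fold_change)
    keep = (results["log2fc"].abs() >= min_abs_lfc) \
        & (results["p"] < max_p) & (results["padj"] < max_padj)
    return results.loc[keep].copy()


def call_kd_degs(results: pd.DataFrame, min_fold_change: float = 1.5,
                 max_p: float = 0.05) -> pd.DataFrame:
    """Knockdown DEGs: |FC| >= 1.5 and p < 0.05 (no FDR filter)."""
    min_abs_lfc = np.log2(min_fold_change)
    keep = (results["log2fc"].abs() >= min_abs_lfc) & (results["p"] < max_p)
    return results.loc[keep].copy()
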