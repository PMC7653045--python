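"""Post-quantification HERV expression analysis.

Input is a locus x sample TPM matrix (mean TPM across a locus's transcripts).
All values are floored at 0.05 TPM before any log computation; fold changes
are log2(x) - log2(y).  Two fold-change modes mirror the study design:
per-patient versus the healthy-donor mean, and paired pre- versus
post-treatment within each patient.  Heatmap values are clipped to +/-6.
The expression/recognition relationship is quantified with a Spearman
correlation, and immunogenic versus non-immunogenic loci are compared with
the exact two-tailed Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import logging
from math import factorial
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_models import exact_rank_test

__all__ = [
    "floor_tpm",
    "log2_fold_change",
    "group_fold_changes",
    "clip_for_heatmap",
    "expression_vs_recognition",
    "immunogenic_group_compare",
    "TPM_FLOOR",
    "HEATMAP_BOUND",
]

logger = logging.getLogger(__name__)

TPM_FLOOR = 0.05
HEATMAP_BOUND = 6.0


def floor_tpm(matrix: pd.DataFrame, floor: float = TPM_FLOOR) -> pd.DataFrame:
    """Set every expression value below ``floor`` to ``floor`` (idempotent)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return matrix.clip(lower=floor)


def log2_fold_change(x, y):
    """log2(x) - log2(y); inputs must already be floored (strictly positive)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("apply floor_tpm first: values must be positive")
    return np.log2(x) - np.log2(y)


def group_fold_changes(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    mode: str = "vs-healthy",
    floor: float = TPM_FLOOR,
) -> pd.DataFrame:
    """Per (locus, patient) log2 fold changes.

    ``sample_sheet`` maps sample IDs (matrix columns) to ``individual_id``
    and ``class_`` in {healthy, pre, post}.  Mode "vs-healthy" compares each
    pre-treatment patient column to the mean of the floored healthy columns;
    mode "paired" computes within-patient post-versus-pre fold changes and
    drops unpaired patients (with a logged count).
    """
    meta = sample_sheet.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    floored = floor_tpm(matrix, floor)
    cls = meta.loc[matrix.columns, "class_"]
    indiv = meta.loc[matrix.columns, "individual_id"]

    if mode == "vs-healthy":
        healthy_cols = matrix.columns[cls == "healthy"]
        if len(healthy_cols) == 0:
            raise ValueError("no healthy samples for vs-healthy mode")
        ref = floored[healthy_cols].mean(axis=1)
        patient_cols = matrix.columns[cls == "pre"]
        out = {}
        for col in patient_cols:
            out[indiv[col]] = log2_fold_change(floored[col], ref)
        return pd.DataFrame(out, index=matrix.index)

    if mode == "paired":
        pre_by_ind = {indiv[c]: c for c in matrix.columns[cls == "pre"]}
        post_by_ind = {indiv[c]: c for c in matrix.columns[cls == "post"]}
        paired = sorted(set(pre_by_ind) & set(post_by_ind))
        dropped = (set(pre_by_ind) | set(post_by_ind)) - set(paired)
        if dropped:
            logger.info("dropped %d unpaired patients: %s", len(dropped), sorted(dropped))
        out = {
            ind: log2_fold_change(floored[post_by_ind[ind]], floored[pre_by_ind[ind]])
            for ind in paired
        }
        return pd.DataFrame(out, index=matrix.index)

    raise ValueError(f"unknown mode {mode!r}; use 'vs-healthy' or 'paired'")


def clip_for_heatmap(values, bound: float = HEATMAP_BOUND):
    """Clamp fold changes to [-bound, +bound] for a bounded color scale."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return values.clip(lower=-bound, upper=bound)
    return np.clip(np.asarray(values, dtype=float), -bound, bound)


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho: float) -> float:
    """Two-tailed exact permutation p-value for Spearman rho (small n only)."""
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    total = factorial(n)
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(xc[list(perm)], yc)) / denom
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def expression_vs_recognition(
    mean_expression: Mapping[str, float] | pd.Series,
    epitope_proportion: Mapping[str, float] | pd.Series,
    method: str = "t-approx",
) -> tuple[float, float, int]:
    """Spearman correlation between per-locus mean patient TPM and the
    proportion of predicted epitopes detected.

    Ties are handled by midranks.  The p-value is two-tailed from the
    t-approximation by default; ``method='exact'`` enumerates all rank
    permutations (intended for <= 10 loci).  Returns (rho, p, n).
    """
    expr = pd.Series(mean_expression)
    prop = pd.Series(epitope_proportion)
    loci = expr.index.intersection(prop.index)
    if set(expr.index) != set(prop.index):
        raise ValueError("the two inputs must cover the same locus set")
    if len(loci) < 3:
        raise ValueError("need at least 3 loci")
    x = expr.loc[loci].to_numpy(float)
    y = prop.loc[loci].to_numpy(float)
    rho, p = stats.spearmanr(x, y)
    if method == "exact":
        if len(loci) > 10:
            raise ValueError("exact permutation p-value supported for <= 10 loci")
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), float(rho))
    elif method != "t-approx":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), int(len(loci))


def immunogenic_group_compare(
    mean_expression: Mapping[str, float] | pd.Series,
    immunogenic_flags: Mapping[str, bool] | pd.Series,
) -> dict:
    """Compare mean expression of T-cell-recognized loci to unrecognized loci.

    Reports per-group medians and the exact two-tailed Mann-Whitney p-value.
    """
    expr = pd.Series(mean_expression)
    flags = pd.Series(immunogenic_flags).astype(bool)
    pos = expr[flags.reindex(expr.index, fill_value=False)]
    neg = expr[~flags.reindex(expr.index, fill_value=False)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both immunogenic and non-immunogenic groups must be non-empty")
    res = exact_rank_test(pos.to_numpy(), neg.to_numpy(), alternative="two-sided")
    return {
        "median_immunogenic": float(pos.median()),
        "median_non_immunogenic": float(neg.median()),
        "p_value": res.pvalue,
        "n_immunogenic": int(len(pos)),
        "n_non_immunogenic": int(len(neg)),
    }
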