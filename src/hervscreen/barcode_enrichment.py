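"""Detection of pMHC-specific T cell populations from DNA-barcode read counts.

Each sorted (multimer-positive) sample is sequenced together with triplicate
baseline aliquots of the full pMHC pool.  Barcode counts are normalized with
trimmed-mean-of-M-values (TMM) factors, fold changes are computed against the
mean baseline fraction, and each barcode gets a one-sided upper-tail p-value
under a negative binomial model with fixed dispersion (variance = mu + phi*mu^2,
phi = 0.1 by default).  Benjamini-Hochberg FDR is applied per sorted sample and
a barcode is called significant when FDR < 0.1% AND it carries at least 1/1000
of the sample's raw barcode reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountsTable",
    "tmm_factors",
    "log2fc_vs_baseline",
    "nb_pvalues",
    "bh_fdr",
    "detect",
    "call_detections",
    "clonal_reduce",
    "DEFAULT_DISPERSION",
    "DEFAULT_FDR_THRESHOLD",
    "DEFAULT_MIN_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_DISPERSION = 0.1
DEFAULT_FDR_THRESHOLD = 0.001
DEFAULT_MIN_FRACTION = 0.001

_BASELINE_SUFFIXES = ("_baseline_1", "_baseline_2", "_baseline_3")


@dataclass
class CountsTable:
    """Barcode x sample read counts with baseline-replicate designation.

    ``counts`` is a DataFrame indexed by barcode.  ``experiments`` maps each
    sorted-sample column to its exactly three baseline replicate columns.
    """

    counts: pd.DataFrame
    experiments: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("barcode IDs must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for sorted_col, baselines in self.experiments.items():
            if len(baselines) != 3:
                raise ValueError(
                    f"sorted sample {sorted_col!r} must map to exactly 3 "
                    f"baseline replicates, got {len(baselines)}"
                )
            missing = [c for c in [sorted_col, *baselines] if c not in self.counts]
            if missing:
                raise ValueError(f"columns missing from counts table: {missing}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sorted_samples(self) -> list[str]:
        return list(self.experiments)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountsTable":
        """Read a counts TSV whose baseline columns follow the
        ``<experiment>_baseline_{1,2,3}`` naming convention."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        experiments: dict[str, list[str]] = {}
        for col in df.columns:
            for suf in _BASELINE_SUFFIXES:
                if col.endswith(suf):
                    experiments.setdefault(col[: -len(suf)], []).append(col)
                    break
        experiments = {
            exp: sorted(cols) for exp, cols in experiments.items() if exp in df.columns
        }
        return cls(counts=df, experiments=experiments)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="barcode")


def tmm_factors(
    counts: pd.DataFrame | CountsTable,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference column is the sample whose 75th-percentile count fraction is
    closest to the mean of those percentiles.  For every sample, barcodes with
    positive counts in both the sample and the reference contribute
    M = log2 fraction ratio and A = mean log2 fraction; the top/bottom
    ``trim_m`` by M and ``trim_a`` by A are trimmed and the remaining M values
    averaged with inverse asymptotic binomial variance weights.  Factors are
    rescaled so their geometric mean is 1.
    """
    df = counts.counts if isinstance(counts, CountsTable) else counts
    mat = df.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot <= 0:
            raise ValueError(f"sample {df.columns[j]!r} has all-zero counts")
    frac = mat / lib

    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(df.shape[1])
    for j in range(df.shape[1]):
        if j == ref:
            continue
        ok = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if not ok.any():
            continue
        fj, fr = frac[ok, j], frac[ok, ref]
        cj, cr = mat[ok, j], mat[ok, ref]
        m = np.log2(fj / fr)
        a = 0.5 * np.log2(fj * fr)
        w = (lib[j] - cj) / (lib[j] * cj) + (lib[ref] - cr) / (lib[ref] * cr)
        n = ok.sum()
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            # inverse-variance weighted trimmed mean of M values
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    log_factors -= log_factors.mean()  # geometric mean of factors = 1
    return pd.Series(2.0 ** log_factors, index=df.columns, name="tmm_factor")


def _effective_lib(df: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return df.sum(axis=0) * factors


def log2fc_vs_baseline(
    table: CountsTable,
    factors: pd.Series | None = None,
    pseudo_fraction: float | None = None,
) -> pd.DataFrame:
    """log2 fold change of each barcode's normalized fraction in every sorted
    sample relative to the mean of its triplicate baseline fractions.

    A pseudo-fraction (default 0.5 / median effective library size) keeps all
    fold changes finite at zero counts.
    """
    df = table.counts
    if factors is None:
        factors = tmm_factors(df)
    eff = _effective_lib(df, factors)
    if pseudo_fraction is None:
        pseudo_fraction = 0.5 / float(np.median(eff))
    out = {}
    for sorted_col, baselines in table.experiments.items():
        f_s = df[sorted_col].to_numpy(float) / eff[sorted_col]
        f_b = np.column_stack(
            [df[b].to_numpy(float) / eff[b] for b in baselines]
        ).mean(axis=1)
        out[sorted_col] = np.log2((f_s + pseudo_fraction) / (f_b + pseudo_fraction))
    return pd.DataFrame(out, index=df.index)


def nb_pvalues(
    table: CountsTable,
    factors: pd.Series | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    mu_floor: float = 0.5,
) -> pd.DataFrame:
    """One-sided upper-tail NB p-values, P(X >= observed count).

    The NB mean is the normalized baseline mean fraction rescaled to the
    sorted sample's effective library size, with variance mu + dispersion*mu^2.
    A zero baseline mean with a nonzero observation is floored at ``mu_floor``
    reads so the p-value stays positive; a zero observation at zero mean gets
    p = 1 (the upper tail contains all mass).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    df = table.counts
    if factors is None:
        factors = tmm_factors(df)
    eff = _effective_lib(df, factors)
    size = 1.0 / dispersion
    out = {}
    for sorted_col, baselines in table.experiments.items():
        base_frac = np.column_stack(
            [df[b].to_numpy(float) / eff[b] for b in baselines]
        ).mean(axis=1)
        mu = base_frac * eff[sorted_col]
        obs = df[sorted_col].to_numpy(float)
        mu_adj = np.where((mu <= 0) & (obs > 0), mu_floor, mu)
        p = np.ones_like(mu_adj)
        pos = mu_adj > 0
        prob = size / (size + mu_adj[pos])
        p[pos] = stats.nbinom.sf(obs[pos] - 1, size, prob)
        out[sorted_col] = p
    return pd.DataFrame(out, index=df.index)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def detect(
    table: CountsTable,
    annotation: pd.DataFrame | None = None,
    factors: pd.Series | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    pseudo_fraction: float | None = None,
) -> pd.DataFrame:
    """Run the full detection pipeline; one row per (sorted sample, barcode).

    FDR is computed per sorted sample (each experiment is tested
    individually).  The read-fraction filter uses raw, pre-normalization
    counts.  ``annotation`` (index barcode; columns peptide, allele, ...) is
    merged into the result when given.
    """
    df = table.counts
    if factors is None:
        factors = tmm_factors(df)
    lfc = log2fc_vs_baseline(table, factors, pseudo_fraction)
    pvals = nb_pvalues(table, factors, dispersion)

    frames = []
    for sorted_col in table.experiments:
        raw = df[sorted_col].to_numpy(float)
        total = raw.sum()
        read_fraction = raw / total if total > 0 else np.zeros_like(raw)
        fdr = bh_fdr(pvals[sorted_col].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "sample": sorted_col,
                    "barcode": df.index,
                    "log2_fc": lfc[sorted_col].to_numpy(),
                    "p_value": pvals[sorted_col].to_numpy(),
                    "fdr": fdr,
                    "read_fraction": read_fraction,
                }
            )
        )
    res = pd.concat(frames, ignore_index=True)
    res["significant"] = (res["fdr"] < fdr_threshold) & (
        res["read_fraction"] >= min_fraction
    )
    if annotation is not None:
        res = res.merge(
            annotation, left_on="barcode", right_index=True, how="left"
        )
    return res


def call_detections(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> set[tuple[str, str]]:
    """Set of (sample, barcode) pairs passing the dual significance filter."""
    mask = (results["fdr"] < fdr_threshold) & (
        results["read_fraction"] >= min_fraction
    )
    return set(zip(results.loc[mask, "sample"], results.loc[mask, "barcode"]))


def clonal_reduce(reads: pd.DataFrame, table_template: CountsTable | None = None) -> pd.DataFrame:
    """Collapse reads to clonally reduced counts: distinct molecule tags per
    (barcode, sample).  ``reads`` is long-form with columns barcode, sample
    and optionally tag; without a tag column the input count table is passed
    through unchanged (with a logged notice)."""
    if "tag" not in reads.columns:
        logger.info("no molecule-tag column supplied; clonal reduction is a pass-through")
        return reads.pivot_table(
            index="barcode", columns="sample", values="count", fill_value=0
        ) if {"count"} <= set(reads.columns) else reads
    reduced = (
        reads.groupby(["barcode", "sample"])["tag"].nunique().unstack(fill_value=0)
    )
    reduced.columns.name = None
    return reduced
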