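"""Bayesian cohort-comparison models and exact rank tests.

Four models compare T cell reactivity between healthy donors and patients
before/after hypomethylating (AZA) therapy:

* a binomial proportion model with Beta(1, 1) priors per group (proportion of
  individuals responding, or of viral peptides recognized),
* an HLA-corrected logistic regression where the proportion of recognized
  peptides per (individual, allele) observation is
  ``p_i = logistic(beta0 + beta_HLA[i] + beta_class[i])`` with sum-to-zero
  deflections, from which HLA-corrected class proportions
  ``p_class = logistic(beta0 + beta_class)`` and between-class log fold
  changes ``log(p_class1 / p_class2)`` are derived per posterior draw,
* a normalization of the HERV class proportions to the viral-antigen class
  proportions (viral responses as an internal control of immune status), and
* a clinical-outcome logistic regression with a hierarchical normal prior
  shared by the HERV, viral, and interaction coefficients.

Frequentist group comparisons use exact Mann-Whitney / Wilcoxon signed-rank
tests whose null distributions are computed exactly even with ties (midranks;
full enumeration for small samples, a counted-shift convolution otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .mcmc import mcmc_diagnostics, sample_rwm, sample_rwm_factorized

__all__ = [
    "McmcConfig",
    "PosteriorSummary",
    "ProportionFit",
    "HlaModelFit",
    "OutcomeModelFit",
    "fit_proportion_model",
    "fit_hla_corrected_model",
    "normalize_to_viral",
    "fit_outcome_model",
    "exact_rank_test",
    "RankTestResult",
    "prior_sensitivity",
    "contrast_table",
]


@dataclass
class McmcConfig:
    """Sampler settings: 3 chains x 10,000 iterations with 5,000 warmup by
    default, giving 15,000 post-warmup draws."""

    chains: int = 3
    iterations: int = 10_000
    warmup: int = 5_000
    seed: int = 0
    rhat_tolerance: float = 1.01
    min_ess: float = 400.0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    @property
    def n_post(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclass
class PosteriorSummary:
    """Named posterior draws with medians, equal-tailed 50%/90% credible
    intervals, and split-R-hat / ESS per parameter."""

    draws: dict[str, np.ndarray]  # name -> (chains, n_draws)
    table: pd.DataFrame
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])

    def ci(self, name: str, level: int = 90) -> tuple[float, float]:
        return (
            float(self.table.loc[name, f"ci{level}_lo"]),
            float(self.table.loc[name, f"ci{level}_hi"]),
        )


def _summarize(
    draws: dict[str, np.ndarray], cfg: McmcConfig
) -> PosteriorSummary:
    names = list(draws)
    stacked = np.stack([draws[n] for n in names], axis=-1)  # (chains, n, dim)
    rhat, ess = mcmc_diagnostics(stacked)
    rows = []
    for i, name in enumerate(names):
        flat = draws[name].reshape(-1)
        q = np.quantile(flat, [0.05, 0.25, 0.5, 0.75, 0.95])
        rows.append(
            {
                "parameter": name,
                "median": q[2],
                "ci50_lo": q[1],
                "ci50_hi": q[3],
                "ci90_lo": q[0],
                "ci90_hi": q[4],
                "rhat": rhat[i],
                "ess": ess[i],
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    msgs: list[str] = []
    with np.errstate(invalid="ignore"):
        bad_rhat = np.nan_to_num(rhat, nan=np.inf) > cfg.rhat_tolerance
        bad_ess = np.nan_to_num(ess, nan=0.0) < cfg.min_ess
    if stacked.shape[0] < 2:
        msgs.append("single chain: R-hat unavailable")
    elif bad_rhat.any():
        msgs.append(
            "non-converged chains (R-hat > "
            f"{cfg.rhat_tolerance}): {[names[i] for i in np.where(bad_rhat)[0]]}"
        )
    if bad_ess.any():
        msgs.append(
            f"low effective sample size (< {cfg.min_ess}): "
            f"{[names[i] for i in np.where(bad_ess)[0]]}"
        )
    return PosteriorSummary(draws=draws, table=table, converged=not msgs, warnings=msgs)


def contrast_table(
    draws: dict[str, np.ndarray],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise posterior contrasts of strictly positive quantities.

    For each pair (a, b) the natural-log fold change ``log(a/b)`` is computed
    per draw; the table reports its median, equal-tailed 90% CI, and the
    posterior probability that it exceeds 0 (equivalently P(a > b))."""
    labels = list(draws)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    columns = ["lfc_median", "lfc_ci90_lo", "lfc_ci90_hi", "prob_greater"]
    if not pairs:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="contrast"))
    rows = []
    for a, b in pairs:
        da, db = draws[a].reshape(-1), draws[b].reshape(-1)
        lfc = np.log(da / db)
        q = np.quantile(lfc, [0.05, 0.5, 0.95])
        rows.append(
            {
                "contrast": f"{a}_vs_{b}",
                "lfc_median": q[1],
                "lfc_ci90_lo": q[0],
                "lfc_ci90_hi": q[2],
                "prob_greater": float(np.mean(lfc > 0)),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# Proportion model

class ProportionFit(NamedTuple):
    summary: PosteriorSummary
    p_draws: dict[str, np.ndarray]  # group -> (chains, n_draws)
    contrasts: pd.DataFrame


def fit_proportion_model(
    k: Sequence[int],
    n: Sequence[int],
    cfg: McmcConfig | None = None,
    labels: Sequence[str] | None = None,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> ProportionFit:
    """Binomial proportion model, one independent proportion per group.

    With a Beta(a, b) prior (non-informative Beta(1,1) by default) the exact
    posterior is Beta(k + a, n - k + b); the MCMC draws are checked against
    that closed form in the test suite.  Sampling runs on the logit scale.
    """
    cfg = cfg or McmcConfig()
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != n.shape:
        raise ValueError("k and n must have the same length")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n per group")
    groups = list(labels) if labels is not None else [f"group{i}" for i in range(len(k))]

    a_post = k + prior_a
    b_post = n - k + prior_b

    def log_post(x: np.ndarray) -> np.ndarray:
        # x: (chains, G) on logit scale; Beta(a,b) prior + Jacobian.
        # The groups are independent, so the target factorizes and the
        # component-wise sampler applies.
        log_p = -np.logaddexp(0.0, -x)
        log_q = -np.logaddexp(0.0, x)
        return a_post * log_p + b_post * log_q

    x0 = special.logit((k + prior_a) / (n + prior_a + prior_b))
    draws, _ = sample_rwm_factorized(
        log_post,
        x0,
        n_chains=cfg.chains,
        n_iter=cfg.iterations,
        n_warmup=cfg.warmup,
        seed=cfg.seed,
    )
    p_draws = {g: special.expit(draws[:, :, i]) for i, g in enumerate(groups)}
    summary = _summarize({f"p[{g}]": d for g, d in p_draws.items()}, cfg)
    contrasts = contrast_table(p_draws)
    return ProportionFit(summary=summary, p_draws=p_draws, contrasts=contrasts)


# ---------------------------------------------------------------------------
# HLA-corrected logistic regression

class HlaModelFit(NamedTuple):
    summary: PosteriorSummary
    p_class_draws: dict[str, np.ndarray]
    contrasts: pd.DataFrame


def _expand_sum_to_zero(free: np.ndarray, size: int) -> np.ndarray:
    """Append the determined last coefficient so the vector sums to zero."""
    if size == 1:
        return np.zeros((free.shape[0], 1))
    return np.concatenate([free, -free.sum(axis=1, keepdims=True)], axis=1)


def fit_hla_corrected_model(
    data: pd.DataFrame,
    cfg: McmcConfig | None = None,
    prior_scale: float = 2.5,
    class_order: Sequence[str] | None = None,
) -> HlaModelFit:
    """HLA-corrected logistic regression of recognized-peptide proportions.

    ``data`` holds one observation per (individual, allele): columns
    ``n_tested``, ``n_positive``, ``hla``, ``class_``.  The linear predictor
    is beta0 + beta_HLA + beta_class with exact sum-to-zero constraints
    (K-1 free coefficients, last = minus their sum).  Derived per draw:
    HLA-corrected class proportions and pairwise log fold changes.
    """
    cfg = cfg or McmcConfig()
    req = {"n_tested", "n_positive", "hla", "class_"}
    if not req <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(req)}")
    if ((data["n_positive"] < 0) | (data["n_positive"] > data["n_tested"])).any():
        raise ValueError("require 0 <= n_positive <= n_tested")

    alleles = sorted(data["hla"].unique())
    classes = list(class_order) if class_order is not None else sorted(data["class_"].unique())
    present = set(data["class_"].unique())
    empty = [c for c in classes if c not in present]
    if empty:
        raise ValueError(f"classes with no observations: {empty}")

    hla_idx = data["hla"].map({a: i for i, a in enumerate(alleles)}).to_numpy()
    cls_idx = data["class_"].map({c: i for i, c in enumerate(classes)}).to_numpy()
    n_tested = data["n_tested"].to_numpy(float)
    n_pos = data["n_positive"].to_numpy(float)

    H, C = len(alleles), len(classes)
    dim = 1 + (H - 1) + (C - 1)
    inv_two_var = 1.0 / (2.0 * prior_scale**2)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        b0 = x[:, 0]
        bh = _expand_sum_to_zero(x[:, 1:H], H)
        bc = _expand_sum_to_zero(x[:, H : H + C - 1], C)
        return b0, bh, bc

    def log_post(x: np.ndarray) -> np.ndarray:
        b0, bh, bc = unpack(x)
        eta = b0[:, None] + bh[:, hla_idx] + bc[:, cls_idx]
        ll = -(
            n_pos * np.logaddexp(0.0, -eta) + (n_tested - n_pos) * np.logaddexp(0.0, eta)
        ).sum(axis=1)
        lp = -(b0**2 + (bh**2).sum(axis=1) + (bc**2).sum(axis=1)) * inv_two_var
        return ll + lp

    pooled = (n_pos.sum() + 0.5) / (n_tested.sum() + 1.0)
    x0 = np.zeros(dim)
    x0[0] = special.logit(pooled)
    draws, _ = sample_rwm(
        log_post,
        x0,
        n_chains=cfg.chains,
        n_iter=cfg.iterations,
        n_warmup=cfg.warmup,
        seed=cfg.seed,
        init_jitter=0.2,
    )
    flat = draws.reshape(-1, dim)
    b0_d, bh_d, bc_d = unpack(flat)
    shape = draws.shape[:2]

    named: dict[str, np.ndarray] = {"beta0": b0_d.reshape(shape)}
    for i, a in enumerate(alleles):
        named[f"beta_hla[{a}]"] = bh_d[:, i].reshape(shape)
    for i, c in enumerate(classes):
        named[f"beta_class[{c}]"] = bc_d[:, i].reshape(shape)

    p_class_draws = {
        c: special.expit(b0_d + bc_d[:, i]).reshape(shape) for i, c in enumerate(classes)
    }
    for c, d in p_class_draws.items():
        named[f"p_class[{c}]"] = d
    summary = _summarize(named, cfg)
    contrasts = contrast_table(p_class_draws)
    return HlaModelFit(summary=summary, p_class_draws=p_class_draws, contrasts=contrasts)


def normalize_to_viral(
    herv_p_class: dict[str, np.ndarray],
    viral_p_class: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], pd.DataFrame, int]:
    """Normalize HLA-corrected HERV class proportions by the viral class
    proportions, pairing draws by index.

    Returns the per-class ratio draws, between-class contrasts of the
    normalized quantity, and the number of draw indices excluded because a
    viral draw was zero (division impossible)."""
    classes = list(herv_p_class)
    if set(classes) != set(viral_p_class):
        raise ValueError("HERV and viral draws must cover the same classes")
    herv = {c: np.asarray(herv_p_class[c]).reshape(-1) for c in classes}
    viral = {c: np.asarray(viral_p_class[c]).reshape(-1) for c in classes}
    n = len(herv[classes[0]])
    if any(len(v) != n for v in herv.values()) or any(len(v) != n for v in viral.values()):
        raise ValueError("draw counts must be equal across classes and models")
    keep = np.ones(n, dtype=bool)
    for c in classes:
        keep &= viral[c] > 0
    n_excluded = int(n - keep.sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} draws with zero viral proportion")
    ratios = {c: herv[c][keep] / viral[c][keep] for c in classes}
    return ratios, contrast_table(ratios), n_excluded


# ---------------------------------------------------------------------------
# Clinical-outcome model

class OutcomeModelFit(NamedTuple):
    summary: PosteriorSummary
    ci_includes_zero: dict[str, bool]


def fit_outcome_model(
    data: pd.DataFrame,
    cfg: McmcConfig | None = None,
    hla_columns: Sequence[str] | None = None,
    prior_scale: float = 2.5,
    tau_scale: float = 1.0,
    ci_level: int = 90,
) -> OutcomeModelFit:
    """Logistic regression of clinical outcome on T cell response indicators.

    ``p(responder) = logistic(beta0 + beta_HLA.x_HLA + beta_HERV x_HERV +
    beta_VIR x_VIR + beta_HxV x_HERV x_VIR)``.  The HERV, viral, and
    interaction coefficients share a hierarchical normal(0, tau) prior with
    half-normal(tau_scale) on tau, which regularizes against separation in
    small cohorts.  Reports whether each coefficient's credible interval
    includes zero.
    """
    cfg = cfg or McmcConfig()
    if hla_columns is None:
        hla_columns = [c for c in data.columns if c.startswith("HLA")]
    y = data["outcome"]
    if y.dtype == object:
        y = y.map({"responder": 1, "non-responder": 0})
        if y.isna().any():
            raise ValueError("outcome must be responder/non-responder")
    y = y.to_numpy(float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary")
    x_hla = data[list(hla_columns)].to_numpy(float)
    x_herv = data["herv_response"].to_numpy(float)
    x_vir = data["viral_response"].to_numpy(float)
    x_int = x_herv * x_vir

    n_hla = x_hla.shape[1]
    dim = 1 + n_hla + 3 + 1  # beta0, beta_hla, (herv, vir, hxv), log_tau
    inv_two_var = 1.0 / (2.0 * prior_scale**2)
    inv_two_tau_scale = 1.0 / (2.0 * tau_scale**2)

    def log_post(x: np.ndarray) -> np.ndarray:
        # Non-centered parameterization: the three response coefficients are
        # tau * u with u ~ N(0, 1), which avoids the funnel geometry of
        # sampling (beta, tau) jointly.
        b0 = x[:, 0]
        bhla = x[:, 1 : 1 + n_hla]
        u = x[:, 1 + n_hla : 4 + n_hla]
        log_tau = x[:, 4 + n_hla]
        tau = np.exp(log_tau)
        b = tau[:, None] * u  # (herv, vir, herv_x_vir)
        eta = (
            b0[:, None]
            + bhla @ x_hla.T
            + b[:, 0:1] * x_herv
            + b[:, 1:2] * x_vir
            + b[:, 2:3] * x_int
        )
        ll = -(
            y * np.logaddexp(0.0, -eta) + (1.0 - y) * np.logaddexp(0.0, eta)
        ).sum(axis=1)
        lp = -(b0**2 + (bhla**2).sum(axis=1)) * inv_two_var
        # u ~ N(0, 1); half-normal(tau_scale) on tau plus log_tau Jacobian
        lp += -0.5 * (u**2).sum(axis=1)
        lp += -(tau**2) * inv_two_tau_scale + log_tau
        return ll + lp

    x0 = np.zeros(dim)
    x0[-1] = np.log(0.5)
    draws, _ = sample_rwm(
        log_post,
        x0,
        n_chains=cfg.chains,
        n_iter=cfg.iterations,
        n_warmup=cfg.warmup,
        seed=cfg.seed,
        init_jitter=0.2,
    )
    shape = draws.shape[:2]
    tau_d = np.exp(draws[:, :, 4 + n_hla])
    named: dict[str, np.ndarray] = {"beta0": draws[:, :, 0]}
    for i, c in enumerate(hla_columns):
        named[f"beta_hla[{c}]"] = draws[:, :, 1 + i]
    for i, nm in enumerate(["beta_herv", "beta_vir", "beta_herv_x_vir"]):
        named[nm] = tau_d * draws[:, :, 1 + n_hla + i]
    named["tau"] = tau_d
    summary = _summarize(named, cfg)
    coef_names = [n for n in named if n.startswith("beta")]
    includes_zero = {}
    for nm in coef_names:
        lo, hi = summary.ci(nm, ci_level)
        includes_zero[nm] = bool(lo <= 0.0 <= hi)
    return OutcomeModelFit(summary=summary, ci_includes_zero=includes_zero)


# ---------------------------------------------------------------------------
# Exact rank tests

class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _doubled(ranks: np.ndarray) -> np.ndarray:
    doubled = np.rint(2.0 * ranks).astype(int)
    assert np.allclose(doubled, 2.0 * ranks)
    return doubled


def _tail_p(values2: np.ndarray, probs: np.ndarray, t2: int, alternative: str) -> float:
    eps = 1e-9
    if alternative == "greater":
        return float(probs[values2 >= t2 - eps].sum())
    if alternative == "less":
        return float(probs[values2 <= t2 + eps].sum())
    if alternative == "two-sided":
        mean2 = float((values2 * probs).sum())
        dev = abs(t2 - mean2)
        return float(min(1.0, probs[np.abs(values2 - mean2) >= dev - eps].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def _signed_rank_null(ranks2: np.ndarray, bound: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the doubled positive-rank sum W+ under
    independent random signs."""
    n = len(ranks2)
    if 2**n <= bound:
        sums = np.zeros(2**n, dtype=int)
        for i, signs in enumerate(itertools.product([0, 1], repeat=n)):
            sums[i] = int(np.dot(signs, ranks2))
        values, counts = np.unique(sums, return_counts=True)
        return values, counts / counts.sum()
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    values = np.arange(total + 1)
    nz = counts > 0
    return values[nz], counts[nz] / counts.sum()


def _rank_sum_null(
    ranks2: np.ndarray, n1: int, bound: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the doubled rank sum of a size-n1 subset
    drawn without replacement from the combined midranks."""
    N = len(ranks2)
    if comb(N, n1) <= bound:
        sums = [
            int(sum(ranks2[list(idx)])) for idx in itertools.combinations(range(N), n1)
        ]
        values, counts = np.unique(sums, return_counts=True)
        return values, counts / counts.sum()
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for kk in range(n1, 0, -1):
            dp[kk, r:] += dp[kk - 1, : total + 1 - r]
    counts = dp[n1]
    values = np.arange(total + 1)
    nz = counts > 0
    return values[nz], counts[nz] / counts.sum()


def exact_rank_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "two-sided",
    paired: bool = False,
    enumeration_bound: int = 50_000,
) -> RankTestResult:
    """Exact Mann-Whitney-Wilcoxon (unpaired) or Wilcoxon signed-rank
    (paired) test with midrank tie handling.

    The null distribution is enumerated in full when the permutation space is
    at most ``enumeration_bound``, otherwise by the counted-shift
    (distribution-convolution) algorithm; both are exact and agree.  For the
    unpaired test the statistic is the rank sum of ``x``; ``alternative``
    "less" ("greater") means x tends to be smaller (larger) than y.  For the
    paired test the statistic is the positive-rank sum of the differences
    x - y (zeros dropped); "greater" means the differences tend positive.
    """
    x = np.asarray(x, dtype=float)
    if paired or y is None:
        d = x if y is None else x - np.asarray(y, dtype=float)
        if d.size == 0:
            raise ValueError("samples must be non-empty")
        d = d[d != 0.0]
        if d.size == 0:
            warnings.warn("all paired differences are zero; p = 1")
            return RankTestResult(statistic=0.0, pvalue=1.0)
        ranks = _midranks(np.abs(d))
        ranks2 = _doubled(ranks)
        w2 = int(ranks2[d > 0].sum())
        values2, probs = _signed_rank_null(ranks2, enumeration_bound)
        return RankTestResult(
            statistic=w2 / 2.0, pvalue=_tail_p(values2, probs, w2, alternative)
        )

    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks2 = _doubled(_midranks(combined))
    w2 = int(ranks2[: x.size].sum())
    values2, probs = _rank_sum_null(ranks2, x.size, enumeration_bound)
    return RankTestResult(
        statistic=w2 / 2.0, pvalue=_tail_p(values2, probs, w2, alternative)
    )


# ---------------------------------------------------------------------------
# Prior sensitivity

def prior_sensitivity(
    fit: Callable[[float], object],
    prior_scales: Sequence[float],
) -> pd.DataFrame:
    """Refit a model across a grid of prior scales and tabulate posterior
    medians plus the maximum absolute shift per parameter.

    ``fit`` maps a prior scale to a fit object exposing a PosteriorSummary
    (either directly or as a ``.summary`` attribute)."""
    if len(prior_scales) < 2:
        raise ValueError("need at least two prior scales")
    medians = {}
    for s in prior_scales:
        res = fit(s)
        summary = res if isinstance(res, PosteriorSummary) else res.summary
        medians[s] = summary.table["median"]
    out = pd.DataFrame(medians)
    out["max_shift"] = out.max(axis=1) - out.min(axis=1)
    return out
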