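"""Bayesian cohort models: conjugate agreement, sum-to-zero constraints,
derived contrasts, hierarchical outcome model, and exact rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from hervscreen.cohort_models import (
    McmcConfig,
    exact_rank_test,
    fit_hla_corrected_model,
    fit_outcome_model,
    fit_proportion_model,
    normalize_to_viral,
    prior_sensitivity,
)
from hervscreen.mcmc import mcmc_diagnostics

FAST = McmcConfig(chains=2, iterations=4000, warmup=2000, seed=42)


# ---------------------------------------------------------------------------
# Proportion model

def test_proportion_posterior_matches_beta_closed_form():
    fit = fit_proportion_model([0, 3], [10, 27], FAST, labels=["a", "b"])
    for (k, n, g) in [(0, 10, "a"), (3, 27, "b")]:
        exact = stats.beta(k + 1, n - k + 1)
        d = fit.p_draws[g].reshape(-1)
        for q in (0.05, 0.5, 0.95):
            assert abs(np.quantile(d, q) - exact.ppf(q)) < 0.01


def test_proportion_identical_groups_symmetric_contrast():
    fit = fit_proportion_model([5, 5], [20, 20], FAST, labels=["a", "b"])
    p = fit.contrasts.loc["a_vs_b", "prob_greater"]
    assert abs(p - 0.5) < 0.02


def test_proportion_contrast_antisymmetry():
    fit = fit_proportion_model([3, 9], [20, 20], FAST, labels=["a", "b"])
    da, db = fit.p_draws["a"].reshape(-1), fit.p_draws["b"].reshape(-1)
    p_ab = float(np.mean(da > db))
    p_ba = float(np.mean(db > da))
    assert p_ab + p_ba == 1.0  # continuous posterior: ties have measure zero


def test_proportion_invalid_counts_rejected():
    with pytest.raises(ValueError):
        fit_proportion_model([11], [10], FAST)


def test_proportion_ci_nesting():
    fit = fit_proportion_model([4, 12], [27, 34], FAST, labels=["hd", "pre"])
    for name in fit.summary.table.index:
        lo50, hi50 = fit.summary.ci(name, 50)
        lo90, hi90 = fit.summary.ci(name, 90)
        assert lo90 <= lo50 <= hi50 <= hi90


# ---------------------------------------------------------------------------
# HLA-corrected model

def _simulate_hla_data(rng, n_ind=120, b0=-3.0, bh=(0.3, -0.1, -0.4, 0.2),
                       bc=(-0.5, 0.0, 0.5)):
    alleles = ["A1", "A2", "B7", "B8"]
    classes = ["healthy", "pre", "post"]
    rows = []
    for i in range(n_ind):
        cls = classes[i % 3]
        carried = rng.choice(4, size=rng.integers(1, 5), replace=False)
        for a in carried:
            n = int(rng.integers(50, 150))
            p = expit(b0 + bh[a] + bc[classes.index(cls)])
            rows.append(
                {
                    "individual": i,
                    "hla": alleles[a],
                    "class_": cls,
                    "n_tested": n,
                    "n_positive": int(rng.binomial(n, p)),
                }
            )
    return pd.DataFrame(rows), classes


def test_hla_model_sum_to_zero_every_draw():
    rng = np.random.default_rng(0)
    data, classes = _simulate_hla_data(rng, n_ind=60)
    fit = fit_hla_corrected_model(data, FAST, class_order=classes)
    bh = sum(fit.summary.draws[f"beta_hla[{a}]"] for a in ["A1", "A2", "B7", "B8"])
    bc = sum(fit.summary.draws[f"beta_class[{c}]"] for c in classes)
    assert np.abs(bh).max() < 1e-10
    assert np.abs(bc).max() < 1e-10


def test_hla_model_null_symmetry():
    # Under identical true class proportions the evidence for a difference in
    # any single dataset is driven by sampling noise, so symmetry is checked
    # on averages over replicate datasets.
    rng = np.random.default_rng(1)
    medians, probs = [], []
    for _ in range(5):
        data, classes = _simulate_hla_data(rng, n_ind=120, bc=(0.0, 0.0, 0.0))
        fit = fit_hla_corrected_model(data, FAST, class_order=classes)
        medians.append(fit.contrasts["lfc_median"].to_numpy())
        probs.append(fit.contrasts["prob_greater"].to_numpy())
    assert np.abs(np.mean(medians, axis=0)).max() < 0.1
    mean_probs = np.mean(probs, axis=0)
    assert np.all((0.35 <= mean_probs) & (mean_probs <= 0.65))


def test_hla_model_degenerate_single_cell_consistency():
    # one allele, one class, large n: posterior median -> pooled rate
    rng = np.random.default_rng(2)
    rows = [
        {"individual": i, "hla": "A2", "class_": "pre",
         "n_tested": 200, "n_positive": int(rng.binomial(200, 0.05))}
        for i in range(50)
    ]
    data = pd.DataFrame(rows)
    fit = fit_hla_corrected_model(data, FAST)
    pooled = data["n_positive"].sum() / data["n_tested"].sum()
    assert abs(fit.summary.median("p_class[pre]") - pooled) < 0.02


def test_hla_model_lfc_ci_propagates_from_draws():
    rng = np.random.default_rng(3)
    data, classes = _simulate_hla_data(rng, n_ind=60)
    fit = fit_hla_corrected_model(data, FAST, class_order=classes)
    d1 = fit.p_class_draws["healthy"].reshape(-1)
    d2 = fit.p_class_draws["pre"].reshape(-1)
    lfc = np.log(d1 / d2)
    assert fit.contrasts.loc["healthy_vs_pre", "lfc_ci90_lo"] == np.quantile(lfc, 0.05)
    assert fit.contrasts.loc["healthy_vs_pre", "lfc_ci90_hi"] == np.quantile(lfc, 0.95)


def test_hla_model_empty_class_error():
    data = pd.DataFrame(
        [{"individual": 0, "hla": "A2", "class_": "pre", "n_tested": 10, "n_positive": 1}]
    )
    with pytest.raises(ValueError, match="no observations"):
        fit_hla_corrected_model(data, FAST, class_order=["healthy", "pre"])


# ---------------------------------------------------------------------------
# Viral normalization

def test_normalize_identical_draws_unit_ratio():
    rng = np.random.default_rng(4)
    draws = {c: rng.uniform(0.2, 0.4, 1000) for c in ["healthy", "pre"]}
    ratios, contrasts, excluded = normalize_to_viral(draws, {c: d.copy() for c, d in draws.items()})
    assert excluded == 0
    for c in ratios:
        assert np.allclose(ratios[c], 1.0)
    assert contrasts.loc["healthy_vs_pre", "lfc_median"] == 0.0


def test_normalize_halved_viral_doubles_ratio():
    rng = np.random.default_rng(5)
    herv = {"pre": rng.uniform(0.2, 0.4, 2000)}
    viral_full = {"pre": rng.uniform(0.4, 0.6, 2000)}
    r1, _, _ = normalize_to_viral(herv, viral_full)
    r2, _, _ = normalize_to_viral(herv, {"pre": viral_full["pre"] / 2.0})
    assert np.isclose(np.median(r2["pre"]), 2 * np.median(r1["pre"]))
    assert (r1["pre"] > 0).all()


def test_normalize_excludes_zero_viral_draws():
    herv = {"pre": np.full(100, 0.3)}
    viral = {"pre": np.concatenate([np.zeros(10), np.full(90, 0.5)])}
    with pytest.warns(UserWarning, match="excluded 10"):
        ratios, _, excluded = normalize_to_viral(herv, viral)
    assert excluded == 10 and len(ratios["pre"]) == 90


def test_normalize_mismatched_draw_counts_error():
    with pytest.raises(ValueError, match="draw counts"):
        normalize_to_viral({"a": np.ones(10)}, {"a": np.ones(11)})


# ---------------------------------------------------------------------------
# Outcome model

def _outcome_frame(rng, n, beta_vir=0.0):
    x_h = rng.integers(0, 2, n)
    x_v = rng.integers(0, 2, n)
    eta = beta_vir * x_v
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {
            "outcome": y,
            "herv_response": x_h,
            "viral_response": x_v,
            "HLA-A*01:01": rng.integers(0, 2, n),
            "HLA-A*02:01": rng.integers(0, 2, n),
            "HLA-B*07:02": rng.integers(0, 2, n),
            "HLA-B*08:01": rng.integers(0, 2, n),
        }
    )


def test_outcome_model_strong_effect_detected():
    rng = np.random.default_rng(6)
    fit = fit_outcome_model(_outcome_frame(rng, 500, beta_vir=2.0), FAST)
    lo, hi = fit.summary.ci("beta_vir", 90)
    assert lo > 0.0  # CI excludes zero for the planted effect
    assert not fit.ci_includes_zero["beta_vir"]


def test_outcome_model_separated_data_stays_finite():
    # perfect separation: regularized by the priors
    df = pd.DataFrame(
        {
            "outcome": [1] * 5 + [0] * 5,
            "herv_response": [1] * 5 + [0] * 5,
            "viral_response": [0] * 10,
            "HLA-A*02:01": [1] * 10,
        }
    )
    fit = fit_outcome_model(df, FAST, hla_columns=["HLA-A*02:01"])
    assert fit.summary.table["median"].abs().max() < 20


def test_outcome_model_string_outcomes():
    rng = np.random.default_rng(7)
    df = _outcome_frame(rng, 40)
    df["outcome"] = df["outcome"].map({1: "responder", 0: "non-responder"})
    fit = fit_outcome_model(df, FAST)
    assert "beta_herv" in fit.summary.table.index


# ---------------------------------------------------------------------------
# Exact rank tests

def mw_enumeration_oracle(x, y, alternative):
    """Full enumeration of all C(N, n1) group labelings."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, N = len(x), len(combined)
    w_obs = ranks[:n1].sum()
    all_w = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(N), n1)]
    )
    if alternative == "greater":
        return float(np.mean(all_w >= w_obs - 1e-9))
    if alternative == "less":
        return float(np.mean(all_w <= w_obs + 1e-9))
    mean = all_w.mean()
    return float(min(1.0, np.mean(np.abs(all_w - mean) >= abs(w_obs - mean) - 1e-9)))


def signed_rank_enumeration_oracle(d, alternative):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    all_w = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    )
    if alternative == "greater":
        return float(np.mean(all_w >= w_obs - 1e-9))
    if alternative == "less":
        return float(np.mean(all_w <= w_obs + 1e-9))
    mean = all_w.mean()
    return float(min(1.0, np.mean(np.abs(all_w - mean) >= abs(w_obs - mean) - 1e-9)))


def test_mann_whitney_worked_example():
    assert exact_rank_test([1, 2], [3, 4], alternative="less").pvalue == pytest.approx(1 / 6)


def test_signed_rank_worked_example():
    res = exact_rank_test([1, 2, 3], paired=True, alternative="greater")
    assert res.pvalue == pytest.approx(1 / 8)


def test_mann_whitney_two_sided_no_overlap():
    res = exact_rank_test([1, 2, 3], [4, 5, 6], alternative="two-sided")
    assert res.pvalue == pytest.approx(2 / 20)


def test_identical_groups_p_one():
    res = exact_rank_test([1, 2, 3], [1, 2, 3], alternative="two-sided")
    assert res.pvalue == pytest.approx(1.0)


def test_all_zero_differences_warns_p_one():
    with pytest.warns(UserWarning, match="zero"):
        res = exact_rank_test([1, 1], [1, 1], paired=True)
    assert res.pvalue == 1.0


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        exact_rank_test([], [1, 2])


@pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
def test_mann_whitney_matches_enumeration_with_ties(alternative):
    rng = np.random.default_rng(10)
    for _ in range(20):
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 5))
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        expected = mw_enumeration_oracle(x, y, alternative)
        for bound in (1, 10**6):  # shift algorithm and full enumeration paths
            res = exact_rank_test(x, y, alternative=alternative, enumeration_bound=bound)
            assert res.pvalue == pytest.approx(expected), (x, y, bound)


@pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
def test_signed_rank_matches_enumeration_with_ties(alternative):
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(3, 8))
        d = rng.integers(-3, 4, n).astype(float)
        if not (d != 0).any():
            continue
        expected = signed_rank_enumeration_oracle(d, alternative)
        for bound in (1, 10**6):
            res = exact_rank_test(d, paired=True, alternative=alternative,
                                  enumeration_bound=bound)
            assert res.pvalue == pytest.approx(expected), (d, bound)


def test_mann_whitney_agrees_with_scipy_exact_no_ties():
    rng = np.random.default_rng(12)
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        ours = exact_rank_test(x, y, alternative="greater").pvalue
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref)


def test_signed_rank_agrees_with_scipy_exact_no_ties():
    rng = np.random.default_rng(13)
    for _ in range(10):
        d = rng.normal(size=7)
        ours = exact_rank_test(d, paired=True, alternative="greater").pvalue
        ref = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref)


# ---------------------------------------------------------------------------
# Diagnostics and prior sensitivity

def test_diagnostics_well_mixed_chains():
    rng = np.random.default_rng(14)
    draws = rng.standard_normal((3, 2000, 1))
    rhat, ess = mcmc_diagnostics(draws)
    assert 0.99 <= rhat[0] <= 1.01
    assert abs(ess[0] - 6000) < 0.2 * 6000  # i.i.d.: ESS ~ draw count


def test_diagnostics_flag_offset_chain():
    rng = np.random.default_rng(15)
    draws = rng.standard_normal((3, 500, 1))
    draws[0] += 10.0
    rhat, _ = mcmc_diagnostics(draws)
    assert rhat[0] > 1.1


def test_diagnostics_single_chain_unavailable():
    rng = np.random.default_rng(16)
    rhat, ess = mcmc_diagnostics(rng.standard_normal((1, 500, 1)))
    assert np.isnan(rhat[0]) and np.isfinite(ess[0])


def test_prior_sensitivity_proportion_model():
    def fit(scale):
        return fit_proportion_model([30], [100], FAST, labels=["g"],
                                    prior_a=scale, prior_b=scale)

    table = prior_sensitivity(fit, [1.0, 2.0])
    assert table.loc["p[g]", "max_shift"] < 0.02


def test_prior_sensitivity_identical_priors_zero_shift():
    def fit(scale):
        return fit_proportion_model([5], [50], FAST, labels=["g"])

    table = prior_sensitivity(fit, [1.0, 1.0])
    assert table.loc["p[g]", "max_shift"] == 0.0
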