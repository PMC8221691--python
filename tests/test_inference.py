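"""Adjusted comparisons: screening, OLS, BCa bootstrap, MI pooling."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carebench import (
    bca_ci,
    collinearity_screen,
    compare_models,
    fit_adjusted_model,
    pooled_contrast,
)
from carebench.data_io import CASE_MIX_COVARIATES, RunConfig
from carebench.inference import (
    DegenerateBootstrapWarning,
    _bootstrap_betas,
    _build_design,
    _jackknife_contrast,
    adjusted_contrast,
    bca_from_samples,
)


def toy_frame(n=60, n_models=2, seed=0, effect=0.0, confounded=True):
    """Clients with case-mix covariates, model labels and a known cost law."""
    rng = np.random.default_rng(seed)
    models = [f"CM{i + 1}" for i in range(n_models)]
    frame = pd.DataFrame(
        {
            "model": rng.choice(models, size=n),
            "age": rng.integers(65, 95, size=n),
            "sex": rng.integers(0, 2, size=n),
            "living_alone": rng.integers(0, 2, size=n),
            "cps": rng.integers(0, 7, size=n),
            "drs": rng.integers(0, 15, size=n),
            "adlh": rng.integers(0, 7, size=n),
            "iadl": rng.integers(0, 49, size=n),
            "chess": rng.integers(0, 6, size=n),
        }
    )
    if confounded:
        frame.loc[frame["model"] == models[-1], "adlh"] += 2
        frame["adlh"] = frame["adlh"].clip(0, 6)
    cost = (
        5000.0
        + 900.0 * frame["adlh"]
        + effect * (frame["model"] == models[-1])
        + rng.gamma(2.0, 500.0, size=n)
    )
    frame["total_societal_6m"] = cost
    return frame


class TestCollinearityScreen:
    def test_duplicated_covariate_flagged_with_rho_one(self):
        frame = toy_frame(n=100)
        frame["iadl"] = frame["adlh"] * 3  # perfect monotone duplicate
        result = collinearity_screen(frame)
        pairs = {(a, b): r for a, b, r in result.flagged_pairs}
        assert pairs[("adlh", "iadl")] == pytest.approx(1.0)
        # adlh has higher priority than iadl in the default ordering
        assert "iadl" in result.dropped
        assert "adlh" in result.retained

    def test_negated_covariate_flagged_by_absolute_value(self):
        frame = toy_frame(n=100)
        frame["chess"] = 5 - frame["adlh"].clip(0, 5)
        result = collinearity_screen(frame)
        rhos = [r for a, b, r in result.flagged_pairs if {a, b} == {"adlh", "chess"}]
        assert rhos and rhos[0] < -0.4

    def test_independent_uniform_covariates_not_flagged(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            {name: rng.uniform(size=1000) for name in CASE_MIX_COVARIATES}
        )
        result = collinearity_screen(frame)
        assert result.flagged_pairs == ()
        assert result.retained == tuple(CASE_MIX_COVARIATES)

    def test_constant_covariate_degenerate(self):
        frame = toy_frame(n=50)
        frame["chess"] = 2
        result = collinearity_screen(frame)
        assert "chess" in result.degenerate
        assert "chess" not in result.retained

    def test_requires_three_clients(self):
        with pytest.raises(ValueError, match=">= 3"):
            collinearity_screen(toy_frame(n=2))


class TestFitAdjustedModel:
    def test_two_balanced_groups_no_covariates_gives_mean_difference(self):
        frame = pd.DataFrame(
            {
                "model": ["CM1"] * 4 + ["CM2"] * 4,
                "total_societal_6m": [10.0, 12.0, 8.0, 10.0, 20.0, 22.0, 18.0, 20.0],
            }
        )
        params = fit_adjusted_model(frame, "CM1", covariates=())
        assert params["model_CM2"] == pytest.approx(20.0 - 10.0)

    def test_all_costs_equal_gives_zero_coefficients(self):
        frame = toy_frame(n=40)
        frame["total_societal_6m"] = 777.0
        params = fit_adjusted_model(frame, "CM1")
        assert params.drop("intercept").abs().max() == pytest.approx(0.0, abs=1e-8)
        assert params["intercept"] == pytest.approx(777.0)

    def test_matches_normal_equations_on_tiny_instances(self):
        """OLS oracle: brute-force normal-equations solve, n <= 10."""
        for seed in range(5):
            frame = toy_frame(n=10, seed=seed, confounded=False)
            covariates = ("age", "adlh")
            params = fit_adjusted_model(frame, "CM1", covariates=covariates)
            X, names, _ = _build_design(frame, covariates, "CM1")
            y = frame["total_societal_6m"].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(params.to_numpy(), beta, atol=1e-8)

    def test_adjustment_removes_confounding_bias(self):
        """With confounding via ADLH the adjusted coefficient recovers the
        injected effect while the raw group difference is biased."""
        frame = toy_frame(n=4000, seed=1, effect=2230.0, confounded=True)
        raw_diff = (
            frame.loc[frame["model"] == "CM2", "total_societal_6m"].mean()
            - frame.loc[frame["model"] == "CM1", "total_societal_6m"].mean()
        )
        adjusted = fit_adjusted_model(frame, "CM1")["model_CM2"]
        assert abs(raw_diff - 2230.0) > 800.0
        assert adjusted == pytest.approx(2230.0, abs=150.0)

    def test_rank_deficiency_names_columns(self):
        frame = toy_frame(n=30)
        frame["iadl"] = frame["adlh"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_adjusted_model(frame, "CM1", covariates=("adlh", "iadl"))

    def test_single_model_rejected(self):
        frame = toy_frame(n=20, n_models=1)
        with pytest.raises(ValueError, match=">= 2 care models"):
            fit_adjusted_model(frame, "CM1")


def bca_oracle(sample: np.ndarray, alpha: float = 0.05):
    """Independent formula-by-formula BCa implementation over the full
    resample space (all n^n resamples), for tiny samples.

    Conventions: z0 from the fraction of resample statistics strictly below
    the point estimate; acceleration from jackknife third/second moments;
    endpoints are linearly interpolated empirical quantiles.
    """
    n = len(sample)
    theta_hat = sample.mean()
    boot = np.array(
        [np.mean(sample[list(ix)]) for ix in itertools.product(range(n), repeat=n)]
    )
    z0 = stats.norm.ppf(np.sum(boot < theta_hat) / len(boot))
    jack = np.array([np.delete(sample, i).mean() for i in range(n)])
    d = jack.mean() - jack
    a = np.sum(d**3) / (6.0 * np.sum(d**2) ** 1.5)
    lo_z, hi_z = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    lo_p = stats.norm.cdf(z0 + (z0 + lo_z) / (1 - a * (z0 + lo_z)))
    hi_p = stats.norm.cdf(z0 + (z0 + hi_z) / (1 - a * (z0 + hi_z)))
    return np.quantile(boot, lo_p), np.quantile(boot, hi_p)


class TestBcaCi:
    def test_constant_data_degenerate_interval_with_warning(self):
        data = np.full(8, 3.25)
        with pytest.warns(DegenerateBootstrapWarning):
            low, high = bca_ci(np.mean, data, B=50, seed=0)
        assert (low, high) == (3.25, 3.25)

    def test_exhaustive_enumeration_matches_independent_oracle(self):
        """All 5^5 = 3125 resamples of a printed toy sample."""
        sample = np.array([3.2, 1.7, 4.5, 2.8, 9.1])
        low, high = bca_ci(np.mean, sample, exhaustive=True)
        oracle_low, oracle_high = bca_oracle(sample)
        assert low == pytest.approx(oracle_low, abs=1e-12)
        assert high == pytest.approx(oracle_high, abs=1e-12)

    def test_reduces_to_percentile_when_z0_and_a_vanish(self):
        """With a symmetric bootstrap distribution centred on the estimate
        and flat jackknife, BCa = plain percentile interval."""
        # even count, symmetric about 0: exactly half the replicates fall
        # strictly below the point estimate, so z0 = 0 exactly
        boot = np.linspace(-1, 1, 500)
        jack = np.zeros(10)  # zero skewness -> a = 0
        low, high = bca_from_samples(0.0, boot, jack, alpha=0.10)
        assert low == pytest.approx(np.quantile(boot, 0.05))
        assert high == pytest.approx(np.quantile(boot, 0.95))

    def test_large_symmetric_sample_close_to_normal_theory(self):
        rng = np.random.default_rng(4)
        sample = rng.normal(10.0, 2.0, size=400)
        low, high = bca_ci(np.mean, sample, B=4000, seed=5)
        se = sample.std(ddof=1) / np.sqrt(len(sample))
        norm_low = sample.mean() - 1.959964 * se
        norm_high = sample.mean() + 1.959964 * se
        assert low == pytest.approx(norm_low, abs=0.12)
        assert high == pytest.approx(norm_high, abs=0.12)

    def test_cross_check_against_scipy_bootstrap(self):
        """Independent route: scipy's BCa on the same data and seed count."""
        rng = np.random.default_rng(10)
        sample = rng.gamma(0.8, 1000.0, size=120)
        low, high = bca_ci(np.mean, sample, B=3000, seed=3)
        res = stats.bootstrap(
            (sample,),
            np.mean,
            n_resamples=3000,
            confidence_level=0.95,
            method="BCa",
            random_state=np.random.default_rng(3),
        )
        width = high - low
        assert low == pytest.approx(res.confidence_interval.low, abs=0.08 * width)
        assert high == pytest.approx(res.confidence_interval.high, abs=0.08 * width)

    def test_deterministic_under_seed(self):
        sample = np.random.default_rng(1).gamma(1.0, 100.0, size=50)
        assert bca_ci(np.mean, sample, B=200, seed=7) == bca_ci(
            np.mean, sample, B=200, seed=7
        )


class TestBootstrapMachinery:
    def test_weighted_gram_equals_row_resampled_ols(self):
        """The batched weighted normal equations equal refitting on the
        literally resampled rows."""
        frame = toy_frame(n=50, seed=2)
        X, names, _ = _build_design(frame, ("adlh",), "CM1")
        y = frame["total_societal_6m"].to_numpy()
        onehot = np.column_stack(
            [(frame["model"] == m).to_numpy(float) for m in ("CM1", "CM2")]
        )
        rng = np.random.default_rng(0)
        betas = _bootstrap_betas(X, y, onehot, B=5, rng=rng)
        # replay the same multinomial draws as explicit index resamples
        rng2 = np.random.default_rng(0)
        W = rng2.multinomial(len(y), np.full(len(y), 1 / len(y)), size=5)
        for b in range(5):
            idx = np.repeat(np.arange(len(y)), W[b])
            ref = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0]
            np.testing.assert_allclose(betas[b], ref, atol=1e-8)

    def test_jackknife_downdate_matches_explicit_loo(self):
        frame = toy_frame(n=25, seed=3)
        X, names, _ = _build_design(frame, ("adlh", "age"), "CM1")
        y = frame["total_societal_6m"].to_numpy()
        c = np.zeros(X.shape[1])
        c[names.index("model_CM2")] = 1.0
        fast = _jackknife_contrast(X, y, c)
        slow = np.array(
            [
                c
                @ np.linalg.lstsq(
                    np.delete(X, i, axis=0), np.delete(y, i), rcond=None
                )[0]
                for i in range(len(y))
            ]
        )
        np.testing.assert_allclose(fast, slow, atol=1e-7)


class TestPooledContrast:
    def test_identical_datasets_degenerate_pooling(self):
        frame = toy_frame(n=80, seed=6, effect=1000.0)
        rng = np.random.default_rng(1)
        single = adjusted_contrast(frame, ("CM2", "CM1"), B=300, rng=np.random.default_rng(1))
        pooled = pooled_contrast([frame] * 3, ("CM2", "CM1"), B=300, rng=rng)
        assert pooled.pooled.between_var == pytest.approx(0.0, abs=1e-12)
        assert pooled.estimate == pytest.approx(single[0])

    def test_ci_low_never_exceeds_ci_high(self):
        frame = toy_frame(n=60, seed=7)
        comp = pooled_contrast([frame], ("CM2", "CM1"), B=200,
                               rng=np.random.default_rng(2))
        assert comp.ci_low <= comp.ci_high


class TestCompareModels:
    def test_lowest_cost_model_is_reference_and_all_pairs_reported(self):
        frame = toy_frame(n=400, seed=8, n_models=3, confounded=False)
        frame.loc[frame["model"] == "CM3", "total_societal_6m"] += 3000.0
        config = RunConfig(n_bootstrap=150, rng_seed=0)
        comparisons = compare_models([frame], config)
        pairs = {c.contrast for c in comparisons}
        assert len(pairs) == 3
        means = frame.groupby("model")["total_societal_6m"].mean()
        reference = means.idxmin()
        # every contrast is oriented (costlier, cheaper); the global
        # reference appears only on the cheaper side
        assert all(b == reference or a != reference for a, b in pairs)
        assert sum(b == reference for _, b in pairs) == 2
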