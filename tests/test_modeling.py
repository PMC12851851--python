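"""Factor analysis, random-forest screening, additive-model recovery, and trend tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kelpcohorts.modeling import (
    CohortLongevityModel,
    CohortSizeModel,
    factor_model,
    screen_predictors,
    trend_tests,
    varimax,
)
from kelpcohorts.simulate import simulate_cohort_table


def _block_data(n=200, seed=0):
    """Two independent latent blocks: size-like {N, singles, PA} and
    longevity-like {life_mn, st_max_mn}."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(0, 1, n)
    f2 = rng.normal(0, 1, n)
    eps = lambda: rng.normal(0, 0.3, n)  # noqa: E731
    return pd.DataFrame({
        "N": f1 + eps(), "singles": 0.9 * f1 + eps(), "PA": 0.8 * f1 + eps(),
        "life_mn": f2 + eps(), "st_max_mn": 0.85 * f2 + eps(),
    })


class TestFactorModel:
    def test_varimax_rotation_is_orthogonal(self):
        rng = np.random.default_rng(1)
        L = rng.normal(0, 1, (8, 2))
        _, R = varimax(L)
        assert np.allclose(R @ R.T, np.eye(2), atol=1e-8)

    def test_block_structure_recovered(self):
        res = factor_model(_block_data(), n_factors=2)
        blocks = [set(res.dominant_block(j)) for j in range(2)]
        assert {"N", "singles", "PA"} in blocks
        assert {"life_mn", "st_max_mn"} in blocks

    def test_variance_shares_sum_below_one_and_ordered(self):
        res = factor_model(_block_data(), n_factors=2)
        assert 0 < res.variance_share.sum() <= 1.0
        assert res.variance_share[0] >= res.variance_share[1]
        # two strong 2-3 variable blocks out of 5 variables each carry >25%
        assert res.variance_share.min() > 0.25

    def test_pure_noise_no_dominant_factor(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, (300, 6)),
                         columns=[f"x{i}" for i in range(6)])
        res = factor_model(X, n_factors=2)
        assert res.variance_share.max() < 0.35

    def test_loadings_reproduce_correlation(self):
        data = _block_data(n=2000, seed=4)
        res = factor_model(data, n_factors=2)
        L = res.loadings.to_numpy()
        psi = res.uniquenesses.to_numpy()
        implied = L @ L.T + np.diag(psi)
        observed = np.corrcoef(((data - data.mean()) / data.std()).to_numpy(), rowvar=False)
        assert np.abs(implied - observed).max() < 0.1

    def test_too_few_inputs_rejected(self):
        with pytest.raises(ValueError):
            factor_model(_block_data().iloc[:, :2], n_factors=2)
        with pytest.raises(ValueError):
            factor_model(_block_data().iloc[:2], n_factors=2)


class TestScreenPredictors:
    def test_relevant_predictor_ranked_first(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            x1 = rng.normal(0, 1, 120)
            x2 = rng.normal(0, 1, 120)
            y = 3 * x1 + rng.normal(0, 0.5, 120)
            df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            rank = screen_predictors(df, "y", n_trees=100, seed=seed)
            hits += rank["predictor"].iloc[0] == "x1"
        assert hits >= 9

    def test_irrelevant_predictors_near_zero(self):
        # permutation null: with y independent of all predictors, importances
        # scatter around zero across replicate data sets
        means = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "y": rng.normal(0, 1, 150),
                "x1": rng.normal(0, 1, 150), "x2": rng.normal(0, 1, 150),
            })
            rank = screen_predictors(df, "y", n_trees=100, seed=seed)
            means.append(rank["importance_mean"].to_numpy())
        means = np.array(means)
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert np.all(np.abs(grand) < 3 * se + 0.05)

    def test_deterministic_given_seed(self):
        df = simulate_cohort_table(60, seed=2)[["N", "Ad", "understory_1yr", "temp80"]]
        r1 = screen_predictors(df, "N", seed=7)
        r2 = screen_predictors(df, "N", seed=7)
        pd.testing.assert_frame_equal(r1, r2)


def _monotone_fraction(values, decreasing=False):
    d = np.diff(values)
    return np.mean(d <= 1e-12) if decreasing else np.mean(d >= -1e-12)


@pytest.fixture(scope="module")
def size_fit():
    table = simulate_cohort_table(150, seed=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CohortSizeModel.from_frame(table).fit()


class TestAdditiveModels:
    def test_size_model_smooth_shapes(self, size_fit):
        ad = size_fit.smooth_values("Ad")["partial"].to_numpy()
        und = size_fit.smooth_values("understory_1yr")["partial"].to_numpy()
        assert _monotone_fraction(ad) >= 0.9            # increasing in prior adults
        assert _monotone_fraction(und, True) >= 0.9     # decreasing in understory

    def test_size_model_fit_statistics(self, size_fit):
        assert 0.0 <= size_fit.deviance_explained <= 1.0
        assert (size_fit.smooth_table["edf"] >= 0).all()
        assert size_fit.params_table["term"].iloc[0] == "(Intercept)"

    def test_summary_has_table_shape(self, size_fit):
        s = size_fit.summary()
        assert "Parametric coefficients" in s
        assert "s(Adults)" in s and "s(Understory)" in s
        assert "deviance explained" in s

    def test_planted_decade_deficit_detected(self):
        table = simulate_cohort_table(200, seed=11, decade_effects={"2020s": -0.9})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CohortSizeModel.from_frame(table).fit(select_penalty=False)
        row = fit.params_table.set_index("term").loc["decade2020"]
        assert row["Estimate"] < 0

    def test_longevity_negative_temperature_effect(self):
        table = simulate_cohort_table(150, seed=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CohortLongevityModel.from_frame(table).fit()
        temp = fit.smooth_values("temp80")["partial"].to_numpy()
        assert _monotone_fraction(temp, True) >= 0.9

    def test_longevity_wave_response_rise_and_fall(self):
        table = simulate_cohort_table(400, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CohortLongevityModel.from_frame(table).fit()
        sv = fit.smooth_values("wave80")
        x, y = sv["wave80"].to_numpy(), sv["partial"].to_numpy()
        # planted response rises to ~4000, declines past ~6800: the fitted
        # smooth is higher mid-range than at either extreme
        low = y[x < 1500].mean()
        mid = y[(x > 4000) & (x < 6800)].mean()
        high = y[x > 9000].mean()
        assert mid > low and mid > high

    def test_living_cohorts_excluded(self):
        table = simulate_cohort_table(80, seed=14)
        table.loc[:9, "alive"] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = CohortSizeModel.from_frame(table)
        assert len(model.data) == 70


class TestTrendTests:
    def test_declining_cohort_size_detected(self):
        rng = np.random.default_rng(0)
        onset = rng.uniform(1983, 2023, 150)
        n = rng.poisson(np.exp(5.0 - 0.035 * (onset - 1983)))  # halving per ~20 yr
        table = pd.DataFrame({"N": n + 1, "onset_date": onset,
                              "pulsed": rng.choice(["pulsed", "trickled"], 150)})
        res = trend_tests(table)
        assert res.slope < 0
        assert res.p_linear < 0.01
        assert res.f_df == (1, 148)

    def test_constant_size_zero_slope(self):
        table = pd.DataFrame({"N": [20] * 30, "onset_date": np.linspace(1990, 2020, 30),
                              "pulsed": ["pulsed", "trickled"] * 15})
        res = trend_tests(table)
        assert res.slope == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_logit_flagged(self):
        table = pd.DataFrame({"N": np.arange(1, 21), "onset_date": np.linspace(1990, 2020, 20),
                              "pulsed": ["pulsed"] * 20})
        res = trend_tests(table)
        assert res.degenerate_logit
        assert np.isnan(res.logit_coef)

    def test_trickling_trend_detected(self):
        rng = np.random.default_rng(5)
        onset = rng.uniform(1983, 2023, 200)
        p_trick = 1 / (1 + np.exp(-(onset - 2003) * 0.2))
        lab = np.where(rng.random(200) < p_trick, "trickled", "pulsed")
        table = pd.DataFrame({"N": rng.poisson(30, 200) + 1, "onset_date": onset, "pulsed": lab})
        res = trend_tests(table)
        assert res.logit_coef > 0
        assert res.p_logit < 0.01
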