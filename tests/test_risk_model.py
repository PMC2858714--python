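"""Logistic risk models: scaling, prediction, unbalanced-data corrections."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import smallarea as sa
from smallarea.errors import ConfigurationError, FittingError, ParameterError
from smallarea.risk_model import (
    CenteredScaler,
    LogitRiskModel,
    _design,
    kz_bias,
    prior_correction,
)


def _simulate_observations(true_beta, n, seed, scaler):
    """Draw (pop, max_combs, label) rows from a known logistic law."""
    rng = np.random.default_rng(seed)
    pop = np.exp(rng.uniform(np.log(200), np.log(78_457), n))
    mc = np.exp(rng.uniform(np.log(6), np.log(250_000), n))
    X = _design(pop, mc, scaler)
    y = rng.binomial(1, expit(X @ np.asarray(true_beta)))
    return pd.DataFrame(
        {"pop": pop.astype(int), "max_combs": mc.astype(int), "I05": y, "I20": y}
    )


SCALER = CenteredScaler(15_000.0, 40_000.0)


class TestCenterScale:
    def test_identity_at_centre(self):
        pop_cs, mc_cs = sa.center_scale(15_000, 40_000, SCALER)
        assert pop_cs == 0.0 and mc_cs == 0.0

    def test_unit_step(self):
        scaler = CenteredScaler(10_000.0, 0.0)
        assert sa.center_scale(20_000, 0, scaler)[0] == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        scaler = CenteredScaler(0.0, 1_000.0)
        assert sa.center_scale(0, 3_240, scaler)[1] == pytest.approx(0.224)

    def test_zero_scale_rejected(self):
        with pytest.raises(ParameterError):
            CenteredScaler(0.0, 0.0, scale=0.0)


class TestPrediction:
    def test_published_models_saturate_at_centering_point(self):
        for label, intercept in [("5%", 779.1), ("20%", 63.3)]:
            model = sa.published_model(label, scaler=SCALER)
            pi = model.predict_probability(15_000, 40_000)
            assert pi == pytest.approx(expit(intercept))
            assert pi > 0.999

    def test_zero_coefficients_give_half(self):
        model = LogitRiskModel("5%", 0.0, 0.0, 0.0, 0.0, scaler=SCALER)
        assert model.predict_probability(123, 456) == pytest.approx(0.5)

    def test_extreme_logits_are_stable(self):
        model = LogitRiskModel("5%", 1e3, -1e3, 0.0, 0.0, scaler=SCALER)
        probs = model.predict_probability(
            np.array([200, 78_457]), np.array([48, 48])
        )
        assert np.all(np.isfinite(probs))
        assert probs[0] == pytest.approx(1.0)

    def test_published_model_without_scaler_warns_then_refuses(self):
        with pytest.warns(UserWarning):
            model = sa.published_model("5%")
        with pytest.raises(ConfigurationError):
            model.predict_probability(1_000, 48)

    def test_published_5pct_logit_decreasing_in_pop(self):
        model = sa.published_model("5%", scaler=SCALER)
        pops = np.linspace(200, 78_457, 50)
        logits = model.logit(pops, np.full_like(pops, SCALER.maxcombs_center))
        assert np.all(np.diff(logits) < 0)


class TestFlag:
    def test_cutoff_half_equals_logit_sign(self):
        model = LogitRiskModel("5%", 0.3, -2.0, 1.5, -0.2, scaler=SCALER)
        pops = np.array([300, 3_000, 30_000, 70_000])
        mcs = np.array([6, 480, 13_728, 250_000])
        by_prob = sa.flag_small_area(model, pops, mcs)
        assert np.array_equal(by_prob, model.logit(pops, mcs) > 0)

    def test_exactly_half_not_flagged(self):
        model = LogitRiskModel("5%", 0.0, 0.0, 0.0, 0.0, scaler=SCALER)
        assert not sa.flag_small_area(model, 1_000, 48)

    def test_low_risk_region_not_flagged(self):
        df = _simulate_observations((-1.0, -4.0, 3.0, -0.5), 4_000, 1, SCALER)
        model = sa.fit_downsampled(df, "I05", seed=2, scaler=SCALER)
        # huge population, tiny MaxCombs: far inside the low-risk region
        assert not sa.flag_small_area(model, 78_000, 6)

    def test_invalid_cutoff_rejected(self):
        model = LogitRiskModel("5%", 0.0, 0.0, 0.0, 0.0, scaler=SCALER)
        with pytest.raises(ParameterError):
            sa.flag_small_area(model, 100, 48, cutoff=1.0)


class TestPriorCorrection:
    def test_balanced_data_no_correction(self):
        assert prior_correction(0.5, 0.5) == 0.0

    def test_one_to_three_imbalance_gives_ln3(self):
        assert prior_correction(0.25, 0.5) == pytest.approx(math.log(3.0))

    @given(
        tau=st.floats(0.01, 0.99),
        ybar=st.floats(0.01, 0.99),
    )
    def test_correction_antisymmetry(self, tau, ybar):
        assert prior_correction(tau, ybar) == pytest.approx(
            -prior_correction(ybar, tau), abs=1e-9
        )


class TestFitting:
    def test_downsampled_fit_recovers_truth(self):
        true = (-1.5, -3.0, 2.5, -0.8)
        df = _simulate_observations(true, 30_000, 7, SCALER)
        model = sa.fit_downsampled(df, "I05", seed=1, scaler=SCALER)
        assert np.allclose(model.coefficients, true, atol=0.5)

    def test_scaler_defaults_to_training_means(self):
        df = _simulate_observations((-1.0, -2.0, 2.0, -0.5), 5_000, 3, SCALER)
        model = sa.fit_downsampled(df, "I05", seed=1)
        assert model.scaler.pop_center == pytest.approx(df["pop"].mean())
        assert model.scaler.maxcombs_center == pytest.approx(df["max_combs"].mean())
        assert model.scaler.scale == 10_000.0

    def test_single_class_is_fitting_error(self):
        df = pd.DataFrame(
            {"pop": [100, 200], "max_combs": [48, 48], "I05": [0, 0], "I20": [0, 0]}
        )
        for fit in (lambda: sa.fit_downsampled(df, "I05", seed=0),
                    lambda: sa.fit_kz(df, "I05")):
            with pytest.raises(FittingError):
                fit()

    def test_kz_matches_plain_ml_on_large_balanced_data(self):
        true = (0.0, -2.0, 2.0, -0.5)
        df = _simulate_observations(true, 100_000, 11, SCALER)
        model = sa.fit_kz(df, "I05", scaler=SCALER)
        X = _design(
            df["pop"].to_numpy(float), df["max_combs"].to_numpy(float), SCALER
        )
        ml = sm.Logit(df["I05"].to_numpy(float), X).fit(disp=0)
        assert np.allclose(model.coefficients, ml.params, atol=0.02)

    def test_kz_beats_uncorrected_ml_with_rare_positives(self):
        """Finite-sample bias correction helps most when positives are rare."""
        true = np.array([-7.2, -2.0, 3.0, -0.5])
        rmse_ml, rmse_kz = [], []
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            pop = np.exp(rng.uniform(np.log(200), np.log(78_457), 5_000))
            mc = np.exp(rng.uniform(np.log(6), np.log(250_000), 5_000))
            X = _design(pop, mc, SCALER)
            y = rng.binomial(1, expit(X @ true))
            if y.sum() < 5:
                continue
            try:
                b = np.asarray(sm.Logit(y, X).fit(disp=0).params)
            except Exception:
                continue
            b_kz = b - kz_bias(X, b)
            rmse_ml.append(np.sqrt(np.mean((b - true) ** 2)))
            rmse_kz.append(np.sqrt(np.mean((b_kz - true) ** 2)))
        assert len(rmse_ml) >= 30
        assert np.mean(rmse_kz) < np.mean(rmse_ml)

    def test_influential_outlier_removed(self):
        df = _simulate_observations((-0.5, -2.0, 2.0, -0.5), 400, 42, SCALER)
        df.loc[0, ["pop", "max_combs"]] = (78_457 * 3, 250_000 * 5)
        df.loc[0, "I05"] = 1
        kept, frac = sa.remove_influential(df, "I05")
        assert not kept[0]
        assert 0.0 < frac < 0.2

    def test_infinite_cutoff_removes_nothing(self):
        df = _simulate_observations((-0.5, -2.0, 2.0, -0.5), 200, 4, SCALER)
        kept, frac = sa.remove_influential(df, "I05", cutoff=np.inf)
        assert kept.all() and frac == 0.0

    def test_removal_emptying_a_class_aborts(self):
        df = _simulate_observations((-6.0, 0.0, 0.0, 0.0), 400, 9, SCALER)
        df["I05"] = 0
        df.loc[0, "I05"] = 1  # lone positive is maximally influential
        with pytest.raises(FittingError):
            sa.remove_influential(df, "I05", cutoff=1e-6)


class TestObservationsAndSerialization:
    def test_risk_observation_invariants(self):
        with pytest.raises(ParameterError):
            sa.RiskObservation(pop=0, max_combs=48)
        with pytest.raises(ParameterError):
            sa.RiskObservation(pop=10, max_combs=1)
        with pytest.raises(ParameterError):
            sa.RiskObservation(pop=10, max_combs=48, I05=0, I20=1)

    def test_fit_accepts_risk_observation_sequences(self):
        rng = np.random.default_rng(0)
        obs = [
            sa.RiskObservation(
                pop=int(p), max_combs=int(m), I05=int(i), I20=0
            )
            for p, m, i in zip(
                rng.integers(200, 78_457, 600),
                rng.integers(6, 250_000, 600),
                rng.integers(0, 2, 600),
            )
        ]
        model = sa.fit_downsampled(obs, "I05", seed=1)
        assert all(np.isfinite(model.coefficients))

    def test_model_file_round_trip(self, tmp_path):
        df = _simulate_observations((-1.0, -2.0, 2.0, -0.5), 2_000, 5, SCALER)
        model = sa.fit_downsampled(df, "I05", seed=1)
        path = tmp_path / "model.json"
        sa.save_model(model, path)
        loaded = sa.load_model(path)
        assert loaded.coefficients == model.coefficients
        assert loaded.scaler == model.scaler
        assert loaded.threshold_label == model.threshold_label
        assert loaded.provenance == model.provenance
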