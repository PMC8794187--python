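"""The explanatory item response model: mapping, response function, fit."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from jajcat import (
    DEFAULT_COEFFS,
    ExplanatoryCoefficients,
    ExplanatoryIrtModel,
    ItemParameters,
    fit_explanatory_model,
    item_information,
    linear_predictor,
    p_correct,
    predictive_accuracy,
    to_irt_params,
)
from jajcat.errors import NonIdentifiableError
from jajcat.simulation import AbilityPopulation, simulate_calibration_dataset


class TestLinearPredictor:
    @pytest.mark.parametrize(
        "length,expected",
        [(2, -0.32), (1, 1.71), (7, -3.27)],
    )
    def test_values_from_published_coefficients(self, coeffs, length, expected):
        assert linear_predictor(coeffs, length) == pytest.approx(expected, abs=1e-9)

    def test_invalid_length(self, coeffs):
        with pytest.raises(ValueError):
            linear_predictor(coeffs, 0)


class TestToIrtParams:
    def test_length2_difficulty_anchor(self, coeffs):
        """The length-2 difficulty is 0.13 on the z-score metric — the
        published quantity tying the logit and ability scales together."""
        assert to_irt_params(coeffs, 2).b == pytest.approx(0.13, abs=5e-3)

    @pytest.mark.parametrize("length,b", [(1, -0.695), (7, 1.329)])
    def test_derived_difficulties(self, coeffs, length, b):
        assert to_irt_params(coeffs, length).b == pytest.approx(b, abs=1e-3)

    def test_discrimination_equals_sigma(self, coeffs):
        assert to_irt_params(coeffs, 3).a == pytest.approx(coeffs.sigma)

    def test_difficulty_monotone_and_dummy_effect(self, coeffs):
        bs = {L: to_irt_params(coeffs, L).b for L in range(1, 10)}
        assert all(bs[L] < bs[L + 1] for L in range(2, 9))
        assert bs[1] < bs[2]

    def test_degenerate_sigma(self):
        c = ExplanatoryCoefficients(0.86, 1.44, -0.59, 0.0)
        with pytest.raises(ValueError):
            to_irt_params(c, 2)

    def test_composition_reproduces_mixed_model_probability(self, coeffs):
        """p_correct(theta, to_irt_params(L)) == logistic(lp(L) + sigma*theta)."""
        for L in range(1, 8):
            pars = to_irt_params(coeffs, L)
            for theta in (-2.5, 0.0, 0.4, 3.0):
                direct = expit(linear_predictor(coeffs, L) + coeffs.sigma * theta)
                assert p_correct(theta, pars) == pytest.approx(direct, abs=1e-14)


class TestResponseFunction:
    def test_half_probability_at_difficulty(self, length_params):
        for pars in length_params.values():
            assert p_correct(pars.b, pars) == pytest.approx(0.5)

    def test_length2_probability_at_zero(self, length_params):
        assert p_correct(0.0, length_params[2]) == pytest.approx(0.4207, abs=5e-4)

    def test_strictly_increasing_in_theta(self, length_params):
        thetas = np.linspace(-6, 6, 101)
        p = p_correct(thetas, length_params[4])
        assert np.all(np.diff(p) > 0)
        assert p[-1] > 0.999

    def test_information_peak_value(self, coeffs, length_params):
        pars = length_params[3]
        assert item_information(pars.b, pars) == pytest.approx(coeffs.sigma ** 2 / 4)
        assert item_information(pars.b + 10, pars) == pytest.approx(0.0, abs=1e-6)

    def test_information_matches_expected_loglik_curvature(self, length_params):
        """I(theta) equals minus the curvature of the expected log-likelihood
        (finite-difference oracle)."""
        pars = length_params[5]
        for theta0 in (-1.0, 0.4, 1.5):
            p0 = p_correct(theta0, pars)
            h = 1e-4

            def ell(t):
                return p0 * np.log(p_correct(t, pars)) + (1 - p0) * np.log(
                    1 - p_correct(t, pars)
                )

            curv = (ell(theta0 + h) - 2 * ell(theta0) + ell(theta0 - h)) / h ** 2
            assert -curv == pytest.approx(item_information(theta0, pars), abs=1e-4)


class TestFit:
    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's Laplace glmer on the same small dataset."""
        data = simulate_calibration_dataset(
            population=AbilityPopulation(0.0, 1.0, 100), rng=42
        )
        ours = ExplanatoryIrtModel(n_quadrature=1).fit(data).coeffs_
        csv = tmp_path / "calib.csv"
        data.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "d$l1 <- as.integer(d$length == 1);"
            "f <- glmer(correct ~ l1 + length + (1|participant_id),"
            " data=d, family=binomial);"
            "cat(fixef(f), sqrt(unlist(VarCorr(f))))"
        )
        assert shutil.which("Rscript"), "Rscript not on PATH"
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        b0, bl1, blen, sig = map(float, out.stdout.split())
        assert ours.beta0 == pytest.approx(b0, abs=5e-3)
        assert ours.beta_l1 == pytest.approx(bl1, abs=5e-3)
        assert ours.beta_len == pytest.approx(blen, abs=5e-3)
        assert ours.sigma == pytest.approx(sig, abs=5e-3)

    def test_recovery_at_calibration_scale(self):
        """N=244 on the static form: each fixed effect within 2 reported SEs
        of the generating truth."""
        data = simulate_calibration_dataset(rng=101)
        c = fit_explanatory_model(data)
        assert c.beta0 == pytest.approx(0.86, abs=2 * 0.21)
        assert c.beta_l1 == pytest.approx(1.44, abs=2 * 0.19)
        assert c.beta_len == pytest.approx(-0.59, abs=2 * 0.04)
        assert c.sigma == pytest.approx(DEFAULT_COEFFS.sigma, abs=0.4)

    def test_recovery_bias_over_replicates(self):
        """Mean estimate over replicate calibration samples deviates from
        truth by less than one reported SE (bias check)."""
        ests = []
        for seed in range(20):
            data = simulate_calibration_dataset(rng=200 + seed)
            c = fit_explanatory_model(data)
            ests.append([c.beta0, c.beta_l1, c.beta_len])
        mean = np.mean(ests, axis=0)
        for m, truth, se in zip(mean, (0.86, 1.44, -0.59), (0.21, 0.19, 0.04)):
            assert abs(m - truth) < se

    def test_sigma_zero_population(self):
        """With no between-person variance the estimated sigma collapses to
        near the boundary (an order of magnitude below the calibrated 2.46;
        marginal ML's sampling spread at the boundary — verified identical
        to lme4 — keeps it from being exactly 0 at this design size)."""
        data = simulate_calibration_dataset(
            population=AbilityPopulation(0.0, 0.0, 150), rng=9
        )
        c = fit_explanatory_model(data)
        assert c.sigma < 0.35

    def test_single_length_not_identifiable(self):
        data = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(10), 4),
                "length": 3,
                "correct": np.tile([0, 1, 1, 0], 10),
            }
        )
        with pytest.raises(NonIdentifiableError):
            fit_explanatory_model(data)

    def test_single_participant_not_identifiable(self):
        data = pd.DataFrame(
            {"participant_id": 1, "length": [2, 3, 4, 5], "correct": [1, 1, 0, 0]}
        )
        with pytest.raises(NonIdentifiableError):
            fit_explanatory_model(data)

    def test_se_magnitudes_match_published_order(self):
        data = simulate_calibration_dataset(rng=11)
        c = fit_explanatory_model(data)
        assert c.se["beta0"] == pytest.approx(0.21, abs=0.08)
        assert c.se["beta_l1"] == pytest.approx(0.19, abs=0.08)
        assert c.se["beta_len"] == pytest.approx(0.04, abs=0.02)


class TestPredictiveAccuracy:
    def test_perfect_agreement_case(self):
        """When every response equals its >0.5 classification, accuracy is 1."""
        lengths = [1, 1, 5, 5, 6, 7]
        data = pd.DataFrame(
            {
                "participant_id": np.repeat([0, 1], len(lengths)),
                "length": lengths * 2,
                # fixed effects predict correct only for length-1 items
                "correct": [1, 1, 0, 0, 0, 0] * 2,
            }
        )
        m = ExplanatoryIrtModel()
        m.coeffs_ = DEFAULT_COEFFS
        m.participants_ = np.array([0, 1])
        m.random_effects_ = np.zeros(2)
        assert predictive_accuracy(m, data, use_random_effects=False) == 1.0

    def test_accuracy_with_and_without_random_effects(self):
        """Synthetic calibration analogue: fixed-effects-only accuracy near
        71.3%, conditional accuracy near 86.7% (diagnostic, wide band)."""
        data = simulate_calibration_dataset(rng=21)
        m = ExplanatoryIrtModel().fit(data)
        fixed = predictive_accuracy(m, data, use_random_effects=False)
        cond = predictive_accuracy(m, data, use_random_effects=True)
        assert fixed == pytest.approx(0.713, abs=0.03)
        assert cond == pytest.approx(0.867, abs=0.03)
        assert cond > fixed

    def test_unfitted_model_rejected(self):
        m = ExplanatoryIrtModel()
        with pytest.raises(Exception):
            m.predict(pd.DataFrame({"participant_id": [0], "length": [2]}))

    def test_estimator_params_roundtrip(self):
        m = ExplanatoryIrtModel(n_quadrature=7)
        assert m.get_params()["n_quadrature"] == 7
        m.set_params(n_quadrature=3)
        assert m.n_quadrature == 3
        with pytest.raises(ValueError):
            m.set_params(bogus=1)
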