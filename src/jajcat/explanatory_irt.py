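"""Explanatory item response model for the JaJ task.

Item difficulty in the JaJ task is driven by a single structural feature —
sequence length — so the calibration model is an *explanatory* IRT model
(LLTM-style): a binomial mixed-effects logistic regression

    logit P(correct_ij) = beta0 + beta_l1 * [length_i == 1]
                          + beta_len * length_i + u_j,
    u_j ~ Normal(0, sigma^2),

with a per-participant random intercept ``u_j`` playing the role of ability.
The length-1 dummy absorbs the discontinuity at length 1, where recall is
likely supported by a different (echoic/short-term) mechanism and the
full-sequence guessing probability is an order of magnitude higher.

Writing ``theta = u / sigma`` for standardised ability (mean 0, SD 1 in the
calibration population) gives the equivalent one-parameter IRT form

    P(correct) = logistic(a * (theta - b)),   a = sigma,
    b(length)  = -(beta0 + beta_l1*[length==1] + beta_len*length) / sigma,

i.e. a common discrimination ``a`` and a difficulty ``b`` that is linear in
length (for length >= 2).  All item difficulties used elsewhere in the
package derive from this mapping.

Calibration maximises the *marginal* likelihood, integrating the random
intercept out per participant by the Laplace approximation (default) or
adaptive Gauss–Hermite quadrature.  No installed Python library offers this
fit for binary outcomes, so it is implemented here directly; ``lme4::glmer``
produces numerically equivalent estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from jajcat.errors import FitFailureError, NonIdentifiableError

__all__ = [
    "ExplanatoryCoefficients",
    "ItemParameters",
    "DEFAULT_COEFFS",
    "linear_predictor",
    "to_irt_params",
    "p_correct",
    "item_information",
    "ExplanatoryIrtModel",
    "fit_explanatory_model",
    "predictive_accuracy",
]


@dataclass(frozen=True)
class ExplanatoryCoefficients:
    """Fixed effects and random-intercept SD of the explanatory model.

    All values are on the logit scale.  ``sigma`` doubles as the common IRT
    discrimination once abilities are standardised.
    """

    beta0: float
    beta_l1: float
    beta_len: float
    sigma: float
    se: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def to_dict(self) -> dict:
        d = {
            "beta0": self.beta0,
            "beta_l1": self.beta_l1,
            "beta_len": self.beta_len,
            "sigma": self.sigma,
        }
        if self.se is not None:
            d["se"] = dict(self.se)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExplanatoryCoefficients":
        return cls(
            beta0=float(d["beta0"]),
            beta_l1=float(d["beta_l1"]),
            beta_len=float(d["beta_len"]),
            sigma=float(d["sigma"]),
            se=d.get("se"),
        )


@dataclass(frozen=True)
class ItemParameters:
    """IRT parameters of one item: discrimination ``a`` and difficulty ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("discrimination a must be positive")
        if not math.isfinite(self.b):
            raise ValueError("difficulty b must be finite")


#: Published calibration of the JaJ task.  The fixed effects are the reported
#: regression coefficients; sigma is anchored so that the transformed
#: difficulty of length-2 items equals 0.13 on the standardised-ability
#: metric (the one published quantity tying the two scales together):
#: b(2) = -(beta0 + 2*beta_len)/sigma = 0.32/sigma = 0.13  =>  sigma ~ 2.462.
DEFAULT_COEFFS = ExplanatoryCoefficients(
    beta0=0.86,
    beta_l1=1.44,
    beta_len=-0.59,
    sigma=0.32 / 0.13,
    se={"beta0": 0.21, "beta_l1": 0.19, "beta_len": 0.04},
)


def load_default_coefficients() -> ExplanatoryCoefficients:
    """Read the bundled default-parameters file (same values as
    :data:`DEFAULT_COEFFS`, provided as an on-disk, editable artifact)."""
    import json
    from importlib import resources

    text = resources.files("jajcat").joinpath("data/default_coefficients.json").read_text()
    return ExplanatoryCoefficients.from_dict(json.loads(text))


def linear_predictor(coeffs: ExplanatoryCoefficients, length) -> np.ndarray | float:
    """Fixed-effects linear predictor (logit scale) for items of ``length``.

    Vectorised over ``length``.
    """
    length = np.asarray(length)
    if np.any(length < 1):
        raise ValueError("length must be >= 1")
    out = coeffs.beta0 + coeffs.beta_l1 * (length == 1) + coeffs.beta_len * length
    return float(out) if out.ndim == 0 else out


def to_irt_params(coeffs: ExplanatoryCoefficients, length: int) -> ItemParameters:
    """Map the explanatory model to 1-PL IRT parameters for one item length.

    ``a = sigma`` and ``b = -linear_predictor/sigma``, so that
    ``logistic(a*(theta - b))`` equals the model probability for a person of
    standardised ability ``theta``.
    """
    if coeffs.sigma <= 0:
        raise ValueError("degenerate model: sigma must be > 0 to define the theta scale")
    eta = linear_predictor(coeffs, length)
    return ItemParameters(a=coeffs.sigma, b=-eta / coeffs.sigma)


def p_correct(theta, params: ItemParameters):
    """Probability of a correct response: ``logistic(a*(theta - b))``.

    Strictly increasing in ``theta``; no guessing asymptote (the length-1
    anomaly is handled by the dummy in the difficulty model, not a 3-PL c).
    """
    theta = np.asarray(theta, dtype=float)
    out = expit(params.a * (theta - params.b))
    return float(out) if out.ndim == 0 else out


def item_information(theta, params: ItemParameters):
    """Fisher information ``a^2 * p * (1-p)``; maximal at ``theta == b``."""
    p = p_correct(theta, params)
    return params.a ** 2 * p * (1.0 - p)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _design(data: pd.DataFrame):
    """Validate a long response table and return arrays for fitting."""
    required = {"participant_id", "length", "correct"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long response table lacks columns: {sorted(missing)}")
    lengths = np.asarray(data["length"], dtype=float)
    y = np.asarray(data["correct"], dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("correct must be 0/1")
    pid, groups = np.unique(np.asarray(data["participant_id"]), return_inverse=True)
    if len(pid) < 2:
        raise NonIdentifiableError("need >= 2 participants to identify the random intercept")
    if len(np.unique(lengths[lengths > 1])) < 2:
        raise NonIdentifiableError(
            "need >= 2 distinct lengths > 1 to separate intercept and length effect"
        )
    return lengths, y, groups, len(pid)


class ExplanatoryIrtModel:
    """Marginal-ML calibration of the explanatory model (estimator idiom).

    Parameters
    ----------
    n_quadrature:
        Number of adaptive Gauss–Hermite nodes used to integrate the random
        intercept.  ``1`` is the Laplace approximation (the reference
        mixed-model default); 7–15 nodes give adaptive quadrature.
    tol:
        Convergence tolerance passed to the outer optimiser.
    max_iter:
        Maximum outer optimiser iterations.

    Attributes (after :meth:`fit`)
    ------------------------------
    coeffs_ : ExplanatoryCoefficients
        Fitted fixed effects, their standard errors, and sigma.
    random_effects_ : ndarray, shape (n_participants,)
        Posterior-mode intercepts ``u_j`` (logit scale) at the optimum.
    participants_ : ndarray
        Participant labels matching ``random_effects_``.
    loglik_ : float
        Maximised marginal log-likelihood.
    converged_ : bool
    """

    def __init__(self, n_quadrature: int = 1, tol: float = 1e-8, max_iter: int = 500):
        self.n_quadrature = n_quadrature
        self.tol = tol
        self.max_iter = max_iter

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_quadrature": self.n_quadrature, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "ExplanatoryIrtModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _posterior_modes(eta_fix, y, groups, n_groups, sigma2, n_iter=50, tol=1e-10):
        """Newton solve for the per-participant conditional modes u_j."""
        u = np.zeros(n_groups)
        for _ in range(n_iter):
            eta = eta_fix + u[groups]
            p = expit(eta)
            grad = np.bincount(groups, weights=y - p, minlength=n_groups) - u / sigma2
            hess = -np.bincount(groups, weights=p * (1 - p), minlength=n_groups) - 1.0 / sigma2
            step = grad / hess
            u -= step
            if np.max(np.abs(step)) < tol:
                break
        return u

    def _neg_marginal_loglik(self, params, lengths, y, groups, n_groups, nodes, weights):
        beta0, beta_l1, beta_len, log_sigma = params
        sigma = math.exp(log_sigma)
        sigma2 = sigma * sigma
        eta_fix = beta0 + beta_l1 * (lengths == 1) + beta_len * lengths
        u = self._posterior_modes(eta_fix, y, groups, n_groups, sigma2)

        eta = eta_fix + u[groups]
        p = expit(eta)
        # negative curvature of the joint log-density at the mode, per group
        h = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        s = 1.0 / np.sqrt(h)  # Laplace scale

        if len(nodes) == 1:
            # Laplace: log ∫ e^f du ≈ f(û) + ½ log(2π) − ½ log h
            ll_data = np.bincount(
                groups, weights=y * log_expit(eta) + (1 - y) * log_expit(-eta),
                minlength=n_groups,
            )
            logf = ll_data - u ** 2 / (2 * sigma2) - 0.5 * math.log(2 * math.pi) - math.log(sigma)
            ll = logf + 0.5 * math.log(2 * math.pi) - 0.5 * np.log(h)
        else:
            # adaptive GH centred at û with scale s: ∫ e^f = Σ_k w̃_k s e^{f(û+s z_k)+z_k²/2}
            uk = u[:, None] + s[:, None] * nodes[None, :]  # (G, K)
            etak = eta_fix[:, None] + uk[groups]  # (N, K)
            ll_data = np.zeros((n_groups, len(nodes)))
            term = y[:, None] * log_expit(etak) + (1 - y)[:, None] * log_expit(-etak)
            for k in range(len(nodes)):
                ll_data[:, k] = np.bincount(groups, weights=term[:, k], minlength=n_groups)
            logf = (
                ll_data
                - uk ** 2 / (2 * sigma2)
                - 0.5 * math.log(2 * math.pi)
                - math.log(sigma)
                + nodes[None, :] ** 2 / 2
            )
            m = logf.max(axis=1, keepdims=True)
            integral = np.sum(weights[None, :] * np.exp(logf - m), axis=1)
            ll = m[:, 0] + np.log(s * integral)
        return -float(np.sum(ll))

    # -- public API --------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None) -> "ExplanatoryIrtModel":
        """Fit to a long response table (participant_id, length, correct)."""
        lengths, resp, groups, n_groups = _design(data)
        if self.n_quadrature < 1:
            raise ValueError("n_quadrature must be >= 1")
        if self.n_quadrature == 1:
            nodes = np.array([0.0])
            weights = np.array([1.0])
        else:
            # probabilists' Hermite rule: ∫ g(z) e^{−z²/2} dz ≈ Σ w_k g(z_k)
            nodes, weights = hermegauss(self.n_quadrature)

        args = (lengths, resp, groups, n_groups, nodes, weights)
        x0 = np.array([0.5, 1.0, -0.5, 0.5])  # mild generic start; log_sigma=0.5
        res = minimize(
            self._neg_marginal_loglik, x0, args=args, method="Nelder-Mead",
            options={"xatol": self.tol, "fatol": self.tol, "maxiter": 4000},
        )
        res = minimize(
            self._neg_marginal_loglik, res.x, args=args, method="BFGS",
            options={"gtol": 1e-6, "maxiter": self.max_iter},
        )
        if not np.all(np.isfinite(res.x)):
            raise FitFailureError(f"optimiser returned non-finite parameters: {res.x}")

        beta = res.x[:3]
        sigma = math.exp(res.x[3])
        se = self._fixed_effect_se(res.x, args)
        self.coeffs_ = ExplanatoryCoefficients(
            beta0=float(beta[0]), beta_l1=float(beta[1]), beta_len=float(beta[2]),
            sigma=float(sigma),
            se={"beta0": se[0], "beta_l1": se[1], "beta_len": se[2]},
        )
        eta_fix = beta[0] + beta[1] * (lengths == 1) + beta[2] * lengths
        self.random_effects_ = self._posterior_modes(
            eta_fix, resp, groups, n_groups, max(sigma, 1e-12) ** 2
        )
        self.participants_ = np.unique(np.asarray(data["participant_id"]))
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success or res.status == 2)  # 2: precision loss, usually benign
        self._groups_cache = None
        return self

    def _fixed_effect_se(self, xhat, args):
        """Standard errors from a central-difference Hessian of −logL."""
        f = self._neg_marginal_loglik
        n = len(xhat)
        h = 1e-4 * np.maximum(1.0, np.abs(xhat))
        H = np.zeros((n, n))
        f0 = f(xhat, *args)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(xhat + ei, *args) - 2 * f0 + f(xhat - ei, *args)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(xhat + ei + ej, *args) - f(xhat + ei - ej, *args)
                        - f(xhat - ei + ej, *args) + f(xhat - ei - ej, *args)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return se[:3]

    def predict_proba(self, data: pd.DataFrame, use_random_effects: bool = False) -> np.ndarray:
        """P(correct) per row; conditional on fitted intercepts if requested."""
        if not hasattr(self, "coeffs_"):
            raise FitFailureError("model is not fitted")
        eta = linear_predictor(self.coeffs_, np.asarray(data["length"], dtype=float))
        if use_random_effects:
            lookup = {p: u for p, u in zip(self.participants_, self.random_effects_)}
            eta = eta + np.array([lookup.get(p, 0.0) for p in data["participant_id"]])
        return expit(eta)

    def predict(self, data: pd.DataFrame, use_random_effects: bool = False) -> np.ndarray:
        """Classify each response as correct iff predicted probability > 0.5."""
        return (self.predict_proba(data, use_random_effects) > 0.5).astype(int)


def fit_explanatory_model(data: pd.DataFrame, n_quadrature: int = 1) -> ExplanatoryCoefficients:
    """Fit the explanatory model and return its coefficients."""
    return ExplanatoryIrtModel(n_quadrature=n_quadrature).fit(data).coeffs_


def predictive_accuracy(
    model: ExplanatoryIrtModel, data: pd.DataFrame, use_random_effects: bool
) -> float:
    """Fraction of responses matching the model's >0.5 classification.

    With ``use_random_effects`` the prediction is conditional on each
    participant's estimated intercept; otherwise it uses fixed effects only
    (the same classification for everyone at a given length).
    """
    pred = model.predict(data, use_random_effects=use_random_effects)
    y = np.asarray(data["correct"], dtype=int)
    return float(np.mean(pred == y))
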