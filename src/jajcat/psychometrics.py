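"""Reliability and reporting statistics.

Includes the IRT-side reliability measures (empirical marginal reliability
from SEMs), the classical-test-theory side (Cronbach's alpha on the binary
item matrix), the accuracy-by-length descriptive regression, and the
conversion of standardised ability back to the task's complex-span scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from jajcat.explanatory_irt import (
    DEFAULT_COEFFS,
    ExplanatoryCoefficients,
    linear_predictor,
)

__all__ = [
    "ScoreSet",
    "SpanEstimate",
    "marginal_reliability",
    "cronbach_alpha",
    "accuracy_by_length",
    "theta_to_span",
    "marginal_p_correct",
]


@dataclass(frozen=True)
class ScoreSet:
    """Matched ability estimates and their SEMs."""

    theta_hats: tuple[float, ...]
    sems: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.theta_hats) != len(self.sems):
            raise ValueError("theta_hats and sems must have equal length")
        if any(s <= 0 for s in self.sems):
            raise ValueError("sems must be positive")


@dataclass(frozen=True)
class SpanEstimate:
    """A complex-span estimate on the task scale (positions, 0..7)."""

    span: float
    in_range: bool


def marginal_reliability(theta_hats, sems=None) -> float:
    """Empirical marginal reliability: ``1 - mean(sem^2) / var(theta_hat)``.

    The IRT analogue of Cronbach's alpha, computed from the standard errors
    of measurement.  May be negative for pathological inputs (returned as-is
    with a warning).
    """
    if isinstance(theta_hats, ScoreSet):
        th = np.asarray(theta_hats.theta_hats, dtype=float)
        se = np.asarray(theta_hats.sems, dtype=float)
    else:
        th = np.asarray(theta_hats, dtype=float)
        se = np.asarray(sems, dtype=float)
    if len(th) < 2:
        raise ValueError("need at least 2 scores")
    var = float(np.var(th, ddof=1))
    if var == 0:
        raise ValueError("undefined reliability: zero score variance")
    rxx = 1.0 - float(np.mean(se ** 2)) / var
    if rxx < 0:
        warnings.warn(f"negative marginal reliability ({rxx:.3f})", stacklevel=2)
    return rxx


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a persons x items score matrix.

    ``(k/(k-1)) * (1 - sum of item variances / total-score variance)``;
    invariant under permutation of the item columns.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 persons and >= 2 items")
    k = X.shape[1]
    total_var = float(np.var(X.sum(axis=1), ddof=1))
    if total_var == 0:
        raise ValueError("undefined alpha: zero total-score variance")
    item_var = float(np.sum(np.var(X, axis=0, ddof=1)))
    return k / (k - 1) * (1.0 - item_var / total_var)


def marginal_p_correct(
    length: int,
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
    population=(0.0, 1.0),
    n_nodes: int = 201,
) -> float:
    """Population-marginal probability of a correct response at a length:
    numerical integration of the conditional probability over a normal
    ability distribution.  Used as the oracle for accuracy regressions."""
    mean, sd = population
    z, step = np.linspace(-8, 8, n_nodes, retstep=True)
    w = norm.pdf(z) * step
    eta = linear_predictor(coeffs, length) + coeffs.sigma * (mean + sd * z)
    return float(np.sum(w / (1.0 + np.exp(-eta))) / np.sum(w))


def accuracy_by_length(responses: pd.DataFrame) -> dict:
    """Per-length accuracies with binomial SEs plus the two descriptive OLS
    fits: over all lengths, and over lengths 2..7 only (length-1 trials sit
    above the linear trend and get their own dummy in the formal model).
    """
    if not {"length", "correct"} <= set(responses.columns):
        raise ValueError("need columns 'length' and 'correct'")
    g = responses.groupby("length")["correct"]
    table = pd.DataFrame(
        {
            "length": g.mean().index.astype(int),
            "accuracy": g.mean().to_numpy(),
            "n": g.count().to_numpy(),
        }
    )
    if len(table) < 2:
        raise ValueError("fit undefined: need >= 2 distinct lengths")
    table["se"] = np.sqrt(table["accuracy"] * (1 - table["accuracy"]) / table["n"])

    def ols(sub: pd.DataFrame):
        slope, intercept = np.polyfit(sub["length"], sub["accuracy"], 1)
        return {"slope": float(slope), "intercept": float(intercept)}

    fits = {"all_lengths": ols(table)}
    sub = table[(table["length"] >= 2) & (table["length"] <= 7)]
    if len(sub) >= 2:
        fits["lengths_2_7"] = ols(sub)
    return {"table": table, "fits": fits}


def theta_to_span(
    theta: float,
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
    rule: str = "p50",
) -> SpanEstimate:
    """Convert a standardised ability back to the task's span scale.

    The default ``"p50"`` rule reads span as the (continuous) sequence
    length at which the person's success probability crosses 0.5:
    ``span = (beta0 + sigma*theta) / (-beta_len)`` (using the length >= 2
    branch of the difficulty model, so theta == b(L) maps to exactly L).
    The rule is pluggable because the published mapping is not fully
    recoverable; estimates whose rounded value falls outside the task range
    [0, 7] are flagged out-of-range and conventionally excluded from means.
    """
    if rule != "p50":
        raise ValueError(f"unknown conversion rule {rule!r}")
    span = (coeffs.beta0 + coeffs.sigma * float(theta)) / (-coeffs.beta_len)
    in_range = 0 <= round(span) <= 7
    return SpanEstimate(span=float(span), in_range=bool(in_range))
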