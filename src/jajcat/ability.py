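"""Ability estimation for the JaJ IRT model.

Two estimators are used operationally:

* **Bayes modal (BM/MAP)** — the posterior mode under a standard-normal
  prior, used for *interim* estimates inside the adaptive engine.  Its SEM by
  default includes the prior precision: ``1/sqrt(I(theta) + 1)``.
* **Warm weighted likelihood (WL)** — the maximiser of
  ``logL(theta) + 0.5*log I(theta)``, the first-order bias-corrected ML
  estimator.  It stays finite for all-correct and all-incorrect patterns and
  is used for *final* scores.  Its SEM is ``1/sqrt(I(theta))``.

Both are found as the unique root of the corresponding score equation by
bracketed root finding; an exhaustive grid search over the same objective is
provided as an independent oracle for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from jajcat.errors import EstimationError
from jajcat.explanatory_irt import ItemParameters

__all__ = [
    "AbilityEstimate",
    "SearchConfig",
    "log_likelihood",
    "estimate_bm",
    "estimate_wl",
    "estimate_ml",
    "grid_oracle",
]


@dataclass(frozen=True)
class AbilityEstimate:
    """An ability estimate on the standardised (z-score) metric."""

    theta: float
    sem: float
    method: str  # {"BM", "WL", "ML"}
    n_items: int


@dataclass(frozen=True)
class SearchConfig:
    """Search interval and prior for ability estimation.

    The interval is wider than the simulated true-ability range used in the
    published evaluations so that observed floors/ceilings are interior
    points of the search, not clipping artefacts.
    """

    bounds: tuple[float, float] = (-6.0, 6.0)
    tolerance: float = 1e-4
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    bm_sem_includes_prior: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be a finite interval with lower < upper")


DEFAULT_SEARCH = SearchConfig()


def _arrays(items: Sequence[ItemParameters], responses: Sequence[int]):
    if len(items) != len(responses):
        raise ValueError("items and responses must have equal length")
    a = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(y) and not np.all((y == 0) | (y == 1)):
        raise ValueError("responses must be 0/1")
    return a, b, y


def _p(theta: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a * (theta - b)))


def log_likelihood(
    theta: float, items: Sequence[ItemParameters], responses: Sequence[int]
) -> float:
    """Bernoulli log-likelihood of a response pattern; 0 for empty input."""
    a, b, y = _arrays(items, responses)
    if len(y) == 0:
        return 0.0
    z = a * (theta - b)
    # y*log p + (1-y)*log(1-p) with log p = -log1p(e^{-z})
    return float(np.sum(-y * np.log1p(np.exp(-z)) - (1 - y) * np.log1p(np.exp(z))))


def test_information(theta: float, items: Sequence[ItemParameters]) -> float:
    """Total Fisher information at ``theta``."""
    a = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    p = _p(theta, a, b)
    return float(np.sum(a * a * p * (1 - p)))


def _score(theta, a, b, y):
    return float(np.sum(a * (y - _p(theta, a, b))))


def _info_and_deriv(theta, a, b):
    p = _p(theta, a, b)
    info = np.sum(a * a * p * (1 - p))
    j = np.sum(a ** 3 * p * (1 - p) * (1 - 2 * p))  # dI/dtheta
    return float(info), float(j)


def _bracketed_root(f, lo, hi, tol):
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        # score function monotone-decreasing: same sign means the optimum
        # sits at (or beyond) a boundary of the search interval
        return lo if flo < 0 else hi
    return float(brentq(f, lo, hi, xtol=tol))


def estimate_bm(
    items: Sequence[ItemParameters],
    responses: Sequence[int],
    config: SearchConfig = DEFAULT_SEARCH,
) -> AbilityEstimate:
    """Bayes modal estimate under a Gaussian prior (default N(0, 1)).

    With no items the prior mode and prior SD are returned.  The posterior is
    strictly log-concave, so the mode is the unique root of the posterior
    score ``S(theta) - (theta - mu)/sd^2``.
    """
    a, b, y = _arrays(items, responses)
    mu, sd = config.prior_mean, config.prior_sd
    if len(y) == 0:
        return AbilityEstimate(theta=mu, sem=sd, method="BM", n_items=0)

    def f(th):
        return _score(th, a, b, y) - (th - mu) / sd ** 2

    theta = _bracketed_root(f, *config.bounds, config.tolerance)
    if not math.isfinite(theta):
        raise EstimationError("BM estimation failed to locate the posterior mode")
    info = test_information(theta, items)
    prior_precision = 1.0 / sd ** 2 if config.bm_sem_includes_prior else 0.0
    sem = 1.0 / math.sqrt(info + prior_precision)
    return AbilityEstimate(theta=theta, sem=sem, method="BM", n_items=len(y))


def estimate_wl(
    items: Sequence[ItemParameters],
    responses: Sequence[int],
    config: SearchConfig = DEFAULT_SEARCH,
) -> AbilityEstimate:
    """Warm weighted-likelihood estimate (bias-corrected ML).

    Root of the weighted score equation ``S(theta) + J(theta)/(2 I(theta))``
    with ``J = dI/dtheta``.  Finite for perfect and null response patterns.
    """
    a, b, y = _arrays(items, responses)
    if len(y) == 0:
        raise ValueError("WL estimation requires at least one item")

    def f(th):
        info, j = _info_and_deriv(th, a, b)
        return _score(th, a, b, y) + j / (2 * info)

    # The weighted objective logL + 0.5*log I is not globally concave: for
    # widely separated difficulties it can be bimodal.  Locate every
    # decreasing zero-crossing of the weighted score on a coarse grid and
    # keep the one with the highest objective value.
    lo, hi = config.bounds
    grid = np.linspace(lo, hi, 49)
    fg = np.array([f(t) for t in grid])
    candidates = []
    for i in range(len(grid) - 1):
        if fg[i] > 0 >= fg[i + 1]:
            candidates.append(
                float(brentq(f, grid[i], grid[i + 1], xtol=config.tolerance))
            )
    if not candidates:
        candidates = [lo if fg[0] < 0 else hi]

    def objective(th):
        p = _p(th, a, b)
        info = np.sum(a * a * p * (1 - p))
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        return ll + 0.5 * math.log(info)

    theta = max(candidates, key=objective)
    info = test_information(theta, items)
    return AbilityEstimate(
        theta=theta, sem=1.0 / math.sqrt(info), method="WL", n_items=len(y)
    )


def estimate_ml(
    items: Sequence[ItemParameters],
    responses: Sequence[int],
    config: SearchConfig = DEFAULT_SEARCH,
) -> AbilityEstimate:
    """Plain maximum likelihood; diverges to the search bounds for extreme
    patterns (kept mainly as a contrast for the WL estimator)."""
    a, b, y = _arrays(items, responses)
    if len(y) == 0:
        raise ValueError("ML estimation requires at least one item")
    theta = _bracketed_root(lambda th: _score(th, a, b, y), *config.bounds, config.tolerance)
    info = test_information(theta, items)
    return AbilityEstimate(
        theta=theta, sem=1.0 / math.sqrt(info), method="ML", n_items=len(y)
    )


def grid_oracle(
    items: Sequence[ItemParameters],
    responses: Sequence[int],
    objective: str = "BM",
    step: float = 1e-3,
    config: SearchConfig = DEFAULT_SEARCH,
) -> float:
    """Exhaustive arg-max of the chosen objective over a bounded grid.

    Reference implementation for testing the production estimators; never on
    the production path.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    a, b, y = _arrays(items, responses)
    lo, hi = config.bounds
    grid = np.arange(lo, hi + step / 2, step)
    z = a[None, :] * (grid[:, None] - b[None, :])
    logp = -np.log1p(np.exp(-z))
    log1mp = -np.log1p(np.exp(z))
    ll = logp @ y + log1mp @ (1 - y)
    if objective == "ML":
        obj = ll
    elif objective == "BM":
        obj = ll - (grid - config.prior_mean) ** 2 / (2 * config.prior_sd ** 2)
    elif objective == "WL":
        p = 1.0 / (1.0 + np.exp(-z))
        info = (a[None, :] ** 2 * p * (1 - p)).sum(axis=1)
        obj = ll + 0.5 * np.log(info)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return float(grid[int(np.argmax(obj))])
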