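"""Synthetic examinees and full study replications.

This module generates everything the package's evaluation needs: no external
data exists for the task, so calibration datasets, static-form studies and
adaptive-test studies are all simulated from the published model.

What the generator emulates: binary full-sequence recall responses drawn
from the calibrated explanatory model, for examinee populations described by
their published moments (the calibration population is standard normal by
construction; the follow-up samples are approximated as normal with the
printed mean/SD).  What it does not emulate: response times, practice or
fatigue effects, hand-judgement errors (simulees are assumed error-free on
the secondary task), and the skew/kurtosis of the real follow-up samples —
a green reliability check therefore establishes consistency with the model
world, not with every feature of the empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from jajcat.ability import estimate_wl, SearchConfig
from jajcat.cat_engine import CatConfig, run_session
from jajcat.explanatory_irt import (
    DEFAULT_COEFFS,
    ExplanatoryCoefficients,
    ItemParameters,
    linear_predictor,
    p_correct,
)
from jajcat.psychometrics import cronbach_alpha, marginal_reliability
from jajcat.task_model import ItemBank, STATIC_LENGTHS, static_form

__all__ = [
    "AbilityPopulation",
    "StudyResult",
    "simulate_response",
    "simulate_calibration_dataset",
    "simulate_static_study",
    "simulate_cat_study",
    "simulate_score_range",
    "curves_by_length",
]


@dataclass(frozen=True)
class AbilityPopulation:
    """A population of true abilities on the standardised metric.

    Either ``normal(mean, sd)`` sampled at draw time, or an explicit grid /
    list of abilities used verbatim.
    """

    mean: float = 0.0
    sd: float = 1.0
    n: int = 1000
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.values is None:
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
            if self.n < 1:
                raise ValueError("n must be >= 1")

    @classmethod
    def grid(cls, lo: float, hi: float, n: int) -> "AbilityPopulation":
        return cls(values=tuple(np.linspace(lo, hi, n)), n=n)

    @classmethod
    def fixed(cls, values: Iterable[float]) -> "AbilityPopulation":
        vals = tuple(float(v) for v in values)
        return cls(values=vals, n=len(vals))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.values is not None:
            return np.asarray(self.values, dtype=float)
        return rng.normal(self.mean, self.sd, self.n)


@dataclass
class StudyResult:
    """Per-simulee micro-data of one simulated study.

    Every summary statistic is recomputable from the stored micro-data
    (``summary()`` does exactly that and nothing else).
    """

    true_theta: np.ndarray
    theta_hat: np.ndarray
    sem: np.ndarray
    test_length: np.ndarray
    item_params: list[list[ItemParameters]]
    responses: list[np.ndarray]
    search: SearchConfig = field(default_factory=SearchConfig)

    @property
    def n_sessions(self) -> int:
        return len(self.theta_hat)

    def response_matrix(self) -> np.ndarray:
        """Persons x items 0/1 matrix (requires a common test length)."""
        if len(set(self.test_length)) != 1:
            raise ValueError("response matrix requires equal test lengths")
        return np.vstack(self.responses)

    def summary(self) -> dict:
        out = {
            "n_sessions": self.n_sessions,
            "mean_sem": float(np.mean(self.sem)),
            "marginal_reliability": marginal_reliability(self.theta_hat, self.sem),
            "score_min": float(np.min(self.theta_hat)),
            "score_max": float(np.max(self.theta_hat)),
            "score_mean": float(np.mean(self.theta_hat)),
            "score_sd": float(np.std(self.theta_hat, ddof=1)),
            "rmse_vs_true": float(
                np.sqrt(np.mean((self.theta_hat - self.true_theta) ** 2))
            ),
        }
        if len(set(self.test_length)) == 1:
            try:
                out["cronbach_alpha"] = cronbach_alpha(self.response_matrix())
            except ValueError:
                pass
        return out


def simulate_response(
    theta: float, params: ItemParameters, rng: np.random.Generator
) -> int:
    """One Bernoulli draw from the item response function."""
    return int(rng.random() < p_correct(theta, params))


def simulate_calibration_dataset(
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
    population: AbilityPopulation = AbilityPopulation(0.0, 1.0, 244),
    form_lengths: Sequence[int] = STATIC_LENGTHS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate a calibration study: every participant takes the static form.

    Responses are generated under the full mixed model — fixed effects plus
    ``sigma * theta_j`` with standardised abilities from ``population`` (the
    calibration population defaults to N(0, 1), its defining property).
    Returns the long response table consumed by the calibration fit.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if population.values is None and population.n < 2:
        raise ValueError("need at least 2 participants")
    thetas = population.draw(rng)
    lengths = np.asarray(form_lengths)
    eta = linear_predictor(coeffs, lengths)[None, :] + coeffs.sigma * thetas[:, None]
    p = 1.0 / (1.0 + np.exp(-eta))
    correct = (rng.random(p.shape) < p).astype(int)
    n, k = p.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), k),
            "item_id": np.tile([f"s{j}" for j in range(k)], n),
            "length": np.tile(lengths, n),
            "l1": np.tile((lengths == 1).astype(int), n),
            "correct": correct.ravel(),
            "true_theta": np.repeat(thetas, k),
        }
    )


def simulate_static_study(
    population: AbilityPopulation,
    bank: ItemBank | None = None,
    rng: np.random.Generator | int | None = None,
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
    search: SearchConfig = SearchConfig(),
) -> StudyResult:
    """Administer the fixed 14-item static form to every simulee.

    Scores are Warm weighted-likelihood estimates with SEM = 1/sqrt(I).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if bank is not None:
        form = static_form(bank)
        params = [bank.params[it.id] for it in form]
    else:
        from jajcat.explanatory_irt import to_irt_params

        params = [to_irt_params(coeffs, L) for L in STATIC_LENGTHS]
    thetas = population.draw(rng)
    a = np.array([pp.a for pp in params])
    b = np.array([pp.b for pp in params])
    p = 1.0 / (1.0 + np.exp(-a[None, :] * (thetas[:, None] - b[None, :])))
    resp = (rng.random(p.shape) < p).astype(int)

    theta_hat = np.empty(len(thetas))
    sems = np.empty(len(thetas))
    for i in range(len(thetas)):
        est = estimate_wl(params, resp[i], search)
        theta_hat[i] = est.theta
        sems[i] = est.sem
    return StudyResult(
        true_theta=thetas,
        theta_hat=theta_hat,
        sem=sems,
        test_length=np.full(len(thetas), len(params)),
        item_params=[params] * len(thetas),
        responses=[resp[i] for i in range(len(thetas))],
        search=search,
    )


def simulate_cat_study(
    population: AbilityPopulation,
    bank: ItemBank,
    config: CatConfig = CatConfig(),
    rng: np.random.Generator | int | None = None,
    replicates: int = 1,
) -> StudyResult:
    """Run one adaptive session per simulee (times ``replicates``)."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    thetas = np.repeat(population.draw(rng), replicates)
    theta_hat = np.empty(len(thetas))
    sems = np.empty(len(thetas))
    lengths = np.empty(len(thetas), dtype=int)
    all_params: list[list[ItemParameters]] = []
    all_resp: list[np.ndarray] = []
    for i, th in enumerate(thetas):
        log = run_session(float(th), bank, config, rng)
        theta_hat[i] = log.final.theta
        sems[i] = log.final.sem
        lengths[i] = len(log.trials)
        all_params.append([bank.params[t.item_id] for t in log.trials])
        all_resp.append(np.array([t.response for t in log.trials]))
    return StudyResult(
        true_theta=thetas,
        theta_hat=theta_hat,
        sem=sems,
        test_length=lengths,
        item_params=all_params,
        responses=all_resp,
        search=config.search,
    )


def simulate_score_range(
    bank: ItemBank,
    rng: np.random.Generator | int | None = None,
    ability_range: tuple[float, float] = (-4.0, 4.15),
    n_abilities: int = 200,
    test_lengths: Sequence[int] = tuple(range(5, 21)),
    replicates: int = 10,
) -> dict:
    """The score-range experiment: adaptive sessions across a uniform grid
    of true abilities and a sweep of fixed test lengths; reports the extreme
    and summary statistics of the final WL scores.

    Grid resolution and replicate count are desk-scale choices that leave
    the extrema stable (they are driven by all-correct / all-incorrect
    sessions at the longest length, which occur with near-certainty at the
    grid edges).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    grid = AbilityPopulation.grid(*ability_range, n_abilities)
    per_length = {}
    all_scores = []
    for L in test_lengths:
        config = CatConfig(max_items=int(L))
        res = simulate_cat_study(grid, bank, config, rng, replicates=replicates)
        per_length[int(L)] = res
        all_scores.append(res.theta_hat)
    scores = np.concatenate(all_scores)
    return {
        "score_min": float(scores.min()),
        "score_max": float(scores.max()),
        "score_mean": float(scores.mean()),
        "score_sd": float(scores.std(ddof=1)),
        "n_sessions": int(len(scores)),
        "per_length": per_length,
    }


def curves_by_length(study: StudyResult, max_len: int) -> pd.DataFrame:
    """Reliability growth curves: re-score each session truncated to its
    first k trials, for k = 1..max_len.

    Returns a frame with mean SEM(k) and marginal reliability(k); the k =
    full-length row reproduces the untruncated study summary exactly.
    """
    if max_len > int(np.min(study.test_length)):
        raise ValueError(
            f"cannot truncate beyond the shortest recorded session "
            f"({int(np.min(study.test_length))} trials)"
        )
    rows = []
    for k in range(1, max_len + 1):
        th = np.empty(study.n_sessions)
        se = np.empty(study.n_sessions)
        for i in range(study.n_sessions):
            est = estimate_wl(
                study.item_params[i][:k], study.responses[i][:k], study.search
            )
            th[i] = est.theta
            se[i] = est.sem
        rows.append(
            {
                "n_trials": k,
                "mean_sem": float(np.mean(se)),
                "median_sem": float(np.median(se)),
                "marginal_reliability": marginal_reliability(th, se),
            }
        )
    return pd.DataFrame(rows)
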