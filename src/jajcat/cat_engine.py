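"""Adaptive administration loop of the a-JaJ.

The adaptive test follows the published procedure: the first item is a
random length-2 item (difficulty 0.13, the average ability level of the
calibration population at the task's midpoint); after each response the
ability is re-estimated by Bayes modal estimation with a standard-normal
prior; the next item is drawn uniformly from the unadministered items whose
difficulty is maximally close to the interim estimate (Urry's criterion —
equivalent to maximum information when all discriminations are equal, as
here); the session ends after ``max_items`` trials (14 in the published
form) or, optionally, once the interim SEM falls below a threshold.  The
final score is a Warm weighted-likelihood estimate over all administered
items.

Because items of equal length share one difficulty, the "maximally close"
subset is typically the whole remaining pool of one length, which yields
natural exposure control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from jajcat.ability import (
    AbilityEstimate,
    SearchConfig,
    estimate_bm,
    estimate_wl,
)
from jajcat.errors import BankExhaustedError, JajError
from jajcat.explanatory_irt import ItemParameters, item_information, p_correct
from jajcat.task_model import Item, ItemBank

__all__ = [
    "CatConfig",
    "TrialRecord",
    "SessionLog",
    "CatState",
    "select_first",
    "select_next",
    "run_session",
    "simulee",
]


@dataclass(frozen=True)
class CatConfig:
    """Configuration of one adaptive administration."""

    start_length: int = 2
    max_items: int = 14
    se_threshold: float | None = None
    selection_epsilon: float = 1e-9
    search: SearchConfig = field(default_factory=SearchConfig)

    def __post_init__(self) -> None:
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")
        if self.se_threshold is not None and not self.se_threshold > 0:
            raise ValueError("se_threshold, if set, must be > 0")


@dataclass(frozen=True)
class TrialRecord:
    item_id: str
    length: int
    b: float
    response: int
    interim_theta: float
    interim_sem: float


@dataclass
class SessionLog:
    """Full trajectory of one administration."""

    trials: list[TrialRecord]
    final: AbilityEstimate
    config: CatConfig
    seed: int | None = None
    true_theta: float | None = None

    @property
    def item_ids(self) -> list[str]:
        return [t.item_id for t in self.trials]


class CatState:
    """Mutable state of an in-progress adaptive session."""

    def __init__(self, bank: ItemBank, config: CatConfig):
        self.bank = bank
        self.config = config
        self.administered: list[Item] = []
        self.responses: list[int] = []
        self.trials: list[TrialRecord] = []
        self._used: set[str] = set()
        # cached per-bank arrays: difficulty and availability by bank position
        self._pos = {it.id: i for i, it in enumerate(bank.items)}
        self._b = np.array([bank.params[it.id].b for it in bank.items])
        self._avail = np.array([not it.is_practice for it in bank.items])
        # before any response the interim estimate is the prior mode; the
        # fixed start rule means it never drives the first selection
        self.interim = estimate_bm([], [], config.search)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def available_items(self) -> list[Item]:
        return [it for it, ok in zip(self.bank.items, self._avail) if ok]

    def step(self, item: Item, response: int) -> "CatState":
        """Record a response and re-estimate ability by BM over all trials."""
        if item.id in self._used:
            raise JajError(f"item {item.id!r} was already administered")
        pos = self._pos.get(item.id)
        if pos is None or self.bank.items[pos] != item:
            raise JajError(f"item {item.id!r} is not in the bank")
        if response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        self.administered.append(item)
        self.responses.append(int(response))
        self._used.add(item.id)
        self._avail[self._pos[item.id]] = False
        params = [self.bank.params[it.id] for it in self.administered]
        self.interim = estimate_bm(params, self.responses, self.config.search)
        self.trials.append(
            TrialRecord(
                item_id=item.id,
                length=item.length,
                b=self.bank.params[item.id].b,
                response=int(response),
                interim_theta=self.interim.theta,
                interim_sem=self.interim.sem,
            )
        )
        return self

    def should_stop(self) -> bool:
        if self.n_trials >= self.config.max_items:
            return True
        thr = self.config.se_threshold
        return thr is not None and self.n_trials > 0 and self.interim.sem <= thr

    def final_estimate(self) -> AbilityEstimate:
        params = [self.bank.params[it.id] for it in self.administered]
        return estimate_wl(params, self.responses, self.config.search)


def select_first(bank: ItemBank, rng: np.random.Generator, start_length: int = 2) -> Item:
    """Start rule: a uniformly random item of the start length (default 2)."""
    pool = [it for it in bank.items_of_length(start_length) if not it.is_practice]
    if not pool:
        raise BankExhaustedError(f"bank has no length-{start_length} items")
    return pool[rng.integers(len(pool))]


def select_next(state: CatState, rng: np.random.Generator) -> Item:
    """Urry selection: uniform draw among unadministered items whose
    difficulty is (within ``selection_epsilon``) closest to the interim
    estimate."""
    if state.n_trials == 0:
        return select_first(state.bank, rng, state.config.start_length)
    if not state._avail.any():
        raise BankExhaustedError("no unadministered items remain")
    d = np.where(state._avail, np.abs(state._b - state.interim.theta), np.inf)
    idx = np.flatnonzero(d <= d.min() + state.config.selection_epsilon)
    return state.bank.items[idx[rng.integers(len(idx))]]


def max_information_candidates(state: CatState) -> set[str]:
    """Ids of unadministered items with maximal Fisher information at the
    interim estimate.  With equal discriminations this coincides with the
    Urry (closest-difficulty) candidate set; kept as a cross-check."""
    pool = state.available_items()
    theta = state.interim.theta
    infos = np.array([item_information(theta, state.bank.params[it.id]) for it in pool])
    best = infos >= infos.max() - 1e-12
    return {it.id for it, ok in zip(pool, best) if ok}


def simulee(true_theta: float, rng: np.random.Generator) -> Callable[[Item, ItemParameters], int]:
    """A responder that answers Bernoulli(p_correct(true_theta, item))."""

    def respond(item: Item, params: ItemParameters) -> int:
        return int(rng.random() < p_correct(true_theta, params))

    return respond


def run_session(
    responder: float | Callable[[Item, ItemParameters], int],
    bank: ItemBank,
    config: CatConfig = CatConfig(),
    rng: np.random.Generator | int | None = None,
) -> SessionLog:
    """Administer one full adaptive session.

    ``responder`` is either a true ability (a float — responses are then
    Bernoulli draws from the model) or a callback ``(item, params) -> 0/1``
    for live administration.
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    true_theta = None
    if isinstance(responder, (int, float, np.floating)) and not callable(responder):
        true_theta = float(responder)
        responder = simulee(true_theta, rng)

    state = CatState(bank, config)
    while not state.should_stop():
        item = select_next(state, rng)
        response = responder(item, bank.params[item.id])
        state.step(item, response)
    return SessionLog(
        trials=state.trials,
        final=state.final_estimate(),
        config=config,
        seed=seed,
        true_theta=true_theta,
    )


# ---------------------------------------------------------------------------
# JSONL serialisation (one trial per line + a final record per session)
# ---------------------------------------------------------------------------


def session_to_lines(log: SessionLog, session_id: str) -> list[str]:
    lines = []
    for i, t in enumerate(log.trials):
        rec = {"session": session_id, "type": "trial", "trial": i + 1, **asdict(t)}
        lines.append(json.dumps(rec))
    fin = {
        "session": session_id,
        "type": "final",
        "theta": log.final.theta,
        "sem": log.final.sem,
        "method": log.final.method,
        "n_items": log.final.n_items,
        "seed": log.seed,
        "true_theta": log.true_theta,
        "max_items": log.config.max_items,
        "se_threshold": log.config.se_threshold,
    }
    lines.append(json.dumps(fin))
    return lines
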