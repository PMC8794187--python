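"""Item structure, automated generation and scoring for the JaJ task.

A JaJ *item* is one trial: a sequence of ball positions drawn from the six
marked screen positions, paired with a same/different hand judgement at each
presentation.  The recall response is scored all-or-nothing: 1 only if the
whole position sequence is reproduced in order.  Item length (1–7 in the
published forms, extensible upward) is the difficulty driver.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from jajcat.errors import BankExhaustedError, FormatError
from jajcat.explanatory_irt import (
    DEFAULT_COEFFS,
    ExplanatoryCoefficients,
    ItemParameters,
    to_irt_params,
)

N_POSITIONS = 6  #: the six marked screen positions, labelled 1..6
STATIC_LENGTHS = (1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7)  #: the 14-trial static form

__all__ = [
    "N_POSITIONS",
    "STATIC_LENGTHS",
    "Item",
    "ItemBank",
    "ResponseRecord",
    "generate_item",
    "generate_bank",
    "score_sequence",
    "guess_probability",
    "static_form",
]


@dataclass(frozen=True)
class Item:
    """One trial: ball-position sequence plus hand-judgement ground truth."""

    id: str
    length: int
    ball_seq: tuple[int, ...]
    hand_same_seq: tuple[bool, ...]
    is_practice: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if len(self.ball_seq) != self.length or len(self.hand_same_seq) != self.length:
            raise ValueError("ball_seq and hand_same_seq must both have `length` entries")
        if any(p < 1 or p > N_POSITIONS for p in self.ball_seq):
            raise ValueError(f"ball positions must lie in 1..{N_POSITIONS}")
        if self.is_practice and self.length > 2:
            raise ValueError("practice items are restricted to lengths 1 and 2")


@dataclass(frozen=True)
class ResponseRecord:
    """A scored response to one item."""

    item_id: str
    clicked_seq: tuple[int, ...]
    hand_judgements: tuple[bool, ...]
    seq_correct: int
    hand_n_correct: int


@dataclass
class ItemBank:
    """A seeded, serialisable collection of items with attached IRT parameters.

    Items of equal length share identical parameters (difficulty is a
    deterministic function of length under the explanatory model).
    """

    items: list[Item]
    params: dict[str, ItemParameters]
    generator_seed: int | None = None
    coeffs: ExplanatoryCoefficients = field(default=DEFAULT_COEFFS)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise FormatError("item ids must be unique within a bank")
        missing = [i for i in ids if i not in self.params]
        if missing:
            raise FormatError(f"items without parameters: {missing[:5]}")

    @property
    def lengths(self) -> set[int]:
        return {it.length for it in self.items}

    def items_of_length(self, length: int) -> list[Item]:
        return [it for it in self.items if it.length == length]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.generator_seed,
                "coeffs": self.coeffs.to_dict(),
                "items": [
                    {
                        "id": it.id,
                        "length": it.length,
                        "ball_seq": list(it.ball_seq),
                        "hand_same_seq": list(it.hand_same_seq),
                        "is_practice": it.is_practice,
                        "a": self.params[it.id].a,
                        "b": self.params[it.id].b,
                    }
                    for it in self.items
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ItemBank":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as e:
            raise FormatError(f"bank is not valid JSON: {e}") from e
        if not isinstance(obj, dict) or "items" not in obj:
            raise FormatError("bank JSON must be an object with an 'items' array")
        items: list[Item] = []
        params: dict[str, ItemParameters] = {}
        for rec in obj["items"]:
            iid = rec.get("id")
            for key in ("id", "length", "ball_seq", "hand_same_seq", "a", "b"):
                if key not in rec:
                    raise FormatError(f"item {iid!r}: missing field '{key}'")
            items.append(
                Item(
                    id=rec["id"],
                    length=int(rec["length"]),
                    ball_seq=tuple(int(p) for p in rec["ball_seq"]),
                    hand_same_seq=tuple(bool(h) for h in rec["hand_same_seq"]),
                    is_practice=bool(rec.get("is_practice", False)),
                )
            )
            params[rec["id"]] = ItemParameters(a=float(rec["a"]), b=float(rec["b"]))
        coeffs = (
            ExplanatoryCoefficients.from_dict(obj["coeffs"])
            if "coeffs" in obj
            else DEFAULT_COEFFS
        )
        return cls(items=items, params=params, generator_seed=obj.get("seed"), coeffs=coeffs)


def generate_item(
    length: int,
    rng: np.random.Generator,
    item_id: str | None = None,
    is_practice: bool = False,
) -> Item:
    """Generate one random item of the given length.

    Ball positions are i.i.d. uniform over the six positions (repeats
    permitted); hand judgements are i.i.d. uniform over same/different.
    Deterministic given the generator state.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    ball_seq = tuple(int(p) for p in rng.integers(1, N_POSITIONS + 1, size=length))
    hand_seq = tuple(bool(h) for h in rng.integers(0, 2, size=length))
    if item_id is None:
        item_id = "p" if is_practice else "i"
        item_id += f"{length}-" + "".join(str(p) for p in ball_seq)
        item_id += "-" + format(int(rng.integers(0, 16 ** 6)), "06x")
    return Item(
        id=item_id, length=length, ball_seq=ball_seq, hand_same_seq=hand_seq,
        is_practice=is_practice,
    )


def generate_bank(
    lengths: Iterable[int],
    per_length: int,
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
    rng: np.random.Generator | int | None = None,
) -> ItemBank:
    """Generate a precalculated item bank: ``per_length`` items per length.

    The default adaptive bank uses 20 items per length so that the
    random-among-closest selection rule has real exposure control.
    """
    lengths = sorted(set(int(L) for L in lengths))
    if not lengths:
        raise ValueError("lengths must be a non-empty set")
    if per_length < 1:
        raise ValueError("per_length must be >= 1")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    items: list[Item] = []
    params: dict[str, ItemParameters] = {}
    for L in lengths:
        pars = to_irt_params(coeffs, L)
        for k in range(per_length):
            it = generate_item(L, rng, item_id=f"L{L}-{k:03d}")
            items.append(it)
            params[it.id] = pars
    return ItemBank(items=items, params=params, generator_seed=seed, coeffs=coeffs)


def score_sequence(item: Item, clicked: Sequence[int]) -> int:
    """All-or-nothing recall score: 1 iff ``clicked`` equals the ball sequence.

    A length mismatch scores 0 (with a warning — the delivery layer normally
    enforces length, but the scorer must be total).
    """
    clicked = tuple(int(p) for p in clicked)
    if any(p < 1 or p > N_POSITIONS for p in clicked):
        raise ValueError(f"clicked positions must lie in 1..{N_POSITIONS}")
    if len(clicked) != item.length:
        warnings.warn(
            f"response length {len(clicked)} != item length {item.length}; scored 0",
            stacklevel=2,
        )
        return 0
    return int(clicked == item.ball_seq)


def score_response(
    item: Item, clicked: Sequence[int], hand_judgements: Sequence[bool]
) -> ResponseRecord:
    """Score a full response, including the secondary hand-judgement count."""
    seq_correct = score_sequence(item, clicked)
    hands = tuple(bool(h) for h in hand_judgements)
    n_hand = sum(
        int(h == truth) for h, truth in zip(hands, item.hand_same_seq)
    )
    return ResponseRecord(
        item_id=item.id, clicked_seq=tuple(int(p) for p in clicked),
        hand_judgements=hands, seq_correct=seq_correct, hand_n_correct=n_hand,
    )


def guess_probability(length: int) -> float:
    """Probability of reproducing a length-L sequence by uniform guessing.

    Equals ``6**(-L)``: ~0.167 for length 1, below .03 for every longer item —
    the rationale for modelling length-1 trials with a dummy rather than a
    guessing asymptote.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return float(N_POSITIONS) ** (-length)


def static_form(
    source: ItemBank | np.random.Generator | int,
    include_practice: bool = False,
    coeffs: ExplanatoryCoefficients = DEFAULT_COEFFS,
) -> list[Item]:
    """Assemble the fixed 14-item form: each length 1..7 twice, increasing.

    ``source`` may be an :class:`ItemBank` (items are drawn from it without
    replacement) or a random generator / seed (items are generated fresh).
    With ``include_practice`` the two feedback trials (lengths 1 and 2) are
    prepended, flagged ``is_practice`` and excluded from scoring downstream.
    """
    items: list[Item] = []
    if isinstance(source, ItemBank):
        used: set[str] = set()
        for L in STATIC_LENGTHS:
            pool = [it for it in source.items_of_length(L) if it.id not in used and not it.is_practice]
            if not pool:
                raise BankExhaustedError(f"bank cannot supply two items of length {L}")
            items.append(pool[0])
            used.add(pool[0].id)
        practice_rng = np.random.default_rng(source.generator_seed or 0)
        practice = [
            generate_item(1, practice_rng, is_practice=True),
            generate_item(2, practice_rng, is_practice=True),
        ]
    else:
        rng = source if isinstance(source, np.random.Generator) else np.random.default_rng(int(source))
        practice = [
            generate_item(1, rng, is_practice=True),
            generate_item(2, rng, is_practice=True),
        ]
        items = [generate_item(L, rng) for L in STATIC_LENGTHS]
    if include_practice:
        return practice + items
    return items
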