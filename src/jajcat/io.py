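"""File formats: item-bank JSON, session JSONL, response CSV, config files.

All artifacts are plain text and embed the seed/config that produced them,
so any result can be regenerated from its own file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from jajcat.ability import AbilityEstimate
from jajcat.cat_engine import CatConfig, SessionLog, TrialRecord, session_to_lines
from jajcat.errors import FormatError
from jajcat.task_model import ItemBank

__all__ = [
    "read_bank",
    "write_bank",
    "read_sessions",
    "write_sessions",
    "read_responses",
    "write_responses",
    "read_config",
]


def write_bank(bank: ItemBank, path) -> None:
    Path(path).write_text(bank.to_json())


def read_bank(path) -> ItemBank:
    return ItemBank.from_json(Path(path).read_text())


def write_sessions(logs: list[SessionLog], path) -> None:
    lines = []
    for i, log in enumerate(logs):
        lines.extend(session_to_lines(log, session_id=f"s{i:05d}"))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sessions(path) -> list[SessionLog]:
    """Parse a session JSONL file back into SessionLog objects.

    Malformed lines are reported with their 1-based line number.
    """
    text = Path(path).read_text()
    trials: dict[str, list[TrialRecord]] = {}
    finals: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as e:
            raise FormatError(f"line {lineno}: malformed JSON ({e.msg})") from e
        sid = rec.get("session")
        kind = rec.get("type")
        if sid is None or kind not in ("trial", "final"):
            raise FormatError(f"line {lineno}: missing 'session' or bad 'type'")
        if sid not in trials:
            trials[sid] = []
            order.append(sid)
        if kind == "trial":
            try:
                trials[sid].append(
                    TrialRecord(
                        item_id=rec["item_id"],
                        length=int(rec["length"]),
                        b=float(rec["b"]),
                        response=int(rec["response"]),
                        interim_theta=float(rec["interim_theta"]),
                        interim_sem=float(rec["interim_sem"]),
                    )
                )
            except (KeyError, ValueError) as e:
                raise FormatError(f"line {lineno}: bad trial record ({e})") from e
        else:
            finals[sid] = rec
    logs = []
    for sid in order:
        if sid not in finals:
            raise FormatError(f"session {sid!r}: no final record")
        fin = finals[sid]
        logs.append(
            SessionLog(
                trials=trials[sid],
                final=AbilityEstimate(
                    theta=float(fin["theta"]),
                    sem=float(fin["sem"]),
                    method=fin.get("method", "WL"),
                    n_items=int(fin["n_items"]),
                ),
                config=CatConfig(
                    max_items=int(fin.get("max_items", 14)),
                    se_threshold=fin.get("se_threshold"),
                ),
                seed=fin.get("seed"),
                true_theta=fin.get("true_theta"),
            )
        )
    return logs


def write_responses(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"participant_id", "length", "correct"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"response CSV lacks columns: {sorted(missing)}")
    return frame


def read_config(path) -> dict:
    """Read a YAML or JSON config file mirroring the CLI flags."""
    text = Path(path).read_text()
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise FormatError(f"config file is not valid YAML/JSON: {e}") from e
    if not isinstance(obj, dict):
        raise FormatError("config file must contain a mapping")
    return obj
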