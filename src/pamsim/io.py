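"""Config, event-log, measures and ratings file round-trips.

All tabular artifacts are UTF-8 CSV with a mandatory header; configs are YAML
or JSON.  Event logs embed the producing config (and seed) as a ``# config:``
comment line so every artifact is self-describing.  Parsing is strict:
schema violations raise :class:`ParseError` with row/field context, never a
silent coercion.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentProfile
from .game import (
    AugmentedVariant,
    Condition,
    EventLog,
    GameConfig,
    Outcome,
    TrialRecord,
)
from .measures import SessionMeasures

__all__ = [
    "ParseError",
    "config_to_dict",
    "config_from_dict",
    "agent_to_dict",
    "agent_from_dict",
    "read_config",
    "write_config",
    "read_event_log",
    "write_event_log",
    "read_ratings",
    "write_ratings",
    "write_measures_table",
    "read_measures_table",
]

EVENT_LOG_COLUMNS = [
    "trial", "fish_id", "lane_before", "lane_after", "escape_before",
    "escape_after", "blink_count", "in_range", "scheduled_recognized",
    "effective_recognized", "help", "outcome", "ticks",
]

MEASURE_COLUMNS = [
    "blink_recognition", "blink_conv_rate", "pos_feedback", "help_rate",
    "fish_caught", "fish_lost", "fish_reel", "fish_unreel", "duration_ticks",
]


class ParseError(ValueError):
    """A malformed config or table, with field/row context in the message."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def config_to_dict(config: GameConfig) -> dict:
    d = dataclasses.asdict(config)
    d["condition"] = config.condition.value
    d["augmented_variant"] = config.augmented_variant.value
    return d


def config_from_dict(d: dict) -> GameConfig:
    if not isinstance(d, dict):
        raise ParseError("game config must be a mapping")
    known = {f.name for f in dataclasses.fields(GameConfig)}
    unknown = set(d) - known
    if unknown:
        raise ParseError(f"unknown game config fields: {sorted(unknown)}")
    kwargs = dict(d)
    try:
        if "condition" in kwargs:
            kwargs["condition"] = Condition(kwargs["condition"])
        if "augmented_variant" in kwargs:
            kwargs["augmented_variant"] = AugmentedVariant(kwargs["augmented_variant"])
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    if kwargs.get("spawn_lane_distribution") is not None:
        try:
            kwargs["spawn_lane_distribution"] = {
                int(k): float(v) for k, v in kwargs["spawn_lane_distribution"].items()
            }
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad spawn_lane_distribution: {exc}") from exc
    config = GameConfig(**kwargs)
    config.validate()
    return config


def agent_to_dict(agent: AgentProfile) -> dict:
    return dataclasses.asdict(agent)


def agent_from_dict(d: dict) -> AgentProfile:
    if not isinstance(d, dict):
        raise ParseError("agent profile must be a mapping")
    known = {f.name for f in dataclasses.fields(AgentProfile)}
    unknown = set(d) - known
    if unknown:
        raise ParseError(f"unknown agent profile fields: {sorted(unknown)}")
    agent = AgentProfile(**d)
    agent.validate()
    return agent


def write_config(path, config: GameConfig, agent: AgentProfile | None = None) -> None:
    path = Path(path)
    doc: dict = {"game": config_to_dict(config)}
    if agent is not None:
        doc["agent"] = agent_to_dict(agent)
    text = (
        json.dumps(doc, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(doc, sort_keys=False)
    )
    path.write_text(text, encoding="utf-8")


def read_config(path) -> tuple[GameConfig, AgentProfile | None]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParseError(f"{path}: malformed config file: {exc}") from exc
    if not isinstance(doc, dict) or "game" not in doc:
        raise ParseError(f"{path}: config file must contain a 'game' mapping")
    config = config_from_dict(doc["game"])
    agent = agent_from_dict(doc["agent"]) if doc.get("agent") is not None else None
    return config, agent


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------

def write_event_log(path, log: EventLog) -> None:
    """CSV, one row per trial, with the producing config embedded as a comment."""
    path = Path(path)
    rows = []
    for r in log.records:
        d = dataclasses.asdict(r)
        d["outcome"] = r.outcome.value
        for col in ("in_range", "scheduled_recognized", "effective_recognized", "help"):
            d[col] = int(d[col])
        rows.append(d)
    frame = pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS)
    header = "# config: " + json.dumps(config_to_dict(log.config)) + "\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def read_event_log(path) -> EventLog:
    path = Path(path)
    config = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# config:"):
                try:
                    config = config_from_dict(json.loads(line[len("# config:"):]))
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}: bad embedded config: {exc}") from exc
            elif not line.startswith("#"):
                break
    if config is None:
        raise ParseError(f"{path}: missing '# config:' header line")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in EVENT_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: event log missing column(s) {missing}")
    records = []
    for i, row in frame.iterrows():
        try:
            outcome = Outcome(row["outcome"])
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: unknown outcome {row['outcome']!r}") from exc
        records.append(
            TrialRecord(
                trial=int(row["trial"]),
                fish_id=int(row["fish_id"]),
                lane_before=int(row["lane_before"]),
                lane_after=int(row["lane_after"]),
                escape_before=int(row["escape_before"]),
                escape_after=int(row["escape_after"]),
                blink_count=int(row["blink_count"]),
                in_range=bool(row["in_range"]),
                scheduled_recognized=bool(row["scheduled_recognized"]),
                effective_recognized=bool(row["effective_recognized"]),
                help=bool(row["help"]),
                outcome=outcome,
                ticks=int(row["ticks"]),
            )
        )
    log = EventLog(config=config, records=tuple(records))
    if len(log.records) != config.n_trials:
        raise ParseError(
            f"{path}: expected {config.n_trials} trials, found {len(log.records)}"
        )
    return log


# ---------------------------------------------------------------------------
# ratings and measures tables
# ---------------------------------------------------------------------------

def write_ratings(path, ratings: pd.DataFrame) -> None:
    for col in ("participant", "condition", "outcome", "rating"):
        if col not in ratings.columns:
            raise ParseError(f"ratings table missing column {col!r}")
    ratings.to_csv(path, index=False, encoding="utf-8")


def read_ratings(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("participant", "condition", "outcome", "rating"):
        if col not in frame.columns:
            raise ParseError(f"{path}: ratings table missing column {col!r}")
    ratings = frame["rating"]
    bad = frame.index[(ratings != np.floor(ratings)) | (ratings < 1) | (ratings > 7)]
    if len(bad):
        raise ParseError(
            f"{path}: row {bad[0]}: rating {frame.loc[bad[0], 'rating']!r} outside 1..7"
        )
    frame["rating"] = frame["rating"].astype(int)
    return frame


def write_measures_table(path, rows: list[dict]) -> None:
    """One row per session: condition/variant/agent/seed plus the measures."""
    frame = pd.DataFrame(rows)
    missing = [c for c in MEASURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"measures table missing column(s) {missing}")
    frame.to_csv(path, index=False, encoding="utf-8")


def read_measures_table(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in MEASURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: measures table missing column(s) {missing}")
    return frame


def measures_row(
    measures: SessionMeasures,
    condition: Condition,
    seed: int,
    agent_label: str,
    variant: AugmentedVariant | None = None,
    participant: int | None = None,
) -> dict:
    row = {
        "condition": condition.value,
        "variant": variant.value if variant is not None else "",
        "agent": agent_label,
        "seed": seed,
    }
    if participant is not None:
        row = {"participant": participant, **row}
    row.update(dataclasses.asdict(measures))
    return row
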