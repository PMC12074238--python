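"""End-to-end replication driver: run a within-subject experiment plan.

A plan mirrors the four-condition within-subject design: every simulated
participant plays each condition block once, with a distinct seed per
participant x block, and the driver aggregates the session measures into a
mean (SD) table shaped like the per-condition summary tables of the two
studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .agents import AgentProfile, preset_profiles
from .game import AugmentedVariant, Condition, GameConfig, run_session
from .io import MEASURE_COLUMNS, ParseError, measures_row, write_event_log, write_measures_table
from .measures import compute_session_measures

__all__ = ["PlanBlock", "ExperimentPlan", "run_experiment", "summarize_measures",
           "read_plan", "write_plan", "format_summary"]

_FRACTION_MEASURES = {"blink_recognition", "blink_conv_rate", "pos_feedback", "help_rate"}


@dataclass(frozen=True)
class PlanBlock:
    """One condition block every participant plays."""

    condition: Condition
    help_rate: float = 0.30
    augmented_variant: AugmentedVariant = AugmentedVariant.CONSTRAINED
    n_trials: int = 20
    success_rate: float = 0.70

    def label(self) -> str:
        if self.condition is Condition.AUGMENTED_SUCCESS:
            return f"{self.condition.value}:{self.augmented_variant.value}"
        return self.condition.value


@dataclass(frozen=True)
class ExperimentPlan:
    """A full experiment: blocks x participants, seeded from ``seed_base``."""

    blocks: tuple[PlanBlock, ...]
    n_participants: int = 19
    agent_preset: str = "ideal"
    seed_base: int = 0
    write_logs: bool = True

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        labels = [b.label() for b in self.blocks]
        if len(labels) != len(set(labels)):
            raise ValueError("each condition/variant may appear at most once per plan")
        if self.agent_preset not in preset_profiles():
            raise ValueError(f"unknown agent preset {self.agent_preset!r}")

    def session_seed(self, participant: int, block_index: int) -> int:
        # distinct per participant x block by construction
        return self.seed_base + participant * len(self.blocks) + block_index


def default_plan(n_participants: int = 19, seed_base: int = 0,
                 agent_preset: str = "ideal",
                 variant: AugmentedVariant = AugmentedVariant.CONSTRAINED) -> ExperimentPlan:
    """The four-condition within-subject design at the studied rates."""
    return ExperimentPlan(
        blocks=(
            PlanBlock(Condition.REFERENCE, help_rate=0.0),
            PlanBlock(Condition.AUGMENTED_SUCCESS, augmented_variant=variant),
            PlanBlock(Condition.MITIGATED_FAILURE),
            PlanBlock(Condition.INPUT_OVERRIDE),
        ),
        n_participants=n_participants,
        agent_preset=agent_preset,
        seed_base=seed_base,
    )


def run_experiment(
    plan: ExperimentPlan, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant x block session of a plan.

    Returns ``(measures, summary)``: the per-session measures table and the
    per-condition mean/SD aggregate.  When ``out_dir`` is given, one event
    log per session plus the measures table are written there; on any error
    the partially written outputs are removed before the exception
    propagates.
    """
    plan.validate()
    agent = preset_profiles()[plan.agent_preset]
    out_dir = Path(out_dir) if out_dir is not None else None
    written: list[Path] = []
    try:
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for p in range(plan.n_participants):
            for b, block in enumerate(plan.blocks):
                config = GameConfig(
                    condition=block.condition,
                    augmented_variant=block.augmented_variant,
                    n_trials=block.n_trials,
                    success_rate=block.success_rate,
                    help_rate=block.help_rate,
                    seed=plan.session_seed(p, b),
                )
                log = run_session(config, agent)
                measures = compute_session_measures(log)
                rows.append(
                    measures_row(
                        measures,
                        condition=block.condition,
                        variant=block.augmented_variant
                        if block.condition is Condition.AUGMENTED_SUCCESS
                        else None,
                        seed=config.seed,
                        agent_label=agent.label,
                        participant=p,
                    )
                )
                if out_dir is not None and plan.write_logs:
                    log_path = out_dir / f"log_p{p:03d}_{block.label().replace(':', '-')}.csv"
                    write_event_log(log_path, log)
                    written.append(log_path)
        measures_df = pd.DataFrame(rows)
        summary = summarize_measures(measures_df)
        if out_dir is not None:
            table_path = out_dir / "measures.csv"
            write_measures_table(table_path, rows)
            written.append(table_path)
            summary_path = out_dir / "summary.csv"
            summary.to_csv(summary_path, encoding="utf-8")
            written.append(summary_path)
        return measures_df, summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def summarize_measures(measures_df: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of every game measure.

    Rows are measures, columns a (condition, statistic) MultiIndex; SD is the
    sample standard deviation (ddof 1, 0.0 for a single session).
    """
    g = measures_df.groupby("condition", sort=False)[MEASURE_COLUMNS]
    mean = g.mean().T
    sd = g.std(ddof=1).fillna(0.0).T
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a summary as ``mean (SD)`` strings, percentages for fractions."""
    conditions = summary.columns.get_level_values(0).unique()
    out = {}
    for cond in conditions:
        col = []
        for measure in summary.index:
            m = summary.loc[measure, (cond, "mean")]
            s = summary.loc[measure, (cond, "sd")]
            if measure in _FRACTION_MEASURES:
                col.append(f"{100 * m:.0f}% ({s:.2f})")
            else:
                col.append(f"{m:.2f} ({s:.2f})")
        out[cond] = col
    return pd.DataFrame(out, index=summary.index)


# ---------------------------------------------------------------------------
# plan files
# ---------------------------------------------------------------------------

def write_plan(path, plan: ExperimentPlan) -> None:
    doc = {
        "n_participants": plan.n_participants,
        "agent_preset": plan.agent_preset,
        "seed_base": plan.seed_base,
        "write_logs": plan.write_logs,
        "blocks": [
            {
                "condition": b.condition.value,
                "help_rate": b.help_rate,
                "augmented_variant": b.augmented_variant.value,
                "n_trials": b.n_trials,
                "success_rate": b.success_rate,
            }
            for b in plan.blocks
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_plan(path) -> ExperimentPlan:
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: malformed plan file: {exc}") from exc
    if not isinstance(doc, dict) or "blocks" not in doc:
        raise ParseError(f"{path}: plan file must contain a 'blocks' list")
    try:
        blocks = tuple(
            PlanBlock(
                condition=Condition(b["condition"]),
                help_rate=float(b.get("help_rate", 0.30)),
                augmented_variant=AugmentedVariant(
                    b.get("augmented_variant", AugmentedVariant.CONSTRAINED.value)
                ),
                n_trials=int(b.get("n_trials", 20)),
                success_rate=float(b.get("success_rate", 0.70)),
            )
            for b in doc["blocks"]
        )
        plan = ExperimentPlan(
            blocks=blocks,
            n_participants=int(doc.get("n_participants", 19)),
            agent_preset=str(doc.get("agent_preset", "ideal")),
            seed_base=int(doc.get("seed_base", 0)),
            write_logs=bool(doc.get("write_logs", True)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"{path}: bad plan entry: {exc}") from exc
    plan.validate()
    return plan
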