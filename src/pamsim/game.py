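"""Trial-based engine for the fishing game used to study help under imprecise input.

The game emulates a motor-imagery BCI rehabilitation exercise: a player reels a
hooked fish up one lane per recognized blink, but the system only recognizes
input during a scheduled fraction of the trial windows (the recognition
schedule stands in for BCI false negatives).  Three explicit help mechanisms
("performance accommodation mechanisms") can soften that imprecision:

* augmented success   -- a successful reel moves the fish two lanes instead of one;
* mitigated failure   -- a failed trial does not advance the fish toward escape;
* input override      -- a system character reels the fish up after a failed trial.

Every session is driven by a predefined per-trial schedule, so outcomes are
bit-for-bit reproducible from ``(config, agent, seed)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .agents import AgentProfile, simulate_trial_blinks

__all__ = [
    "Condition",
    "AugmentedVariant",
    "Outcome",
    "GameConfig",
    "TrialSchedule",
    "FishState",
    "TrialResult",
    "TrialRecord",
    "EventLog",
    "ConfigError",
    "ScheduleError",
    "build_trial_schedule",
    "spawn_fish",
    "resolve_trial",
    "run_session",
    "play_schedule",
    "round_half_away",
]


class ConfigError(ValueError):
    """Raised for an invalid game configuration."""


class ScheduleError(ValueError):
    """Raised when a trial schedule cannot satisfy its invariants."""


class Condition(enum.Enum):
    REFERENCE = "reference"
    AUGMENTED_SUCCESS = "augmented_success"
    MITIGATED_FAILURE = "mitigated_failure"
    INPUT_OVERRIDE = "input_override"


class AugmentedVariant(enum.Enum):
    #: help only fires when the fish can be reeled two full lanes without
    #: being caught (the original activation rule, which depresses the
    #: realized help rate)
    CONSTRAINED = "constrained"
    #: help may also complete a catch when the fish is within two lanes of
    #: the top (the follow-up redesign)
    REDESIGNED = "redesigned"


class Outcome(enum.Enum):
    PLAYER_REEL = "PLAYER_REEL"
    PLAYER_CATCH = "PLAYER_CATCH"
    HELP_DOUBLE_REEL = "HELP_DOUBLE_REEL"
    HELP_DOUBLE_CATCH = "HELP_DOUBLE_CATCH"
    HELP_OVERRIDE_REEL = "HELP_OVERRIDE_REEL"
    HELP_OVERRIDE_CATCH = "HELP_OVERRIDE_CATCH"
    HELP_CLAMP = "HELP_CLAMP"
    UNREEL = "UNREEL"
    LOSS = "LOSS"


#: outcomes that constitute positive feedback (a reel-up or a catch, whether
#: caused by the player's blink or by help)
POSITIVE_OUTCOMES = frozenset(
    {
        Outcome.PLAYER_REEL,
        Outcome.PLAYER_CATCH,
        Outcome.HELP_DOUBLE_REEL,
        Outcome.HELP_DOUBLE_CATCH,
        Outcome.HELP_OVERRIDE_REEL,
        Outcome.HELP_OVERRIDE_CATCH,
    }
)

#: outcomes that constitute help feedback
HELP_OUTCOMES = frozenset(
    {
        Outcome.HELP_DOUBLE_REEL,
        Outcome.HELP_DOUBLE_CATCH,
        Outcome.HELP_OVERRIDE_REEL,
        Outcome.HELP_OVERRIDE_CATCH,
        Outcome.HELP_CLAMP,
    }
)

CATCH_OUTCOMES = frozenset(
    {Outcome.PLAYER_CATCH, Outcome.HELP_DOUBLE_CATCH, Outcome.HELP_OVERRIDE_CATCH}
)

#: conditions whose help is triggered by a scheduled failure
FAILURE_TRIGGERED = frozenset({Condition.MITIGATED_FAILURE, Condition.INPUT_OVERRIDE})


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    ``round_half_away(0.5) == 1`` and ``round_half_away(-0.5) == -1``; used for
    converting scheduled rates into integer trial counts so that e.g. a 25%
    rate over 10 trials yields 3 trials, never 2.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class GameConfig:
    """Full specification of one game session.

    Parameters
    ----------
    condition : Condition
        Which help mechanism is active (or REFERENCE for none).
    augmented_variant : AugmentedVariant
        Activation rule for augmented success; ignored otherwise.
    n_trials : int
        Number of reel attempts in the session (20 in both studies).
    success_rate : float
        Scheduled fraction of trials in which a blink is recognized, in (0, 1).
        Strictly below 1: every session must contain scheduled imprecision.
    help_rate : float
        Scheduled fraction of trials receiving help, in [0, 1).  At most
        ``1 - success_rate`` for failure-triggered help and at most
        ``success_rate`` for augmented success.
    n_lanes : int
        Number of horizontal lanes; lane 1 is the top-most.
    spawn_lane_distribution : dict[int, float] | None
        Probability of a new fish being hooked in each lane.  Defaults to
        uniform over lanes ``2..n_lanes``; the top lane gets probability 0
        because a fish hooked there would need no reel-up before the catch.
    escape_threshold : int
        Number of failed reel periods after which the fish escapes.
    trial_ticks, rest_ticks, help_anim_ticks : int
        Simulated time units for the trial window, the rest period, and a
        help animation; session duration is reported in ticks.
    escape_reset_on_success : bool
        If True a successful reel resets a fish's escape progress; by default
        the three failures triggering escape are cumulative per fish.
    seed : int
        Seed for the schedule permutation, lane spawns, and the agent.
    """

    condition: Condition = Condition.REFERENCE
    augmented_variant: AugmentedVariant = AugmentedVariant.CONSTRAINED
    n_trials: int = 20
    success_rate: float = 0.70
    help_rate: float = 0.0
    n_lanes: int = 3
    spawn_lane_distribution: dict[int, float] | None = None
    escape_threshold: int = 3
    trial_ticks: int = 5
    rest_ticks: int = 3
    help_anim_ticks: int = 2
    escape_reset_on_success: bool = False
    seed: int = 0

    def lane_distribution(self) -> dict[int, float]:
        if self.spawn_lane_distribution is not None:
            return dict(self.spawn_lane_distribution)
        lanes = range(2, self.n_lanes + 1)
        return {lane: 1.0 / (self.n_lanes - 1) for lane in lanes}

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be a positive integer")
        if self.n_lanes < 2:
            raise ConfigError("n_lanes must be >= 2")
        if self.escape_threshold < 1:
            raise ConfigError("escape_threshold must be a positive integer")
        if min(self.trial_ticks, self.rest_ticks, self.help_anim_ticks) < 0:
            raise ConfigError("tick counts must be nonnegative")
        if not 0.0 < self.success_rate:
            raise ConfigError("success_rate must be in (0, 1)")
        if self.success_rate >= 1.0:
            raise ConfigError(
                "no scheduled imprecision: success_rate must be < 1 so that "
                "every session contains at least one scheduled failure"
            )
        if not 0.0 <= self.help_rate < 1.0:
            raise ConfigError("help_rate must be in [0, 1)")
        if self.condition is Condition.REFERENCE and self.help_rate > 0:
            raise ConfigError("the reference condition provides no help; set help_rate=0")
        if self.condition in FAILURE_TRIGGERED and self.help_rate > 1.0 - self.success_rate + 1e-12:
            raise ConfigError(
                "failure-triggered help cannot exceed the scheduled failure "
                f"rate: help_rate={self.help_rate} > 1 - success_rate="
                f"{1.0 - self.success_rate:.6g}"
            )
        if self.condition is Condition.AUGMENTED_SUCCESS and self.help_rate > self.success_rate + 1e-12:
            raise ConfigError(
                "success-triggered help cannot exceed the scheduled success rate"
            )
        dist = self.lane_distribution()
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigError("spawn_lane_distribution must sum to 1 (tolerance 1e-9)")
        for lane, p in dist.items():
            if p < 0:
                raise ConfigError(f"spawn probability for lane {lane} is negative")
            if not 2 <= lane <= self.n_lanes and p > 0:
                raise ConfigError(
                    f"spawn lane {lane} outside [2, n_lanes={self.n_lanes}]: fish "
                    "may not be hooked in the top lane"
                )


@dataclass(frozen=True)
class TrialSchedule:
    """Predefined per-trial recognition and help flags emulating input imprecision."""

    recognized: tuple[bool, ...]
    help_flag: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.recognized)


@dataclass(frozen=True)
class FishState:
    """A live hooked fish: its lane (1 = top) and accumulated escape progress."""

    lane: int
    escape_progress: int
    fish_id: int


@dataclass(frozen=True)
class TrialResult:
    outcome: Outcome
    fish_before: FishState
    #: None when the fish left play (caught or lost)
    fish_after: FishState | None
    positive: bool
    help_feedback: bool


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    fish_id: int
    lane_before: int
    lane_after: int  # 0 when the fish was caught; unchanged lane when lost
    escape_before: int
    escape_after: int
    blink_count: int
    in_range: bool
    scheduled_recognized: bool
    effective_recognized: bool
    help: bool
    outcome: Outcome
    ticks: int


@dataclass(frozen=True)
class EventLog:
    """Ground-truth record of one session: one record per trial plus the config."""

    config: GameConfig
    records: tuple[TrialRecord, ...]

    def __len__(self) -> int:
        return len(self.records)


def build_trial_schedule(config: GameConfig, rng: np.random.Generator | None = None) -> TrialSchedule:
    """Draw the predefined recognition/help schedule for a session.

    Exactly ``round(success_rate * n_trials)`` trials are marked recognized;
    the failure positions are a seeded uniform permutation.  For
    failure-triggered conditions help flags mark exactly the first
    ``round(help_rate * n_trials)`` failures in trial order; for augmented
    success they mark the first scheduled successes (activation may still be
    geometrically impossible at resolution time under the constrained
    variant).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    n_success = round_half_away(config.success_rate * n)
    n_fail = n - n_success
    if n_fail < 1:
        raise ScheduleError(
            "no scheduled imprecision: rounding success_rate * n_trials leaves "
            "no failed trial; lower success_rate or raise n_trials"
        )
    n_help = round_half_away(config.help_rate * n)
    if config.condition in FAILURE_TRIGGERED and n_help > n_fail:
        raise ScheduleError(
            f"schedule cannot place {n_help} help trials on {n_fail} failures"
        )
    if config.condition is Condition.AUGMENTED_SUCCESS and n_help > n_success:
        raise ScheduleError(
            f"schedule cannot place {n_help} help trials on {n_success} successes"
        )

    recognized = np.ones(n, dtype=bool)
    fail_positions = rng.permutation(n)[:n_fail]
    recognized[fail_positions] = False

    help_flag = np.zeros(n, dtype=bool)
    if config.condition in FAILURE_TRIGGERED:
        targets = np.flatnonzero(~recognized)[:n_help]
        help_flag[targets] = True
    elif config.condition is Condition.AUGMENTED_SUCCESS:
        targets = np.flatnonzero(recognized)[:n_help]
        help_flag[targets] = True
    return TrialSchedule(tuple(bool(r) for r in recognized), tuple(bool(h) for h in help_flag))


def spawn_fish(config: GameConfig, rng: np.random.Generator, fish_id: int = 0) -> FishState:
    """Hook a new fish in a lane drawn from the spawn distribution."""
    dist = config.lane_distribution()
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError("spawn_lane_distribution must sum to 1 (tolerance 1e-9)")
    lanes = sorted(dist)
    probs = np.array([dist[lane] for lane in lanes], dtype=float)
    lane = int(rng.choice(lanes, p=probs / probs.sum()))
    return FishState(lane=lane, escape_progress=0, fish_id=fish_id)


def resolve_trial(
    fish: FishState,
    scheduled_recognized: bool,
    any_in_range_blink: bool,
    help_flag: bool,
    config: GameConfig,
) -> TrialResult:
    """Resolve one reel trial for a live hooked fish.

    A trial is effectively successful only when the schedule recognizes it
    *and* the agent produced at least one in-range blink.  Help resolution
    follows the active mechanism; under the constrained augmented-success
    variant a help flag that cannot consume two full lanes degrades to a
    plain player reel and is recorded unconsumed.
    """
    if fish.escape_progress >= config.escape_threshold:
        raise ValueError("fish is no longer live: escape_progress at threshold")
    if help_flag:
        if config.condition is Condition.REFERENCE:
            raise ConfigError("help_flag set in the reference condition")
        if config.condition in FAILURE_TRIGGERED and scheduled_recognized:
            raise ConfigError(
                f"{config.condition.value} help triggers on failures, but the "
                "trial is scheduled as recognized"
            )
        if config.condition is Condition.AUGMENTED_SUCCESS and not scheduled_recognized:
            raise ConfigError(
                "augmented success triggers on successes, but the trial is "
                "scheduled as unrecognized"
            )

    effective = scheduled_recognized and any_in_range_blink
    progress = 0 if (effective and config.escape_reset_on_success) else fish.escape_progress

    def _player_success() -> TrialResult:
        if fish.lane == 1:
            return TrialResult(Outcome.PLAYER_CATCH, fish, None, True, False)
        after = replace(fish, lane=fish.lane - 1, escape_progress=progress)
        return TrialResult(Outcome.PLAYER_REEL, fish, after, True, False)

    if effective:
        if config.condition is Condition.AUGMENTED_SUCCESS and help_flag:
            if config.augmented_variant is AugmentedVariant.REDESIGNED:
                if fish.lane <= 2:
                    return TrialResult(Outcome.HELP_DOUBLE_CATCH, fish, None, True, True)
                after = replace(fish, lane=fish.lane - 2, escape_progress=progress)
                return TrialResult(Outcome.HELP_DOUBLE_REEL, fish, after, True, True)
            # constrained: only fire when two full lanes can be reeled
            if fish.lane - 2 >= 1:
                after = replace(fish, lane=fish.lane - 2, escape_progress=progress)
                return TrialResult(Outcome.HELP_DOUBLE_REEL, fish, after, True, True)
            return _player_success()  # help flag unconsumed
        return _player_success()

    # failed trial
    if help_flag and config.condition is Condition.MITIGATED_FAILURE:
        return TrialResult(Outcome.HELP_CLAMP, fish, fish, False, True)
    if help_flag and config.condition is Condition.INPUT_OVERRIDE:
        if fish.lane == 1:
            return TrialResult(Outcome.HELP_OVERRIDE_CATCH, fish, None, True, True)
        after = replace(fish, lane=fish.lane - 1)
        return TrialResult(Outcome.HELP_OVERRIDE_REEL, fish, after, True, True)
    new_progress = fish.escape_progress + 1
    if new_progress >= config.escape_threshold:
        # the loss replaces (does not add to) the unreel event
        return TrialResult(Outcome.LOSS, fish, None, False, False)
    after = replace(fish, escape_progress=new_progress)
    return TrialResult(Outcome.UNREEL, fish, after, False, False)


def play_schedule(
    config: GameConfig,
    schedule: TrialSchedule,
    blink_draws: Sequence[tuple[int, bool]],
    lanes: Iterator[int] | Sequence[int],
) -> EventLog:
    """Run a session from explicit schedule, blink draws and spawn lanes.

    This is the deterministic core of :func:`run_session`; tests can drive it
    with enumerated inputs.  ``blink_draws`` holds one
    ``(blink_count, any_in_range)`` pair per trial and ``lanes`` yields the
    lane of each newly hooked fish.
    """
    if len(schedule) != config.n_trials or len(blink_draws) != config.n_trials:
        raise ValueError("schedule and blink draws must cover every trial")
    lane_iter = iter(lanes)
    records: list[TrialRecord] = []
    fish: FishState | None = None
    next_id = 0
    for t in range(config.n_trials):
        if fish is None:
            try:
                lane = int(next(lane_iter))
            except StopIteration:  # pragma: no cover - caller bug
                raise ValueError("lane sequence exhausted before session end") from None
            fish = FishState(lane=lane, escape_progress=0, fish_id=next_id)
            next_id += 1
        blink_count, in_range = blink_draws[t]
        any_in_range = bool(in_range) and blink_count >= 1
        result = resolve_trial(
            fish, schedule.recognized[t], any_in_range, schedule.help_flag[t], config
        )
        ticks = config.rest_ticks + config.trial_ticks
        if result.help_feedback:
            ticks += config.help_anim_ticks
        records.append(
            TrialRecord(
                trial=t,
                fish_id=fish.fish_id,
                lane_before=fish.lane,
                lane_after=(
                    0
                    if result.outcome in CATCH_OUTCOMES
                    else (result.fish_after.lane if result.fish_after is not None else fish.lane)
                ),
                escape_before=fish.escape_progress,
                escape_after=(
                    result.fish_after.escape_progress
                    if result.fish_after is not None
                    else (
                        config.escape_threshold
                        if result.outcome is Outcome.LOSS
                        else fish.escape_progress
                    )
                ),
                blink_count=blink_count,
                in_range=any_in_range,
                scheduled_recognized=schedule.recognized[t],
                effective_recognized=schedule.recognized[t] and any_in_range,
                help=schedule.help_flag[t],
                outcome=result.outcome,
                ticks=ticks,
            )
        )
        fish = result.fish_after
    return EventLog(config=config, records=tuple(records))


def run_session(
    config: GameConfig, agent: AgentProfile, seed: int | None = None
) -> EventLog:
    """Simulate one full session; bit-for-bit reproducible from (config, agent, seed).

    A new fish is spawned and hooked whenever the previous one is caught or
    lost.  ``seed`` defaults to ``config.seed``; schedule, spawns and agent
    behavior use independent child streams of that seed.
    """
    config.validate()
    agent.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    sched_rng, spawn_rng, agent_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    schedule = build_trial_schedule(config, rng=sched_rng)
    blink_draws = [simulate_trial_blinks(agent, agent_rng) for _ in range(config.n_trials)]

    def lane_stream() -> Iterator[int]:
        fish_id = 0
        while True:
            yield spawn_fish(config, spawn_rng, fish_id).lane
            fish_id += 1

    return play_schedule(config, schedule, blink_draws, lane_stream())
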