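"""Session summary measures, screening, and plot-prep transforms.

These reproduce the game measures reported per condition: blink recognition
(sensor reliability), blink conversion rate, positive-feedback and help-rate
fractions, and the fish reel/unreel/caught/lost counts, plus the
zero-recognition screening rule and the 0-1 normalization with jitter used to
de-overplot Likert points on violin plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .game import (
    CATCH_OUTCOMES,
    HELP_OUTCOMES,
    POSITIVE_OUTCOMES,
    EventLog,
    Outcome,
)

__all__ = [
    "SessionMeasures",
    "compute_session_measures",
    "flag_recognition_anomalies",
    "prep_violin_data",
]

#: outcomes caused by the player's own blink (augmented-success doubles are
#: blink-caused; override reels are not -- no blink produced them)
_BLINK_CONVERSION_OUTCOMES = frozenset(
    {
        Outcome.PLAYER_REEL,
        Outcome.PLAYER_CATCH,
        Outcome.HELP_DOUBLE_REEL,
        Outcome.HELP_DOUBLE_CATCH,
    }
)


@dataclass(frozen=True)
class SessionMeasures:
    """Summary statistics of one session.

    Fractions are in [0, 1]; the CSV/report layer renders them as percent.
    ``blink_conv_rate`` counts catches as conversions (the catch is the final
    reel) but excludes override-helped reels, which no blink caused.
    """

    blink_recognition: float
    blink_conv_rate: float
    pos_feedback: float
    help_rate: float
    fish_caught: int
    fish_lost: int
    fish_reel: int
    fish_unreel: int
    duration_ticks: int


def compute_session_measures(log: EventLog) -> SessionMeasures:
    """Compute the per-session game measures from a complete event log."""
    n = log.config.n_trials
    if len(log.records) != n:
        raise ValueError(
            f"incomplete log: expected {n} trials, found {len(log.records)}"
        )
    records = log.records
    outcomes = [r.outcome for r in records]
    total_blinks = sum(r.blink_count for r in records)
    conversions = sum(o in _BLINK_CONVERSION_OUTCOMES for o in outcomes)
    catches = sum(o in CATCH_OUTCOMES for o in outcomes)
    return SessionMeasures(
        blink_recognition=sum(r.in_range for r in records) / n,
        blink_conv_rate=(conversions / total_blinks) if total_blinks else 0.0,
        pos_feedback=sum(o in POSITIVE_OUTCOMES for o in outcomes) / n,
        help_rate=sum(o in HELP_OUTCOMES for o in outcomes) / n,
        fish_caught=catches,
        fish_lost=sum(o is Outcome.LOSS for o in outcomes),
        fish_reel=sum(o in POSITIVE_OUTCOMES for o in outcomes) - catches,
        fish_unreel=sum(o is Outcome.UNREEL for o in outcomes),
        duration_ticks=sum(r.ticks for r in records),
    )


def flag_recognition_anomalies(
    measures_per_session: Iterable[SessionMeasures | float],
    exclusion_threshold: float = 0.0,
) -> list[str]:
    """Label sessions ``"keep"``/``"exclude"`` by blink recognition.

    With the default threshold of 0 only sessions with no blink recognition at
    all are excluded, mirroring the participant-screening rule applied to the
    stroke-patient cohort.
    """
    items = list(measures_per_session)
    if not items:
        raise ValueError("need at least one session")
    labels = []
    for m in items:
        rec = m.blink_recognition if isinstance(m, SessionMeasures) else float(m)
        labels.append("exclude" if rec <= exclusion_threshold else "keep")
    return labels


def prep_violin_data(
    ratings: Sequence[int],
    jitter_fraction: float = 0.02,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Normalize 1-7 ratings to 0-1 and jitter them for violin-plot overlays.

    Each rating ``v`` maps to ``(v - 1) / 6`` plus uniform jitter in
    ``+-jitter_fraction``; output is clipped to
    ``[-jitter_fraction, 1 + jitter_fraction]``.
    """
    arr = np.asarray(ratings)
    if arr.size == 0:
        return np.asarray([], dtype=float)
    if not np.issubdtype(arr.dtype, np.integer) and not np.all(arr == np.floor(arr)):
        raise ValueError("ratings must be integers in 1..7")
    if arr.min() < 1 or arr.max() > 7:
        raise ValueError("ratings must lie in 1..7")
    if jitter_fraction < 0:
        raise ValueError("jitter_fraction must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    normalized = (arr.astype(float) - 1.0) / 6.0
    jitter = rng.uniform(-jitter_fraction, jitter_fraction, size=arr.shape)
    return np.clip(normalized + jitter, -jitter_fraction, 1.0 + jitter_fraction)
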