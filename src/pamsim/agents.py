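"""Stochastic blink-behavior models reproducing the two study cohorts.

An agent emits zero or more blinks per reel trial.  Per-trial recognition --
the chance the eye tracker sees at least one blink -- factors into
``compliance_probability`` (did the agent blink at all during the trial
window) times ``in_range_probability`` (was the agent inside the tracker's
range).  Blink counts follow either a point mass or a 1 + Poisson
distribution truncated at a maximum, matching the "one or more blinks per
attempted trial" behavior observed in both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgentProfile", "simulate_trial_blinks", "preset_profiles"]

# cohort calibration: stroke patients averaged ~2.1 blinks per trial with
# per-trial recognition ~0.88 (occasional leaning out of tracker range or
# forgotten blinks); the game-savvy cohort was near-perfect at ~0.99.
_STUDY1_COMPLIANCE = 0.95
_STUDY1_RECOGNITION = 0.88
_STUDY1_MEAN_BLINKS = 2.1
_STUDY2_RECOGNITION = 0.99
_STUDY2_MEAN_BLINKS = 2.7


@dataclass(frozen=True)
class AgentProfile:
    """Blink behavior of one simulated player.

    ``blink_distribution`` is ``"constant"`` (exactly ``blink_param`` blinks on
    a complied trial) or ``"one_plus_poisson"`` (1 + Poisson(``blink_param``),
    truncated at ``max_blinks``).  A trial yields zero blinks with probability
    ``1 - compliance_probability``; given at least one blink, it is in tracker
    range with probability ``in_range_probability``.
    """

    label: str
    blink_distribution: str = "constant"
    blink_param: float = 1.0
    max_blinks: int = 10
    in_range_probability: float = 1.0
    compliance_probability: float = 1.0

    def validate(self) -> None:
        if self.blink_distribution not in ("constant", "one_plus_poisson"):
            raise ValueError(f"unknown blink distribution {self.blink_distribution!r}")
        if self.blink_distribution == "constant" and (
            self.blink_param < 0 or self.blink_param != int(self.blink_param)
        ):
            raise ValueError("constant blink count must be a nonnegative integer")
        if self.blink_distribution == "one_plus_poisson" and self.blink_param < 0:
            raise ValueError("Poisson mean must be nonnegative")
        if self.max_blinks < 1:
            raise ValueError("max_blinks must be >= 1")
        for name in ("in_range_probability", "compliance_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def recognition_probability(self) -> float:
        """Analytic per-trial probability of an in-range blink."""
        blinks = self.compliance_probability
        if self.blink_distribution == "constant" and int(self.blink_param) == 0:
            blinks = 0.0
        return blinks * self.in_range_probability

    @property
    def mean_blinks_per_trial(self) -> float:
        """Marginal expected blink count per trial (ignoring truncation)."""
        if self.blink_distribution == "constant":
            return self.compliance_probability * self.blink_param
        return self.compliance_probability * (1.0 + self.blink_param)


def simulate_trial_blinks(
    profile: AgentProfile, rng: np.random.Generator
) -> tuple[int, bool]:
    """Draw one trial's ``(blink_count, any_in_range)`` pair.

    The count is zero with probability ``1 - compliance_probability``;
    ``any_in_range`` can only be true when at least one blink occurred and the
    in-range draw succeeds.
    """
    profile.validate()
    if rng.random() >= profile.compliance_probability:
        return 0, False
    if profile.blink_distribution == "constant":
        count = int(profile.blink_param)
    else:
        count = 1 + min(int(rng.poisson(profile.blink_param)), profile.max_blinks - 1)
    if count == 0:
        return 0, False
    in_range = bool(rng.random() < profile.in_range_probability)
    return count, in_range


def preset_profiles() -> dict[str, AgentProfile]:
    """Named profiles spanning the behaviors observed in the two cohorts."""
    return {
        "ideal": AgentProfile(label="ideal"),
        "study1_patient": AgentProfile(
            label="study1_patient",
            blink_distribution="one_plus_poisson",
            blink_param=_STUDY1_MEAN_BLINKS / _STUDY1_COMPLIANCE - 1.0,
            in_range_probability=_STUDY1_RECOGNITION / _STUDY1_COMPLIANCE,
            compliance_probability=_STUDY1_COMPLIANCE,
        ),
        "study2_gamer": AgentProfile(
            label="study2_gamer",
            blink_distribution="one_plus_poisson",
            blink_param=_STUDY2_MEAN_BLINKS - 1.0,
            in_range_probability=_STUDY2_RECOGNITION,
            compliance_probability=1.0,
        ),
        "absent": AgentProfile(label="absent", compliance_probability=0.0),
    }
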