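"""Synthetic ordinal self-report data from a cumulative-logit generative model.

Ratings on a 7-point Likert scale are drawn from the generative inverse of a
cumulative link mixed model: participant ``i`` gets a Gaussian random
intercept ``u_i ~ N(0, sd^2)``, and the rating in a cell with covariates ``x``
satisfies ``P(Y <= j) = logistic(cutpoint_j - x.beta - u_i)``.  Default model
specs carry the fitted effect sizes from the stroke-patient study: each fish
reeled shifts perceived control by +0.61 log-odds (between-participant SD
2.31), and shifts frustration by -0.24 while each fish lost adds +0.37.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RatingModelSpec", "default_rating_specs", "generate_ratings", "centered_cutpoints"]

N_CATEGORIES = 7

# reference covariate means used to center default cutpoints: per-condition
# fish-reel means of roughly 3-9 per 20-trial session and ~1.5 fish lost
_REF_MEANS = {"fish_reel": 6.0, "fish_lost": 1.5, "fish_caught": 5.5, "help_rate": 0.22}

# frustration random-intercept spread is not pinned by the fitted models;
# a moderate between-participant heterogeneity is assumed
_FRUSTRATION_SD = 1.5


def centered_cutpoints(center: float, spacing: float = 1.0) -> np.ndarray:
    """Six equally spaced cutpoints for a 7-point scale, centered on ``center``."""
    return center + spacing * (np.arange(N_CATEGORIES - 1) - (N_CATEGORIES - 2) / 2.0)


@dataclass(frozen=True)
class RatingModelSpec:
    """Generative spec for one ordinal outcome.

    ``fixed_effects`` maps covariate names (game-measure columns or condition
    indicators) to log-odds-per-unit coefficients on raw covariate scales.
    """

    outcome_label: str
    fixed_effects: dict[str, float]
    random_intercept_sd: float
    cutpoints: np.ndarray = field(default_factory=lambda: centered_cutpoints(0.0))
    seed: int | None = None

    def validate(self) -> None:
        cuts = np.asarray(self.cutpoints, dtype=float)
        if cuts.shape != (N_CATEGORIES - 1,):
            raise ValueError(f"need {N_CATEGORIES - 1} cutpoints for a 7-point scale")
        if not np.all(np.diff(cuts) > 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be nonnegative")


def _center_for(fixed_effects: dict[str, float]) -> float:
    return sum(beta * _REF_MEANS.get(name, 0.0) for name, beta in fixed_effects.items())


def default_rating_specs() -> dict[str, RatingModelSpec]:
    """Generative specs parameterized by the fitted study effects.

    Cutpoints are equally spaced (spacing 1.0) and centered on the linear
    predictor at reference covariate means so default draws span the scale.
    The ``help_quantity`` spec is illustrative: its coefficient signs follow
    the observed directional relationships (more help-shielding, fewer
    unreels -> higher perceived help) but its magnitudes are not fitted
    values.
    """
    control_fx = {"fish_reel": 0.61}
    frustration_fx = {"fish_reel": -0.24, "fish_lost": 0.37}
    help_quantity_fx = {"fish_unreel": -0.45, "help_rate": 4.0}
    return {
        "perceived_control": RatingModelSpec(
            outcome_label="perceived_control",
            fixed_effects=control_fx,
            random_intercept_sd=2.31,
            cutpoints=centered_cutpoints(_center_for(control_fx)),
        ),
        "frustration": RatingModelSpec(
            outcome_label="frustration",
            fixed_effects=frustration_fx,
            random_intercept_sd=_FRUSTRATION_SD,
            # frustration was rated low throughout: center between categories
            # 2 and 3 rather than mid-scale
            cutpoints=centered_cutpoints(_center_for(frustration_fx) + 2.0, spacing=1.0) ,
        ),
        "help_quantity": RatingModelSpec(
            outcome_label="help_quantity",
            fixed_effects=help_quantity_fx,
            random_intercept_sd=1.0,
            cutpoints=centered_cutpoints(_center_for(help_quantity_fx)),
        ),
    }


def generate_ratings(
    covariates: pd.DataFrame,
    spec: RatingModelSpec,
    n_participants: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a long-format rating dataset from a cumulative-logit model.

    ``covariates`` holds one row per participant x condition cell with every
    fixed-effect column present.  If it lacks a ``participant`` column the
    table is treated as a per-condition template replicated for
    ``n_participants`` participants.  Each participant receives one Gaussian
    random intercept; ratings are drawn by thresholding a logistic latent
    variable at the cutpoints, which is exactly the cumulative-logit law.
    """
    spec.validate()
    missing = [c for c in spec.fixed_effects if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing fixed-effect columns: {missing}")

    if "participant" not in covariates.columns:
        if n_participants is None:
            raise ValueError(
                "covariates have no 'participant' column; pass n_participants "
                "to replicate the template per participant"
            )
        frames = []
        for pid in range(n_participants):
            block = covariates.copy()
            block.insert(0, "participant", pid)
            frames.append(block)
        covariates = pd.concat(frames, ignore_index=True)
    data = covariates.reset_index(drop=True).copy()
    if "condition" not in data.columns:
        data["condition"] = np.arange(len(data)) % max(len(covariates), 1)

    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    participants = pd.unique(data["participant"])
    u = dict(
        zip(participants, rng.normal(0.0, spec.random_intercept_sd, len(participants)))
    )
    eta = np.zeros(len(data))
    for name, beta in spec.fixed_effects.items():
        eta += beta * data[name].to_numpy(dtype=float)
    eta += np.array([u[p] for p in data["participant"]])

    latent = eta + rng.logistic(0.0, 1.0, size=len(data))
    ratings = 1 + np.digitize(latent, np.asarray(spec.cutpoints, dtype=float))

    out = data.copy()
    out["outcome"] = spec.outcome_label
    out["rating"] = ratings.astype(int)
    return out
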