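"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the rules themselves, in a
different style from the package (explicit per-trial branching, scalar
loops, quadrature instead of Laplace), so agreement is evidence and not
tautology.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar
from scipy.special import expit


# ---------------------------------------------------------------------------
# brute-force game interpreter
# ---------------------------------------------------------------------------

def brute_force_outcomes(
    condition: str,
    variant: str,
    recognized: list[bool],
    help_flag: list[bool],
    in_range: list[bool],
    lanes: list[int],
    escape_threshold: int = 3,
) -> list[tuple[str, int, int, int, int]]:
    """Replay a session by literal rule application.

    Returns one ``(outcome, lane_before, lane_after, escape_before,
    escape_after)`` tuple per trial.  ``lanes`` is consumed one entry per
    newly hooked fish; ``in_range`` says whether the (always-blinking-once)
    agent was seen by the tracker that trial.
    """
    out = []
    lane_iter = iter(lanes)
    lane = None
    escape = 0
    for t in range(len(recognized)):
        if lane is None:
            lane = next(lane_iter)
            escape = 0
        before = (lane, escape)
        success = recognized[t] and in_range[t]
        if success:
            boost = condition == "augmented_success" and help_flag[t]
            if boost and variant == "redesigned":
                if lane <= 2:
                    outcome, lane = "HELP_DOUBLE_CATCH", None
                else:
                    outcome, lane = "HELP_DOUBLE_REEL", lane - 2
            elif boost and variant == "constrained" and lane >= 3:
                outcome, lane = "HELP_DOUBLE_REEL", lane - 2
            else:
                if lane == 1:
                    outcome, lane = "PLAYER_CATCH", None
                else:
                    outcome, lane = "PLAYER_REEL", lane - 1
        else:
            if help_flag[t] and condition == "mitigated_failure":
                outcome = "HELP_CLAMP"
            elif help_flag[t] and condition == "input_override":
                if lane == 1:
                    outcome, lane = "HELP_OVERRIDE_CATCH", None
                else:
                    outcome, lane = "HELP_OVERRIDE_REEL", lane - 1
            else:
                escape = escape + 1
                if escape >= escape_threshold:
                    outcome, lane = "LOSS", None
                else:
                    outcome = "UNREEL"
        after_lane = 0 if outcome.endswith("CATCH") else (lane if lane is not None else before[0])
        after_escape = escape if lane is not None else (
            escape_threshold if outcome == "LOSS" else before[1]
        )
        out.append((outcome, before[0], after_lane, before[1], after_escape))
    return out


# ---------------------------------------------------------------------------
# ordinal-model oracles
# ---------------------------------------------------------------------------

def direct_cumlogit_loglik(cutpoints, eta, y) -> float:
    """Fixed-effects cumulative-logit log-likelihood by explicit summation."""
    cut = list(cutpoints)
    total = 0.0
    for yi, ei in zip(np.atleast_1d(y), np.atleast_1d(eta)):
        upper = 1.0 if yi == len(cut) + 1 else expit(cut[yi - 1] - ei)
        lower = 0.0 if yi == 1 else expit(cut[yi - 2] - ei)
        total += np.log(upper - lower)
    return total


def agh_group_loglik(cutpoints, etas, ys, sd: float, nodes: int = 61) -> float:
    """Adaptive Gauss-Hermite log marginal likelihood of one group."""
    def h(u):
        return direct_cumlogit_loglik(cutpoints, np.asarray(etas) + u, ys) - 0.5 * u * u / sd**2

    res = minimize_scalar(lambda u: -h(u), bounds=(-10 * sd - 5, 10 * sd + 5),
                          method="bounded", options={"xatol": 1e-12})
    u_hat = res.x
    eps = 1e-5
    h2 = (h(u_hat + eps) - 2 * h(u_hat) + h(u_hat - eps)) / eps**2
    scale = 1.0 / np.sqrt(-h2)
    t, w = hermgauss(nodes)
    vals = np.array([h(u_hat + np.sqrt(2) * scale * ti) for ti in t])
    integral = np.sum(w * np.exp(vals + t**2)) * np.sqrt(2) * scale
    return float(np.log(integral) - np.log(sd * np.sqrt(2 * np.pi)))


def agh_dataset_loglik(cutpoints, slopes, sd, data, fixed, nodes: int = 61) -> float:
    """Adaptive-quadrature marginal log-likelihood of a long rating table."""
    total = 0.0
    for _, grp in data.groupby("participant"):
        eta = np.zeros(len(grp))
        for name in fixed:
            eta += slopes.get(name, 0.0) * grp[name].to_numpy(dtype=float)
        total += agh_group_loglik(cutpoints, eta, grp["rating"].to_numpy(), sd, nodes)
    return total


def midrank_spearman(x, y) -> float:
    """Spearman correlation with hand-rolled midranks."""
    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return np.array(ranks)

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
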