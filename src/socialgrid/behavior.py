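"""Behavioral map-formation indices.

These quantify whether a participant internalised the 2D social value
map: occupancy of the map during free exploration (time at edges / at
avatars), precision of navigating to avatar locations from random starts
(collect task), the distance effect when comparing avatar pairs
(response time and accuracy as a function of task-relevant distance) and
recall accuracy. The distance-effect slopes double as per-participant
covariates for second-level neural analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .space import SocialSpace, expected_profit

__all__ = [
    "OccupancyMap",
    "occupancy",
    "collect_metrics",
    "compare_distance_effect",
    "recall_accuracy",
]

GRID_SIZE = 15  # map divided into 15 × 15 subregions


@dataclass
class OccupancyMap:
    """15 × 15 grid of explore-time fractions with edge/avatar summaries."""

    grid: np.ndarray
    edge_fraction: float
    avatar_fraction: float


def _cell_index(coords: np.ndarray) -> np.ndarray:
    # half-open cells; the top/right boundary at 1.0 belongs to the last cell
    idx = np.floor(coords * GRID_SIZE).astype(int)
    return np.clip(idx, 0, GRID_SIZE - 1)


def occupancy(
    samples: pd.DataFrame,
    space: SocialSpace | None = None,
    avatar_positions: np.ndarray | None = None,
) -> OccupancyMap:
    """Fraction of explore time per map subregion.

    ``samples`` needs columns x, y (equally spaced location samples, so
    sample counts are time fractions). Edge cells are the outermost rows
    and columns. Time at avatars counts samples within the pop-out radius
    of any avatar (the interval during which an avatar is on screen).
    """
    space = space or SocialSpace()
    xy = samples[["x", "y"]].to_numpy(dtype=float)
    if np.any(xy < 0) or np.any(xy > 1):
        raise ValueError("explore samples outside the unit square")
    ix = _cell_index(xy[:, 0])
    iy = _cell_index(xy[:, 1])
    grid = np.zeros((GRID_SIZE, GRID_SIZE))
    np.add.at(grid, (ix, iy), 1.0)
    grid /= len(xy)
    edge = grid.sum() - grid[1:-1, 1:-1].sum()
    if avatar_positions is None:
        avatar_positions = space.centers
    d = np.linalg.norm(xy[:, None, :] - avatar_positions[None, :, :], axis=2)
    at_avatar = np.any(d <= space.popout_radius, axis=1).mean()
    return OccupancyMap(grid, float(edge), float(at_avatar))


def _angle_deviation(a_deg, b_deg):
    """Absolute angular difference in [0°, 180°]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float), 360.0)
    return np.minimum(d, 360.0 - d)


def collect_metrics(
    trials: pd.DataFrame,
    avatar_positions: np.ndarray,
    deviation_threshold_deg: float = 15.0,
    distance_threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-trial collect-task results and summary indices.

    The deviation is the absolute angular difference between the first
    transition and the ideal start→target direction; summaries use the
    strict thresholds <15° and <0.01 map units.
    """
    avatar_positions = np.asarray(avatar_positions, dtype=float)
    start = trials[["start_x", "start_y"]].to_numpy(dtype=float)
    target = avatar_positions[trials["target"].to_numpy(dtype=int)]
    resp = trials[["response_x", "response_y"]].to_numpy(dtype=float)
    ideal = np.rad2deg(np.arctan2(target[:, 1] - start[:, 1], target[:, 0] - start[:, 0]))
    deviation = _angle_deviation(trials["first_transition_deg"].to_numpy(), ideal)
    distance = np.linalg.norm(resp - target, axis=1)
    per_trial = pd.DataFrame(
        {
            "deviation_deg": deviation,
            "response_distance": distance,
            "n_transitions": trials["n_transitions"].to_numpy(dtype=int)
            if "n_transitions" in trials
            else 1,
        }
    )
    summary = {
        "pct_deviation_below": float(np.mean(deviation < deviation_threshold_deg) * 100.0),
        "pct_distance_below": float(np.mean(distance < distance_threshold) * 100.0),
        "mean_deviation_deg": float(deviation.mean()),
        "mean_distance": float(distance.mean()),
        "mean_transitions": float(per_trial["n_transitions"].mean()),
    }
    return per_trial, summary


def compare_distance_effect(
    trials: pd.DataFrame,
    avatars=None,
    block: str | None = "cooperation",
    investment: float = 1.0,
) -> dict:
    """Per-participant distance-effect slopes in the compare task.

    The task-relevant distance is the separation of the pair on the
    compared axis, or — for the cooperation block — the absolute
    difference in expected profit. Ordinary least-squares slopes of
    log-RT and accuracy on distance are the exported indices (negative
    RT slope and positive accuracy slope signal a map-like
    representation).
    """
    tab = trials if block is None else trials[trials["block"] == block]
    if "distance" in tab:
        dist = tab["distance"].to_numpy(dtype=float)
    else:
        if avatars is None:
            raise ValueError("need avatars to compute task-relevant distances")
        dist = np.empty(len(tab))
        for k, (_, row) in enumerate(tab.iterrows()):
            i, j = int(row["pair_i"]), int(row["pair_j"])
            b = row["block"] if block is None else block
            if b == "competence":
                dist[k] = abs(avatars[i].competence - avatars[j].competence)
            elif b == "trustworthiness":
                dist[k] = abs(avatars[i].trustworthiness - avatars[j].trustworthiness)
            else:
                dist[k] = abs(
                    expected_profit(investment, avatars[i].competence, avatars[i].trustworthiness)
                    - expected_profit(investment, avatars[j].competence, avatars[j].trustworthiness)
                )
    if np.allclose(dist, dist[0]):
        raise ValueError("constant task-relevant distance; slope undefined")
    log_rt = (
        tab["log_rt"].to_numpy(dtype=float)
        if "log_rt" in tab
        else np.log(tab["rt"].to_numpy(dtype=float))
    )
    rt_fit = stats.linregress(dist, log_rt)
    acc_fit = stats.linregress(dist, tab["accuracy"].to_numpy(dtype=float))
    return {
        "rt_slope": float(rt_fit.slope),
        "rt_p": float(rt_fit.pvalue),
        "accuracy_slope": float(acc_fit.slope),
        "accuracy_p": float(acc_fit.pvalue),
        "n_trials": int(len(tab)),
    }


def recall_accuracy(responses: pd.DataFrame, by: str | None = None):
    """Fraction of correct recall responses (optionally per session/run)."""
    if by is not None and by in responses:
        return responses.groupby(by)["correct"].mean()
    return float(responses["correct"].mean())
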