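"""The abstract social value space and its landmarks.

The task space is a unit square whose axes are two social-perception
dimensions: competence (x) and trustworthiness (y), both restricted to
[0, 1] so that the dimensions are orthogonal and share a metric. Six
"avatar" landmarks live in this square at locations equal to their
(competence, trustworthiness) values; each participant's avatar set is
jittered inside small discs around fixed center coordinates so layouts
differ across participants while preserving the overall arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SocialSpace",
    "Avatar",
    "Trajectory",
    "expected_profit",
    "sample_avatar_layout",
    "DEFAULT_AVATAR_CENTERS",
]

#: Center coordinates of the six avatars (competence, trustworthiness).
#: Chosen to be distinguishable on both dimensions and to spread widely
#: across the unit square.
DEFAULT_AVATAR_CENTERS: tuple[tuple[float, float], ...] = (
    (0.15, 0.35),
    (0.30, 0.75),
    (0.45, 0.15),
    (0.60, 0.55),
    (0.75, 0.85),
    (0.90, 0.30),
)


@dataclass(frozen=True)
class SocialSpace:
    """The unit-square social value map.

    Parameters
    ----------
    avatar_centers : array-like of shape (6, 2)
        Center coordinates around which avatar positions are jittered.
    jitter_radius : float
        Radius (map units) of the disc around each center inside which a
        participant's avatar position is sampled. Default 1/30.
    popout_radius : float
        Radius (map units) within which an avatar counts as "on screen"
        (reached) during exploration. Default 0.01.
    """

    avatar_centers: tuple[tuple[float, float], ...] = DEFAULT_AVATAR_CENTERS
    jitter_radius: float = 1.0 / 30.0
    popout_radius: float = 0.01

    def __post_init__(self) -> None:
        centers = np.asarray(self.avatar_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("avatar_centers must be an (n, 2) array")
        if np.any(centers < 0.0) or np.any(centers > 1.0):
            raise ValueError("avatar centers must lie inside the unit square")
        if self.popout_radius <= 0:
            raise ValueError("popout_radius must be positive")
        if self.jitter_radius < 0:
            raise ValueError("jitter_radius must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray(self.avatar_centers, dtype=float)


@dataclass(frozen=True)
class Avatar:
    """A landmark person: location = (competence, trustworthiness)."""

    competence: float
    trustworthiness: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.competence <= 1.0):
            raise ValueError("competence must be in [0, 1]")
        if not (0.0 <= self.trustworthiness <= 1.0):
            raise ValueError("trustworthiness must be in [0, 1]")

    @property
    def location(self) -> np.ndarray:
        return np.array([self.competence, self.trustworthiness])


@dataclass(frozen=True)
class Trajectory:
    """A straight movement vector in the map: start + d·(cos θ, sin θ).

    ``theta`` is in radians, measured as atan2(Δtrustworthiness,
    Δcompetence); ``distance`` is the Euclidean length in map units.
    """

    start: tuple[float, float]
    theta: float
    distance: float
    end: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        end = (
            self.start[0] + self.distance * np.cos(self.theta),
            self.start[1] + self.distance * np.sin(self.theta),
        )
        object.__setattr__(self, "end", end)
        for p in (self.start, self.end):
            if not (-1e-9 <= p[0] <= 1 + 1e-9 and -1e-9 <= p[1] <= 1 + 1e-9):
                raise ValueError("trajectory leaves the unit square")


def expected_profit(investment: float, competence: float, trustworthiness: float) -> float:
    """Expected profit for an investor in the trust game.

    ``investment × (1 + competence) × trustworthiness``: competence is the
    rate at which the trustee multiplies the stake, trustworthiness the
    proportion of the earnings returned.

    >>> expected_profit(1000, 0.5, 0.5)
    750.0
    """
    if investment < 0:
        raise ValueError("investment must be non-negative")
    if not (0.0 <= competence <= 1.0):
        raise ValueError("competence must be in [0, 1]")
    if not (0.0 <= trustworthiness <= 1.0):
        raise ValueError("trustworthiness must be in [0, 1]")
    return float(investment * (1.0 + competence) * trustworthiness)


def sample_avatar_layout(
    space: SocialSpace,
    rng_seed: int | np.random.Generator = 0,
    clip: bool = True,
) -> list[Avatar]:
    """Sample one participant's avatar layout.

    Each avatar position is drawn uniformly inside the disc of radius
    ``space.jitter_radius`` around its center. Positions are clipped to
    the unit square; with ``clip=False`` a center too close to the
    boundary raises instead.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    centers = space.centers
    r = space.jitter_radius
    if not clip:
        near = (centers < r) | (centers > 1.0 - r)
        if np.any(near):
            raise ValueError(
                "avatar center within jitter_radius of the boundary and clipping disabled"
            )
    # uniform over the disc: radius ∝ sqrt(u)
    u = rng.uniform(size=len(centers))
    ang = rng.uniform(0.0, 2.0 * np.pi, size=len(centers))
    rad = r * np.sqrt(u)
    pos = centers + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    pos = np.clip(pos, 0.0, 1.0)
    return [Avatar(float(c), float(t)) for c, t in pos]
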