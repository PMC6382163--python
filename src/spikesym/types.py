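"""Core domain types and angle utilities.

Conventions used throughout the package:

* Coordinates are in meters, with the origin at the lower-left corner of the
  arena and y increasing towards north.
* Angles are measured counter-clockwise from the positive horizontal axis.
* Grid orientations are defined modulo ``360/M`` degrees and reported in the
  half-open interval ``(-180/M, 180/M]`` — for hexagonal symmetry ``(-30, 30]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SpikeSymError",
    "ValidationError",
    "DegenerateInputError",
    "SpacingDetectionError",
    "Arena",
    "SpikeMap",
    "Shell",
    "SymmetryProfile",
    "SpikeScores",
    "GlobalScore",
    "wrap_orientation",
    "circular_mean_orientation",
]

POSITION_TOLERANCE = 1e-9  # spikes may sit this far outside the arena (m)


class SpikeSymError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpikeSymError, ValueError):
    """Invalid input data or parameters."""


class DegenerateInputError(SpikeSymError, ValueError):
    """Input that is formally valid but carries no usable structure."""


class SpacingDetectionError(SpikeSymError, RuntimeError):
    """Grid-spacing detection from the pairwise-distance histogram failed.

    Carries the histogram (when available) for diagnostics; downstream
    pipelines typically catch this and report all-zero scores with a
    failure flag instead of aborting.
    """

    def __init__(self, message: str, histogram=None):
        super().__init__(message)
        self.histogram = histogram


@dataclass(frozen=True)
class Arena:
    """Axis-aligned bounding box of the recording arena (meters)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(
                f"arena must have positive width and height, got {self}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def side(self) -> float:
        """Shorter side length, used to scale resolution parameters."""
        return min(self.width, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the arena (within ``tol``)."""
        p = np.asarray(points, dtype=float)
        return (
            (p[..., 0] >= self.x_min - tol)
            & (p[..., 0] <= self.x_max + tol)
            & (p[..., 1] >= self.y_min - tol)
            & (p[..., 1] <= self.y_max + tol)
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.x_max, self.y_min, self.y_max)


def _as_arena(arena) -> Arena:
    if isinstance(arena, Arena):
        return arena
    return Arena(*arena)


@dataclass
class SpikeMap:
    """Ordered 2-D spike locations with optional spike times.

    Parameters
    ----------
    positions
        Array of shape (n, 2); spike locations in meters.
    arena
        Bounding box containing all positions (within 1e-9 m).
    times
        Optional spike times in seconds, nondecreasing, same length as
        positions.
    """

    positions: np.ndarray
    arena: Arena
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.arena = _as_arena(self.arena)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError(
                f"positions must have shape (n, 2), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValidationError("a spike map needs at least one spike")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions contain non-finite values")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.positions.shape[0],):
                raise ValidationError(
                    "times must have one entry per spike "
                    f"({self.times.shape[0]} times, {self.positions.shape[0]} spikes)"
                )
            if np.any(np.diff(self.times) < 0):
                raise ValidationError("spike times must be nondecreasing")
        inside = self.arena.contains(self.positions, tol=POSITION_TOLERANCE)
        if not np.all(inside):
            k = int(np.flatnonzero(~inside)[0])
            raise ValidationError(
                f"spike {k} at {tuple(self.positions[k])} lies outside the "
                f"arena {self.arena.as_tuple()}"
            )

    @property
    def n_spikes(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_spikes


HEX_INNER_FRACTION = 5.0 / 6.0
HEX_OUTER_FRACTION = 7.0 / 6.0


@dataclass(frozen=True)
class Shell:
    """Annular spike neighborhood: grid spacing ``ell`` and shell radii (m)."""

    ell: float
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (self.ell > 0):
            raise ValidationError(f"grid spacing must be positive, got {self.ell}")
        if not (0 < self.r_inner < self.r_outer):
            raise ValidationError(
                f"need 0 < r_inner < r_outer, got ({self.r_inner}, {self.r_outer})"
            )

    @classmethod
    def hexagonal(cls, ell: float) -> "Shell":
        """Default shell for 6-fold symmetry: radii 5/6 and 7/6 of ``ell``."""
        return cls(ell=ell, r_inner=HEX_INNER_FRACTION * ell, r_outer=HEX_OUTER_FRACTION * ell)


@dataclass
class SymmetryProfile:
    """Per-spike complex order parameters psi^(M) and the neighbor count.

    ``psi[M]`` is the M-fold bond-orientational order parameter over the
    spike's shell neighbors; ``|psi[M]| <= 1`` always. With zero neighbors
    the profile is undefined and every psi is NaN.
    """

    psi: Mapping[int, complex]
    n_neighbors: int

    @property
    def defined(self) -> bool:
        return self.n_neighbors > 0

    def magnitudes(self) -> dict[int, float]:
        return {m: abs(v) for m, v in self.psi.items()}


@dataclass
class SpikeScores:
    """Per-spike grid scores and orientations for a whole spike map.

    ``psi_hat`` is in [0, 1] and exactly 0 for spikes with no neighbors or
    with a non-dominant target symmetry. ``theta_deg`` is NaN where
    undefined (no neighbors or vanishing order parameter).
    """

    psi_hat: np.ndarray
    theta_deg: np.ndarray
    n_neighbors: np.ndarray
    psi_mag: Mapping[int, np.ndarray]
    target_m: int = 6
    shell: Optional[Shell] = None
    detection_failed: bool = False

    @property
    def n_spikes(self) -> int:
        return self.psi_hat.shape[0]

    @property
    def no_neighbors(self) -> np.ndarray:
        """Mask of spikes whose score is zero for lack of neighbors (as
        opposed to spikes that failed the symmetry comparison)."""
        return self.n_neighbors == 0

    def __len__(self) -> int:
        return self.n_spikes


@dataclass
class GlobalScore:
    """Arena-wide mean grid score Psi and circular-mean orientation Theta."""

    psi: float
    theta_deg: float  # NaN when no spike has a defined orientation

    @property
    def theta_defined(self) -> bool:
        return np.isfinite(self.theta_deg)


def wrap_orientation(theta_deg, m: int = 6):
    """Wrap orientation(s) in degrees to the interval ``(-180/M, 180/M]``."""
    half = 180.0 / m
    period = 360.0 / m
    theta = np.asarray(theta_deg, dtype=float)
    wrapped = np.mod(theta + half, period) - half
    # mod maps the upper boundary to the lower one; put it back
    wrapped = np.where(wrapped <= -half, wrapped + period, wrapped)
    if np.ndim(theta_deg) == 0:
        return float(wrapped)
    return wrapped


def circular_mean_orientation(
    theta_deg: Sequence[float],
    m: int = 6,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Circular mean of orientations with period ``360/M`` degrees.

    Each orientation contributes a unit vector at angle ``M * theta``; the
    mean is ``arg`` of the resultant divided by M, wrapped to
    ``(-180/M, 180/M]``. Returns NaN for an empty input or a vanishing
    resultant (no preferred orientation).
    """
    theta = np.asarray(theta_deg, dtype=float)
    theta = theta[np.isfinite(theta)] if weights is None else theta
    if theta.size == 0:
        return float("nan")
    z = np.exp(1j * np.deg2rad(theta) * m)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        keep = np.isfinite(np.asarray(theta_deg, dtype=float)) & (w > 0)
        if not np.any(keep):
            return float("nan")
        z = np.exp(1j * np.deg2rad(np.asarray(theta_deg, dtype=float)[keep]) * m)
        resultant = np.sum(w[keep] * z)
    else:
        resultant = np.sum(z)
    if abs(resultant) < 1e-15:
        return float("nan")
    return wrap_orientation(np.rad2deg(np.angle(resultant)) / m, m=m)
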