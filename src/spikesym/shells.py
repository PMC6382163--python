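"""Neighborhood-shell detection from the pairwise-distance histogram.

For a periodic firing pattern the histogram of pairwise spike distances
shows a first peak at the grid-field size and a second peak at the grid
spacing ell; the hexagonal neighborhood shell is the annulus from
(5/6) ell to (7/6) ell. The histogram is smoothed with a Gaussian kernel
whose standard deviation is 1% of the maximal pairwise distance.

Two remedies for noisy patterns are provided: a distance cutoff (use the
first peak beyond 15% of the arena side length), and pooling the spacing
across several cells of the same grid module (median of the successful
detections).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist

from .types import (
    DegenerateInputError,
    Shell,
    SpacingDetectionError,
    SpikeMap,
    ValidationError,
)

__all__ = [
    "DistanceHistogram",
    "distance_histogram",
    "detect_spacing",
    "shell_for_symmetry",
    "detect_shell",
    "spacing_from_module",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_FRACTION = 0.005  # bin width as a fraction of the max pairwise distance
SMOOTHING_FRACTION = 0.01  # Gaussian sigma as a fraction of the max pairwise distance
DEFAULT_CUTOFF_FRACTION = 0.15  # cutoff remedy: fraction of the arena side length

#: Shell center radius as a fraction of the grid spacing, per symmetry order.
#: 6-fold: one spacing (the six nearest fields); 4-fold: 2/3 ell; 2-fold
#: (bands): ell/2 so the next band stays outside the shell.
SHELL_CENTER_FRACTION = {6: 1.0, 4: 2.0 / 3.0, 2: 0.5}

#: Shell half-width as a fraction of the grid spacing (shell width ell/3).
SHELL_HALF_WIDTH_FRACTION = 1.0 / 6.0


@dataclass
class DistanceHistogram:
    """Histogram of all pairwise spike distances, raw and smoothed."""

    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    d_max: float
    bin_width: float

    def peak_distances(self) -> np.ndarray:
        """Distances of the strict local maxima of the smoothed histogram.

        A peak must exceed both neighboring values; plateaus count once,
        at their leftmost bin. Boundary bins cannot be peaks.
        """
        idx, props = find_peaks(self.smoothed, plateau_size=(1, None))
        left = props.get("left_edges", idx)
        return self.bin_centers[np.asarray(left, dtype=int)]


def distance_histogram(
    spikes: SpikeMap, bin_fraction: float = DEFAULT_BIN_FRACTION
) -> DistanceHistogram:
    """Histogram of the N(N-1)/2 pairwise distances, Gaussian-smoothed.

    Bin width is ``bin_fraction`` of the maximal pairwise distance (default
    0.5%, so the 1%-of-d_max smoothing kernel spans two bins).
    """
    if spikes.n_spikes < 2:
        raise ValidationError("need at least two spikes for a distance histogram")
    if not (0 < bin_fraction < 1):
        raise ValidationError(f"bin_fraction must be in (0, 1), got {bin_fraction}")
    d = pdist(spikes.positions)
    d_max = float(d.max())
    if d_max == 0.0:
        raise DegenerateInputError("all spikes are coincident")
    n_bins = int(round(1.0 / bin_fraction))
    edges = np.linspace(0.0, d_max, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    bin_width = d_max / n_bins
    sigma_bins = SMOOTHING_FRACTION * d_max / bin_width
    smoothed = gaussian_filter1d(counts.astype(float), sigma_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DistanceHistogram(
        bin_centers=centers,
        counts=counts,
        smoothed=smoothed,
        d_max=d_max,
        bin_width=bin_width,
    )


def detect_spacing(
    hist: Optional[DistanceHistogram],
    mode: str = "second_peak",
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    arena_side: Optional[float] = None,
    manual_ell: Optional[float] = None,
) -> float:
    """Estimate the grid spacing ell (m) from the distance histogram.

    Modes
    -----
    ``second_peak``
        Distance of the second local maximum of the smoothed histogram
        (the first maximum reflects the grid-field size).
    ``cutoff``
        Distance of the first local maximum beyond
        ``cutoff_fraction * arena_side`` — a remedy for noisy patterns
        whose field-size peak is unreliable.
    ``manual``
        ``manual_ell`` passed through unchanged (e.g. a value read off the
        histograms of a whole module by eye).
    """
    if mode == "manual":
        if manual_ell is None or not (manual_ell > 0):
            raise ValidationError("manual mode requires manual_ell > 0")
        return float(manual_ell)
    if hist is None:
        raise ValidationError(f"mode {mode!r} requires a distance histogram")
    peaks = hist.peak_distances()
    if mode == "second_peak":
        if peaks.size < 2:
            raise SpacingDetectionError(
                f"need two histogram peaks, found {peaks.size}", histogram=hist
            )
        return float(peaks[1])
    if mode == "cutoff":
        if arena_side is None or not (arena_side > 0):
            raise ValidationError("cutoff mode requires arena_side > 0")
        cutoff = cutoff_fraction * arena_side
        above = peaks[peaks > cutoff]
        if above.size == 0:
            raise SpacingDetectionError(
                f"no histogram peak beyond the cutoff {cutoff:.4g} m", histogram=hist
            )
        return float(above[0])
    raise ValidationError(f"unknown spacing-detection mode {mode!r}")


def shell_for_symmetry(ell: float, m: int = 6) -> Shell:
    """Neighborhood shell for an M-fold target symmetry.

    The shell is the annulus of half-width ell/6 centered at ell (M=6),
    (2/3) ell (M=4) or ell/2 (M=2).
    """
    if not (ell > 0):
        raise ValidationError(f"grid spacing must be positive, got {ell}")
    if m not in SHELL_CENTER_FRACTION:
        raise ValidationError(
            f"no shell rule for M={m}; supported: {sorted(SHELL_CENTER_FRACTION)}"
        )
    center = SHELL_CENTER_FRACTION[m] * ell
    half = SHELL_HALF_WIDTH_FRACTION * ell
    return Shell(ell=ell, r_inner=center - half, r_outer=center + half)


def detect_shell(
    spikes: SpikeMap,
    mode: str = "second_peak",
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    manual_ell: Optional[float] = None,
    bin_fraction: float = DEFAULT_BIN_FRACTION,
    target_m: int = 6,
) -> Shell:
    """End-to-end shell detection: histogram -> spacing -> shell."""
    hist = None
    if mode != "manual":
        hist = distance_histogram(spikes, bin_fraction=bin_fraction)
    ell = detect_spacing(
        hist,
        mode=mode,
        cutoff_fraction=cutoff_fraction,
        arena_side=spikes.arena.side,
        manual_ell=manual_ell,
    )
    shell = shell_for_symmetry(ell, m=target_m)
    logger.info(
        "detected grid spacing ell=%.4g m (mode=%s); shell [%.4g, %.4g] m",
        ell, mode, shell.r_inner, shell.r_outer,
    )
    return shell


def spacing_from_module(
    maps: Sequence[SpikeMap],
    mode: str = "second_peak",
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    bin_fraction: float = DEFAULT_BIN_FRACTION,
) -> float:
    """Pooled grid spacing for cells of one grid module.

    Runs spacing detection on every map, skips (and logs) failures, and
    returns the median of the successful detections. Raises if every map
    fails.
    """
    maps = list(maps)
    if len(maps) == 0:
        raise ValidationError("need at least one spike map")
    detected = []
    for i, sm in enumerate(maps):
        try:
            hist = distance_histogram(sm, bin_fraction=bin_fraction)
            detected.append(
                detect_spacing(
                    hist,
                    mode=mode,
                    cutoff_fraction=cutoff_fraction,
                    arena_side=sm.arena.side,
                )
            )
        except (SpacingDetectionError, DegenerateInputError) as exc:
            logger.info("module pooling: skipping map %d (%s)", i, exc)
    if not detected:
        raise SpacingDetectionError("spacing detection failed on every map in the module")
    return float(np.median(detected))
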