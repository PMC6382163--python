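"""Conventional correlogram-based grid score (the rho baseline).

Spike locations are binned into a smoothed spike-density map ("rate map";
no occupancy normalization — no trajectory is modeled), its spatial
autocorrelogram is computed as a Pearson correlation at every integer lag,
an annulus around the six inner peaks is cropped, and the annulus is
correlated with copies of itself rotated by 30..150 degrees:

    rho = min(r_60, r_120) - max(r_30, r_90, r_150)

Perfect hexagonal patterns give rho near 1.5; patterns without hexagonal
structure give rho near -0.5 to 0. Annulus construction rules (the 0.1
central-peak threshold, the 1.25 outer-radius factor, the minimum overlap)
are package defaults exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .types import Arena, SpikeMap, ValidationError

__all__ = [
    "RateMap",
    "Correlogram",
    "RhoResult",
    "rate_map",
    "autocorrelogram",
    "rho_score",
    "rho_for_spike_map",
]

DEFAULT_BIN_SIZE_FRACTION = 0.02  # of the arena side (2 cm for a 1 m arena)
DEFAULT_SIGMA_FRACTION = 0.04  # of the arena side (4 cm for a 1 m arena)
DEFAULT_MIN_OVERLAP = 20  # bins
CENTRAL_PEAK_THRESHOLD = 0.1
OUTER_RADIUS_FACTOR = 1.25
ROTATION_ANGLES = (30, 60, 90, 120, 150)


@dataclass
class RateMap:
    """Smoothed spike density on a regular grid covering the arena."""

    values: np.ndarray  # shape (ny, nx), row 0 = southmost bin row
    bin_size: float
    smoothing_sigma: float
    arena: Arena


@dataclass
class Correlogram:
    """Spatial autocorrelogram: Pearson correlation at every integer lag."""

    values: np.ndarray  # shape (2*ny-1, 2*nx-1); center = zero lag
    valid_mask: np.ndarray  # lags with sufficient overlap and variance
    bin_size: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


@dataclass
class RhoResult:
    """Outcome of the rho computation, including failure diagnostics."""

    rho: float  # NaN when failed
    failed: bool
    reason: str = ""
    inner_radius: float = float("nan")  # meters
    outer_radius: float = float("nan")
    peak_distances_m: Optional[np.ndarray] = None
    rotation_corr: dict = field(default_factory=dict)


def rate_map(
    spikes: SpikeMap,
    bin_size: Optional[float] = None,
    sigma: Optional[float] = None,
) -> RateMap:
    """Gaussian-smoothed 2-D spike-count histogram over the arena.

    Defaults scale with the arena: 2 cm bins and 4 cm smoothing for a
    1 m arena. Smoothing truncates at the arena boundary (zero padding),
    so total mass is preserved only up to boundary losses.
    """
    arena = spikes.arena
    if bin_size is None:
        bin_size = DEFAULT_BIN_SIZE_FRACTION * arena.side
    if sigma is None:
        sigma = DEFAULT_SIGMA_FRACTION * arena.side
    if not (bin_size > 0 and sigma >= 0):
        raise ValidationError("bin_size must be > 0 and sigma >= 0")
    nx = int(round(arena.width / bin_size))
    ny = int(round(arena.height / bin_size))
    if nx < 3 or ny < 3:
        raise ValidationError(
            f"arena must span at least 3x3 bins, got {ny}x{nx} at bin_size={bin_size}"
        )
    counts, _, _ = np.histogram2d(
        spikes.positions[:, 1],
        spikes.positions[:, 0],
        bins=[ny, nx],
        range=[[arena.y_min, arena.y_max], [arena.x_min, arena.x_max]],
    )
    smoothed = ndimage.gaussian_filter(counts, sigma / bin_size, mode="constant")
    return RateMap(values=smoothed, bin_size=bin_size, smoothing_sigma=sigma, arena=arena)


def autocorrelogram(rmap: RateMap, min_overlap: int = DEFAULT_MIN_OVERLAP) -> Correlogram:
    """Pearson autocorrelation of the rate map at every spatial lag.

    For each lag the correlation is computed over the overlap region of
    the map and its shifted copy; lags whose overlap is smaller than
    ``min_overlap`` bins, or where either side has zero variance, are
    masked invalid. The value at zero lag is 1 and the correlogram is
    centrally symmetric.
    """
    a = np.asarray(rmap.values, dtype=float)
    ones = np.ones_like(a)
    flip = (slice(None, None, -1), slice(None, None, -1))
    n = np.round(fftconvolve(ones, ones[flip])).astype(int)
    s_x = fftconvolve(a, ones[flip])
    s_y = fftconvolve(ones, a[flip])
    s_xy = fftconvolve(a, a[flip])
    s_xx = fftconvolve(a * a, ones[flip])
    s_yy = fftconvolve(ones, (a * a)[flip])
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * s_xy - s_x * s_y
        var_x = n * s_xx - s_x**2
        var_y = n * s_yy - s_y**2
        denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_y, 0, None))
        r = cov / denom
    # tolerance for "zero variance" scaled to the FFT round-off magnitude
    var_tol = 1e-10 * np.maximum(n, 1) ** 2 * (float(np.mean(a * a)) + 1e-300)
    valid = (n >= min_overlap) & (var_x > var_tol) & (var_y > var_tol)
    r = np.clip(np.where(valid, r, np.nan), -1.0, 1.0)
    center = (r.shape[0] // 2, r.shape[1] // 2)
    if valid[center]:
        r[center] = 1.0
    return Correlogram(values=r, valid_mask=valid, bin_size=rmap.bin_size)


def _radial_profile(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean correlogram value per integer-radius ring from the center."""
    cy, cx = values.shape[0] // 2, values.shape[1] // 2
    yy, xx = np.indices(values.shape)
    rad = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    n_r = rad.max() + 1
    prof = np.full(n_r, np.nan)
    ok = valid & np.isfinite(values)
    sums = np.bincount(rad[ok], weights=values[ok], minlength=n_r)
    cnts = np.bincount(rad[ok], minlength=n_r)
    nz = cnts > 0
    prof[nz] = sums[nz] / cnts[nz]
    return prof


def _inner_radius_bins(profile: np.ndarray) -> Optional[float]:
    """Inner annulus radius: where the central peak first drops below the
    0.1 threshold, or the first local minimum, whichever is smaller."""
    finite = np.isfinite(profile)
    below = None
    for r in range(1, profile.size):
        if finite[r] and profile[r] < CENTRAL_PEAK_THRESHOLD:
            below = float(r)
            break
    local_min = None
    for r in range(1, profile.size - 1):
        if finite[r - 1] and finite[r] and finite[r + 1]:
            if profile[r] < profile[r - 1] and profile[r] <= profile[r + 1]:
                local_min = float(r)
                break
    candidates = [c for c in (below, local_min) if c is not None]
    return min(candidates) if candidates else None


def _field_peak_radii(
    values: np.ndarray,
    valid: np.ndarray,
    radius: np.ndarray,
    inner_bins: float,
    threshold: float,
) -> np.ndarray:
    """Radii (bins) of correlogram peaks outside the central field.

    Peaks are the value-weighted centroids of connected regions where the
    correlogram exceeds the threshold — the standard way autocorrelogram
    fields are located for rotation-based grid scores, and far more robust
    on noisy maps than raw local maxima.
    """
    mask = valid & np.isfinite(values) & (np.nan_to_num(values) > threshold)
    mask &= radius >= inner_bins
    labels, n_regions = ndimage.label(mask)
    if n_regions == 0:
        return np.empty(0)
    cy, cx = values.shape[0] // 2, values.shape[1] // 2
    centroids = np.atleast_2d(
        ndimage.center_of_mass(np.nan_to_num(values), labels, np.arange(1, n_regions + 1))
    )
    return np.hypot(centroids[:, 0] - cy, centroids[:, 1] - cx)


def rho_score(
    corr: Correlogram,
    central_peak_threshold: float = CENTRAL_PEAK_THRESHOLD,
    outer_radius_factor: float = OUTER_RADIUS_FACTOR,
) -> RhoResult:
    """Rotation-correlation grid score of an autocorrelogram.

    Finds the six off-center peaks nearest the center, crops the annulus
    around them, and compares Pearson correlations of the annulus with
    copies rotated by 60/120 degrees (hexagonal angles) versus 30/90/150
    degrees.
    """
    v = corr.values
    valid = corr.valid_mask & np.isfinite(v)
    cy, cx = corr.center
    yy, xx = np.indices(v.shape)
    radius = np.hypot(yy - cy, xx - cx)

    profile = _radial_profile(v, valid)
    inner_bins = _inner_radius_bins(profile)
    if inner_bins is None:
        return RhoResult(rho=float("nan"), failed=True, reason="no central-peak boundary")

    rad = _field_peak_radii(v, valid, radius, inner_bins, central_peak_threshold)
    if rad.size < 6:
        return RhoResult(
            rho=float("nan"), failed=True,
            reason=f"only {rad.size} off-center peaks found",
        )
    six_rad = np.sort(rad)[:6]
    outer_bins = outer_radius_factor * float(np.mean(six_rad))
    if outer_bins <= inner_bins:
        return RhoResult(rho=float("nan"), failed=True, reason="degenerate annulus")

    annulus = (radius >= inner_bins) & (radius <= outer_bins)

    v0 = np.where(valid, v, 0.0)
    w0 = valid.astype(float)
    rot_corr = {}
    for ang in ROTATION_ANGLES:
        v_rot = ndimage.rotate(v0, ang, reshape=False, order=1)
        w_rot = ndimage.rotate(w0, ang, reshape=False, order=1)
        ok = annulus & valid & (w_rot > 0.99)
        if np.count_nonzero(ok) < 3:
            return RhoResult(
                rho=float("nan"), failed=True, reason=f"empty overlap at {ang} deg"
            )
        x = v[ok]
        y = v_rot[ok] / w_rot[ok]
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            rot_corr[ang] = 0.0
        else:
            rot_corr[ang] = float(np.corrcoef(x, y)[0, 1])
    rho = min(rot_corr[60], rot_corr[120]) - max(rot_corr[30], rot_corr[90], rot_corr[150])
    return RhoResult(
        rho=float(rho),
        failed=False,
        inner_radius=inner_bins * corr.bin_size,
        outer_radius=outer_bins * corr.bin_size,
        peak_distances_m=six_rad * corr.bin_size,
        rotation_corr=rot_corr,
    )


def rho_for_spike_map(
    spikes: SpikeMap,
    bin_size: Optional[float] = None,
    sigma: Optional[float] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RhoResult:
    """Full rho pipeline: spike map -> rate map -> correlogram -> rho."""
    rmap = rate_map(spikes, bin_size=bin_size, sigma=sigma)
    corr = autocorrelogram(rmap, min_overlap=min_overlap)
    return rho_score(corr)
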