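"""Spatially and temporally local aggregation of per-spike scores.

Because every spike carries its own grid score and orientation, local
analyses reduce to averaging: mean psi_hat and circular-mean theta inside
arbitrary arena partitions (poolable across cells), boxcar smoothing of
scores over spike time, per-block means within repeated trials, scoring
against a reference spike map, and correlating the smoothed score with an
external covariate such as the lighting condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .psi import score_against_reference
from .types import (
    Arena,
    SpikeMap,
    SpikeScores,
    ValidationError,
    wrap_orientation,
)

__all__ = [
    "Region",
    "Partitioning",
    "PartitionSummary",
    "grid_partitioning",
    "strip_partitioning",
    "partition_means",
    "pool_cells",
    "ScoreSeries",
    "temporal_filter",
    "reference_scores",
    "block_average",
    "covariate_correlation",
]

reference_scores = score_against_reference  # per-spike scoring against a reference map


@dataclass(frozen=True)
class Region:
    """Named arena region: an axis-aligned rectangle or a predicate.

    Rectangles are half-open, ``[min, max)`` on each axis, except that a
    rectangle edge coinciding with the arena's maximum edge is closed —
    so a set of abutting strips assigns every spike to exactly one region.
    """

    name: str
    rect: Optional[tuple[float, float, float, float]] = None  # x_min, x_max, y_min, y_max
    predicate: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if (self.rect is None) == (self.predicate is None):
            raise ValidationError("a region needs exactly one of rect or predicate")

    def contains(self, points: np.ndarray, arena: Arena) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if self.predicate is not None:
            return np.asarray(self.predicate(p), dtype=bool)
        x_min, x_max, y_min, y_max = self.rect
        x_hi = p[:, 0] <= x_max if np.isclose(x_max, arena.x_max) else p[:, 0] < x_max
        y_hi = p[:, 1] <= y_max if np.isclose(y_max, arena.y_max) else p[:, 1] < y_max
        return (p[:, 0] >= x_min) & x_hi & (p[:, 1] >= y_min) & y_hi


@dataclass(frozen=True)
class Partitioning:
    """Ordered list of regions; first matching region wins.

    Regions need not tile the arena; spikes matching no region are left
    unassigned.
    """

    regions: tuple[Region, ...]

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate region names: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def assign(self, points: np.ndarray, arena: Arena) -> np.ndarray:
        """Region index per point (-1 if unassigned), first match wins."""
        out = np.full(len(points), -1, dtype=int)
        for i, region in enumerate(self.regions):
            unset = out == -1
            if not np.any(unset):
                break
            hit = region.contains(points, arena)
            out[unset & hit] = i
        return out


def grid_partitioning(arena: Arena, nx: int, ny: int, prefix: str = "cell") -> Partitioning:
    """Regular nx-by-ny rectangular partitioning of the arena.

    Regions are named ``{prefix}_{ix}_{iy}`` with ix increasing eastward
    and iy increasing northward.
    """
    if nx < 1 or ny < 1:
        raise ValidationError("need nx >= 1 and ny >= 1")
    xs = np.linspace(arena.x_min, arena.x_max, nx + 1)
    ys = np.linspace(arena.y_min, arena.y_max, ny + 1)
    regions = []
    for iy in range(ny):
        for ix in range(nx):
            regions.append(
                Region(
                    name=f"{prefix}_{ix}_{iy}",
                    rect=(xs[ix], xs[ix + 1], ys[iy], ys[iy + 1]),
                )
            )
    return Partitioning(regions=tuple(regions))


def strip_partitioning(arena: Arena, n: int, axis: str = "x", prefix: str = "strip") -> Partitioning:
    """n parallel strips along the west-east (``axis='x'``) or
    south-north (``axis='y'``) direction, numbered from west/south."""
    if axis == "x":
        return grid_partitioning(arena, n, 1, prefix=prefix)
    if axis == "y":
        return grid_partitioning(arena, 1, n, prefix=prefix)
    raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")


@dataclass
class PartitionSummary:
    """Per-region score summary.

    ``theta_resultant`` stores the summed unit vectors exp(i M theta) of
    the contributing spikes, so circular means pool exactly across cells.
    Regions without spikes have NaN means and are flagged via n_spikes=0.
    """

    names: tuple[str, ...]
    n_spikes: np.ndarray
    mean_psi: np.ndarray  # NaN where undefined
    theta_deg: np.ndarray  # circular mean, NaN where undefined
    n_cells: np.ndarray
    target_m: int = 6
    psi_sum: np.ndarray = None
    theta_resultant: np.ndarray = None
    n_theta: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": list(self.names),
                "n_spikes": self.n_spikes,
                "n_cells": self.n_cells,
                "mean_psi": self.mean_psi,
                "theta_deg": self.theta_deg,
            }
        )


def partition_means(
    scores: SpikeScores, spikes: SpikeMap, parts: Partitioning
) -> PartitionSummary:
    """Mean psi_hat and circular-mean theta per region.

    The orientation mean uses the same 60-degree-period construction as
    the global Theta, over spikes with psi_hat > 0.
    """
    if scores.n_spikes != spikes.n_spikes:
        raise ValidationError("scores and spikes are not aligned")
    idx = parts.assign(spikes.positions, spikes.arena)
    k = len(parts.regions)
    m = scores.target_m
    n_spk = np.bincount(idx[idx >= 0], minlength=k)
    psi_sum = np.bincount(idx[idx >= 0], weights=scores.psi_hat[idx >= 0], minlength=k)

    contributes = (idx >= 0) & (scores.psi_hat > 0) & np.isfinite(scores.theta_deg)
    z = np.exp(1j * m * np.deg2rad(scores.theta_deg[contributes]))
    zi = idx[contributes]
    resultant = (
        np.bincount(zi, weights=z.real, minlength=k)
        + 1j * np.bincount(zi, weights=z.imag, minlength=k)
    )
    n_theta = np.bincount(zi, minlength=k)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_psi = np.where(n_spk > 0, psi_sum / np.maximum(n_spk, 1), np.nan)
    theta = np.full(k, np.nan)
    ok = np.abs(resultant) > 1e-15
    theta[ok] = wrap_orientation(np.rad2deg(np.angle(resultant[ok])) / m, m=m)
    return PartitionSummary(
        names=parts.names,
        n_spikes=n_spk,
        mean_psi=mean_psi,
        theta_deg=theta,
        n_cells=(n_spk > 0).astype(int),
        target_m=m,
        psi_sum=psi_sum,
        theta_resultant=resultant,
        n_theta=n_theta,
    )


def pool_cells(per_cell: Sequence[PartitionSummary]) -> PartitionSummary:
    """Pool partition summaries across cells.

    Psi pools as the spike-count-weighted mean; theta pools by summing the
    per-spike unit-vector resultants (count-weighted circular mean).
    """
    per_cell = list(per_cell)
    if not per_cell:
        raise ValidationError("need at least one summary to pool")
    names = per_cell[0].names
    m = per_cell[0].target_m
    for s in per_cell[1:]:
        if s.names != names or s.target_m != m:
            raise ValidationError("summaries have mismatched partitionings")
    n_spk = np.sum([s.n_spikes for s in per_cell], axis=0)
    psi_sum = np.sum([s.psi_sum for s in per_cell], axis=0)
    resultant = np.sum([s.theta_resultant for s in per_cell], axis=0)
    n_theta = np.sum([s.n_theta for s in per_cell], axis=0)
    n_cells = np.sum([(s.n_spikes > 0).astype(int) for s in per_cell], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_psi = np.where(n_spk > 0, psi_sum / np.maximum(n_spk, 1), np.nan)
    k = len(names)
    theta = np.full(k, np.nan)
    ok = np.abs(resultant) > 1e-15
    theta[ok] = wrap_orientation(np.rad2deg(np.angle(resultant[ok])) / m, m=m)
    return PartitionSummary(
        names=names,
        n_spikes=n_spk,
        mean_psi=mean_psi,
        theta_deg=theta,
        n_cells=n_cells,
        target_m=m,
        psi_sum=psi_sum,
        theta_resultant=resultant,
        n_theta=n_theta,
    )


@dataclass
class ScoreSeries:
    """Per-spike score values over spike time, optionally smoothed."""

    times: np.ndarray
    values: np.ndarray
    smoothed: Optional[np.ndarray] = None
    window: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have the same length")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("times must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.times, "psi_hat": self.values}
        if self.smoothed is not None:
            d["smoothed"] = self.smoothed
        return pd.DataFrame(d)


def temporal_filter(series: ScoreSeries, window: float) -> ScoreSeries:
    """Centered boxcar smoothing over time (not index).

    The smoothed value at spike k is the mean of values over all spikes j
    with ``|t_j - t_k| <= window / 2``; edge windows are truncated, not
    padded. ``window = 0`` averages only exactly-coincident spikes, which
    for distinct times is the identity.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    t, v = series.times, series.values
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(t, t - window / 2.0, side="left")
    hi = np.searchsorted(t, t + window / 2.0, side="right")
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return ScoreSeries(times=t, values=v, smoothed=smoothed, window=window)


def block_average(
    scores: SpikeScores,
    times: np.ndarray,
    trial_len: float,
    block_len: float,
    trial_labels: Sequence,
) -> pd.DataFrame:
    """Mean psi_hat per (trial label, within-trial time block).

    Spikes are binned by ``floor((t mod trial_len) / block_len)`` within
    each label (e.g. "light"/"dark" trials of 2 minutes split into
    12 x 10 s blocks). Empty blocks appear with NaN mean.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(trial_labels)
    if times.shape[0] != scores.n_spikes or labels.shape[0] != scores.n_spikes:
        raise ValidationError("times and trial_labels must have one entry per spike")
    n_blocks_f = trial_len / block_len
    n_blocks = int(round(n_blocks_f))
    if not np.isclose(n_blocks_f, n_blocks) or n_blocks < 1:
        raise ValidationError("trial_len must be an integer multiple of block_len")
    block = np.floor(np.mod(times, trial_len) / block_len).astype(int)
    block = np.minimum(block, n_blocks - 1)  # guard t == trial_len boundary
    df = pd.DataFrame({"label": labels, "block": block, "psi_hat": scores.psi_hat})
    grouped = df.groupby(["label", "block"])["psi_hat"].agg(["mean", "count"])
    full = pd.MultiIndex.from_product(
        [np.unique(labels), np.arange(n_blocks)], names=["label", "block"]
    )
    out = grouped.reindex(full).reset_index()
    out = out.rename(columns={"mean": "mean_psi", "count": "n_spikes"})
    out["n_spikes"] = out["n_spikes"].fillna(0).astype(int)
    return out


def covariate_correlation(
    series: ScoreSeries,
    covariate: Union[Callable[[np.ndarray], np.ndarray], np.ndarray],
) -> float:
    """Pearson correlation between the (smoothed) score series and a
    time-varying covariate evaluated at the spike times.

    Returns NaN when either series has zero variance.
    """
    y = series.smoothed if series.smoothed is not None else series.values
    if callable(covariate):
        c = np.asarray(covariate(series.times), dtype=float)
    else:
        c = np.asarray(covariate, dtype=float)
    if c.shape != y.shape:
        raise ValidationError("covariate must be evaluable at every spike time")
    if np.std(y) < 1e-15 or np.std(c) < 1e-15:
        return float("nan")
    r, _ = stats.pearsonr(y, c)
    return float(r)
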