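"""Shuffling-based grid-cell classification with a flexible threshold.

The spike locations are shuffled (redrawn uniformly over the arena, which
destroys all spatial structure while preserving the spike count), the grid
score is computed for each of ``n_shuffles`` shuffled maps, and the cell
is called a grid cell only if its actual score strictly exceeds the 95th
percentile of the shuffled scores. The procedure works with either the
spike-based Psi score or the correlogram-based rho score; because the
per-cell null carries the cell's own spike count, cells with many
background spikes keep a fair threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import shells
from .correlogram import rho_for_spike_map
from .psi import DEFAULT_M_SET, global_scores, score_spike_map
from .shells import detect_shell
from .types import (
    DegenerateInputError,
    SpacingDetectionError,
    SpikeMap,
    SpikeScores,
    ValidationError,
)

__all__ = [
    "shuffle_spike_map",
    "psi_pipeline",
    "rho_pipeline",
    "classify",
    "ClassificationResult",
    "PipelineResult",
]

DEFAULT_N_SHUFFLES = 100
DEFAULT_PERCENTILE = 95.0

#: Score assigned when the pipeline fails on a shuffled map (shell or
#: annulus detection failure). Floors keep failed shuffles from inflating
#: the null threshold.
FAILURE_SCORE = {"psi": 0.0, "rho": -2.0}


def shuffle_spike_map(spikes: SpikeMap, seed=None) -> SpikeMap:
    """Shuffled copy: same spike count, positions uniform over the arena.

    Times (when present) are preserved in order. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    a = spikes.arena
    pos = np.column_stack(
        [
            rng.uniform(a.x_min, a.x_max, spikes.n_spikes),
            rng.uniform(a.y_min, a.y_max, spikes.n_spikes),
        ]
    )
    return SpikeMap(positions=pos, arena=a, times=spikes.times)


@dataclass
class PipelineResult:
    """Score of a full spike map, with failure diagnostics."""

    value: float
    failed: bool
    reason: str = ""
    scores: Optional[SpikeScores] = None


def psi_pipeline(
    spikes: SpikeMap,
    shell_mode: str = "second_peak",
    cutoff_fraction: float = shells.DEFAULT_CUTOFF_FRACTION,
    manual_ell: Optional[float] = None,
    m_set=DEFAULT_M_SET,
    target_m: int = 6,
) -> PipelineResult:
    """Spike map -> shell detection -> per-spike scores -> global Psi.

    Shell-detection failure does not raise: it yields all-zero scores with
    a failure flag, matching how such cells are treated downstream.
    """
    try:
        shell = detect_shell(
            spikes,
            mode=shell_mode,
            cutoff_fraction=cutoff_fraction,
            manual_ell=manual_ell,
            target_m=target_m,
        )
    except (SpacingDetectionError, DegenerateInputError, ValidationError) as exc:
        n = spikes.n_spikes
        zero = SpikeScores(
            psi_hat=np.zeros(n),
            theta_deg=np.full(n, np.nan),
            n_neighbors=np.zeros(n, dtype=int),
            psi_mag={m: np.full(n, np.nan) for m in m_set},
            target_m=target_m,
            shell=None,
            detection_failed=True,
        )
        return PipelineResult(
            value=FAILURE_SCORE["psi"], failed=True, reason=str(exc), scores=zero
        )
    scores = score_spike_map(spikes, shell, m_set=m_set, target_m=target_m)
    return PipelineResult(value=global_scores(scores).psi, failed=False, scores=scores)


def rho_pipeline(spikes: SpikeMap, **rho_kwargs) -> PipelineResult:
    """Spike map -> rate map -> correlogram -> rho."""
    try:
        result = rho_for_spike_map(spikes, **rho_kwargs)
    except (ValidationError, DegenerateInputError) as exc:
        return PipelineResult(value=FAILURE_SCORE["rho"], failed=True, reason=str(exc))
    if result.failed:
        return PipelineResult(value=FAILURE_SCORE["rho"], failed=True, reason=result.reason)
    return PipelineResult(value=result.rho, failed=False)


_PIPELINES = {"psi": psi_pipeline, "rho": rho_pipeline}


@dataclass
class ClassificationResult:
    """Outcome of the flexible-threshold classification of one cell."""

    score_type: str
    actual: float
    threshold: float
    is_grid: bool
    n_shuffles: int
    percentile: float
    seed: Optional[int]
    actual_failed: bool
    shuffle_scores: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "score_type": self.score_type,
            "actual": self.actual,
            "threshold": self.threshold,
            "is_grid": bool(self.is_grid),
            "n_shuffles": self.n_shuffles,
            "percentile": self.percentile,
            "seed": self.seed,
            "actual_failed": bool(self.actual_failed),
        }


def classify(
    spikes: SpikeMap,
    score: str = "psi",
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    percentile: float = DEFAULT_PERCENTILE,
    seed: Optional[int] = None,
    **pipeline_kwargs,
) -> ClassificationResult:
    """Flexible-threshold grid-cell test for one spike map.

    Computes the chosen score on the actual map and on ``n_shuffles``
    uniformly-relocated shuffles; the threshold is the requested
    percentile (linear interpolation between order statistics) of the
    shuffled scores and the cell is a grid cell only if the actual score
    strictly exceeds it. Shell or annulus re-detection runs per shuffled
    map, exactly as for the actual map.
    """
    if score not in _PIPELINES:
        raise ValidationError(f"score must be one of {sorted(_PIPELINES)}, got {score!r}")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    if not (0 < percentile < 100):
        raise ValidationError("percentile must be in (0, 100)")
    pipeline = _PIPELINES[score]
    actual = pipeline(spikes, **pipeline_kwargs)
    rng = np.random.default_rng(seed)
    shuffle_seeds = rng.integers(0, 2**31, size=n_shuffles)
    shuffled_scores = np.array(
        [
            pipeline(shuffle_spike_map(spikes, seed=int(s)), **pipeline_kwargs).value
            for s in shuffle_seeds
        ]
    )
    threshold = float(np.percentile(shuffled_scores, percentile, method="linear"))
    is_grid = (not actual.failed) and (actual.value > threshold)
    return ClassificationResult(
        score_type=score,
        actual=float(actual.value),
        threshold=threshold,
        is_grid=is_grid,
        n_shuffles=n_shuffles,
        percentile=percentile,
        seed=seed,
        actual_failed=actual.failed,
        shuffle_scores=shuffled_scores,
    )
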