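"""Spike-based M-fold symmetry scores.

Each spike k receives a complex order parameter per symmetry order M,

    psi_k^(M) = (1/N) sum_l exp(i M phi_l),

where the phi_l are the angles from spike k to its N shell neighbors,
measured from the positive horizontal axis. The per-spike grid score
``psi_hat_k`` is ``|psi_k^(6)|`` if the 6-fold magnitude strictly exceeds
the magnitudes of all competing symmetries (M in {2,3,4,5,7} by default),
and 0 otherwise — the comparison suppresses false positives from, e.g.,
collinear field arrangements. The per-spike orientation is
``theta_k = arg(psi_k^(6)) / 6`` in degrees, wrapped to (-30, 30].

Arena-wide summaries: Psi is the plain arithmetic mean of psi_hat over all
spikes (zeros included); Theta is the circular mean (period 60 degrees) of
the orientations of spikes with psi_hat > 0.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .types import (
    GlobalScore,
    Shell,
    SpikeMap,
    SpikeScores,
    SymmetryProfile,
    ValidationError,
    circular_mean_orientation,
    wrap_orientation,
)

__all__ = [
    "DEFAULT_M_SET",
    "neighbor_angles",
    "psi_m",
    "symmetry_profile",
    "psi_hat",
    "spike_orientation",
    "score_spike_map",
    "score_against_reference",
    "global_scores",
]

#: Symmetry orders compared by default. Orders above 7 have no effect on
#: the comparison outcome for grid-like patterns.
DEFAULT_M_SET = (2, 3, 4, 5, 6, 7)

#: Absolute tolerance for the "hexagonal strictly strongest" comparison.
#: Exact ties (e.g. two opposite neighbors: |psi2| = |psi6| = 1) must give
#: psi_hat = 0; the tolerance makes this robust to floating-point noise.
TIE_TOLERANCE = 1e-12


def _pair_angles(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Angles in (-pi, pi] from displacement components."""
    ang = np.arctan2(dy, dx)
    # arctan2 maps (-x, -0.0) to -pi; fold onto the upper boundary
    ang = np.where(ang == -np.pi, np.pi, ang)
    return ang


def neighbor_angles(spikes: SpikeMap, k: int, shell: Shell) -> np.ndarray:
    """Angles phi_l (radians) from spike ``k`` to each of its shell neighbors.

    A neighbor is any other spike whose distance from spike k lies in the
    closed interval [r_inner, r_outer]. Angles are measured from the
    positive horizontal axis, counter-clockwise, in (-pi, pi]; the order
    follows the spike index order.
    """
    n = spikes.n_spikes
    if not (-n <= k < n):
        raise IndexError(f"spike index {k} out of range for {n} spikes")
    k = k % n
    delta = spikes.positions - spikes.positions[k]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    mask = (dist >= shell.r_inner) & (dist <= shell.r_outer)
    mask[k] = False
    return _pair_angles(delta[mask, 0], delta[mask, 1])


def psi_m(angles: Iterable[float], m: int) -> complex:
    """M-fold order parameter ``(1/N) sum_l exp(i M phi_l)`` over angles.

    Returns complex NaN for an empty angle list (undefined profile); the
    caller is expected to track the no-neighbor condition explicitly.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 2):
        raise ValidationError(f"symmetry order must be an integer >= 2, got {m}")
    phi = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles,
                     dtype=float)
    if phi.size == 0:
        return complex(np.nan, np.nan)
    return complex(np.mean(np.exp(1j * m * phi)))


def symmetry_profile(
    spikes: SpikeMap,
    k: int,
    shell: Shell,
    m_set: Iterable[int] = DEFAULT_M_SET,
) -> SymmetryProfile:
    """Full per-spike symmetry profile: psi^(M) for each M and the neighbor count."""
    phi = neighbor_angles(spikes, k, shell)
    return SymmetryProfile(
        psi={int(m): psi_m(phi, int(m)) for m in m_set},
        n_neighbors=int(phi.size),
    )


def psi_hat(profile: SymmetryProfile, target_m: int = 6) -> float:
    """Grid score of one spike: |psi^(target)| if it strictly dominates.

    Returns |psi^(target_m)| when that magnitude exceeds every competing
    |psi^(M)| by more than a 1e-12 tolerance; otherwise (ties included) 0.
    Undefined profiles (no neighbors) score 0.
    """
    if not profile.defined:
        return 0.0
    mags = profile.magnitudes()
    if target_m not in mags:
        raise ValidationError(f"profile lacks the target symmetry M={target_m}")
    target = mags[target_m]
    others = [v for m, v in mags.items() if m != target_m]
    if others and target <= max(others) + TIE_TOLERANCE:
        return 0.0
    return float(target)


def spike_orientation(profile: SymmetryProfile, target_m: int = 6) -> float:
    """Orientation of one spike in degrees, ``arg(psi^(M)) / M`` wrapped to
    ``(-180/M, 180/M]``. NaN when undefined (no neighbors or |psi| = 0)."""
    if not profile.defined:
        return float("nan")
    z = profile.psi[target_m]
    if abs(z) == 0.0 or not np.isfinite(z):
        return float("nan")
    return wrap_orientation(np.rad2deg(np.angle(z)) / target_m, m=target_m)


def _scores_from_pairs(
    qi: np.ndarray,
    angles: np.ndarray,
    n_query: int,
    m_set: tuple[int, ...],
    target_m: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Vectorized psi_hat/theta from a flat (query index, angle) pair list."""
    counts = np.bincount(qi, minlength=n_query)
    psi = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in m_set:
            z = np.exp(1j * m * angles)
            re = np.bincount(qi, weights=z.real, minlength=n_query)
            im = np.bincount(qi, weights=z.imag, minlength=n_query)
            psi[m] = np.where(counts > 0, (re + 1j * im) / np.maximum(counts, 1), np.nan)
    mags = {m: np.abs(psi[m]) for m in m_set}
    target = mags[target_m]
    competitors = np.vstack([mags[m] for m in m_set if m != target_m])
    dominant = target > competitors.max(axis=0) + TIE_TOLERANCE
    psi_hat_arr = np.where((counts > 0) & dominant, target, 0.0)

    theta = np.full(n_query, np.nan)
    ok = (counts > 0) & (target > 0)
    theta[ok] = wrap_orientation(
        np.rad2deg(np.angle(psi[target_m][ok])) / target_m, m=target_m
    )
    return psi_hat_arr, theta, counts, mags


def _validate_m_set(m_set, target_m: int) -> tuple[int, ...]:
    ms = tuple(sorted({int(m) for m in m_set}))
    if target_m not in ms:
        raise ValidationError(f"M set {ms} must contain the target symmetry {target_m}")
    if any(m < 2 for m in ms):
        raise ValidationError(f"symmetry orders must be >= 2, got {ms}")
    return ms


def score_spike_map(
    spikes: SpikeMap,
    shell: Shell,
    m_set: Iterable[int] = DEFAULT_M_SET,
    target_m: int = 6,
) -> SpikeScores:
    """Per-spike grid scores psi_hat_k and orientations theta_k for a map.

    Equivalent to evaluating :func:`symmetry_profile` / :func:`psi_hat` /
    :func:`spike_orientation` spike by spike, but vectorized over all pairs.
    """
    ms = _validate_m_set(m_set, target_m)
    pos = spikes.positions
    dist = cdist(pos, pos)
    np.fill_diagonal(dist, np.inf)
    qi, rj = np.nonzero((dist >= shell.r_inner) & (dist <= shell.r_outer))
    angles = _pair_angles(pos[rj, 0] - pos[qi, 0], pos[rj, 1] - pos[qi, 1])
    psi_hat_arr, theta, counts, mags = _scores_from_pairs(
        qi, angles, spikes.n_spikes, ms, target_m
    )
    return SpikeScores(
        psi_hat=psi_hat_arr,
        theta_deg=theta,
        n_neighbors=counts,
        psi_mag=mags,
        target_m=target_m,
        shell=shell,
    )


def score_against_reference(
    spikes: SpikeMap,
    reference: SpikeMap,
    shell: Shell,
    m_set: Iterable[int] = DEFAULT_M_SET,
    target_m: int = 6,
) -> SpikeScores:
    """Score each query spike against neighbors drawn from a reference map.

    Conceptually each query spike is added individually to the reference
    spike map and scored as usual; it contributes no neighbors to itself.
    Because the shell's inner radius is positive, a reference spike
    coincident with the query never counts as a neighbor, so scoring a
    map against itself reproduces :func:`score_spike_map` exactly.
    """
    ms = _validate_m_set(m_set, target_m)
    if reference.n_spikes < 1:
        raise ValidationError("reference map must be nonempty")
    qpos, rpos = spikes.positions, reference.positions
    dist = cdist(qpos, rpos)
    qi, rj = np.nonzero((dist >= shell.r_inner) & (dist <= shell.r_outer))
    angles = _pair_angles(rpos[rj, 0] - qpos[qi, 0], rpos[rj, 1] - qpos[qi, 1])
    psi_hat_arr, theta, counts, mags = _scores_from_pairs(
        qi, angles, spikes.n_spikes, ms, target_m
    )
    return SpikeScores(
        psi_hat=psi_hat_arr,
        theta_deg=theta,
        n_neighbors=counts,
        psi_mag=mags,
        target_m=target_m,
        shell=shell,
    )


def global_scores(scores: SpikeScores, include_zero_score_spikes: bool = False) -> GlobalScore:
    """Arena-wide Psi (mean of psi_hat over all spikes) and Theta.

    Theta is the circular mean (period ``360/M``) over spikes with
    psi_hat > 0 by default; set ``include_zero_score_spikes`` to average
    over every spike with a defined orientation instead.
    """
    if scores.n_spikes < 1:
        raise ValidationError("need at least one spike")
    psi = float(np.mean(scores.psi_hat))
    if include_zero_score_spikes:
        contributing = np.isfinite(scores.theta_deg)
    else:
        contributing = (scores.psi_hat > 0) & np.isfinite(scores.theta_deg)
    theta = circular_mean_orientation(scores.theta_deg[contributing], m=scores.target_m)
    return GlobalScore(psi=psi, theta_deg=theta)
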