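"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: they
loop over spike pairs with scalar math (cmath) so they can serve as an
independent check of the pipeline.
"""

import cmath
import math

import numpy as np
import pytest

from spikesym import Arena, GridSpec, Shell, SpikeMap, generate_grid_map

M_SET = (2, 3, 4, 5, 6, 7)
TIE_TOL = 1e-12


def brute_force_spike_scores(positions, shell, m_set=M_SET, target_m=6):
    """Per-spike psi_hat/theta/neighbor counts by explicit pair loops."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    psi_hat = np.zeros(n)
    theta = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    mags = {m: np.full(n, np.nan) for m in m_set}
    for k in range(n):
        angles = []
        for j in range(n):
            if j == k:
                continue
            dx = positions[j, 0] - positions[k, 0]
            dy = positions[j, 1] - positions[k, 1]
            d = math.hypot(dx, dy)
            if shell.r_inner <= d <= shell.r_outer:
                a = math.atan2(dy, dx)
                if a == -math.pi:
                    a = math.pi
                angles.append(a)
        counts[k] = len(angles)
        if not angles:
            continue
        psis = {}
        for m in m_set:
            total = 0j
            for a in angles:
                total += cmath.exp(1j * m * a)
            psis[m] = total / len(angles)
            mags[m][k] = abs(psis[m])
        target = abs(psis[target_m])
        others = max(abs(psis[m]) for m in m_set if m != target_m)
        if target > others + TIE_TOL:
            psi_hat[k] = target
        if target > 0:
            t = math.degrees(cmath.phase(psis[target_m])) / target_m
            half = 180.0 / target_m
            while t <= -half:
                t += 2 * half
            while t > half:
                t -= 2 * half
            theta[k] = t
    return psi_hat, theta, counts, mags


def brute_force_circular_mean(thetas_deg, m=6):
    """Circular mean by summing unit vectors at angle m*theta."""
    total = 0j
    for t in thetas_deg:
        total += cmath.exp(1j * m * math.radians(t))
    if abs(total) < 1e-15:
        return float("nan")
    t = math.degrees(cmath.phase(total)) / m
    half = 180.0 / m
    while t <= -half:
        t += 2 * half
    while t > half:
        t -= 2 * half
    return t


def hexagon_map(ell=1.0, center=(0.0, 0.0), phase_deg=0.0, arena=None):
    """One center spike plus six spikes on hexagon corners at distance ell."""
    cx, cy = center
    pts = [(cx, cy)]
    for i in range(6):
        a = math.radians(phase_deg + 60 * i)
        pts.append((cx + ell * math.cos(a), cy + ell * math.sin(a)))
    if arena is None:
        arena = Arena(cx - 2 * ell, cx + 2 * ell, cy - 2 * ell, cy + 2 * ell)
    return SpikeMap(np.array(pts), arena)


@pytest.fixture(scope="session")
def perfect_map():
    """Default synthetic perfect-grid map (0.5 m spacing, 1 m arena)."""
    return generate_grid_map(GridSpec(seed=42))


@pytest.fixture(scope="session")
def small_random_map():
    """200 uniform spikes in the unit arena (no grid structure)."""
    rng = np.random.default_rng(7)
    return SpikeMap(rng.uniform(0, 1, (200, 2)), Arena(0, 1, 0, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
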