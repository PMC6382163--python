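"""File formats: spike CSV in/out, per-spike score CSV, summary JSON.

Spike maps travel as plain CSV with a header — columns ``x,y`` (meters)
and optionally ``t`` (seconds). Per-spike scores are written with full
float precision so a write/read round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import Arena, SpikeMap, SpikeScores, ValidationError

__all__ = [
    "read_spike_map",
    "write_spike_map",
    "write_scores",
    "read_scores",
    "write_json",
]

ARENA_PAD_FRACTION = 0.01  # tight-bbox expansion when no arena is given


def _infer_arena(pos: np.ndarray) -> Arena:
    x_min, y_min = pos.min(axis=0)
    x_max, y_max = pos.max(axis=0)
    pad_x = max(ARENA_PAD_FRACTION * (x_max - x_min), 1e-6)
    pad_y = max(ARENA_PAD_FRACTION * (y_max - y_min), 1e-6)
    return Arena(x_min - pad_x, x_max + pad_x, y_min - pad_y, y_max + pad_y)


def read_spike_map(path, arena: Optional[Arena] = None) -> SpikeMap:
    """Read a spike map from CSV (columns x, y and optional t).

    Without an explicit arena, the tight bounding box of the spikes
    expanded by 1% is used. Non-numeric rows and missing columns raise
    descriptive errors with data line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    cols = ["x", "y"] + (["t"] if "t" in df.columns else [])
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df[cols].isna().all(axis=1)
    bad |= df[cols].isna().any(axis=1)
    if bad.any():
        lines = (numeric.index[bad] + 2).tolist()[:5]
        raise ValidationError(f"{path}: non-numeric or missing values at lines {lines}")
    pos = numeric[["x", "y"]].to_numpy(dtype=float)
    times = numeric["t"].to_numpy(dtype=float) if "t" in numeric.columns else None
    if arena is None:
        arena = _infer_arena(pos)
    return SpikeMap(positions=pos, arena=arena, times=times)


def write_spike_map(spikes: SpikeMap, path) -> None:
    """Write a spike map as CSV (x, y[, t]) with full float precision."""
    d = {"x": spikes.positions[:, 0], "y": spikes.positions[:, 1]}
    if spikes.times is not None:
        d["t"] = spikes.times
    pd.DataFrame(d).to_csv(path, index=False, float_format="%.17g")


def write_scores(scores: SpikeScores, spikes: SpikeMap, path) -> None:
    """Per-spike score CSV: x, y, t, psi_hat, theta_deg, n_neighbors and
    the |psi^(M)| magnitudes (columns psi2..psi7 for the default M set).
    Undefined orientations and magnitudes are written as empty fields."""
    if scores.n_spikes != spikes.n_spikes:
        raise ValidationError("scores and spikes are not aligned")
    d = {
        "x": spikes.positions[:, 0],
        "y": spikes.positions[:, 1],
        "t": spikes.times if spikes.times is not None else np.full(len(spikes), np.nan),
        "psi_hat": scores.psi_hat,
        "theta_deg": scores.theta_deg,
        "n_neighbors": scores.n_neighbors,
    }
    for m in sorted(scores.psi_mag):
        d[f"psi{m}"] = scores.psi_mag[m]
    # %.17g guarantees an exact float round trip through the CSV
    pd.DataFrame(d).to_csv(path, index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    """Read back a per-spike score CSV as a DataFrame."""
    return pd.read_csv(path, float_precision="round_trip")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
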