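"""Semi-quantitative measures needing no arterial input.

The modified standard uptake value (mSUV) scales the mean tissue activity
over a late time window by a size term and the injected dose,

    mSUV = activity * ((weight_kg + 70) / 2) / dose_MBq,

with activity the duration-weighted mean concentration (kBq/ml) over the
window (default 1790-3530 s post-injection, ~30-59 min).  The global
intensity (GI) of a summed image is the mean of all voxels exceeding 1/8 of
the whole-image mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import TimeActivityCurve

__all__ = ["MSUV_WINDOW", "MSUVResult", "msuv", "global_intensity"]

#: default mSUV window, seconds post-injection
MSUV_WINDOW: Tuple[float, float] = (1790.0, 3530.0)


@dataclass
class MSUVResult:
    region_id: str
    msuv: float
    window: Tuple[float, float]  # s post-injection
    mean_activity: float         # kBq/ml over the window


def window_mean(tac: TimeActivityCurve,
                window: Tuple[float, float] = MSUV_WINDOW) -> float:
    """Duration-weighted mean activity over a post-injection time window.

    Frames partially overlapping the window contribute in proportion to
    their overlap.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window end must exceed window start")
    sched = tac.schedule
    start = sched.frame_start - sched.injection_offset
    end = sched.frame_end - sched.injection_offset
    overlap = np.clip(np.minimum(end, w1) - np.maximum(start, w0), 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError("window lies outside the frame schedule")
    return float(np.sum(tac.values * overlap) / total)


def msuv(tac: TimeActivityCurve, weight_kg: float, dose_MBq: float,
         window: Tuple[float, float] = MSUV_WINDOW) -> MSUVResult:
    """Modified SUV of one region (see module docstring)."""
    if dose_MBq <= 0:
        raise ValueError("injected dose must be positive")
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    activity = window_mean(tac, window)
    value = activity * ((weight_kg + 70.0) / 2.0) / dose_MBq
    return MSUVResult(region_id=tac.region_id, msuv=float(value),
                      window=tuple(window), mean_activity=activity)


def global_intensity(volume: np.ndarray) -> float:
    """Mean of voxels above 1/8 of the whole-volume mean."""
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise ValueError("volume is empty")
    threshold = volume.mean() / 8.0
    mask = volume > threshold
    if not np.any(mask):
        raise ValueError("no voxel exceeds the 1/8-mean threshold")
    return float(volume[mask].mean())
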