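"""Core domain types for dynamic PET quantification.

All times are seconds; activity concentrations are kBq/ml and are assumed
decay-corrected to injection time.  Two time origins exist: the *scan* clock
(frame schedule) and the *injection* clock (kinetics, input function).  A
:class:`FrameSchedule` carries the offset between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: decay constant of carbon-11 (s^-1), half-life ~20.4 min
C11_LAMBDA = 5.663e-4

#: the acquisition design emulated throughout: a 30 s pre-injection frame
#: followed by frames of (mostly) increasing length over ~89 min
DEFAULT_FRAME_SPEC: Tuple[Tuple[int, float], ...] = (
    (1, 30.0), (6, 10.0), (3, 20.0), (3, 30.0),
    (3, 60.0), (6, 120.0), (8, 300.0), (3, 600.0),
)

#: seconds from scan start to bolus injection
DEFAULT_INJECTION_OFFSET = 30.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous frame grid of a dynamic PET acquisition.

    Parameters
    ----------
    frame_start : array of float
        Frame start times, seconds from scan start.
    frame_duration : array of float
        Frame lengths ``L_i`` in seconds, strictly positive.
    injection_offset : float
        Seconds from scan start to tracer injection.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    injection_offset: float = 0.0

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.size == 0:
            raise ValueError("frame schedule must contain at least one frame")
        if start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must have equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be strictly positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        if not 0 <= self.injection_offset < self.total_duration:
            raise ValueError("injection_offset must lie within the scan")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_duration(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoints on the scan clock (s)."""
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def midpoints_post_injection(self) -> np.ndarray:
        """Frame midpoints relative to injection (s); negative before it."""
        return self.midpoints - self.injection_offset


def build_frame_schedule(
    spec: Sequence[Tuple[int, float]],
    injection_offset: float = 0.0,
) -> FrameSchedule:
    """Expand a ``(count, duration)`` design into a contiguous schedule.

    ``build_frame_schedule([(1, 30), (6, 10)], 30.0)`` gives a 30 s frame
    followed by six 10 s frames, with injection at scan second 30.
    """
    if len(spec) == 0:
        raise ValueError("frame spec is empty")
    durations = []
    for count, dur in spec:
        if count < 1:
            raise ValueError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur, injection_offset=injection_offset)


def default_schedule() -> FrameSchedule:
    """The 33-frame, 5340 s acquisition design used by default."""
    return build_frame_schedule(DEFAULT_FRAME_SPEC, DEFAULT_INJECTION_OFFSET)


def frame_average(
    y: np.ndarray, dt: float, schedule: FrameSchedule, time_origin: str = "scan"
) -> np.ndarray:
    """Average a finely sampled curve over each frame of a schedule.

    ``y`` samples a piecewise-linear curve at ``t_k = k*dt`` on the chosen
    clock (``"scan"`` or ``"injection"``); the frame mean is the exact
    trapezoidal integral over the frame divided by the frame length.  The
    curve is taken as zero outside its support.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(y.size) * dt
    integral = np.concatenate([[0.0], cumulative_trapezoid(y, dx=dt)])
    starts = schedule.frame_start.copy()
    ends = schedule.frame_end.copy()
    if time_origin == "injection":
        starts = starts - schedule.injection_offset
        ends = ends - schedule.injection_offset
    elif time_origin != "scan":
        raise ValueError("time_origin must be 'scan' or 'injection'")
    lo = np.clip(starts, t[0], t[-1])
    hi = np.clip(ends, t[0], t[-1])
    area = np.interp(hi, t, integral) - np.interp(lo, t, integral)
    return area / schedule.frame_duration


@dataclass
class TimeActivityCurve:
    """Frame-averaged activity concentration of one region (kBq/ml)."""

    region_id: str
    values: np.ndarray
    schedule: FrameSchedule
    trues_rate: Optional[np.ndarray] = None  # true-coincidence rate T_i (1/s)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC for {self.region_id!r} has {self.values.size} values "
                f"but the schedule has {self.schedule.n_frames} frames"
            )
        if self.trues_rate is not None:
            self.trues_rate = np.asarray(self.trues_rate, dtype=float)
            if self.trues_rate.size != self.schedule.n_frames:
                raise ValueError("trues_rate length must match the frame count")
            if np.any(self.trues_rate <= 0):
                raise ValueError("trues_rate must be strictly positive")


@dataclass
class InputFunction:
    """Arterial input data on a fine time grid (seconds post-injection).

    ``parent_plasma`` is the metabolite-corrected parent concentration in
    plasma; ``whole_blood`` the total whole-blood activity.  When the fitted
    correction curves are attached, ``parent_plasma = whole_blood *
    plasma_over_blood * parent_fraction`` holds on the grid.
    """

    time: np.ndarray
    parent_plasma: np.ndarray
    whole_blood: np.ndarray
    plasma_over_blood: Optional[np.ndarray] = None
    parent_fraction: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        n = self.time.size
        if self.parent_plasma.size != n or self.whole_blood.size != n:
            raise ValueError("input-function arrays must share one time grid")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.parent_plasma < -1e-9) or np.any(self.whole_blood < -1e-9):
            raise ValueError("activities must be non-negative")
        for name in ("plasma_over_blood", "parent_fraction"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"{name} must match the time grid")
                setattr(self, name, arr)
        if self.parent_fraction is not None:
            pf = self.parent_fraction
            if np.any(pf < -1e-9) or np.any(pf > 1 + 1e-9):
                raise ValueError("parent_fraction must lie in [0, 1]")
            if np.any(np.diff(pf) > 1e-9):
                raise ValueError("parent_fraction must be non-increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def parent_on_grid(self, t: np.ndarray) -> np.ndarray:
        """Parent-plasma activity interpolated at times ``t`` (s post-injection)."""
        return np.interp(t, self.time, self.parent_plasma, left=0.0, right=float(self.parent_plasma[-1]))

    def blood_on_grid(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.time, self.whole_blood, left=0.0, right=float(self.whole_blood[-1]))


@dataclass
class BloodSamples:
    """Raw arterial blood data before input-function derivation.

    ``continuous`` holds (time s post-injection, whole-blood activity) pairs
    from the online detector over roughly the first 15 min; ``discrete_*``
    the manual samples.  ``parent_fraction`` entries may be NaN where the
    metabolite assay was not possible (e.g. the final sample).
    """

    continuous_time: np.ndarray
    continuous_blood: np.ndarray
    discrete_time: np.ndarray
    discrete_blood: np.ndarray
    discrete_plasma: np.ndarray
    parent_fraction: np.ndarray
    calibration_factor: Optional[float] = None

    def __post_init__(self):
        for name in ("continuous_time", "continuous_blood", "discrete_time",
                     "discrete_blood", "discrete_plasma", "parent_fraction"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.continuous_time) <= 0) or np.any(np.diff(self.discrete_time) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.discrete_time < 0) or np.any(self.discrete_time > 5400):
            raise ValueError("discrete sampling times must lie within [0, 90] min")
        pf = self.parent_fraction
        ok = ~np.isnan(pf)
        if np.any(pf[ok] < 0) or np.any(pf[ok] > 1):
            raise ValueError("measured parent fractions must lie in [0, 1]")


@dataclass
class SubjectSession:
    """One PET session of one subject: demographics, TACs and input function."""

    subject_id: str
    session: str  # "test" | "retest"
    age: float
    weight: float  # kg
    injected_dose: float  # MBq
    scan_interval: float  # days between test and retest (pair-level)
    tacs: Mapping[str, TimeActivityCurve] = field(default_factory=dict)
    input: Optional[InputFunction] = None

    def __post_init__(self):
        if self.session not in ("test", "retest"):
            raise ValueError("session must be 'test' or 'retest'")
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule
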