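"""Synthetic arterial input functions, TACs, phantoms and test-retest cohorts.

The generator emulates a two-session PET study of a reversible, slowly
clearing neuroreceptor tracer: a bolus-shaped metabolite-corrected plasma
input function, one- or two-tissue-compartment tissue kinetics with a
vascular signal fraction, frame-averaged sampling on the 33-frame schedule,
count-dependent Gaussian noise, and a cohort with separate between-subject
and within-subject (session) variability of the total volume of
distribution ``V_T``.

Variability model
-----------------
Each subject carries one log-normal factor ``g_s`` (coefficient of variation
``bs_cv``) and each session one log-normal factor ``h_{s,sess}`` (CV
``ws_cv``); both multiply the fixed regional V_T profile and are *shared
across regions*, emulating global, calibration-like sources of variation
(injected dose, peripheral metabolism, input-function errors).  For direct
V_T read-outs this yields the classical one-way variance decomposition
``ICC = bs_cv^2 / (bs_cv^2 + ws_cv^2)``; measures formed as ratios of two
regions of the same scan (e.g. a pseudo-reference binding potential) cancel
the shared factors and retain only measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (FrameSchedule, InputFunction, SubjectSession,
                   TimeActivityCurve, default_schedule, frame_average)
from .kinetic import one_tissue_curve, two_tissue_curve

__all__ = [
    "REGION_VT_PROFILE", "FengInputParams", "TruthEntry", "GroundTruth",
    "simulate_input", "simulate_tac", "simulate_cohort", "simulate_phantom",
]

#: default regional V_T profile of the emulated tracer: high binding in
#: pallidum/cingulate, low in thalamus and (lowest) pons
REGION_VT_PROFILE: Dict[str, float] = {
    "hippocampus": 8.0,
    "anterior_cingulate": 10.3,
    "inferior_frontal": 8.8,
    "caudate": 7.4,
    "pallidum": 10.8,
    "accumbens": 8.4,
    "thalamus": 5.1,
    "pons": 3.0,
}

#: counts/s of true coincidences per kBq/ml of regional activity (arbitrary
#: detector scale) and the floor keeping frame weights finite
TRUES_PER_KBQ = 50.0
TRUES_FLOOR = 10.0


@dataclass(frozen=True)
class FengInputParams:
    """Bolus input-function shape: linear upslope times a fast exponential
    plus two slower washout exponentials (rates in 1/min, ``t`` in minutes).

    ``cp(t) = a1 t e^{-l1 t} + a2 (e^{-l2 t} - e^{-l1 t})
              + a3 (e^{-l3 t} - e^{-l1 t})``
    """

    a1: float = 60.0   # kBq/ml per min
    l1: float = 1.25   # 1/min, sets the peak near 1/l1 min
    a2: float = 4.0    # kBq/ml
    l2: float = 0.18   # 1/min
    a3: float = 1.2    # kBq/ml
    l3: float = 0.012  # 1/min
    pob: float = 1.6           # plasma-over-blood ratio (constant)
    pf_t50: float = 25.0       # parent-fraction half-time, min
    pf_hill: float = 1.3       # parent-fraction Hill exponent

    def validate(self):
        if any(v < 0 for v in (self.a1, self.a2, self.a3)):
            raise ValueError("input-function amplitudes must be non-negative")
        if any(v <= 0 for v in (self.l1, self.l2, self.l3)):
            raise ValueError("input-function washout rates must be positive")
        if self.pob <= 0 or self.pf_t50 <= 0 or self.pf_hill <= 0:
            raise ValueError("correction-model parameters must be positive")


def _feng_curve(t_min: np.ndarray, p: FengInputParams) -> np.ndarray:
    e1 = np.exp(-p.l1 * t_min)
    return (p.a1 * t_min * e1
            + p.a2 * (np.exp(-p.l2 * t_min) - e1)
            + p.a3 * (np.exp(-p.l3 * t_min) - e1))


def simulate_input(params: Optional[FengInputParams] = None,
                   seed: Optional[int] = None,
                   t_max: float = 5400.0, dt: float = 1.0,
                   amplitude_scale: float = 1.0) -> InputFunction:
    """Generate a bolus-injection input function on a fine grid.

    With a ``seed``, the shape parameters are jittered (amplitudes +-20%,
    rates +-10%) to emulate between-session physiological variation; the
    deterministic default shape peaks ~0.8 min post-injection.
    """
    p = params or FengInputParams()
    if seed is not None:
        rng = np.random.default_rng(seed)
        p = replace(
            p,
            a1=p.a1 * rng.uniform(0.8, 1.2),
            a2=p.a2 * rng.uniform(0.8, 1.2),
            a3=p.a3 * rng.uniform(0.8, 1.2),
            l1=p.l1 * rng.uniform(0.9, 1.1),
            l2=p.l2 * rng.uniform(0.9, 1.1),
            l3=p.l3 * rng.uniform(0.9, 1.1),
            pf_t50=p.pf_t50 * rng.uniform(0.9, 1.1),
        )
    p.validate()
    t = np.arange(0.0, t_max + dt, dt)
    t_min = t / 60.0
    parent = amplitude_scale * _feng_curve(t_min, p)
    parent = np.clip(parent, 0.0, None)
    pf = 1.0 / (1.0 + (t_min / p.pf_t50) ** p.pf_hill)
    pob = np.full_like(t, p.pob)
    with np.errstate(divide="ignore", invalid="ignore"):
        blood = np.where(pf > 0, parent / (pob * pf), 0.0)
    return InputFunction(time=t, parent_plasma=parent, whole_blood=blood,
                         plasma_over_blood=pob, parent_fraction=pf)


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth kinetic parameters of one region in one session."""

    K1: float          # ml cm^-3 min^-1
    k2: float          # 1/min
    bv: float = 0.05
    k3: float = float("nan")
    k4: float = float("nan")

    def __post_init__(self):
        if not (self.K1 >= 0 and self.k2 > 0):
            raise ValueError("K1 must be >= 0 and k2 > 0")
        if not 0.0 <= self.bv <= 0.2:
            raise ValueError("bv must lie in [0, 0.2]")
        if np.isfinite(self.k3) != np.isfinite(self.k4):
            raise ValueError("k3 and k4 must be given together")
        if np.isfinite(self.k3) and (self.k3 <= 0 or self.k4 <= 0):
            raise ValueError("k3 and k4 must be positive when present")

    @property
    def is_two_tissue(self) -> bool:
        return bool(np.isfinite(self.k3))

    @property
    def vt(self) -> float:
        if self.is_two_tissue:
            return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)
        return self.K1 / self.k2


@dataclass
class GroundTruth:
    """Per subject/session/region truth plus the cohort-level knobs."""

    frame: pd.DataFrame  # subject_id, session, region_id, K1, k2, k3, k4, bv, vt
    bs_cv: float
    ws_cv: float
    rng_seed: Optional[int] = None

    def vt_table(self) -> pd.DataFrame:
        """Pivot of true V_T: rows (subject, session), columns regions."""
        return self.frame.pivot_table(index=["subject_id", "session"],
                                      columns="region_id", values="vt")

    def entry(self, subject_id: str, session: str, region_id: str) -> TruthEntry:
        row = self.frame[(self.frame.subject_id == subject_id)
                         & (self.frame.session == session)
                         & (self.frame.region_id == region_id)].iloc[0]
        return TruthEntry(K1=row.K1, k2=row.k2, bv=row.bv,
                          k3=row.k3, k4=row.k4)


def noise_free_tac(truth: TruthEntry, input_function: InputFunction,
                   schedule: FrameSchedule, dt: float = 1.0) -> np.ndarray:
    """Frame-averaged noise-free model TAC for a truth entry."""
    t_max = schedule.total_duration - schedule.injection_offset
    t = np.arange(0.0, t_max + dt, dt)
    cp = input_function.parent_on_grid(t)
    cb = input_function.blood_on_grid(t)
    if truth.is_two_tissue:
        fine = two_tissue_curve(cp, cb, dt, truth.K1, truth.k2, truth.k3,
                                truth.k4, truth.bv)
    else:
        fine = one_tissue_curve(cp, cb, dt, truth.K1, truth.k2, truth.bv)
    return frame_average(fine, dt, schedule, time_origin="injection")


def simulate_tac(truth: TruthEntry, input_function: InputFunction,
                 schedule: FrameSchedule, noise_scale: float = 1.0,
                 seed=None, region_id: str = "region",
                 dt: float = 1.0) -> TimeActivityCurve:
    """Simulate one frame-averaged TAC with count-dependent noise.

    Noise is zero-mean Gaussian with standard deviation
    ``noise_scale * sqrt(C_i / L_i)`` per frame (activity over frame
    length), matching the information content that the ``w_i = L_i/T_i``
    frame weights assume.  ``trues_rate`` is filled proportionally to the
    frame activity (plus a small floor).
    """
    if input_function.time[-1] < schedule.total_duration - schedule.injection_offset - 1e-6:
        raise ValueError("frame schedule extends beyond the input-function support")
    clean = noise_free_tac(truth, input_function, schedule, dt=dt)
    L = schedule.frame_duration
    sd = noise_scale * np.sqrt(np.clip(clean, 0.0, None) / L)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = clean + rng.normal(0.0, 1.0, clean.size) * sd
    trues = TRUES_PER_KBQ * np.clip(clean, 0.0, None) + TRUES_FLOOR
    return TimeActivityCurve(region_id=region_id, values=values,
                             schedule=schedule, trues_rate=trues)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean log-normal multiplier with the requested CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_cohort(
    n_subjects: int = 15,
    regions: Optional[Mapping[str, float]] = None,
    bs_cv: float = 0.35,
    ws_cv: float = 0.10,
    noise_scale: float = 1.0,
    seed: Optional[int] = None,
    schedule: Optional[FrameSchedule] = None,
    k1_band: Tuple[float, float] = (0.08, 0.20),
    bv: float = 0.05,
    generate_tacs: bool = True,
) -> Tuple[list, GroundTruth]:
    """Simulate a full two-session cohort with known ground truth.

    Returns ``(sessions, truth)`` where ``sessions`` is a flat list of
    :class:`~cb1tacs.core.SubjectSession` (two per subject) and ``truth``
    records every generating parameter.  Fully reproducible from ``seed``.
    ``generate_tacs=False`` draws the same ground truth but skips the input
    function and TAC synthesis (for variance-component studies that only
    need true V_T values); the returned sessions then carry empty TACs.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if bs_cv < 0 or ws_cv < 0 or noise_scale < 0:
        raise ValueError("variability parameters must be non-negative")
    regions = dict(regions or REGION_VT_PROFILE)
    schedule = schedule or default_schedule()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    sessions = []
    rows = []
    for s in range(n_subjects):
        sid = f"s{s + 1:02d}"
        age = float(rng.integers(25, 66))
        weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 110.0))
        interval = float(np.clip(np.round(rng.lognormal(np.log(24.0), 1.2)), 1, 309))
        g = _lognormal_factor(rng, bs_cv)
        k1 = {r: float(rng.uniform(*k1_band)) for r in regions}
        for session in ("test", "retest"):
            dose = float(rng.uniform(316.0, 399.0))
            h = _lognormal_factor(rng, ws_cv)
            # session-to-session input-function shape variation belongs to
            # the within-subject variability the ws_cv knob controls; with
            # ws_cv = 0 both sessions share the deterministic default shape
            if_seed = int(rng.integers(0, 2**31 - 1))
            inp = (simulate_input(seed=if_seed if ws_cv > 0 else None,
                                  amplitude_scale=dose / 364.0)
                   if generate_tacs else None)
            tacs = {}
            for r, vt0 in regions.items():
                vt = vt0 * g * h
                truth = TruthEntry(K1=k1[r], k2=k1[r] / vt, bv=bv)
                tac_seed = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
                if generate_tacs:
                    tacs[r] = simulate_tac(truth, inp, schedule,
                                           noise_scale=noise_scale,
                                           seed=tac_seed, region_id=r)
                rows.append(dict(subject_id=sid, session=session, region_id=r,
                                 K1=truth.K1, k2=truth.k2, k3=np.nan,
                                 k4=np.nan, bv=truth.bv, vt=truth.vt))
            sessions.append(SubjectSession(
                subject_id=sid, session=session, age=age, weight=weight,
                injected_dose=dose, scan_interval=interval, tacs=tacs,
                input=inp))
    truth = GroundTruth(frame=pd.DataFrame(rows), bs_cv=bs_cv, ws_cv=ws_cv,
                        rng_seed=seed)
    return sessions, truth


def simulate_phantom(
    shape: Tuple[int, int, int],
    region_masks: Mapping[str, np.ndarray],
    truth: Mapping[str, TruthEntry],
    input_function: InputFunction,
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Generate a small 4-D dynamic volume (x, y, z, frame).

    Each voxel follows its region's kinetics plus independent voxel-level
    noise; voxels outside every mask stay zero.  Masks must be disjoint.
    """
    if int(np.prod(shape)) > 32 ** 3:
        raise ValueError("phantom grid too large; keep it <= 32^3 voxels")
    cover = np.zeros(shape, dtype=int)
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(shape):
            raise ValueError(f"mask {name!r} does not match the grid shape")
        cover += mask
    if np.any(cover > 1):
        raise ValueError("region masks overlap")
    rng = np.random.default_rng(seed)
    vol = np.zeros(tuple(shape) + (schedule.n_frames,))
    L = schedule.frame_duration
    for name, mask in region_masks.items():
        clean = noise_free_tac(truth[name], input_function, schedule)
        sd = noise_scale * np.sqrt(np.clip(clean, 0.0, None) / L)
        idx = np.argwhere(np.asarray(mask, dtype=bool))
        for (i, j, k) in idx:
            vol[i, j, k, :] = clean + rng.normal(0.0, 1.0, clean.size) * sd
    return vol


def block_masks(shape: Tuple[int, int, int],
                regions: Sequence[str]) -> Dict[str, np.ndarray]:
    """Partition a grid into equal slabs along x, one per region."""
    nx = shape[0]
    n = len(regions)
    if nx < n:
        raise ValueError("grid too small for the requested regions")
    edges = np.linspace(0, nx, n + 1).astype(int)
    masks = {}
    for i, r in enumerate(regions):
        m = np.zeros(shape, dtype=bool)
        m[edges[i]:edges[i + 1], :, :] = True
        masks[r] = m
    return masks
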