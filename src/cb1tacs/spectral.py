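"""Spectral analysis of TACs: classic NNLS, voxelwise maps, rank shaping.

Spectral analysis decomposes a TAC into a non-negative sum of
input-convolved exponentials,

    C(t) = sum_j alpha_j * Cp (*) exp(-beta_j t),    alpha_j >= 0,

with the rates ``beta_j`` log-spaced between a slow and a fast frequency
boundary; the total volume of distribution is the integral of the fitted
impulse response, ``V_T = sum_j alpha_j / beta_j``.

Frequency boundaries and decay handling
---------------------------------------
The boundaries (defaults 0.00063 and 0.1 s^-1) are conventionally stated on
the *non-decay-corrected* scale, where the physical decay of the 11C label
(lambda = 5.663e-4 s^-1) adds to every tissue clearance rate, so the slow
boundary just above lambda spans all physically possible components.  The
data handled by this package are decay-corrected, so the fit uses the
equivalent corrected rates ``beta_j - lambda`` (strictly positive) and
reports ``V_T = sum_j alpha_j / (beta_j - lambda)``; this is algebraically
identical to fitting non-corrected data with the stated boundaries.

Rank shaping replaces the non-negativity constraint by a linear,
SVD-filtered solution: singular components are attenuated by a Wiener-type
factor ``s_i^2 / (s_i^2 + (s_1/R)^2)`` where the regularisation parameter
``R`` is the expected signal-to-noise ratio.  ``V_T`` is read from the
plateau of the resulting ``V_T(R)`` curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from ._conv import expconv
from .core import (C11_LAMBDA, FrameSchedule, InputFunction,
                   TimeActivityCurve, frame_average)
from .kinetic import compute_weights

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralBasis", "SpectralResult", "RankShapingResult", "ParametricMap",
    "SpectralVT", "RankShapingVT",
    "sa_fit", "rs_sa_fit", "sa_voxelwise", "sample_map",
]


@dataclass(frozen=True)
class SpectralBasis:
    """Frame-averaged exponential basis for one input function / schedule.

    ``rates`` are the apparent (non-decay-corrected) rates ``beta_j``;
    ``rates_corrected = beta_j - lambda`` are the rates actually convolved
    against the decay-corrected input.  ``kinetic`` holds one column per
    rate; ``blood`` is the frame-averaged whole-blood curve used as the
    vascular component.
    """

    rates: np.ndarray
    rates_corrected: np.ndarray
    kinetic: np.ndarray  # (n_frames, n_basis)
    blood: np.ndarray    # (n_frames,)
    schedule: FrameSchedule

    @classmethod
    def build(cls, input_function: InputFunction, schedule: FrameSchedule,
              n_basis: int = 100, slow: float = 0.00063, fast: float = 0.1,
              decay_constant: float = C11_LAMBDA, dt: float = 1.0,
              spacing: str = "apparent") -> "SpectralBasis":
        if n_basis < 2:
            raise ValueError("need at least 2 basis rates")
        if not (0 <= decay_constant < slow < fast):
            raise ValueError("require 0 <= decay_constant < slow < fast")
        if spacing == "apparent":
            beta = np.geomspace(slow, fast, n_basis)
            beta_c = beta - decay_constant
        elif spacing == "corrected":
            beta_c = np.geomspace(slow - decay_constant,
                                  fast - decay_constant, n_basis)
            beta = beta_c + decay_constant
        else:
            raise ValueError("spacing must be 'apparent' or 'corrected'")
        t_max = schedule.total_duration - schedule.injection_offset
        t = np.arange(0.0, t_max + dt, dt)
        cp = input_function.parent_on_grid(t)
        cb = input_function.blood_on_grid(t)
        cols = np.empty((schedule.n_frames, n_basis))
        for j, b in enumerate(beta_c):
            cols[:, j] = frame_average(expconv(cp, dt, b), dt, schedule,
                                       time_origin="injection")
        blood = frame_average(cb, dt, schedule, time_origin="injection")
        return cls(rates=beta, rates_corrected=beta_c, kinetic=cols,
                   blood=blood, schedule=schedule)

    @property
    def n_basis(self) -> int:
        return self.rates.size

    def design_matrix(self, include_blood: bool = True) -> np.ndarray:
        if include_blood:
            return np.column_stack([self.kinetic, self.blood])
        return self.kinetic


@dataclass
class SpectralResult:
    """Classic SA solution: sparse non-negative spectrum and its V_T."""

    rates: np.ndarray        # apparent rates of retained components
    amplitudes: np.ndarray   # alpha_j >= 0 (same order as ``rates``)
    vt: float
    vascular: float          # blood-column amplitude + fast-boundary amplitude
    resid_norm: float


@dataclass
class RankShapingResult:
    """Rank-shaping solution: the V_T(R) curve and its plateau."""

    r_grid: np.ndarray
    vt_curve: np.ndarray
    vt: float
    plateau_window: Tuple[int, int]   # index range [lo, hi) on the R grid
    plateau_found: bool


def _nnls_spectrum(basis: SpectralBasis, y: np.ndarray, sqrt_w: np.ndarray,
                   include_blood: bool):
    """Weighted NNLS spectrum; returns (sol, vt, resid_norm, vascular).

    The fastest basis component behaves like residual vascular signal and
    is excluded from the kinetic V_T sum.  When a blood column is present
    its amplitude estimates the blood-volume fraction ``bv``, and the
    tissue amplitudes carry the complementary ``(1 - bv)`` factor, which is
    divided out of V_T.
    """
    A = basis.design_matrix(include_blood)
    sol, rnorm = nnls(sqrt_w[:, None] * A, sqrt_w * y)
    alpha = sol[:basis.n_basis]
    blood_amp = float(sol[basis.n_basis]) if include_blood else 0.0
    vascular = blood_amp + float(alpha[-1])
    vt = float(np.sum(alpha[:-1] / basis.rates_corrected[:-1]))
    if include_blood:
        vt /= (1.0 - np.clip(blood_amp, 0.0, 0.5))
    return sol, vt, float(rnorm), vascular


class SpectralVT(BaseEstimator):
    """Classic (non-regularised) spectral analysis of one TAC.

    Parameters mirror :meth:`SpectralBasis.build`; ``include_blood`` adds a
    whole-blood column absorbing intravascular signal.
    """

    def __init__(self, n_basis=100, slow=0.00063, fast=0.1,
                 decay_constant=C11_LAMBDA, dt=1.0, include_blood=True,
                 spacing="apparent"):
        self.n_basis = n_basis
        self.slow = slow
        self.fast = fast
        self.decay_constant = decay_constant
        self.dt = dt
        self.include_blood = include_blood
        self.spacing = spacing

    def _basis(self, input_function, schedule, basis=None) -> SpectralBasis:
        if basis is not None:
            return basis
        return SpectralBasis.build(input_function, schedule,
                                   n_basis=self.n_basis, slow=self.slow,
                                   fast=self.fast,
                                   decay_constant=self.decay_constant,
                                   dt=self.dt, spacing=self.spacing)

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction,
            weights: Optional[np.ndarray] = None,
            basis: Optional[SpectralBasis] = None):
        b = self._basis(input_function, tac.schedule, basis)
        if weights is None:
            weights = compute_weights(tac)
        sqrt_w = np.sqrt(np.asarray(weights, dtype=float))
        sol, vt, rnorm, vasc = _nnls_spectrum(b, tac.values, sqrt_w,
                                              self.include_blood)
        alpha = sol[:b.n_basis]
        self.rates_ = b.rates
        self.amplitudes_ = alpha
        self.vt_ = vt
        self.vascular_ = vasc
        self.resid_norm_ = rnorm
        self.basis_ = b
        return self

    @property
    def result_(self) -> SpectralResult:
        keep = self.amplitudes_ > 0
        return SpectralResult(rates=self.rates_[keep],
                              amplitudes=self.amplitudes_[keep],
                              vt=self.vt_, vascular=self.vascular_,
                              resid_norm=self.resid_norm_)


class RankShapingVT(BaseEstimator):
    """Rank-shaping regularised spectral analysis with V_T(R) plateau read.

    ``r_grid`` spans the expected signal-to-noise regularisation parameter
    (default 66 log-spaced points in [1, 1e13]; the upper decades matter
    only for near-noiseless data, where the curve flattens once every
    numerically meaningful singular component has been admitted).  The
    plateau is the window of ``plateau_width`` consecutive grid points with
    the smallest mean relative slope |dV_T/dlog10 R|, accepted when that
    slope is below ``plateau_tol`` (fraction per decade).
    """

    def __init__(self, n_basis=150, slow=0.00063, fast=0.1,
                 decay_constant=C11_LAMBDA, dt=1.0, include_blood=True,
                 r_grid=None, plateau_width=5, plateau_tol=0.01,
                 filter_order=2, spacing="corrected"):
        self.n_basis = n_basis
        self.slow = slow
        self.fast = fast
        self.decay_constant = decay_constant
        self.dt = dt
        self.include_blood = include_blood
        self.r_grid = r_grid
        self.plateau_width = plateau_width
        self.plateau_tol = plateau_tol
        self.filter_order = filter_order
        self.spacing = spacing

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction,
            weights: Optional[np.ndarray] = None,
            basis: Optional[SpectralBasis] = None):
        r_grid = (np.asarray(self.r_grid, dtype=float) if self.r_grid is not None
                  else np.geomspace(1.0, 1e13, 66))
        if r_grid.size < self.plateau_width or r_grid[-1] / r_grid[0] < 100:
            raise ValueError("R grid must span at least 2 decades")
        if basis is None:
            basis = SpectralBasis.build(input_function, tac.schedule,
                                        n_basis=self.n_basis, slow=self.slow,
                                        fast=self.fast,
                                        decay_constant=self.decay_constant,
                                        dt=self.dt, spacing=self.spacing)
        if weights is None:
            weights = compute_weights(tac)
        sqrt_w = np.sqrt(np.asarray(weights, dtype=float))
        nb = basis.n_basis
        # basis columns rescaled to unit distribution volume, so each
        # coefficient is directly a V_T contribution; this fixes the norm in
        # which the SVD filter shrinks the (underdetermined) solution and
        # keeps the slow tail extrapolation well behaved
        A = basis.kinetic * basis.rates_corrected[None, :]
        if self.include_blood:
            A = np.column_stack([A, basis.blood])
        Aw = sqrt_w[:, None] * A
        yw = sqrt_w * tac.values
        U, s, Vt = np.linalg.svd(Aw, full_matrices=False)
        uy = U.T @ yw
        q = np.zeros(A.shape[1])
        q[:nb - 1] = 1.0  # fast-boundary component excluded as vascular
        q_v = Vt @ q
        with np.errstate(divide="ignore"):
            core = np.where(s > 0, uy / s, 0.0) * q_v
        core[s <= 0] = 0.0
        blood_core = None
        if self.include_blood:
            qb = np.zeros(A.shape[1])
            qb[-1] = 1.0
            blood_core = np.where(s > 0, uy / s, 0.0) * (Vt @ qb)
        # Wiener-type shaping of the singular spectrum: components with
        # singular value below s_1 / R (the expected noise floor at
        # signal-to-noise R) are attenuated
        p = 2 * self.filter_order
        vt_curve = np.empty(r_grid.size)
        for i, R in enumerate(r_grid):
            phi = s ** p / (s ** p + (s[0] / R) ** p)
            vt = float(phi @ core)
            if blood_core is not None:
                bv_hat = float(np.clip(phi @ blood_core, 0.0, 0.5))
                vt /= (1.0 - bv_hat)
            vt_curve[i] = vt

        lo, hi, slope = self._find_plateau(r_grid, vt_curve)
        found = slope < self.plateau_tol
        if not found:
            logger.warning("no V_T(R) plateau below %.3g/decade; flattest "
                           "window has slope %.3g", self.plateau_tol, slope)
        self.r_grid_ = r_grid
        self.vt_curve_ = vt_curve
        self.plateau_window_ = (lo, hi)
        self.plateau_found_ = bool(found)
        self.vt_ = float(np.mean(vt_curve[lo:hi]))
        self.basis_ = basis
        return self

    def _find_plateau(self, r_grid, vt_curve):
        """Last qualifying flat window, or the flattest window overall.

        Of all ``plateau_width``-point windows whose mean relative slope
        |dV_T/dlog10 R| is below ``plateau_tol``, the one at the highest R
        (least regularisation, hence least bias) is returned; if none
        qualifies the globally flattest window is reported with a warning
        by the caller.
        """
        w = self.plateau_width
        logr = np.log10(r_grid)
        dv = np.abs(np.diff(vt_curve) / np.diff(logr))
        n_win = dv.size - (w - 1) + 1
        slopes = np.empty(max(n_win, 1))
        for lo in range(slopes.size):
            local = np.mean(np.abs(vt_curve[lo:lo + w]))
            slopes[lo] = np.mean(dv[lo:lo + w - 1]) / max(local, 1e-12)
        # qualifying windows are admissible only up to the onset of noise
        # amplification (relative slope above 50%/decade) *after* the first
        # plateau candidate; the initial transient is steep by construction
        qualifying = np.flatnonzero(slopes < self.plateau_tol)
        if qualifying.size:
            blown = np.flatnonzero(slopes > 0.5)
            blown = blown[blown > qualifying[0]]
            if blown.size:
                qualifying = qualifying[qualifying < blown[0]]
        lo = int(qualifying[-1]) if qualifying.size else int(np.argmin(slopes))
        return lo, lo + w, float(slopes[lo])

    @property
    def result_(self) -> RankShapingResult:
        return RankShapingResult(r_grid=self.r_grid_, vt_curve=self.vt_curve_,
                                 vt=self.vt_,
                                 plateau_window=self.plateau_window_,
                                 plateau_found=self.plateau_found_)


@dataclass
class ParametricMap:
    """Voxelwise V_T volume plus provenance."""

    data: np.ndarray  # 3-D
    method: str = "sa"
    boundaries: Tuple[float, float] = (0.00063, 0.1)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("parametric map must be 3-D")


def sa_fit(tac, input_function, weights=None, basis=None,
           **options) -> SpectralResult:
    """Classic spectral analysis of one TAC; see :class:`SpectralVT`."""
    return SpectralVT(**options).fit(tac, input_function, weights,
                                     basis=basis).result_


def rs_sa_fit(tac, input_function, weights=None, basis=None,
              **options) -> RankShapingResult:
    """Rank-shaping regularised SA; see :class:`RankShapingVT`."""
    return RankShapingVT(**options).fit(tac, input_function, weights,
                                        basis=basis).result_


def sa_voxelwise(volume: np.ndarray, input_function: InputFunction,
                 schedule: FrameSchedule,
                 weights: Optional[np.ndarray] = None,
                 brain_mask: Optional[np.ndarray] = None,
                 **options) -> ParametricMap:
    """Voxel-by-voxel classic SA over a 4-D dynamic volume.

    All-zero voxels (and voxels outside ``brain_mask``) get V_T = 0.  The
    basis is built once and shared by every voxel, so the map is
    deterministic given the inputs.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[-1] != schedule.n_frames:
        raise ValueError("volume must be (x, y, z, n_frames)")
    est = SpectralVT(**options)
    basis = SpectralBasis.build(input_function, schedule,
                                n_basis=est.n_basis, slow=est.slow,
                                fast=est.fast,
                                decay_constant=est.decay_constant, dt=est.dt,
                                spacing=est.spacing)
    if weights is None:
        w = np.ones(schedule.n_frames)
    else:
        w = np.asarray(weights, dtype=float)
    sqrt_w = np.sqrt(w)
    out = np.zeros(volume.shape[:3])
    it = np.ndindex(volume.shape[:3])
    for idx in it:
        if brain_mask is not None and not brain_mask[idx]:
            continue
        y = volume[idx]
        if not np.any(y != 0):
            continue
        _, vt, _, _ = _nnls_spectrum(basis, y, sqrt_w, est.include_blood)
        out[idx] = vt
    return ParametricMap(data=out, method="sa",
                         boundaries=(est.slow, est.fast))


def sample_map(pmap: ParametricMap,
               masks: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Mask-mean of a parametric map per region."""
    values = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pmap.data.shape:
            raise ValueError(f"mask {name!r} does not match the map shape")
        if not np.any(mask):
            raise ValueError(f"mask {name!r} is empty")
        values[name] = float(np.mean(pmap.data[mask]))
    return values
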