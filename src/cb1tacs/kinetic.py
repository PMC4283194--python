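"""Compartmental models and the simplified reference tissue model.

Two plasma-input models are provided, both with a variable blood-volume
fraction ``bv`` multiplying the whole-blood curve:

* one tissue compartment, two rate constants ("2kbv"):
  ``C(t) = (1-bv) * K1 * Cp (*) exp(-k2 t) + bv * Cb(t)``, ``V_T = K1/k2``;
* two tissue compartments, four rate constants ("4kbv"):
  the standard bi-exponential impulse response,
  ``V_T = (K1/k2) * (1 + k3/k4)``.

Rate constants are expressed in 1/min (K1 in ml cm^-3 min^-1) as is
conventional; internally everything runs on a fine uniform grid (1 s for
the one-tissue model, 2 s for the two-tissue model, configurable).  Fits
are weighted least squares with frame weights ``w_i = L_i / T_i`` (frame
length over true-coincidence rate).  The linear parameters (amplitude and
blood volume) are solved by variable projection, so the nonlinear search
runs only over the rate constants, from a deterministic log-spaced
multi-start grid screened by initial cost.

The SRTM estimates ``R1``, ``k2`` and ``BP_ND`` from a target and a
(pseudo-)reference TAC without blood data, using the basis-function
formulation over a log-spaced grid of apparent efflux rates ``k2a``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator

from ._conv import expconv
from .core import InputFunction, TimeActivityCurve, frame_average

logger = logging.getLogger(__name__)

__all__ = [
    "compute_weights", "KineticFit", "SRTMFit",
    "OneTissueModel", "TwoTissueModel", "SRTM",
    "fit_2kbv", "fit_4kbv", "fit_srtm",
    "one_tissue_curve", "two_tissue_curve", "srtm_forward",
]


def compute_weights(tac: TimeActivityCurve, normalize: bool = False) -> np.ndarray:
    """Frame weights ``w_i = L_i / T_i``.

    Falls back to uniform weights (with a logged warning) when the TAC
    carries no true-coincidence rates.
    """
    L = tac.schedule.frame_duration
    if tac.trues_rate is None:
        logger.warning(
            "TAC %r has no trues_rate; using uniform frame weights", tac.region_id
        )
        w = np.ones_like(L)
    else:
        w = L / tac.trues_rate
    if normalize:
        w = w / w.sum()
    return w


# ---------------------------------------------------------------------------
# forward models on a fine grid (time in seconds post-injection)

def one_tissue_curve(cp: np.ndarray, cb: np.ndarray, dt: float,
                     K1: float, k2: float, bv: float) -> np.ndarray:
    """Fine-grid 1TC model (rates in 1/min, grid in seconds)."""
    tissue = (K1 / 60.0) * expconv(cp, dt, k2 / 60.0)
    return (1.0 - bv) * tissue + bv * cb


def _two_tissue_irf_terms(k2: float, k3: float, k4: float) -> Tuple[float, float, float, float]:
    # eigenrates (1/min) and amplitude factors (per unit K1) of the 2TC IRF
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if root < 1e-12:
        # degenerate equal-eigenvalue limit; nudge apart for stability
        root = 1e-12
    c1 = (k3 + k4 - a1) / root
    c2 = (a2 - k3 - k4) / root
    return a1, a2, c1, c2


def two_tissue_curve(cp: np.ndarray, cb: np.ndarray, dt: float,
                     K1: float, k2: float, k3: float, k4: float,
                     bv: float) -> np.ndarray:
    """Fine-grid 2TC model (rates in 1/min, grid in seconds)."""
    a1, a2, c1, c2 = _two_tissue_irf_terms(k2, k3, k4)
    tissue = (K1 / 60.0) * (
        c1 * expconv(cp, dt, a1 / 60.0) + c2 * expconv(cp, dt, a2 / 60.0)
    )
    return (1.0 - bv) * tissue + bv * cb


def srtm_forward(ref_fine: np.ndarray, dt: float,
                 R1: float, k2: float, bp: float) -> np.ndarray:
    """SRTM prediction of the target on the reference's fine grid."""
    k2a = k2 / (1.0 + bp)
    return R1 * ref_fine + ((k2 - R1 * k2a) / 60.0) * expconv(ref_fine, dt, k2a / 60.0)


# ---------------------------------------------------------------------------
# fit containers

@dataclass
class KineticFit:
    """Result of a compartmental fit; rates in 1/min, ``vt`` dimensionless."""

    K1: float
    k2: float
    bv: float
    vt: float
    resid_norm: float
    converged: bool
    n_starts: int
    k3: float = np.nan
    k4: float = np.nan
    flags: Tuple[str, ...] = ()


@dataclass
class SRTMFit:
    R1: float
    k2: float
    bp_nd: float
    resid_norm: float
    converged: bool


class _FrameModelContext:
    """Precomputed quantities shared by all evaluations of one fit."""

    def __init__(self, tac: TimeActivityCurve, input_function: InputFunction,
                 weights: Optional[np.ndarray], dt: float):
        sched = tac.schedule
        t_max = sched.total_duration - sched.injection_offset
        self.dt = dt
        self.t = np.arange(0.0, t_max + dt, dt)
        self.cp = input_function.parent_on_grid(self.t)
        self.cb = input_function.blood_on_grid(self.t)
        self.schedule = sched
        self.y = tac.values
        if weights is None:
            weights = compute_weights(tac)
        self.sqrt_w = np.sqrt(np.asarray(weights, dtype=float))
        self.ywn = np.linalg.norm(self.sqrt_w * self.y)
        self.cb_frames = frame_average(self.cb, dt, sched, time_origin="injection")

    def frames(self, fine: np.ndarray) -> np.ndarray:
        return frame_average(fine, self.dt, self.schedule, time_origin="injection")


def _solve_amplitude_bv(h: np.ndarray, cb: np.ndarray, y: np.ndarray,
                        sqrt_w: np.ndarray, bv_max: float) -> Tuple[float, float]:
    """Weighted LSQ for ``y ~ a*h + b*cb`` with ``a >= 0``, ``0 <= b <= bv_max``."""
    H = sqrt_w * h
    B = sqrt_w * cb
    Y = sqrt_w * y

    def solve_a(b):
        num = H @ (Y - b * B)
        den = H @ H
        return max(num / den, 0.0) if den > 0 else 0.0

    # unconstrained 2x2 solve, then clamp onto the box edges as needed
    G = np.array([[H @ H, H @ B], [H @ B, B @ B]])
    r = np.array([H @ Y, B @ Y])
    try:
        a, b = np.linalg.solve(G, r)
    except np.linalg.LinAlgError:
        a, b = -1.0, -1.0
    if not (a >= 0.0 and 0.0 <= b <= bv_max):
        candidates = []
        for b_edge in (0.0, bv_max):
            candidates.append((solve_a(b_edge), b_edge))
        if B @ B > 0:
            b_free = np.clip((B @ Y) / (B @ B), 0.0, bv_max)  # a = 0 edge
            candidates.append((0.0, float(b_free)))
        best, best_cost = None, np.inf
        for a_c, b_c in candidates:
            cost = np.sum((Y - a_c * H - b_c * B) ** 2)
            if cost < best_cost:
                best, best_cost = (a_c, b_c), cost
        a, b = best
    return float(a), float(b)


class _CompartmentalBase(BaseEstimator):
    """Shared fitting machinery for the plasma-input models."""

    _N_RATES = 0

    def _rate_names(self) -> Tuple[str, ...]:
        raise NotImplementedError

    def _start_grid(self) -> Sequence[Tuple[float, ...]]:
        raise NotImplementedError

    def _tissue_h(self, ctx: _FrameModelContext, rates: np.ndarray) -> np.ndarray:
        """Frame-averaged tissue response per unit ``K1 (1-bv)``."""
        raise NotImplementedError

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction,
            weights: Optional[np.ndarray] = None):
        """Weighted fit of the model to one TAC.

        Never raises on optimisation failure: a fully failed fit is returned
        with ``converged_ = False`` and NaN parameters so that cohort runs
        can proceed.
        """
        n_post = np.sum(tac.schedule.frame_end > tac.schedule.injection_offset)
        if n_post < 6:
            raise ValueError("need at least 6 post-injection frames")
        if input_function.time[-1] < tac.schedule.total_duration - tac.schedule.injection_offset - 1e-6:
            raise ValueError("input function does not cover the frame schedule")
        if not np.any(input_function.parent_plasma > 0):
            raise ValueError("input function is identically zero")
        ctx = _FrameModelContext(tac, input_function, weights, self.dt)
        lo = np.log(np.asarray(self.rate_bounds)[:, 0])
        hi = np.log(np.asarray(self.rate_bounds)[:, 1])

        def residual(theta):
            rates = np.exp(theta)
            h = self._tissue_h(ctx, rates)
            a, b = _solve_amplitude_bv(h, ctx.cb_frames, ctx.y, ctx.sqrt_w, self.bv_max)
            return ctx.sqrt_w * (a * h + b * ctx.cb_frames - ctx.y)

        # screened multi-start: rank the deterministic start grid by initial
        # cost and run the local optimiser only from the most promising ones
        starts = [np.clip(np.log(np.asarray(s)), lo, hi)
                  for s in self._start_grid()]
        start_costs = [float(np.sum(residual(theta) ** 2)) for theta in starts]
        order = np.argsort(start_costs, kind="stable")[:self.n_polish]

        best = None
        n_used = 0
        perfect = (1e-7 * max(ctx.ywn, 1e-30)) ** 2
        for idx in order:
            n_used += 1
            try:
                res = least_squares(residual, starts[idx], bounds=(lo, hi),
                                    ftol=self.tol, xtol=self.tol, gtol=self.tol,
                                    max_nfev=400)
            except Exception:  # pragma: no cover - defensive
                continue
            rates = np.exp(res.x)
            h = self._tissue_h(ctx, rates)
            a, b = _solve_amplitude_bv(h, ctx.cb_frames, ctx.y, ctx.sqrt_w, self.bv_max)
            key = (res.cost, b)
            if best is None or key < best[0]:
                best = (key, rates, a, b, res)
            if res.cost < perfect:
                break

        if best is None:
            self._set_failed(n_used)
            return self
        _, rates, a, b, res = best
        h = self._tissue_h(ctx, rates)
        self.fitted_curve_ = a * h + b * ctx.cb_frames
        self._set_fitted(rates, a, b, res, n_used)
        return self

    def _set_failed(self, n_used: int):
        for name in ("K1_", "bv_", "vt_", "resid_norm_") + tuple(
                f"{r}_" for r in self._rate_names()):
            setattr(self, name, np.nan)
        self.converged_ = False
        self.n_starts_ = n_used
        self.flags_ = ("all_starts_failed",)

    def predict(self) -> np.ndarray:
        """Frame-averaged model curve at the fitted parameters."""
        if not hasattr(self, "fitted_curve_"):
            raise RuntimeError("model is not fitted or did not converge")
        return self.fitted_curve_

    @property
    def result_(self) -> KineticFit:
        return KineticFit(
            K1=self.K1_, k2=self.k2_, bv=self.bv_,
            k3=getattr(self, "k3_", np.nan), k4=getattr(self, "k4_", np.nan),
            vt=self.vt_, resid_norm=self.resid_norm_,
            converged=self.converged_, n_starts=self.n_starts_,
            flags=self.flags_,
        )


class OneTissueModel(_CompartmentalBase):
    """One-tissue-compartment model with variable blood volume ("2kbv").

    Parameters
    ----------
    bv_max : float
        Upper bound of the blood-volume fraction (default 0.2).
    rate_bounds : tuple of (low, high)
        Bounds for ``k2`` in 1/min.
    n_starts : int
        Number of log-spaced ``k2`` starting values.
    dt : float
        Fine-grid step for the convolution, seconds.
    tol : float
        Relative optimiser tolerance.
    """

    def __init__(self, bv_max=0.2, rate_bounds=((1e-5, 2.0),), n_starts=3,
                 n_polish=3, dt=1.0, tol=1e-8):
        self.bv_max = bv_max
        self.rate_bounds = rate_bounds
        self.n_starts = n_starts
        self.n_polish = n_polish
        self.dt = dt
        self.tol = tol

    def _rate_names(self):
        return ("k2",)

    def _start_grid(self):
        k2s = np.geomspace(0.004, 0.1, self.n_starts)
        return [(k2,) for k2 in k2s]

    def _tissue_h(self, ctx, rates):
        (k2,) = rates
        fine = (1.0 / 60.0) * expconv(ctx.cp, ctx.dt, k2 / 60.0)
        return ctx.frames(fine)

    def _set_fitted(self, rates, a, b, res, n_used):
        self.k2_ = float(rates[0])
        self.bv_ = b
        self.K1_ = a / (1.0 - b)
        self.vt_ = self.K1_ / self.k2_
        self.resid_norm_ = float(np.sqrt(2.0 * res.cost))
        self.converged_ = bool(res.success)
        self.n_starts_ = n_used
        self.flags_ = ()


class TwoTissueModel(_CompartmentalBase):
    """Two-tissue-compartment model with variable blood volume ("4kbv")."""

    def __init__(self, bv_max=0.2,
                 rate_bounds=((1e-4, 2.0), (1e-4, 1.0), (1e-4, 1.0)),
                 n_starts_per_rate=3, n_polish=6, dt=2.0, tol=1e-8):
        self.bv_max = bv_max
        self.rate_bounds = rate_bounds
        self.n_starts_per_rate = n_starts_per_rate
        self.n_polish = n_polish
        self.dt = dt
        self.tol = tol

    def _rate_names(self):
        return ("k2", "k3", "k4")

    def _start_grid(self):
        m = self.n_starts_per_rate
        k2s = np.geomspace(0.01, 0.25, m)
        k3s = np.geomspace(0.005, 0.1, m)
        k4s = np.geomspace(0.005, 0.08, m)
        return list(itertools.product(k2s, k3s, k4s))

    def _tissue_h(self, ctx, rates):
        k2, k3, k4 = rates
        a1, a2, c1, c2 = _two_tissue_irf_terms(k2, k3, k4)
        fine = (1.0 / 60.0) * (
            c1 * expconv(ctx.cp, ctx.dt, a1 / 60.0)
            + c2 * expconv(ctx.cp, ctx.dt, a2 / 60.0)
        )
        return ctx.frames(fine)

    def _set_fitted(self, rates, a, b, res, n_used):
        self.k2_, self.k3_, self.k4_ = (float(r) for r in rates)
        self.bv_ = b
        self.K1_ = a / (1.0 - b)
        self.vt_ = (self.K1_ / self.k2_) * (1.0 + self.k3_ / self.k4_)
        self.resid_norm_ = float(np.sqrt(2.0 * res.cost))
        self.converged_ = bool(res.success)
        self.n_starts_ = n_used
        flags = []
        if self.k4_ <= 2.0 * self.rate_bounds[2][0]:
            flags.append("k4_near_zero")
        self.flags_ = tuple(flags)


class SRTM(BaseEstimator):
    """Simplified reference tissue model, basis-function implementation.

    The apparent reference efflux rate ``k2a`` is scanned over a log-spaced
    grid (default 100 points in [0.006, 0.6] 1/min); for each value the two
    linear coefficients are solved by weighted least squares, and the best
    grid point is refined by bounded scalar minimisation.
    """

    def __init__(self, k2a_range=(0.006, 0.6), n_basis=100, dt=1.0,
                 refine=True):
        self.k2a_range = k2a_range
        self.n_basis = n_basis
        self.dt = dt
        self.refine = refine

    def fit(self, tac: TimeActivityCurve, reference_tac: TimeActivityCurve,
            weights: Optional[np.ndarray] = None):
        if tac.schedule.n_frames != reference_tac.schedule.n_frames:
            raise ValueError("target and reference must share one schedule")
        sched = tac.schedule
        ref = reference_tac.values
        if np.nanmax(ref) <= 0:
            raise ValueError("reference TAC must contain positive activity")
        if weights is None:
            weights = compute_weights(tac)
        sqrt_w = np.sqrt(np.asarray(weights, dtype=float))
        y = tac.values

        # continuous reference curve: linear interpolation through frame
        # midpoints, anchored at zero activity at injection
        t_max = sched.total_duration - sched.injection_offset
        t = np.arange(0.0, t_max + self.dt, self.dt)
        mids = sched.midpoints_post_injection
        keep = mids > 0
        knots_t = np.concatenate([[0.0], mids[keep]])
        knots_v = np.concatenate([[0.0], ref[keep]])
        ref_fine = np.interp(t, knots_t, knots_v)
        # the measured reference frames *are* the frame averages of C_R, so
        # they enter the R1 column directly; only the convolution term needs
        # the reconstructed continuous curve
        ref_frames = ref

        def solve(k2a):
            conv_fine = (1.0 / 60.0) * expconv(ref_fine, self.dt, k2a / 60.0)
            conv_frames = frame_average(conv_fine, self.dt, sched,
                                        time_origin="injection")
            A = np.column_stack([sqrt_w * ref_frames, sqrt_w * conv_frames])
            coef, res_, _, _ = np.linalg.lstsq(A, sqrt_w * y, rcond=None)
            resid = A @ coef - sqrt_w * y
            return float(resid @ resid), coef

        grid = np.geomspace(self.k2a_range[0], self.k2a_range[1], self.n_basis)
        costs = np.array([solve(k)[0] for k in grid])
        i = int(np.argmin(costs))
        k2a_best = grid[i]
        if self.refine:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, grid.size - 1)]
            if hi > lo:
                opt = minimize_scalar(lambda u: solve(np.exp(u))[0],
                                      bounds=(np.log(lo), np.log(hi)),
                                      method="bounded",
                                      options={"xatol": 1e-10})
                if opt.fun <= costs[i]:
                    k2a_best = float(np.exp(opt.x))
        cost, coef = solve(k2a_best)
        R1, theta2 = float(coef[0]), float(coef[1])
        k2 = theta2 + R1 * k2a_best
        self.R1_ = R1
        self.k2_ = float(k2)
        self.k2a_ = float(k2a_best)
        self.bp_nd_ = float(k2 / k2a_best - 1.0)
        self.resid_norm_ = float(np.sqrt(cost))
        self.converged_ = np.isfinite(self.bp_nd_)
        return self

    @property
    def result_(self) -> SRTMFit:
        return SRTMFit(R1=self.R1_, k2=self.k2_, bp_nd=self.bp_nd_,
                       resid_norm=self.resid_norm_, converged=self.converged_)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_2kbv(tac, input_function, weights=None, **options) -> KineticFit:
    """Fit the one-tissue (2kbv) model; see :class:`OneTissueModel`."""
    return OneTissueModel(**options).fit(tac, input_function, weights).result_


def fit_4kbv(tac, input_function, weights=None, **options) -> KineticFit:
    """Fit the two-tissue (4kbv) model; see :class:`TwoTissueModel`."""
    return TwoTissueModel(**options).fit(tac, input_function, weights).result_


def fit_srtm(tac, reference_tac, weights=None, **options) -> SRTMFit:
    """Fit the SRTM with a (pseudo-)reference region; see :class:`SRTM`."""
    return SRTM(**options).fit(tac, reference_tac, weights).result_
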