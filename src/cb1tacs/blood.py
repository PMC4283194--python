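"""Derivation of the metabolite-corrected plasma input function.

Raw arterial data comprise a continuous whole-blood detector segment
(roughly the first 15 min) and sparse discrete samples from which plasma
and whole-blood activity and the parent (unmetabolised) tracer fraction are
assayed.  The pipeline is:

1. cross-calibrate the continuous segment against the overlapping discrete
   whole-blood samples (multiplicative factor, unless one is supplied);
2. merge: calibrated continuous curve while it lasts, linear interpolation
   of the discrete whole-blood samples afterwards;
3. fit the plasma-over-blood ratio (linear in time, clamped positive) and
   the parent fraction (Hill-type sigmoid ``1 / (1 + (t/t50)^h)``, which is
   monotone non-increasing and bounded in [0, 1] by construction; missing
   late assays are covered by model extrapolation);
4. parent plasma = whole blood x plasma-over-blood x parent fraction on a
   1 s grid.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .core import BloodSamples, InputFunction

__all__ = ["derive_input_function"]

_POB_FLOOR = 0.05  # positivity clamp for the fitted plasma-over-blood ratio


def _fit_plasma_over_blood(t: np.ndarray, ratio: np.ndarray, model: str):
    if model not in ("linear", "constant"):
        raise ValueError("pob_model must be 'linear' or 'constant'")
    if model == "constant" or t.size < 2 or np.allclose(ratio, ratio[0]):
        c = float(np.mean(ratio))
        return lambda tt: np.full_like(np.asarray(tt, dtype=float), max(c, _POB_FLOOR))
    slope, intercept = np.polyfit(t, ratio, 1)
    return lambda tt: np.clip(intercept + slope * np.asarray(tt, dtype=float),
                              _POB_FLOOR, None)


def _fit_parent_fraction(t: np.ndarray, pf: np.ndarray, model: str):
    if model not in ("hill", "constant"):
        raise ValueError("pf_model must be 'hill' or 'constant'")
    if model == "constant" or np.allclose(pf, pf[0]):
        c = float(np.clip(np.mean(pf), 0.0, 1.0))
        return lambda tt: np.full_like(np.asarray(tt, dtype=float), c)

    def hill(tt, t50, h):
        return 1.0 / (1.0 + (np.asarray(tt, dtype=float) / t50) ** h)

    p0 = (max(np.median(t), 1.0), 1.5)
    popt, _ = curve_fit(hill, t, pf, p0=p0,
                        bounds=([1.0, 0.1], [1e6, 10.0]), maxfev=10000)
    fitted = hill(t, *popt)
    if np.any(fitted < -1e-9) or np.any(fitted > 1 + 1e-9):
        raise RuntimeError("parent-fraction fit left [0, 1]; model failure")
    return lambda tt: hill(tt, *popt)


def derive_input_function(blood: BloodSamples, pob_model: str = "linear",
                          pf_model: str = "hill", t_max: float = 5400.0,
                          dt: float = 1.0) -> InputFunction:
    """Build the metabolite-corrected input function from raw blood data.

    Requires at least 3 discrete plasma samples and 2 parent-fraction
    assays.  Returns an :class:`~cb1tacs.core.InputFunction` on a ``dt``
    grid over [0, ``t_max``] seconds post-injection.
    """
    td = blood.discrete_time
    plasma_ok = ~np.isnan(blood.discrete_plasma)
    if plasma_ok.sum() < 3:
        raise ValueError("need at least 3 discrete plasma samples")
    pf_ok = ~np.isnan(blood.parent_fraction)
    if pf_ok.sum() < 2:
        raise ValueError("need at least 2 parent-fraction measurements")

    # 1. cross-calibration on the overlap of the two whole-blood records
    tc, yc = blood.continuous_time, blood.continuous_blood
    if blood.calibration_factor is not None:
        cal = float(blood.calibration_factor)
    else:
        overlap = (td >= tc[0]) & (td <= tc[-1])
        cont_at = np.interp(td[overlap], tc, yc)
        good = cont_at > 0
        cal = float(np.mean(blood.discrete_blood[overlap][good] / cont_at[good])) \
            if np.any(good) else 1.0
    yc = yc * cal

    # 2. merged whole-blood curve: continuous segment, then discrete interp
    t = np.arange(0.0, t_max + dt, dt)
    late = td > tc[-1]
    knots_t = np.concatenate([tc, td[late]])
    knots_v = np.concatenate([yc, blood.discrete_blood[late]])
    if np.any(np.diff(knots_t) <= 0):
        raise ValueError("blood sample times are not orderable after merging")
    wb = np.interp(t, knots_t, knots_v)

    # 3. correction models from the discrete assays
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = blood.discrete_plasma[plasma_ok] / blood.discrete_blood[plasma_ok]
    ratio_ok = np.isfinite(ratio)
    pob = _fit_plasma_over_blood(td[plasma_ok][ratio_ok], ratio[ratio_ok],
                                 pob_model)
    pf = _fit_parent_fraction(td[pf_ok], blood.parent_fraction[pf_ok],
                              pf_model)

    pob_t = pob(t)
    pf_t = np.clip(pf(t), 0.0, 1.0)
    # enforce the monotone-decline invariant against numerical wiggle
    pf_t = np.minimum.accumulate(pf_t)
    parent = np.clip(wb, 0.0, None) * pob_t * pf_t
    return InputFunction(time=t, parent_plasma=parent,
                         whole_blood=np.clip(wb, 0.0, None),
                         plasma_over_blood=pob_t, parent_fraction=pf_t)
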