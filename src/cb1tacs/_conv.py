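"""Exact exponential convolution on a uniform grid.

Every model in this package reduces to convolutions of a sampled input curve
with decaying exponentials.  ``expconv`` evaluates

    y(t_n) = \\int_0^{t_n} f(s) exp(-k (t_n - s)) ds

exactly for a piecewise-linear ``f`` on a uniform grid, via the linear
recurrence

    y[i+1] = E y[i] + c[i],   E = exp(-k dt),

with an update term integrated in closed form over each interval.  The
recurrence is solved vectorised in blocks short enough that the rescaling by
``E^{-i}`` stays within float64 range, so the routine is O(n) without any
compiled dependency.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["expconv"]


def _increments(f: np.ndarray, dt: float, k: float) -> np.ndarray:
    # closed-form integral of the linear segment against the decaying kernel
    E = np.exp(-k * dt)
    a = (1.0 - E) / k
    b = 1.0 / k - (1.0 - E) / (k * k * dt)  # coefficient of (f[i+1]-f[i])
    f0 = f[:-1]
    f1 = f[1:]
    return f0 * a + (f1 - f0) * b


def expconv(f: np.ndarray, dt: float, k: float) -> np.ndarray:
    """Convolve samples ``f`` (uniform spacing ``dt``) with ``exp(-k t)``.

    Parameters
    ----------
    f : array
        Samples of the input at ``t = 0, dt, 2*dt, ...``.
    dt : float
        Grid spacing (s).
    k : float
        Decay rate of the kernel (1/s), ``k >= 0``.

    Returns
    -------
    array of the same length as ``f`` with the running convolution integral.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("f must be one-dimensional")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if k < 0:
        raise ValueError("kernel rate k must be non-negative")
    n = f.size
    y = np.empty(n)
    y[0] = 0.0
    if n == 1:
        return y
    if k * dt < 1e-12:
        # pure integration limit
        y[1:] = cumulative_trapezoid(f, dx=dt)
        return y

    c = _increments(f, dt, k)
    # block length keeping exp(k*dt*m) < ~1e15 so the rescaled cumsum is exact
    m = max(1, int(34.0 / (k * dt)))
    carry = 0.0  # y at the start of the current block
    pos = 0
    while pos < n - 1:
        blk = c[pos:min(pos + m, n - 1)]
        L = blk.size
        i = np.arange(L)
        # y[pos+j] = E^j * carry + E^(j-1) * sum_{i<j} c[pos+i] E^{-i}
        s = np.cumsum(blk * np.exp(k * dt * i))
        Ej = np.exp(-k * dt * (i + 1))  # E^j for j = 1..L
        y_blk = Ej * carry + Ej * np.exp(k * dt) * s
        y[pos + 1:pos + 1 + L] = y_blk
        carry = y_blk[-1]
        pos += L
    return y
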