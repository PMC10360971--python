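"""Angle arithmetic, the von Mises density, and the kappa <-> circular-SD map.

Internal unit is radians; user-facing I/O is degrees. "Precision" throughout
the package is defined as ``1 / SD`` with the circular SD expressed in
degrees, so typical working-memory precisions land in the 0.04-0.10 range.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "wrap_angle",
    "wrap_error",
    "vm_pdf",
    "kappa_to_sd",
    "sd_to_kappa",
]

_TWO_PI = 2.0 * np.pi


def wrap_angle(x):
    """Wrap an angle (radians) into the half-open interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angle must be finite")
    wrapped = -(((np.pi - x) % _TWO_PI) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_error(target_deg, response_deg):
    """Signed minimal angular difference ``response - target`` in radians.

    Both inputs are in degrees (any range); the result lies in (-pi, pi].
    """
    target = np.asarray(target_deg, dtype=float)
    response = np.asarray(response_deg, dtype=float)
    if not (np.all(np.isfinite(target)) and np.all(np.isfinite(response))):
        raise ValueError("target and response must be finite")
    return wrap_angle(np.deg2rad(response - target))


def vm_pdf(x, mu=0.0, kappa=1.0):
    """von Mises density at ``x`` (radians) with mean ``mu`` and concentration ``kappa``.

    Uses exponentially scaled Bessel functions so large concentrations do not
    overflow. ``kappa = 0`` gives the circular-uniform density 1/(2*pi).
    """
    kappa = float(kappa)
    if not np.isfinite(kappa) or kappa < 0:
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")
    x = np.asarray(x, dtype=float)
    # exp(k*cos(d)) / I0(k) == exp(k*(cos(d) - 1)) / i0e(k)
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (_TWO_PI * i0e(kappa))
    return out if out.ndim else float(out)


def mean_resultant_length(kappa):
    """R = I1(kappa)/I0(kappa), the mean resultant length of a von Mises."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    return i1e(kappa) / i0e(kappa)


def kappa_to_sd(kappa):
    """Circular standard deviation (degrees) of a von Mises with concentration ``kappa``.

    ``SD = sqrt(-2 ln R)`` with ``R = I1(kappa)/I0(kappa)``; strictly
    decreasing in kappa, +inf at kappa = 0.
    """
    r = mean_resultant_length(kappa)
    with np.errstate(divide="ignore"):
        sd_rad = np.sqrt(-2.0 * np.log(r))
    out = np.rad2deg(sd_rad)
    return out if out.ndim else float(out)


def sd_to_kappa(sd_deg, kappa_max=1e8):
    """Numerical inverse of :func:`kappa_to_sd` (input in degrees)."""
    sd_deg = float(sd_deg)
    if not np.isfinite(sd_deg) or sd_deg <= 0:
        raise ValueError(f"sd must be finite and > 0, got {sd_deg}")
    lo, hi = 1e-10, kappa_max
    if kappa_to_sd(hi) >= sd_deg:
        return hi
    if kappa_to_sd(lo) <= sd_deg:  # SD grows only like sqrt(-log kappa)
        return lo
    # bracket in log space: SD is monotone decreasing in kappa
    f = lambda logk: kappa_to_sd(np.exp(logk)) - sd_deg
    return float(np.exp(brentq(f, np.log(lo), np.log(hi), xtol=1e-12, rtol=1e-14)))
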