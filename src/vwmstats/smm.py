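"""Standard mixture model for continuous-reproduction errors.

Recall errors are modelled as a mixture of a von Mises centred on the target
(the item is in memory, recalled with limited precision) and a circular
uniform (random guess with probability ``g``):

    P(x) = (1 - g) * vonmises(x; 0, kappa) + g / (2*pi)

The fitted ``g`` and ``kappa`` yield the derived quantities used throughout:
Pm = 1 - g, capacity K = Pm * set_size, and precision = 1 / SD(kappa) with
the circular SD in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, i0e, i1e, logit

from .circular import kappa_to_sd

__all__ = [
    "SMMParams",
    "SMMFit",
    "FitConfig",
    "InsufficientDataError",
    "smm_loglik",
    "fit_smm",
    "capacity_from_g",
]

_TWO_PI = 2.0 * np.pi


class InsufficientDataError(ValueError):
    """Raised when a cell has fewer trials than the configured minimum."""


@dataclass(frozen=True)
class SMMParams:
    """Mixture parameters: guess probability ``g`` and concentration ``kappa``."""

    g: float
    kappa: float

    def __post_init__(self):
        if not (0.0 <= self.g <= 1.0):
            raise ValueError(f"g must be in [0, 1], got {self.g}")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError(f"kappa must be finite and >= 0, got {self.kappa}")


@dataclass(frozen=True)
class FitConfig:
    """Settings for maximum-likelihood fitting of the mixture model.

    The optimiser runs from a fixed grid of deterministic starts (3 x 3 in
    (g, kappa) minus the centre point, i.e. 8 starts by default), so fitting
    is reproducible without randomness; ``seed`` is reserved for future
    stochastic extensions (e.g. MAP with sampled starts).
    """

    min_trials: int = 30
    g_bounds: tuple[float, float] = (1e-6, 1.0 - 1e-6)
    kappa_bounds: tuple[float, float] = (1e-3, 500.0)
    start_g: tuple[float, ...] = (0.1, 0.5, 0.9)
    start_kappa: tuple[float, ...] = (2.0, 8.0, 32.0)
    drop_centre_start: bool = True
    seed: int | None = None


@dataclass(frozen=True)
class SMMFit:
    """A fitted mixture model with its derived capacity/precision estimates."""

    params: SMMParams
    pm: float
    capacity_k: float | None
    set_size: int | None
    sd_deg: float
    precision: float
    loglik: float
    n_trials: int
    converged: bool
    boundary: bool
    n_starts: int
    method: str = "smm_mle"


def smm_loglik(errors, params: SMMParams) -> float:
    """Log-likelihood of target-relative errors (radians) under the mixture."""
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise ValueError("at least one error is required")
    g, kappa = params.g, params.kappa
    vm = np.exp(kappa * (np.cos(x) - 1.0)) / (_TWO_PI * i0e(kappa))
    with np.errstate(divide="ignore"):
        ll = np.log((1.0 - g) * vm + g / _TWO_PI)
    return float(ll.sum())


def capacity_from_g(g: float, set_size: int) -> float:
    """Capacity K = (1 - g) * set_size."""
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"g must be in [0, 1], got {g}")
    if set_size < 1:
        raise ValueError(f"set_size must be >= 1, got {set_size}")
    return (1.0 - g) * set_size


def _nll_and_grad(theta, cosx):
    """Negative log-likelihood and gradient in (logit g, log kappa) space."""
    g = expit(theta[0])
    kappa = np.exp(theta[1])
    u = np.exp(kappa * (cosx - 1.0)) / (_TWO_PI * i0e(kappa))  # von Mises pdf
    p = (1.0 - g) * u + g / _TWO_PI
    nll = -np.log(p).sum()
    r = i1e(kappa) / i0e(kappa)
    d_g = -np.sum((1.0 / _TWO_PI - u) / p) * g * (1.0 - g)
    d_k = -np.sum((1.0 - g) * u * (cosx - r) / p) * kappa
    return nll, np.array([d_g, d_k])


def fit_smm(errors, set_size: int | None = None, config: FitConfig | None = None) -> SMMFit:
    """Fit the mixture model by multi-start bounded maximum likelihood.

    Parameters
    ----------
    errors
        Target-relative recall errors in radians (any values; used via cos).
    set_size
        If given, the fit carries capacity K = (1 - g) * set_size.
    config
        Fit settings; see :class:`FitConfig`.
    """
    config = config or FitConfig()
    x = np.asarray(errors, dtype=float)
    if x.size < config.min_trials:
        raise InsufficientDataError(
            f"need at least {config.min_trials} trials, got {x.size}"
        )
    cosx = np.cos(x)

    lo = np.array([logit(config.g_bounds[0]), np.log(config.kappa_bounds[0])])
    hi = np.array([logit(config.g_bounds[1]), np.log(config.kappa_bounds[1])])
    bounds = list(zip(lo, hi))

    starts = [
        (g0, k0)
        for g0 in config.start_g
        for k0 in config.start_kappa
    ]
    if config.drop_centre_start and len(starts) == 9:
        starts.pop(4)  # drop the grid centre; 8 deterministic starts remain

    best = None
    any_success = False
    for g0, k0 in starts:
        theta0 = np.clip([logit(g0), np.log(k0)], lo, hi)
        res = minimize(
            _nll_and_grad,
            theta0,
            args=(cosx,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    g_hat = float(expit(best.x[0]))
    kappa_hat = float(np.exp(best.x[1]))
    boundary = bool(
        best.x[1] >= np.log(config.kappa_bounds[1]) - 1e-6
        or best.x[1] <= np.log(config.kappa_bounds[0]) + 1e-6
        or abs(best.x[0] - lo[0]) < 1e-6
        or abs(best.x[0] - hi[0]) < 1e-6
    )
    if boundary:
        warnings.warn(
            "mixture fit ended on a parameter bound; estimates are boundary values",
            RuntimeWarning,
            stacklevel=2,
        )
    params = SMMParams(g=g_hat, kappa=kappa_hat)
    sd_deg = kappa_to_sd(kappa_hat)
    return SMMFit(
        params=params,
        pm=1.0 - g_hat,
        capacity_k=None if set_size is None else capacity_from_g(g_hat, set_size),
        set_size=set_size,
        sd_deg=sd_deg,
        precision=1.0 / sd_deg,
        loglik=float(-best.fun),
        n_trials=int(x.size),
        converged=any_success,
        boundary=boundary,
        n_starts=len(starts),
    )
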