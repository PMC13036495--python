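"""Occupancy inference and cooperative (Hill) binding analysis.

A bound filament stiffens the tether, so fractional occupancy is read off
the persistence length through the normalization

    alpha = (sqrt(1/Lp_i) - sqrt(1/Lp_bare)) / (sqrt(1/Lp_sat) - sqrt(1/Lp_bare)),

where Lp_bare is the mean persistence length of the bare tether and Lp_sat
the persistence length at the saturating concentration (a complete filament).
Occupancy versus concentration is then fitted with the Hill isotherm

    alpha(c) = c^n / (K_D^n + c^n),

by weighted nonlinear least squares with binomial standard errors as
weights, averaged over bootstrap resamples (case resampling of the
occupancy points): the point estimate is the mean of the bootstrap
estimates and the quoted uncertainty their standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize


@dataclass(frozen=True)
class OccupancyPoint:
    """Fractional occupancy at one concentration with its uncertainty."""

    concentration: float  # nM
    alpha: float  # unitless; may fall outside [0, 1] for noisy inputs
    sigma_alpha: float  # unitless standard error
    n_tethers: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be non-negative")


@dataclass(frozen=True)
class FractionWithError:
    """Relative event fraction n_i / n_all with its binomial standard error."""

    f_rel: float
    delta_f: float
    n_i: int
    n_all: int


@dataclass
class HillFit:
    """Bootstrap-averaged Hill fit: K_D (nM), Hill coefficient, and draws."""

    kd: float
    n_hill: float
    kd_sd: float
    n_sd: float
    n_boot: int
    kd_draws: np.ndarray = field(default_factory=lambda: np.array([]))
    n_draws: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False


def hill_alpha(concentration, kd: float, n: float):
    """Hill isotherm: alpha = c^n / (kd^n + c^n)."""
    c = np.asarray(concentration, dtype=float)
    out = c**n / (kd**n + c**n)
    return float(out) if np.isscalar(concentration) else out


def fractional_occupancy(lp_i: float, lp_bare_mean: float,
                         lp_300: float) -> float:
    """Occupancy from a persistence length via the inverse-sqrt normalization.

    Returns 0 at the bare value and 1 at the saturating (complete-filament)
    value.  Noisy inputs can land outside [0, 1]; the value is returned
    unclamped (a warning is emitted) because clamping would bias downstream
    fits near the boundaries.
    """
    if min(lp_i, lp_bare_mean, lp_300) <= 0:
        raise ValueError("persistence lengths must be positive")
    if lp_300 <= lp_bare_mean:
        raise ValueError("lp_300 must exceed lp_bare_mean")
    num = math.sqrt(1.0 / lp_i) - math.sqrt(1.0 / lp_bare_mean)
    den = math.sqrt(1.0 / lp_300) - math.sqrt(1.0 / lp_bare_mean)
    alpha = num / den
    if not 0.0 <= alpha <= 1.0:
        warnings.warn(f"occupancy {alpha:.3f} outside [0, 1]; returned unclamped",
                      stacklevel=2)
    return alpha


def binomial_error(n_i: int, n_all: int) -> FractionWithError:
    """Relative fraction and its binomial standard error sqrt(f(1-f)/N)."""
    if n_all < 1:
        raise ValueError("n_all must be at least 1")
    if not 0 <= n_i <= n_all:
        raise ValueError("require 0 <= n_i <= n_all")
    f = n_i / n_all
    return FractionWithError(f_rel=f, delta_f=math.sqrt(f * (1.0 - f) / n_all),
                             n_i=n_i, n_all=n_all)


def _weighted_hill_fit(conc, alpha, sigma, kd_guess, n_guess, kd_max):
    pars = Parameters()
    pars.add("kd", value=kd_guess, min=1e-9, max=kd_max)
    pars.add("n", value=n_guess, min=1e-3, max=10.0)

    def residual(p):
        model = hill_alpha(conc, p["kd"].value, p["n"].value)
        return (model - alpha) / sigma

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        return None
    return float(out.params["kd"].value), float(out.params["n"].value)


def hill_fit(points: list[OccupancyPoint], n_boot: int = 1000,
             seed: int = 0, sigma_floor: float = 1e-3,
             resample: bool = True) -> HillFit:
    """Bootstrap-averaged weighted Hill fit of occupancy points.

    Requires at least three concentrations.  Each bootstrap replicate
    resamples the points with replacement (``resample=False`` refits the
    original data, so ``n_boot=1`` reproduces the plain weighted fit) and
    refits; the reported estimates are bootstrap means, the uncertainties
    bootstrap standard deviations.

    A binomial standard error of exactly zero (an observed fraction of 0 or
    1) is an artifact of the point estimate, not a real certainty, and would
    otherwise give boundary points unbounded weight and bias the isotherm
    steep; zero sigmas are therefore floored at the smallest nonzero sigma
    among the points (or ``sigma_floor`` when every sigma is zero, e.g. for
    noiseless data, making the fit unweighted).  Fails when more than 20% of
    the refits do not converge; a cohort with no occupancy spread is flagged
    degenerate (the Hill coefficient is then unidentifiable).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 occupancy points")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    conc = np.array([p.concentration for p in points])
    alpha = np.array([p.alpha for p in points])
    sigma = np.array([p.sigma_alpha for p in points])
    floor = float(np.min(sigma[sigma > 0])) if (sigma > 0).any() else sigma_floor
    sigma = np.maximum(sigma, max(floor, sigma_floor))

    degenerate = float(np.ptp(alpha)) < 1e-12
    kd_guess = float(np.exp(np.mean(np.log(conc))))
    kd_max = 10.0 * float(np.max(conc))
    rng = np.random.default_rng(seed)

    kd_draws, n_draws, failures = [], [], 0
    for _ in range(n_boot):
        if resample:
            idx = rng.integers(0, len(points), size=len(points))
        else:
            idx = np.arange(len(points))
        result = None
        if np.unique(conc[idx]).size >= 2:
            result = _weighted_hill_fit(conc[idx], alpha[idx], sigma[idx],
                                        kd_guess, 1.0, kd_max)
        if result is None:
            failures += 1
            continue
        kd_draws.append(result[0])
        n_draws.append(result[1])

    if failures > 0.2 * n_boot or not kd_draws:
        raise RuntimeError(
            f"Hill fit failed: {failures}/{n_boot} bootstrap refits did not "
            "converge (check occupancy spread and uncertainties)")
    kd_draws = np.asarray(kd_draws)
    n_draws = np.asarray(n_draws)
    return HillFit(
        kd=float(np.mean(kd_draws)),
        n_hill=float(np.mean(n_draws)),
        kd_sd=float(np.std(kd_draws, ddof=1)) if kd_draws.size > 1 else 0.0,
        n_sd=float(np.std(n_draws, ddof=1)) if n_draws.size > 1 else 0.0,
        n_boot=n_boot,
        kd_draws=kd_draws,
        n_draws=n_draws,
        degenerate=degenerate,
    )
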