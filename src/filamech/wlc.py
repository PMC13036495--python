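"""Inextensible worm-like chain mechanics and force-extension fitting.

The WLC force law used throughout is the Bustamante interpolation for an
inextensible chain,

    F(L) = (kBT / Lp) * [ 1 / (4 (1 - L/Lc)^2) - 1/4 + L/Lc ],

with persistence length ``Lp`` (nm), contour length ``Lc`` (nm) and thermal
energy ``kBT`` (pN nm).  Because raw bead positions carry large Brownian
fluctuations, parameter estimation is done in the energy domain: the measured
force-extension samples are integrated (trapezoid over extension-sorted
samples) and the closed-form integral of the force law,

    E(L) = (1/4) kBT L^2 (2 L - 3 Lc) / (Lp Lc (L - Lc)),

is least-squares fitted to the accumulated energy.  Integration acts as a
low-pass filter on the Brownian noise, which is what makes this transform
worthwhile compared to fitting the force law directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import brentq

KBT_ROOM = 4.11
"""Thermal energy at 25 C, pN nm. Single constant used package-wide."""

#: parameter-acceptance window applied to individual fits, nm
LP_BOUNDS = (0.0, 500.0)
LC_BOUNDS = (700.0, 2000.0)


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: persistence length, contour length, kBT."""

    lp: float  # persistence length, nm
    lc: float  # contour length, nm
    kbt: float = KBT_ROOM  # thermal energy, pN nm

    def __post_init__(self) -> None:
        if self.lp <= 0 or self.lc <= 0 or self.kbt <= 0:
            raise ValueError("lp, lc and kbt must all be positive")


@dataclass
class ForceExtensionCurve:
    """A force-extension record: paired extension (nm) and force (pN) arrays."""

    extension: np.ndarray
    force: np.ndarray
    direction: str = "loading"
    source: str | None = None

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError("extension and force must have equal length")
        if np.any(self.force <= 0):
            raise ValueError("forces must be positive")


@dataclass
class WLCFitResult:
    """Outcome of an energy-domain WLC fit.

    ``accepted`` applies the standard parameter window (0 <= Lp <= 500 nm,
    700 <= Lc <= 2000 nm); out-of-window fits are retained and flagged rather
    than discarded, so callers can always audit them.
    """

    params: WLCParams
    accepted: bool
    residual_norm: float
    per_trace: list["WLCFitResult"] = field(default_factory=list)

    @property
    def lp(self) -> float:
        return self.params.lp

    @property
    def lc(self) -> float:
        return self.params.lc


def wlc_force(extension, params: WLCParams):
    """Force (pN) of the inextensible WLC at the given extension (nm).

    Accepts scalars or arrays; extension must lie in [0, lc).
    """
    ext = np.asarray(extension, dtype=float)
    if np.any(ext < 0) or np.any(ext >= params.lc):
        raise ValueError("extension must satisfy 0 <= extension < lc")
    x = ext / params.lc
    out = (params.kbt / params.lp) * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return float(out) if np.isscalar(extension) else out


def wlc_energy(extension, params: WLCParams):
    """Stretching energy (pN nm): closed-form integral of `wlc_force` from 0."""
    ext = np.asarray(extension, dtype=float)
    if np.any(ext < 0) or np.any(ext >= params.lc):
        raise ValueError("extension must satisfy 0 <= extension < lc")
    out = _energy_model(ext, params.lp, params.lc, params.kbt)
    return float(out) if np.isscalar(extension) else out


def _energy_model(ext, lp, lc, kbt):
    return 0.25 * kbt * ext**2 * (2.0 * ext - 3.0 * lc) / (lp * lc * (ext - lc))


def invert_wlc(force, params: WLCParams):
    """Extension (nm) at which the WLC force law equals ``force`` (pN).

    The force law is strictly increasing on (0, lc) so the root is unique;
    found by bracketed root search to relative force tolerance 1e-9.
    Accepts scalars or arrays.
    """

    def solve_one(f: float) -> float:
        if f <= 0:
            raise ValueError("force must be positive")
        lo, hi = 0.0, params.lc * (1.0 - 1e-14)
        return brentq(
            lambda e: wlc_force(e, params) - f, lo, hi,
            xtol=1e-12 * params.lc, rtol=8.9e-16, maxiter=200,
        )

    if np.isscalar(force):
        return solve_one(float(force))
    return np.array([solve_one(float(f)) for f in np.asarray(force, dtype=float)])


def integrate_curve(curve: ForceExtensionCurve) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated stretching energy E = integral of F dL over the samples.

    For a monotone force protocol (a loading or unloading ramp) the trapezoid
    rule is applied in acquisition order: the Brownian part of consecutive
    extension increments then telescopes out of the sum, which is exactly the
    noise-suppressing point of the energy transform.  Sorting noisy samples
    by extension instead would rearrange the noise into spurious path length
    and bias the stiffness upward (persistence length downward).  When the
    force channel is not monotone, samples are extension-sorted with
    duplicate-extension averaging as a fallback.  Returns ``(extension,
    energy)`` with energy zero at the first (smallest-force) sample.
    """
    dF = np.diff(curve.force)
    if curve.force.size >= 2 and (np.all(dF >= 0) or np.all(dF <= 0)):
        ext = curve.extension if dF.sum() >= 0 else curve.extension[::-1]
        frc = curve.force if dF.sum() >= 0 else curve.force[::-1]
        energy = np.concatenate(
            [[0.0], np.cumsum(np.diff(ext) * 0.5 * (frc[1:] + frc[:-1]))])
        return ext, energy
    order = np.argsort(curve.extension, kind="stable")
    ext = curve.extension[order]
    frc = curve.force[order]
    # average duplicated extensions so the trapezoid abscissa is strictly increasing
    uniq, inv = np.unique(ext, return_inverse=True)
    if uniq.size < ext.size:
        sums = np.bincount(inv, weights=frc)
        counts = np.bincount(inv)
        ext, frc = uniq, sums / counts
    energy = np.concatenate([[0.0], np.cumsum(np.diff(ext) * 0.5 * (frc[1:] + frc[:-1]))])
    return ext, energy


def fit_wlc_integrated(
    curve: ForceExtensionCurve,
    kbt: float = KBT_ROOM,
    lp_guess: float = 50.0,
) -> WLCFitResult:
    """Fit (Lp, Lc) to one curve via the integrated-energy transform.

    Requires at least 50 samples spanning a >= 5-fold force range.  The
    measured energy has an arbitrary offset (integration starts at the
    smallest observed extension, not zero), so a free additive offset is
    included in the fit and discarded.
    """
    if curve.extension.size < 50:
        raise ValueError("need at least 50 samples to fit")
    fmax, fmin = float(np.max(curve.force)), float(np.min(curve.force))
    if fmax / fmin < 5.0:
        raise ValueError("force range must span at least 5-fold")

    ext, energy = integrate_curve(curve)
    max_ext = float(np.max(ext))

    pars = Parameters()
    pars.add("lp", value=lp_guess, min=1e-3, max=1e4)
    pars.add("lc", value=1.05 * max_ext, min=max_ext * (1 + 1e-6), max=1e5)
    pars.add("offset", value=0.0)

    def residual(p):
        model = _energy_model(ext, p["lp"].value, p["lc"].value, kbt) + p["offset"].value
        return model - energy

    out = minimize(residual, pars, method="leastsq")
    lp = float(out.params["lp"].value)
    lc = float(out.params["lc"].value)
    accepted = bool(
        out.success
        and LP_BOUNDS[0] <= lp <= LP_BOUNDS[1]
        and LC_BOUNDS[0] <= lc <= LC_BOUNDS[1]
    )
    return WLCFitResult(
        params=WLCParams(lp=lp, lc=lc, kbt=kbt),
        accepted=accepted,
        residual_norm=float(np.linalg.norm(out.residual)),
    )


def fit_wlc_direct(curve: ForceExtensionCurve, kbt: float = KBT_ROOM,
                   lp_guess: float = 50.0) -> WLCFitResult:
    """Fit (Lp, Lc) by least squares on the force law itself (no transform).

    Kept as the comparison baseline for the energy-domain procedure; noisier
    at low force where Brownian excursions dominate.
    """
    ext, frc = curve.extension, curve.force
    max_ext = float(np.max(ext))
    pars = Parameters()
    pars.add("lp", value=lp_guess, min=1e-3, max=1e4)
    pars.add("lc", value=1.05 * max_ext, min=max_ext * (1 + 1e-6), max=1e5)

    def residual(p):
        x = ext / p["lc"].value
        model = (kbt / p["lp"].value) * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
        return model - frc

    out = minimize(residual, pars, method="leastsq")
    lp, lc = float(out.params["lp"].value), float(out.params["lc"].value)
    accepted = bool(out.success and LP_BOUNDS[0] <= lp <= LP_BOUNDS[1]
                    and LC_BOUNDS[0] <= lc <= LC_BOUNDS[1])
    return WLCFitResult(WLCParams(lp=lp, lc=lc, kbt=kbt), accepted,
                        float(np.linalg.norm(out.residual)))


def fit_wlc_replicates(
    curves: list[ForceExtensionCurve], kbt: float = KBT_ROOM
) -> WLCFitResult:
    """Fit each replicate curve individually and pool the accepted results.

    Returns the mean (Lp, Lc) over accepted per-curve fits, with all
    individual results (including rejected ones) attached as ``per_trace``.
    """
    results = [fit_wlc_integrated(c, kbt=kbt) for c in curves]
    accepted = [r for r in results if r.accepted]
    if not accepted:
        raise ValueError("no replicate fit fell inside the acceptance bounds")
    lp = float(np.mean([r.lp for r in accepted]))
    lc = float(np.mean([r.lc for r in accepted]))
    pooled = WLCFitResult(
        params=WLCParams(lp=lp, lc=lc, kbt=kbt),
        accepted=True,
        residual_norm=float(np.mean([r.residual_norm for r in accepted])),
        per_trace=results,
    )
    return pooled


def replicate_summary(result: WLCFitResult) -> dict:
    """Mean and sd of accepted per-trace (Lp, Lc) from a pooled fit."""
    acc = [r for r in result.per_trace if r.accepted]
    return {
        "n_total": len(result.per_trace),
        "n_accepted": len(acc),
        "lp_mean": float(np.mean([r.lp for r in acc])) if acc else np.nan,
        "lp_sd": float(np.std([r.lp for r in acc], ddof=1)) if len(acc) > 1 else 0.0,
        "lc_mean": float(np.mean([r.lc for r in acc])) if acc else np.nan,
        "lc_sd": float(np.std([r.lc for r in acc], ddof=1)) if len(acc) > 1 else 0.0,
    }


def extract_rupture_forces(
    curve: ForceExtensionCurve, jump_threshold: float = 50.0
) -> list[float]:
    """Rupture forces from a high-force loading curve.

    Automated surrogate for manual selection: finds the largest single-sample
    extension increase; if it exceeds ``jump_threshold`` (nm) the force at
    that sample is reported.  An empty list (no detectable rupture) is a
    valid outcome.
    """
    if curve.extension.size < 2:
        return []
    jumps = np.diff(curve.extension)
    i = int(np.argmax(jumps))
    if jumps[i] <= jump_threshold:
        return []
    return [float(curve.force[i])]
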