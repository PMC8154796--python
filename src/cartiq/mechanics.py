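"""Stress-relaxation indentation analysis.

A ramp-and-hold indentation on cartilage produces a force curve with three
phases: a slow approach until tissue contact is detected as a force
threshold crossing, a fast linear loading ramp to the target depth, and a
long hold during which the force relaxes toward equilibrium as interstitial
fluid redistributes.  This module turns one such curve, together with the
local cartilage thickness, into apparent peak and equilibrium moduli and a
per-compartment hydraulic permeability.

The relaxation transient is modelled as a third-order exponential decay

    F(t) = F_eq + sum_{i=1..3} A_i * exp(-t / tau_i),

whose three time constants are interpreted as three fluid compartments.
Permeability for compartment i follows poroelastic scaling

    k_i = z**2 / (h * tau_i),

with z the cartilage height (mm) and h the apparent equilibrium modulus
(MPa), so k carries units mm^2 MPa^-1 s^-1.

Moduli are *apparent* (nominal) quantities: peak stress is peak force over
the projected spherical-cap contact area, and nominal strain is indentation
depth over cartilage height.  No Hertzian contact correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "IndenterGeometry",
    "ForceCurve",
    "LoadingFit",
    "TriexpFit",
    "BiomechResult",
    "ContactError",
    "SegmentationError",
    "detect_contact",
    "split_phases",
    "fit_loading",
    "fit_relaxation",
    "contact_area",
    "apparent_modulus",
    "permeability",
    "analyze_curve",
]


class ContactError(ValueError):
    """The force never reached the contact threshold (denuded site)."""


class SegmentationError(ValueError):
    """The curve cannot be split into loading and relaxation phases."""


@dataclass(frozen=True)
class IndenterGeometry:
    """Hemispherical-tip indenter and ramp-and-hold protocol constants.

    Defaults describe a 2 mm diameter stainless steel tip advanced 0.3 mm
    into the tissue at 0.5 mm/s after a 0.1 N contact threshold, then held
    for 240 s.
    """

    tip_radius_mm: float = 1.0
    contact_threshold_N: float = 0.1
    indentation_depth_mm: float = 0.3
    ramp_speed_mm_s: float = 0.5
    hold_s: float = 240.0

    def __post_init__(self) -> None:
        for name in (
            "tip_radius_mm",
            "contact_threshold_N",
            "indentation_depth_mm",
            "ramp_speed_mm_s",
            "hold_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.indentation_depth_mm > self.tip_radius_mm:
            raise ValueError("indentation depth cannot exceed tip radius")

    @property
    def ramp_duration_s(self) -> float:
        return self.indentation_depth_mm / self.ramp_speed_mm_s


@dataclass
class ForceCurve:
    """Sampled time / displacement / force record of one indentation."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_N: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        n = self.time_s.size
        if n == 0:
            raise ValueError("empty curve")
        if self.displacement_mm.size != n or self.force_N.size != n:
            raise ValueError("time, displacement and force must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time samples must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class LoadingFit:
    """Ordinary least-squares line through the linear loading ramp."""

    slope_N_s: float
    intercept_N: float
    peak_force_N: float
    peak_index: int
    residuals_N: np.ndarray


@dataclass
class TriexpFit:
    """Triexponential relaxation fit; taus sorted ascending (fastest first)."""

    eq_force_N: float
    amplitudes_N: np.ndarray
    taus_s: np.ndarray
    residuals_N: np.ndarray
    r_squared: float
    converged: bool = True


@dataclass
class BiomechResult:
    """Per-site biomechanical summary with fit diagnostics attached."""

    apparent_peak_modulus_MPa: float | None = None
    apparent_equilibrium_modulus_MPa: float | None = None
    permeability_per_compartment: np.ndarray | None = None
    contact_area_mm2: float | None = None
    nominal_strain: float | None = None
    peak_force_N: float | None = None
    eq_force_N: float | None = None
    last_sample_force_N: float | None = None
    taus_s: np.ndarray | None = None
    amplitudes_N: np.ndarray | None = None
    r_squared: float | None = None
    qc_flag: str = "ok"


def detect_contact(curve: ForceCurve, threshold_N: float) -> int:
    """Index of the first sample at or above the contact threshold.

    Raises :class:`ContactError` when the threshold is never reached,
    which flags a denuded site to be excluded downstream.
    """
    above = np.nonzero(curve.force_N >= threshold_N)[0]
    if above.size == 0:
        raise ContactError(
            f"force never reached contact threshold {threshold_N} N"
        )
    return int(above[0])


def split_phases(
    curve: ForceCurve, geometry: IndenterGeometry, min_samples: int = 5
) -> tuple[ForceCurve, ForceCurve]:
    """Split a curve at the force maximum into loading and relaxation.

    The peak is the global force maximum (earliest index on ties): the end
    of the linear loading slope transitioning into the exponential decay.
    The relaxation segment is re-timed so its first sample is t = 0.
    """
    contact = detect_contact(curve, geometry.contact_threshold_N)
    peak = contact + int(np.argmax(curve.force_N[contact:]))
    loading = slice(contact, peak + 1)
    relaxation = slice(peak, len(curve))
    n_load = loading.stop - loading.start
    n_relax = relaxation.stop - relaxation.start
    if n_load < min_samples or n_relax < min_samples:
        raise SegmentationError(
            f"too few samples around peak (loading={n_load}, relaxation={n_relax})"
        )
    load_seg = ForceCurve(
        curve.time_s[loading],
        curve.displacement_mm[loading],
        curve.force_N[loading],
    )
    relax_seg = ForceCurve(
        curve.time_s[relaxation] - curve.time_s[peak],
        curve.displacement_mm[relaxation],
        curve.force_N[relaxation],
    )
    return load_seg, relax_seg


def fit_loading(segment: ForceCurve) -> LoadingFit:
    """OLS line of force versus time over the loading ramp."""
    if len(segment) < 5:
        raise ValueError("need at least 5 samples for the loading fit")
    t, f = segment.time_s, segment.force_N
    if np.ptp(t) == 0:
        raise ValueError("degenerate loading segment: constant time")
    res = stats.linregress(t, f)
    fitted = res.intercept + res.slope * t
    peak_index = int(np.argmax(f))
    return LoadingFit(
        slope_N_s=float(res.slope),
        intercept_N=float(res.intercept),
        peak_force_N=float(f[peak_index]),
        peak_index=peak_index,
        residuals_N=f - fitted,
    )


def _triexp(t: np.ndarray, feq: float, a1: float, a2: float, a3: float,
            t1: float, t2: float, t3: float) -> np.ndarray:
    return feq + a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + a3 * np.exp(-t / t3)


def fit_relaxation(segment: ForceCurve, hold_s: float = 240.0) -> TriexpFit:
    """Nonlinear least-squares triexponential fit of the relaxation phase.

    F(t) = F_eq + A1 e^(-t/tau1) + A2 e^(-t/tau2) + A3 e^(-t/tau3), with
    amplitudes constrained non-negative and taus bounded in
    [0.01 s, 10 * hold].  Initialisation: F_eq from the last sample,
    amplitudes as equal thirds of (first - last), taus at hold/100,
    hold/10 and hold/2, spanning fast, intermediate and slow compartments.
    Non-convergence is reported via ``converged=False``, never raised.
    """
    if len(segment) < 8:
        raise ValueError("need at least 8 samples for the relaxation fit")
    t, f = segment.time_s, segment.force_N
    t = t - t[0]
    f_last = float(f[-1])
    drop = max(float(f[0]) - f_last, 0.0)
    p0 = [f_last, drop / 3, drop / 3, drop / 3,
          hold_s / 100, hold_s / 10, hold_s / 2]
    lo = [0.0, 0.0, 0.0, 0.0, 0.01, 0.01, 0.01]
    hi = [np.inf, np.inf, np.inf, np.inf, 10 * hold_s, 10 * hold_s, 10 * hold_s]
    try:
        popt, _ = optimize.curve_fit(
            _triexp, t, f, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, optimize.OptimizeWarning):
        popt = np.full(7, np.nan)
        converged = False
    if converged:
        feq, amps, taus = popt[0], np.array(popt[1:4]), np.array(popt[4:7])
        order = np.argsort(taus)
        taus, amps = taus[order], amps[order]
        fitted = _triexp(t, feq, *amps, *taus)
        residuals = f - fitted
        ss_tot = float(np.sum((f - f.mean()) ** 2))
        ss_res = float(np.sum(residuals**2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        feq, amps, taus = np.nan, np.full(3, np.nan), np.full(3, np.nan)
        residuals, r2 = np.full_like(f, np.nan), np.nan
    return TriexpFit(
        eq_force_N=float(feq),
        amplitudes_N=amps,
        taus_s=taus,
        residuals_N=residuals,
        r_squared=float(r2),
        converged=converged,
    )


def contact_area(tip_radius_mm: float, depth_mm: float) -> float:
    """Projected spherical-cap contact area pi*(2*R*d - d^2) in mm^2.

    At R = 1 mm and d = 0.3 mm this is pi*0.51 = 1.60 mm^2, the nominal
    contact area of the protocol.
    """
    if depth_mm < 0:
        raise ValueError("depth must be non-negative")
    if depth_mm > tip_radius_mm:
        raise ValueError("depth cannot exceed tip radius")
    return math.pi * (2.0 * tip_radius_mm * depth_mm - depth_mm**2)


def apparent_modulus(
    force_N: float, area_mm2: float, depth_mm: float, thickness_mm: float
) -> float:
    """Nominal stress over nominal strain: (F/A) / (depth/height), in MPa.

    Used for both the peak modulus (F = peak force) and the equilibrium
    modulus (F = relaxed end-point force).
    """
    if min(force_N, area_mm2, depth_mm, thickness_mm) <= 0:
        raise ValueError("all inputs must be positive")
    if depth_mm >= thickness_mm:
        raise ValueError("indentation depth must be below cartilage height")
    stress = force_N / area_mm2  # N/mm^2 == MPa
    strain = depth_mm / thickness_mm
    return stress / strain


def permeability(thickness_mm: float, eq_modulus_MPa: float, tau_s: float) -> float:
    """Poroelastic permeability k = z^2 / (h * tau), mm^2 MPa^-1 s^-1."""
    if min(thickness_mm, eq_modulus_MPa, tau_s) <= 0:
        raise ValueError("thickness, modulus and tau must be positive")
    return thickness_mm**2 / (eq_modulus_MPa * tau_s)


def analyze_curve(
    curve: ForceCurve,
    thickness_mm: float,
    geometry: IndenterGeometry | None = None,
) -> BiomechResult:
    """Full per-curve analysis: contact, phase split, fits, moduli, k1..k3.

    Denuded sites (no contact) and unsplittable curves come back as flagged
    results rather than exceptions so that batch runs never drop sites
    silently.
    """
    geometry = geometry or IndenterGeometry()
    try:
        loading, relaxation = split_phases(curve, geometry)
    except ContactError:
        return BiomechResult(qc_flag="no_contact")
    except SegmentationError:
        return BiomechResult(qc_flag="segmentation_failure")

    load_fit = fit_loading(loading)
    relax_fit = fit_relaxation(relaxation, hold_s=geometry.hold_s)
    area = contact_area(geometry.tip_radius_mm, geometry.indentation_depth_mm)
    strain = geometry.indentation_depth_mm / thickness_mm
    peak_force = float(relaxation.force_N[0])
    last_force = float(relaxation.force_N[-1])

    if not relax_fit.converged:
        return BiomechResult(
            contact_area_mm2=area,
            nominal_strain=strain,
            peak_force_N=peak_force,
            last_sample_force_N=last_force,
            qc_flag="fit_failure",
        )

    peak_modulus = apparent_modulus(
        peak_force, area, geometry.indentation_depth_mm, thickness_mm
    )
    # Equilibrium force read as the fitted asymptote: the noise-robust
    # estimate of the relaxed end point.  The raw last sample is kept too.
    eq_force = relax_fit.eq_force_N
    eq_modulus = apparent_modulus(
        eq_force, area, geometry.indentation_depth_mm, thickness_mm
    )
    ks = np.array(
        [permeability(thickness_mm, eq_modulus, tau) for tau in relax_fit.taus_s]
    )
    return BiomechResult(
        apparent_peak_modulus_MPa=peak_modulus,
        apparent_equilibrium_modulus_MPa=eq_modulus,
        permeability_per_compartment=ks,
        contact_area_mm2=area,
        nominal_strain=strain,
        peak_force_N=peak_force,
        eq_force_N=eq_force,
        last_sample_force_N=last_force,
        taus_s=relax_fit.taus_s,
        amplitudes_N=relax_fit.amplitudes_N,
        r_squared=relax_fit.r_squared,
    )
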