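"""Synthetic ground truth: sites, indentation curves and image volumes.

No specimen data accompany the analysis this package implements, so every
downstream stage is exercised against simulated inputs with the same
statistical structure the pipeline assumes:

* a population of indentation sites spread over a few tibial plateaus,
  with cartilage thickness in the 1.2-3.0 mm range (quantised to the
  0.3 mm proton voxel, the granularity at which thickness is measurable),
  GAG content coupled positively to both tissue sodium concentration and
  stiffness, plus Gaussian scatter;
* ramp-and-hold force curves — approach to a 0.1 N contact threshold,
  a 0.6 s linear ramp to 0.3 mm depth, then a 240 s hold whose force
  relaxes as a triexponential decay toward the equilibrium plateau;
* paired sodium (3 mm) and proton (0.3 mm) volumes built by laying each
  site's cartilage slab into a 0.3 mm ground-truth grid and
  block-averaging to the sodium voxel size, which produces a *genuine*
  partial-volume effect rather than a multiplicative shortcut; three
  saline calibration phantoms (75/225/300 mM) fill whole voxels.

Voxel intensity model: cartilage intensity per unit high-res volume is
``gain * C_Na * water_fraction * biexp_fraction(TE)`` (sodium dissolved in
the tissue water, attenuated by biexponential T2* decay) and phantom
intensity is ``gain * C_Na * liquid_fraction(TE)``, so the quantification
chain's corrections are all exercised with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import ForceCurve, IndenterGeometry, contact_area
from .sodium import (
    ImageVolume,
    PhantomSpec,
    RelaxationParams,
    biexp_signal_fraction,
    liquid_signal_fraction,
)

__all__ = [
    "GroundTruthSite",
    "SimulationConfig",
    "VolumeLayout",
    "generate_sites",
    "simulate_indentation_curve",
    "simulate_volumes",
]

# Approach phase: protocol advances at 50 um/s until the 0.1 N contact
# threshold; simulated as a linear force rise over a fixed 0.15 mm of
# travel (only the threshold crossing matters downstream).
APPROACH_SPEED_MM_S = 0.05
APPROACH_TRAVEL_MM = 0.15

# Thickness is quantised to the proton voxel; measurable range of degraded
# tibial-plateau cartilage.
THICKNESS_GRID_MM = np.round(np.arange(1.2, 3.0 + 1e-9, 0.3), 10)


@dataclass(frozen=True)
class GroundTruthSite:
    """True state of one indentation location."""

    plateau_id: int
    site_id: int
    thickness_mm: float
    gag_mg_per_ml: float
    true_sodium_mM: float
    eq_force_N: float
    amplitudes_N: tuple[float, float, float]
    taus_s: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if any(a < 0 for a in self.amplitudes_N):
            raise ValueError("amplitudes must be non-negative")
        taus = self.taus_s
        if not (0 < taus[0] < taus[1] < taus[2]):
            raise ValueError("taus must be positive and strictly increasing")
        if not 50 <= self.true_sodium_mM <= 600:
            raise ValueError("sodium concentration outside plausible [50, 600] mM")

    @property
    def peak_force_N(self) -> float:
        """Force at the start of the hold: equilibrium plus all decay amplitudes."""
        return self.eq_force_N + sum(self.amplitudes_N)


@dataclass
class SimulationConfig:
    """Study-population and acquisition parameters of the simulation.

    Defaults emulate the ex vivo study design: 4 plateaus x 16 sites
    (64 locations), mean apparent peak modulus ~3.4 MPa with the
    equilibrium modulus near a quarter of it, mean GAG ~3.4 mg/mL, mean
    tissue sodium ~225 mM, phantoms at 75/225/300 mM, 3 mm sodium and
    0.3 mm proton voxels.  Coupling slopes are positive (more GAG ->
    more sodium, stiffer tissue); scatter SDs set the realistic noise
    floor of each measurement.
    """

    n_plateaus: int = 4
    sites_per_plateau: int = 16
    seed: int = 0
    force_noise_sd_N: float = 0.008
    image_noise_sd: float = 1.0
    phantom_concentrations_mM: tuple[float, ...] = (75.0, 225.0, 300.0)
    sodium_voxel_mm: float = 3.0
    proton_voxel_mm: float = 0.3
    gag_sodium_slope: float = 25.0  # mM per (mg/mL)
    gag_modulus_slope: float = 0.5  # MPa per (mg/mL)
    gag_mean_mg_per_ml: float = 3.4
    gag_sd_mg_per_ml: float = 2.0
    sodium_baseline_mM: float = 225.0
    sodium_noise_sd_mM: float = 30.0
    peak_modulus_baseline_MPa: float = 3.4
    modulus_noise_sd_MPa: float = 0.5
    eq_to_peak_ratio: float = 0.24
    eq_modulus_noise_sd_MPa: float = 0.08
    intensity_gain_per_mM: float = 0.3
    sampling_rate_hz: float = 10.0
    proton_tissue_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.n_plateaus < 1 or self.sites_per_plateau < 1:
            raise ValueError("counts must be >= 1")
        if min(self.force_noise_sd_N, self.image_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.sodium_voxel_mm, self.proton_voxel_mm) <= 0:
            raise ValueError("voxel sizes must be positive")
        concs = self.phantom_concentrations_mM
        if len(set(concs)) != len(concs) or min(concs) <= 0:
            raise ValueError("phantom concentrations must be distinct and positive")
        if self.sampling_rate_hz < 0:
            raise ValueError("sampling rate must be non-negative")


@dataclass
class VolumeLayout:
    """Where each site and phantom sits in the simulated volumes."""

    phantoms: list[PhantomSpec]
    site_sodium_index: dict[int, tuple[int, int, int]]
    site_proton_column: dict[int, tuple[int, int]]


def generate_sites(
    config: SimulationConfig,
    geometry: IndenterGeometry | None = None,
) -> list[GroundTruthSite]:
    """Draw the ground-truth site population.

    GAG is a truncated Gaussian; sodium and peak modulus are affine in GAG
    (the configured coupling slopes) plus Gaussian scatter; the equilibrium
    modulus is a fixed fraction of the peak modulus plus scatter.  Forces
    follow from the moduli through the nominal area and strain, so the
    indentation analysis can recover the moduli exactly in the noise-free
    limit.  Time constants are drawn on three separated scales (fast ~1-4 s,
    intermediate ~10-30 s, slow ~80-160 s).  Deterministic given the seed.
    """
    geometry = geometry or IndenterGeometry()
    rng = np.random.default_rng((config.seed, 0))
    area = contact_area(geometry.tip_radius_mm, geometry.indentation_depth_mm)
    sites: list[GroundTruthSite] = []
    site_id = 0
    for plateau in range(1, config.n_plateaus + 1):
        for _ in range(config.sites_per_plateau):
            site_id += 1
            thickness = float(rng.choice(THICKNESS_GRID_MM))
            gag = config.gag_mean_mg_per_ml + config.gag_sd_mg_per_ml * rng.standard_normal()
            gag = max(gag, 0.3)
            sodium = (
                config.sodium_baseline_mM
                + config.gag_sodium_slope * (gag - config.gag_mean_mg_per_ml)
                + config.sodium_noise_sd_mM * rng.standard_normal()
            )
            sodium = float(np.clip(sodium, 50.0, 600.0))
            peak_mod = (
                config.peak_modulus_baseline_MPa
                + config.gag_modulus_slope * (gag - config.gag_mean_mg_per_ml)
                + config.modulus_noise_sd_MPa * rng.standard_normal()
            )
            peak_mod = max(peak_mod, 0.3)
            eq_mod = (
                config.eq_to_peak_ratio * peak_mod
                + config.eq_modulus_noise_sd_MPa * rng.standard_normal()
            )
            eq_mod = float(np.clip(eq_mod, 0.05, 0.8 * peak_mod))
            strain = geometry.indentation_depth_mm / thickness
            peak_force = peak_mod * area * strain
            eq_force = eq_mod * area * strain
            total_amp = peak_force - eq_force
            weights = rng.uniform(0.5, 1.5, size=3)
            weights /= weights.sum()
            amps = tuple(float(total_amp * w) for w in weights)
            taus = (
                float(rng.uniform(1.0, 4.0)),
                float(rng.uniform(10.0, 30.0)),
                float(rng.uniform(80.0, 160.0)),
            )
            sites.append(
                GroundTruthSite(
                    plateau_id=plateau,
                    site_id=site_id,
                    thickness_mm=thickness,
                    gag_mg_per_ml=float(gag),
                    true_sodium_mM=sodium,
                    eq_force_N=float(eq_force),
                    amplitudes_N=amps,
                    taus_s=taus,
                )
            )
    return sites


def simulate_indentation_curve(
    site: GroundTruthSite,
    geometry: IndenterGeometry | None = None,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """Ramp-and-hold force curve for one site.

    Phases: linear force rise to the contact threshold over 0.15 mm at
    50 um/s; linear ramp to the indentation depth (0.3 mm / 0.5 mm/s =
    0.6 s) ending at the peak force; 240 s hold with triexponential
    relaxation toward the equilibrium force.  Additive Gaussian force
    noise per the config; with zero noise, the hold-phase force is the
    closed-form decay exactly and its first sample equals
    ``eq_force + sum(amplitudes)``.
    """
    geometry = geometry or IndenterGeometry()
    config = config or SimulationConfig()
    if config.sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if rng is None:
        rng = np.random.default_rng((config.seed, 1, site.site_id))

    dt = 1.0 / config.sampling_rate_hz
    t_approach = APPROACH_TRAVEL_MM / APPROACH_SPEED_MM_S
    t_ramp = geometry.ramp_duration_s
    t_total = t_approach + t_ramp + geometry.hold_s
    time = np.arange(0.0, t_total + dt / 2, dt)

    threshold = geometry.contact_threshold_N
    peak = site.peak_force_N
    amps = np.asarray(site.amplitudes_N)
    taus = np.asarray(site.taus_s)

    force = np.empty_like(time)
    displacement = np.empty_like(time)
    in_approach = time < t_approach
    in_ramp = (time >= t_approach) & (time < t_approach + t_ramp)
    in_hold = time >= t_approach + t_ramp

    force[in_approach] = threshold * time[in_approach] / t_approach
    displacement[in_approach] = APPROACH_SPEED_MM_S * time[in_approach]

    tr = time[in_ramp] - t_approach
    force[in_ramp] = threshold + (peak - threshold) * tr / t_ramp
    displacement[in_ramp] = APPROACH_TRAVEL_MM + geometry.ramp_speed_mm_s * tr

    th = time[in_hold] - t_approach - t_ramp
    force[in_hold] = site.eq_force_N + (amps * np.exp(-th[:, None] / taus)).sum(axis=1)
    displacement[in_hold] = APPROACH_TRAVEL_MM + geometry.indentation_depth_mm

    if config.force_noise_sd_N > 0:
        force = force + rng.normal(0.0, config.force_noise_sd_N, size=force.size)

    return ForceCurve(time_s=time, displacement_mm=displacement, force_N=force)


def simulate_volumes(
    sites: list[GroundTruthSite],
    config: SimulationConfig | None = None,
    relaxation: RelaxationParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, ImageVolume, VolumeLayout]:
    """Paired sodium and proton volumes plus the site/phantom layout.

    Each site occupies one sodium voxel column; its cartilage slab of the
    site's true thickness is painted into a 0.3 mm ground-truth grid at
    intensity ``gain * C_Na * water_fraction * biexp_fraction`` and then
    block-averaged down to the 3 mm sodium grid, so thin cartilage is
    genuinely diluted by the surrounding signal-free volume.  Phantom
    tubes fill whole voxels at ``gain * C * liquid_fraction``.  The proton
    volume marks the same slabs at full resolution.
    """
    if not sites:
        raise ValueError("need at least one site")
    config = config or SimulationConfig()
    relaxation = relaxation or RelaxationParams()
    if rng is None:
        rng = np.random.default_rng((config.seed, 2))

    ratio = config.sodium_voxel_mm / config.proton_voxel_mm
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError("sodium voxel must be an integer multiple of proton voxel")

    n = len(sites)
    nx = int(math.ceil(math.sqrt(n)))
    ny = int(math.ceil(n / nx))
    n_ph = len(config.phantom_concentrations_mM)
    nx = max(nx, n_ph)
    ny_total = ny + 1  # extra row of voxels for the phantoms

    cart_frac = biexp_signal_fraction(relaxation)
    liq_frac = liquid_signal_fraction(relaxation)
    gain = config.intensity_gain_per_mM

    field_hi = np.zeros((nx * r, ny_total * r, r))
    proton_hi = np.zeros_like(field_hi)
    site_sodium_index: dict[int, tuple[int, int, int]] = {}
    site_proton_column: dict[int, tuple[int, int]] = {}

    for idx, site in enumerate(sites):
        ix, iy = idx % nx, idx // nx
        m = int(round(site.thickness_mm / config.proton_voxel_mm))
        if m > r:
            raise ValueError(
                f"site {site.site_id}: slab of {site.thickness_mm} mm exceeds "
                f"the {config.sodium_voxel_mm} mm field of view"
            )
        sl = (slice(ix * r, (ix + 1) * r), slice(iy * r, (iy + 1) * r), slice(0, m))
        field_hi[sl] = gain * site.true_sodium_mM * relaxation.water_fraction * cart_frac
        proton_hi[sl] = config.proton_tissue_intensity
        site_sodium_index[site.site_id] = (ix, iy, 0)
        site_proton_column[site.site_id] = (ix * r + r // 2, iy * r + r // 2)

    phantoms: list[PhantomSpec] = []
    for p, conc in enumerate(config.phantom_concentrations_mM):
        sl = (slice(p * r, (p + 1) * r), slice(ny * r, (ny + 1) * r), slice(0, r))
        field_hi[sl] = gain * conc * liq_frac
        phantoms.append(
            PhantomSpec(
                concentration_mM=conc,
                roi=((p, p + 1), (ny, ny + 1), (0, 1)),
            )
        )

    sodium_values = field_hi.reshape(nx, r, ny_total, r, 1, r).mean(axis=(1, 3, 5))
    if config.image_noise_sd > 0:
        sodium_values = sodium_values + rng.normal(
            0.0, config.image_noise_sd, size=sodium_values.shape
        )
        proton_hi = proton_hi + rng.normal(0.0, config.image_noise_sd, size=proton_hi.shape)

    sodium_vol = ImageVolume(
        values=sodium_values,
        spacing_mm=(config.sodium_voxel_mm,) * 3,
        modality="sodium",
    )
    proton_vol = ImageVolume(
        values=proton_hi,
        spacing_mm=(config.proton_voxel_mm,) * 3,
        modality="proton",
    )
    return sodium_vol, proton_vol, VolumeLayout(
        phantoms=phantoms,
        site_sodium_index=site_sodium_index,
        site_proton_column=site_proton_column,
    )
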