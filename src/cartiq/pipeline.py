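"""End-to-end orchestration: simulate -> fit -> quantify -> join -> stats.

One :func:`run_pipeline` call executes the full analysis on either
simulated or on-disk inputs and leaves a reproducible trail: every output
table, a run manifest with the config snapshot and per-stage record
counts, and QC flags for every excluded site.  Counts always reconcile:
``sites_in == quantified + excluded_no_cartilage + excluded_fit_failure``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .mechanics import IndenterGeometry, analyze_curve
from .sodium import (
    NoCartilageError,
    RelaxationParams,
    extract_phantom_intensities,
    fit_calibration,
    measure_thickness,
    quantify_site,
)
from .stats import adjusted_linear_model, correlation_table
from .synthetic import (
    SimulationConfig,
    generate_sites,
    simulate_indentation_curve,
    simulate_volumes,
)

__version__ = "0.1.0"

logger = logging.getLogger("cartiq")

MODEL_PAIRS = [
    ("peak_modulus_MPa", "gag_mg_per_ml"),
    ("eq_modulus_MPa", "gag_mg_per_ml"),
    ("permeability_k1", "gag_mg_per_ml"),
    ("sodium_mM", "gag_mg_per_ml"),
    ("peak_modulus_MPa", "sodium_mM"),
    ("eq_modulus_MPa", "sodium_mM"),
    ("permeability_k1", "sodium_mM"),
]


@dataclass
class PipelineConfig:
    """Everything one run needs; every field is YAML-overridable."""

    outdir: str = "cartiq_out"
    seed: int = 0
    simulate: bool = True
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    geometry: IndenterGeometry = field(default_factory=IndenterGeometry)
    relaxation: RelaxationParams = field(default_factory=RelaxationParams)
    # input locations used when simulate is False
    curves_dir: str | None = None
    sodium_path: str | None = None
    proton_path: str | None = None
    sidecar_path: str | None = None
    gag_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_yaml_config(path)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        geom = IndenterGeometry(**raw.pop("geometry", {}))
        relax = RelaxationParams(**raw.pop("relaxation", {}))
        cfg = cls(simulation=sim, geometry=geom, relaxation=relax, **raw)
        return cfg

    def snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        snap["simulation"]["seed"] = self.seed
        return snap


@dataclass
class RunManifest:
    """Config snapshot, software version and reconciled per-stage counts."""

    config: dict
    version: str
    counts: dict[str, int]
    qc_flags: dict[str, int]

    def reconciles(self) -> bool:
        c = self.counts
        return c["sites_in"] == (
            c["quantified"] + c["excluded_no_cartilage"] + c["excluded_fit_failure"]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)
        )


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema and consistency checks; returns human-readable problems."""
    problems: list[str] = []
    if config.simulate:
        return problems
    for name in ("curves_dir", "sodium_path", "proton_path", "sidecar_path", "gag_csv"):
        value = getattr(config, name)
        if value is None:
            problems.append(f"{name} is required when simulate is false")
        elif not Path(value).exists():
            problems.append(f"{name}: {value} does not exist")
    if problems:
        return problems
    layout, _, payload = io.read_sidecar_json(config.sidecar_path)
    if len(layout.phantoms) < 2:
        problems.append("sidecar lists fewer than 2 calibration phantoms")
    sodium = io.read_volume_nifti(config.sodium_path, "sodium")
    if abs(sodium.spacing_mm[0] - payload["sodium_voxel_mm"]) > 1e-6:
        problems.append(
            f"sodium voxel {sodium.spacing_mm[0]} mm does not match "
            f"sidecar {payload['sodium_voxel_mm']} mm"
        )
    for csv in sorted(Path(config.curves_dir).glob("*.csv")):
        try:
            io.read_curve_csv(csv)
        except ValueError as exc:
            problems.append(str(exc))
    gag = pd.read_csv(config.gag_csv)
    for col in ("site_id", "gag_mg_per_ml"):
        if col not in gag.columns:
            problems.append(f"gag table missing column {col}")
    return problems


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    sites = generate_sites(sim, config.geometry)
    inputs = outdir / "inputs"
    curves_dir = inputs / "curves"
    curves_dir.mkdir(parents=True, exist_ok=True)
    io.write_sites_csv(sites, inputs / "truth.csv")
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "plateau_id": [s.plateau_id for s in sites],
            "gag_mg_per_ml": [s.gag_mg_per_ml for s in sites],
        }
    ).to_csv(inputs / "gag.csv", index=False)
    for site in sites:
        curve = simulate_indentation_curve(site, config.geometry, sim)
        io.write_curve_csv(curve, curves_dir / f"site_{site.site_id:03d}.csv")
    sodium, proton, layout = simulate_volumes(sites, sim, config.relaxation)
    io.write_volume_nifti(sodium, inputs / "sodium.nii")
    io.write_volume_nifti(proton, inputs / "proton.nii")
    io.write_sidecar_json(
        inputs / "sidecar.json", layout, config.relaxation,
        sim.sodium_voxel_mm, sim.proton_voxel_mm,
    )
    config.curves_dir = str(curves_dir)
    config.sodium_path = str(inputs / "sodium.nii")
    config.proton_path = str(inputs / "proton.nii")
    config.sidecar_path = str(inputs / "sidecar.json")
    config.gag_csv = str(inputs / "gag.csv")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``config.outdir``.

    Stages: (optional) simulation of inputs; per-curve indentation
    analysis using the proton-measured thickness; per-site sodium
    quantification; the three-way join; correlation tables and
    plateau-adjusted models.  Excluded sites are never dropped silently —
    each carries a QC flag and is tallied in the manifest.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        _simulate_inputs(config, outdir)
    problems = validate_inputs(config)
    if problems:
        raise ValueError("invalid inputs:\n" + "\n".join(problems))

    layout, relaxation, _ = io.read_sidecar_json(config.sidecar_path)
    sodium = io.read_volume_nifti(config.sodium_path, "sodium")
    proton = io.read_volume_nifti(config.proton_path, "proton")
    gag = pd.read_csv(config.gag_csv)

    cal = fit_calibration(extract_phantom_intensities(sodium, layout.phantoms))

    curve_paths = {
        int(p.stem.split("_")[-1]): p
        for p in sorted(Path(config.curves_dir).glob("site_*.csv"))
    }

    rows = []
    qc_tally: dict[str, int] = {}
    for site_id in sorted(layout.site_sodium_index):
        column = layout.site_proton_column[site_id]
        quant = quantify_site(
            sodium, proton, cal, relaxation, site_id,
            layout.site_sodium_index[site_id], column,
        )
        row = {
            "site_id": site_id,
            "raw_intensity": quant.raw_intensity,
            "calibrated_mM": quant.calibrated_mM,
            "thickness_mm": quant.thickness_mm,
            "pv_factor": quant.pv_factor,
            "relaxation_factor": quant.relaxation_factor,
            "sodium_mM": quant.final_concentration_mM,
            "qc_flag": quant.qc_flag,
        }
        if quant.qc_flag == "ok":
            path = curve_paths.get(site_id)
            if path is None:
                raise FileNotFoundError(f"no curve file for site {site_id}")
            curve = io.read_curve_csv(path)
            mech = analyze_curve(curve, quant.thickness_mm, config.geometry)
            row.update(
                peak_modulus_MPa=mech.apparent_peak_modulus_MPa,
                eq_modulus_MPa=mech.apparent_equilibrium_modulus_MPa,
                r_squared=mech.r_squared,
            )
            if mech.qc_flag == "ok":
                for i in range(3):
                    row[f"permeability_k{i + 1}"] = mech.permeability_per_compartment[i]
                    row[f"tau{i + 1}_s"] = mech.taus_s[i]
            else:
                row["qc_flag"] = mech.qc_flag
        rows.append(row)
        qc_tally[row["qc_flag"]] = qc_tally.get(row["qc_flag"], 0) + 1

    results = pd.DataFrame(rows).merge(gag, on="site_id", how="left")
    n_missing_gag = int(results["gag_mg_per_ml"].isna().sum())
    if n_missing_gag:
        logger.info("excluding %d sites without GAG measurements", n_missing_gag)
    results.to_csv(outdir / "site_results.csv", index=False)

    joined = results[results["qc_flag"] == "ok"].dropna(subset=["gag_mg_per_ml"])
    corr = correlation_table(joined)
    corr.to_csv(outdir / "correlations.csv", index=False)

    model_rows = []
    for outcome, predictor in MODEL_PAIRS:
        for method in ("fixed", "mixed"):
            try:
                fit = adjusted_linear_model(joined, outcome, predictor, method=method)
            except (ValueError, KeyError) as exc:
                logger.warning("%s ~ %s (%s) failed: %s", outcome, predictor, method, exc)
                continue
            model_rows.append(
                dict(outcome=outcome, predictor=predictor, method=method,
                     coefficient=fit.coefficient, std_error=fit.std_error,
                     p_value=fit.p_value, n=fit.n)
            )
    pd.DataFrame(model_rows).to_csv(outdir / "model_fits.csv", index=False)

    n_sites = len(rows)
    counts = {
        "sites_in": n_sites,
        "quantified": int(sum(r["qc_flag"] == "ok" for r in rows)),
        "excluded_no_cartilage": qc_tally.get("no_cartilage", 0),
        "excluded_fit_failure": (
            qc_tally.get("fit_failure", 0)
            + qc_tally.get("no_contact", 0)
            + qc_tally.get("segmentation_failure", 0)
        ),
        "missing_gag": n_missing_gag,
        "joined_for_stats": len(joined),
    }
    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        counts=counts,
        qc_flags=qc_tally,
    )
    if not manifest.reconciles():
        raise RuntimeError(f"site accounting does not reconcile: {counts}")
    manifest.to_json(outdir / "manifest.json")
    return manifest
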