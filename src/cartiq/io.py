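"""File formats: curve/site CSV, NIfTI volumes, JSON sidecar, YAML config."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .mechanics import ForceCurve
from .sodium import ImageVolume, PhantomSpec, RelaxationParams
from .synthetic import GroundTruthSite, VolumeLayout

CURVE_COLUMNS = ["time_s", "displacement_mm", "force_N"]


def write_curve_csv(curve: ForceCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": curve.time_s,
            "displacement_mm": curve.displacement_mm,
            "force_N": curve.force_N,
        }
    ).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> ForceCurve:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing curve columns {missing}")
    return ForceCurve(
        time_s=df["time_s"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
    )


def write_sites_csv(sites: list[GroundTruthSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        row = {
            "plateau_id": s.plateau_id,
            "site_id": s.site_id,
            "thickness_mm": s.thickness_mm,
            "gag_mg_per_ml": s.gag_mg_per_ml,
            "true_sodium_mM": s.true_sodium_mM,
            "eq_force_N": s.eq_force_N,
        }
        for i in range(3):
            row[f"amplitude{i + 1}_N"] = s.amplitudes_N[i]
            row[f"tau{i + 1}_s"] = s.taus_s[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[GroundTruthSite]:
    df = pd.read_csv(path)
    return [
        GroundTruthSite(
            plateau_id=int(r.plateau_id),
            site_id=int(r.site_id),
            thickness_mm=float(r.thickness_mm),
            gag_mg_per_ml=float(r.gag_mg_per_ml),
            true_sodium_mM=float(r.true_sodium_mM),
            eq_force_N=float(r.eq_force_N),
            amplitudes_N=(float(r.amplitude1_N), float(r.amplitude2_N), float(r.amplitude3_N)),
            taus_s=(float(r.tau1_s), float(r.tau2_s), float(r.tau3_s)),
        )
        for r in df.itertuples()
    ]


def write_volume_nifti(volume: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_volume_nifti(path: str | Path, modality: str) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(
        values=np.asarray(img.dataobj, dtype=float),
        spacing_mm=spacing,
        modality=modality,
    )


def write_sidecar_json(
    path: str | Path,
    layout: VolumeLayout,
    relaxation: RelaxationParams,
    sodium_voxel_mm: float,
    proton_voxel_mm: float,
) -> None:
    """Acquisition sidecar: relaxation constants, phantom ROIs, site locations."""
    payload = {
        "te_ms": relaxation.te_ms,
        "t2_short_ms": relaxation.t2_short_ms,
        "t2_long_ms": relaxation.t2_long_ms,
        "t2_liquid_ms": relaxation.t2_liquid_ms,
        "short_fraction": relaxation.short_fraction,
        "long_fraction": relaxation.long_fraction,
        "water_fraction": relaxation.water_fraction,
        "sodium_voxel_mm": sodium_voxel_mm,
        "proton_voxel_mm": proton_voxel_mm,
        "phantoms": [
            {"concentration_mM": p.concentration_mM, "roi": [list(ax) for ax in p.roi]}
            for p in layout.phantoms
        ],
        "sites": {
            str(sid): {
                "sodium_index": list(layout.site_sodium_index[sid]),
                "proton_column": list(layout.site_proton_column[sid]),
            }
            for sid in layout.site_sodium_index
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_sidecar_json(path: str | Path) -> tuple[VolumeLayout, RelaxationParams, dict]:
    payload = json.loads(Path(path).read_text())
    relaxation = RelaxationParams(
        te_ms=payload["te_ms"],
        t2_short_ms=payload["t2_short_ms"],
        t2_long_ms=payload["t2_long_ms"],
        t2_liquid_ms=payload["t2_liquid_ms"],
        short_fraction=payload["short_fraction"],
        long_fraction=payload["long_fraction"],
        water_fraction=payload["water_fraction"],
    )
    layout = VolumeLayout(
        phantoms=[
            PhantomSpec(
                concentration_mM=p["concentration_mM"],
                roi=tuple(tuple(ax) for ax in p["roi"]),
            )
            for p in payload["phantoms"]
        ],
        site_sodium_index={
            int(sid): tuple(loc["sodium_index"]) for sid, loc in payload["sites"].items()
        },
        site_proton_column={
            int(sid): tuple(loc["proton_column"]) for sid, loc in payload["sites"].items()
        },
    )
    return layout, relaxation, payload


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
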