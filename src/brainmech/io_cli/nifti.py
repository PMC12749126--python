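"""NIfTI and CSV interchange.

Conventions: volumes are written x-fastest with voxel sizes carried in the
header zooms in millimeters (the NIfTI norm); the package API works in
meters everywhere, so readers convert. Indices are 0-based voxel centers.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from ..synthetic_data import ForceCurve, MegSpec, ProbeSpec, WaveAcquisition

MM = 1e-3


def write_nifti_volume(path, data: np.ndarray, voxel_size_m, dtype=np.float64) -> None:
    data = np.asarray(data)
    affine = np.diag([voxel_size_m[0] / MM, voxel_size_m[1] / MM, voxel_size_m[2] / MM, 1.0])
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms([h / MM for h in voxel_size_m])
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3D/4D NIfTI volume; returns (data, voxel size in meters)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path.name}: expected a 3D or 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) * MM for z in zooms)


def _phase_filename(direction: str, offset: int) -> str:
    return f"phase_d{direction}_t{offset}.nii.gz"


def write_acquisition(outdir, acq: WaveAcquisition, ground_truth: dict | None = None) -> None:
    """One NIfTI per (direction, offset) plus magnitude, masks and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (direction, offset), vol in acq.phase.items():
        write_nifti_volume(outdir / _phase_filename(direction, offset), vol, acq.voxel_size)
    write_nifti_volume(outdir / "magnitude.nii.gz", acq.magnitude, acq.voxel_size)
    for name, m in acq.masks.items():
        write_nifti_volume(outdir / f"mask_{name}.nii.gz", m, acq.voxel_size, dtype=np.uint8)
    sidecar = {
        "frequency_hz": acq.frequency,
        "meg": {
            "encoding_sensitivity_rad_per_m": acq.meg.encoding_sensitivity,
            "n_phase_offsets": acq.meg.n_phase_offsets,
            "directions": list(acq.meg.directions),
        },
        "masks": sorted(acq.masks),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    (outdir / "acquisition.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_acquisition(indir) -> WaveAcquisition:
    indir = Path(indir)
    meta = json.loads((indir / "acquisition.json").read_text())
    meg = MegSpec(
        encoding_sensitivity=meta["meg"]["encoding_sensitivity_rad_per_m"],
        n_phase_offsets=meta["meg"]["n_phase_offsets"],
        directions=meta["meg"]["directions"],
    )
    phase: dict[tuple[str, int], np.ndarray] = {}
    voxel_size = None
    for d in meg.directions:
        for t in range(meg.n_phase_offsets):
            vol, voxel_size = read_nifti_volume(indir / _phase_filename(d, t))
            phase[(d, t)] = vol
    magnitude, _ = read_nifti_volume(indir / "magnitude.nii.gz")
    masks = {}
    for name in meta["masks"]:
        m, _ = read_nifti_volume(indir / f"mask_{name}.nii.gz")
        masks[name] = m.astype(bool)
    return WaveAcquisition(
        phase=phase,
        magnitude=magnitude,
        masks=masks,
        meg=meg,
        frequency=meta["frequency_hz"],
        voxel_size=voxel_size,
    )


def write_force_curve(path, curve: ForceCurve, sidecar_path=None) -> None:
    """CSV with header z_m,deflection_m (or deflection_V); ground truth in sidecar."""
    col = "deflection_m" if curve.deflection_unit == "m" else "deflection_V"
    pd.DataFrame({"z_m": curve.z, col: curve.deflection}).to_csv(path, index=False)
    if sidecar_path is not None:
        meta = {
            "probe": {
                "radius_m": curve.probe.radius,
                "spring_constant_n_per_m": curve.probe.spring_constant,
                "deflection_sensitivity_m_per_v": curve.probe.deflection_sensitivity,
                "poisson_ratio": curve.probe.poisson_ratio,
            },
        }
        if curve.true_E is not None:
            meta["ground_truth"] = {"youngs_modulus_pa": curve.true_E,
                                    "contact_z_m": curve.true_contact}
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_force_curve(path, probe: ProbeSpec) -> ForceCurve:
    df = pd.read_csv(path)
    if "z_m" not in df.columns:
        raise ValueError(f"{path}: missing z_m column")
    if "deflection_m" in df.columns:
        return ForceCurve(df["z_m"].to_numpy(), df["deflection_m"].to_numpy(), probe, "m")
    if "deflection_V" in df.columns:
        return ForceCurve(df["z_m"].to_numpy(), df["deflection_V"].to_numpy(), probe, "V")
    raise ValueError(f"{path}: need a deflection_m or deflection_V column")
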