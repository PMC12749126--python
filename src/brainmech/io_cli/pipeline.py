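"""Stage orchestration: config -> files -> report bundle, with a manifest."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..afm_hertz import analyze_group, compare_groups, fit_curve
from ..inversion import ahi_invert, kpa, negative_loss_fraction, roi_statistics
from ..phase_processing import reconstruct_displacement
from ..synthetic_data import generate_cell_population, simulate_mre_acquisition
from .config import RunConfig, SCHEMA_VERSION, load_config
from .nifti import write_acquisition, write_force_curve, write_nifti_volume

log = logging.getLogger("brainmech")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def roi_masks_from_labels(labels: np.ndarray, margin: int) -> dict[str, np.ndarray]:
    """One eroded mask per nonzero label, named region_<label>.

    Erosion by ``margin`` keeps ROI statistics clear of stencil and
    region-boundary artifacts.
    """
    from scipy.ndimage import binary_erosion, generate_binary_structure

    structure = generate_binary_structure(3, 1)
    masks = {}
    for label in np.unique(labels):
        if label == 0:
            continue
        m = labels == label
        if margin > 0:
            m = binary_erosion(m, structure=structure, iterations=margin)
        masks[f"region_{int(label)}"] = m
    return masks


def run_mre_stage(cfg: RunConfig, outdir: Path) -> dict:
    mre = cfg.mre
    assert mre is not None
    t0 = time.perf_counter()
    log.info("simulate-mre: grid=%s seed=%d noise_sd=%g",
             mre.phantom.grid_shape, mre.phantom.seed, mre.noise_sd)

    masks = roi_masks_from_labels(mre.phantom.region_labels, mre.roi_margin)
    acq, _field = simulate_mre_acquisition(
        mre.phantom, mre.meg, noise_sd=mre.noise_sd, masks=masks
    )
    acq_dir = outdir / "acquisition"
    truth = {
        f"region_{label}": {"storage_pa": g.real, "loss_pa": g.imag}
        for label, g in mre.phantom.region_moduli.items()
    }
    write_acquisition(acq_dir, acq, ground_truth=truth)

    log.info("recon + invert: laplacian=%s", mre.inversion.laplacian)
    support = mre.phantom.region_labels != 0
    field = reconstruct_displacement(acq, mask=support)
    maps = ahi_invert(field, mre.inversion, support)

    maps_dir = outdir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    for name, vol in (("storage", maps.storage), ("loss", maps.loss),
                      ("stiffness", maps.stiffness)):
        write_nifti_volume(maps_dir / f"{name}_pa.nii.gz",
                           np.nan_to_num(vol, nan=0.0), acq.voxel_size, dtype=np.float32)
    write_nifti_volume(maps_dir / "valid.nii.gz", maps.valid, acq.voxel_size, dtype=np.uint8)

    report = roi_statistics(maps, masks)
    frame = report.to_frame()
    frame.to_csv(outdir / "roi_report.csv", index=False)
    roi_json = {
        r.name: {
            "n_voxels": r.n_voxels,
            "storage_kpa": {"mean": kpa(r.mean_storage), "sd": kpa(r.sd_storage)},
            "loss_kpa": {"mean": kpa(r.mean_loss), "sd": kpa(r.sd_loss)},
            "stiffness_kpa": {"mean": kpa(r.mean_stiffness), "sd": kpa(r.sd_stiffness)},
        }
        for r in report.rois
    }
    roi_json["qc_negative_loss_fraction"] = negative_loss_fraction(maps)
    (outdir / "roi_report.json").write_text(json.dumps(roi_json, indent=2, sort_keys=True))
    log.info("mre stage done in %.1fs", time.perf_counter() - t0)
    return roi_json


def run_afm_stage(cfg: RunConfig, outdir: Path) -> dict:
    afm = cfg.afm
    assert afm is not None
    t0 = time.perf_counter()
    curves_dir = outdir / "curves"
    curves_dir.mkdir(parents=True, exist_ok=True)

    per_cell_rows = []
    group_results = {}
    for g in afm.groups:
        log.info("simulate-afm: group=%s n=%d seed=%d", g.name, g.n_cells, g.seed)
        curves = generate_cell_population(
            g.mean_pa, g.sd_pa, g.n_cells, afm.probe, seed=g.seed,
            contact_z=afm.contact_um * 1e-6, ramp_size=afm.ramp_um * 1e-6,
            n_points=afm.n_points, noise_sd=afm.noise_sd_nm * 1e-9,
        )
        results = []
        for i, curve in enumerate(curves):
            write_force_curve(
                curves_dir / f"{g.name}_{i:03d}.csv", curve,
                sidecar_path=curves_dir / f"{g.name}_{i:03d}.json",
            )
            fit = fit_curve(curve)
            results.append(fit)
            per_cell_rows.append({
                "group": g.name, "cell": i,
                "youngs_modulus_pa": fit.youngs_modulus,
                "contact_point_m": fit.contact_point,
                "rms_residual_n": fit.rms_residual,
                "n_fit_points": fit.n_fit_points,
                "converged": fit.converged,
                "true_E_pa": curve.true_E,
            })
        group_results[g.name] = results

    pd.DataFrame(per_cell_rows).to_csv(outdir / "cell_results.csv", index=False)

    summaries = {name: analyze_group(res, name=name) for name, res in group_results.items()}
    out = {"groups": {n: asdict(s) for n, s in summaries.items()}}
    names = list(group_results)
    if len(names) >= 2:
        comparison = compare_groups(
            group_results[names[0]], group_results[names[1]],
            name_a=names[0], name_b=names[1],
        )
        out["comparison"] = asdict(comparison)
    (outdir / "group_comparison.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    log.info("afm stage done in %.1fs", time.perf_counter() - t0)
    return out


def run_pipeline(config_path, outdir) -> dict:
    """Execute every stage present in the config; write a manifest.

    The manifest records the package and schema versions plus a sha256 for
    each output file, so byte-level reproducibility is checkable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)

    bundle: dict = {}
    if cfg.mre is not None:
        try:
            bundle["mre"] = run_mre_stage(cfg, outdir / "mre")
        except Exception as exc:
            raise RuntimeError(f"stage 'mre' failed: {exc}") from exc
    if cfg.afm is not None:
        try:
            bundle["afm"] = run_afm_stage(cfg, outdir / "afm")
        except Exception as exc:
            raise RuntimeError(f"stage 'afm' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config_sha256": _sha256(Path(config_path)),
        "outputs": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
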