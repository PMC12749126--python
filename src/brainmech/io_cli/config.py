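"""YAML run configuration with strict validation.

The schema is deliberately strict: unknown keys are rejected with their
dotted path, and every stage that draws random numbers must carry an
explicit integer seed so runs are reproducible by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ..inversion import InversionConfig
from ..synthetic_data import DEFAULT_DIRECTIONS, MegSpec, PhantomSpec, ProbeSpec

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    if not isinstance(section, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _require(section: dict, key: str, path: str) -> Any:
    if key not in section:
        raise ConfigError(f"{path}: missing required key {key!r}")
    return section[key]


@dataclass
class MreStageConfig:
    phantom: PhantomSpec
    meg: MegSpec
    inversion: InversionConfig
    noise_sd: float
    roi_margin: int


@dataclass
class AfmGroupConfig:
    name: str
    mean_pa: float
    sd_pa: float
    n_cells: int
    seed: int


@dataclass
class AfmStageConfig:
    probe: ProbeSpec
    groups: list[AfmGroupConfig]
    contact_um: float
    ramp_um: float
    n_points: int
    noise_sd_nm: float


@dataclass
class RunConfig:
    schema_version: int
    mre: MreStageConfig | None
    afm: AfmStageConfig | None


def _build_labels(grid_shape, regions, path: str) -> tuple[np.ndarray, dict[int, complex]]:
    labels = np.zeros(grid_shape, dtype=np.int32)
    moduli: dict[int, complex] = {}
    for i, region in enumerate(regions):
        rpath = f"{path}.regions[{i}]"
        _check_keys(region, {"label", "storage_pa", "loss_pa", "shape", "lo", "hi"}, rpath)
        label = int(_require(region, "label", rpath))
        moduli[label] = complex(
            float(_require(region, "storage_pa", rpath)),
            float(region.get("loss_pa", 0.0)),
        )
        shape = region.get("shape", "full")
        if shape == "full":
            labels[...] = label
        elif shape == "box":
            lo = [int(v) for v in _require(region, "lo", rpath)]
            hi = [int(v) for v in _require(region, "hi", rpath)]
            labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = label
        else:
            raise ConfigError(f"{rpath}: unknown shape {shape!r}")
    return labels, moduli


def _parse_mre(section: dict) -> MreStageConfig:
    _check_keys(section, {"phantom", "meg", "inversion", "noise_sd_rad", "roi_margin"}, "mre")
    ph = _require(section, "phantom", "mre")
    _check_keys(
        ph,
        {"grid_shape", "voxel_size_mm", "regions", "density_kg_m3", "frequency_hz",
         "amplitude_um", "propagation", "polarization", "seed"},
        "mre.phantom",
    )
    grid_shape = tuple(int(v) for v in _require(ph, "grid_shape", "mre.phantom"))
    labels, moduli = _build_labels(
        grid_shape, _require(ph, "regions", "mre.phantom"), "mre.phantom"
    )
    phantom = PhantomSpec(
        grid_shape=grid_shape,
        voxel_size=tuple(float(v) * 1e-3 for v in _require(ph, "voxel_size_mm", "mre.phantom")),
        region_labels=labels,
        region_moduli=moduli,
        density=float(ph.get("density_kg_m3", 1000.0)),
        frequency=float(ph.get("frequency_hz", 1000.0)),
        wave_amplitude=float(ph.get("amplitude_um", 5.0)) * 1e-6,
        propagation_direction=ph.get("propagation", (1.0, 0.0, 0.0)),
        polarization=ph.get("polarization", (0.0, 0.0, 1.0)),
        seed=int(_require(ph, "seed", "mre.phantom")),
    )

    mg = section.get("meg", {})
    _check_keys(mg, {"sensitivity_rad_per_m", "n_offsets", "directions"}, "mre.meg")
    meg = MegSpec(
        encoding_sensitivity=float(mg.get("sensitivity_rad_per_m", 1e5)),
        n_phase_offsets=int(mg.get("n_offsets", 4)),
        directions=tuple(mg.get("directions", DEFAULT_DIRECTIONS)),
    )

    inv = section.get("inversion", {})
    _check_keys(
        inv, {"density_kg_m3", "smoothing_sd", "laplacian", "edge_margin"}, "mre.inversion"
    )
    inversion = InversionConfig(
        density=float(inv.get("density_kg_m3", phantom.density)),
        frequency=phantom.frequency,
        smoothing_sd=float(inv.get("smoothing_sd", 0.0)),
        laplacian=inv.get("laplacian", "central"),
        edge_margin=int(inv.get("edge_margin", 1)),
    )
    return MreStageConfig(
        phantom=phantom,
        meg=meg,
        inversion=inversion,
        noise_sd=float(section.get("noise_sd_rad", 0.0)),
        roi_margin=int(section.get("roi_margin", 2)),
    )


def _parse_afm(section: dict) -> AfmStageConfig:
    _check_keys(section, {"probe", "groups", "curve"}, "afm")
    pr = section.get("probe", {})
    _check_keys(
        pr,
        {"radius_um", "spring_constant_n_per_m", "deflection_sensitivity_nm_per_v",
         "poisson_ratio"},
        "afm.probe",
    )
    probe = ProbeSpec(
        radius=float(pr.get("radius_um", 6.0)) * 1e-6,
        spring_constant=float(pr.get("spring_constant_n_per_m", 0.1)),
        deflection_sensitivity=float(pr.get("deflection_sensitivity_nm_per_v", 33.0)) * 1e-9,
        poisson_ratio=float(pr.get("poisson_ratio", 0.5)),
    )
    groups = []
    for i, g in enumerate(_require(section, "groups", "afm")):
        gpath = f"afm.groups[{i}]"
        _check_keys(g, {"name", "mean_pa", "sd_pa", "n_cells", "seed"}, gpath)
        groups.append(
            AfmGroupConfig(
                name=str(_require(g, "name", gpath)),
                mean_pa=float(_require(g, "mean_pa", gpath)),
                sd_pa=float(g.get("sd_pa", 0.0)),
                n_cells=int(_require(g, "n_cells", gpath)),
                seed=int(_require(g, "seed", gpath)),
            )
        )
    cv = section.get("curve", {})
    _check_keys(cv, {"contact_um", "ramp_um", "n_points", "noise_sd_nm"}, "afm.curve")
    return AfmStageConfig(
        probe=probe,
        groups=groups,
        contact_um=float(cv.get("contact_um", 0.5)),
        ramp_um=float(cv.get("ramp_um", 1.5)),
        n_points=int(cv.get("n_points", 200)),
        noise_sd_nm=float(cv.get("noise_sd_nm", 0.0)),
    )


def parse_config(raw: dict) -> RunConfig:
    _check_keys(raw, {"schema_version", "mre", "afm"}, "<root>")
    version = int(_require(raw, "schema_version", "<root>"))
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}; expected {SCHEMA_VERSION}")
    mre = _parse_mre(raw["mre"]) if "mre" in raw else None
    afm = _parse_afm(raw["afm"]) if "afm" in raw else None
    if mre is None and afm is None:
        raise ConfigError("config must define at least one of mre / afm")
    return RunConfig(schema_version=version, mre=mre, afm=afm)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return parse_config(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
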