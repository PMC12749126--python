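"""Algebraic Helmholtz inversion (AHI) and ROI modulus statistics.

Per voxel the complex shear modulus is the least-squares solution of
G* Lap(u_j) = -rho omega^2 u_j across the available displacement
components j:

    G* = -rho omega^2 * sum_j conj(Lap u_j) u_j / sum_j |Lap u_j|^2

The discrete Laplacian is the central 3-point stencil per axis; an
optional modified-wavenumber correction replaces each axis' second
difference by the exact second derivative of the locally estimated plane
wave, which makes recovery of analytic plane waves exact instead of
biased by the stencil's (kh/2)^2 / sin^2(kh/2) factor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter, generate_binary_structure

from .synthetic_data import DisplacementField

LAPLACIANS = ("central", "modified_wavenumber")


class FlatFieldError(ValueError):
    """Raised when the displacement field has no usable curvature anywhere."""


@dataclass
class InversionConfig:
    density: float = 1000.0  # kg/m^3; tissue value, configurable
    frequency: float = 1000.0  # Hz
    smoothing_sd: float = 0.0  # voxels; 0 disables
    laplacian: str = "central"
    edge_margin: int = 1  # voxels eroded from the mask boundary
    denom_floor_rel: float = 1e-12  # validity floor relative to max |Lap u|^2

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.smoothing_sd < 0:
            raise ValueError("smoothing_sd must be >= 0")
        if self.laplacian not in LAPLACIANS:
            raise ValueError(f"laplacian must be one of {LAPLACIANS}")
        if self.edge_margin < 1:
            raise ValueError("edge_margin must be >= 1")


@dataclass
class ElastogramMaps:
    """Per-voxel storage / loss / stiffness maps (Pa) with validity mask."""

    storage: np.ndarray  # G' (Pa)
    loss: np.ndarray  # G'' (Pa)
    stiffness: np.ndarray  # |G*| = sqrt(G'^2 + G''^2) (Pa)
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = self.valid
        if not np.allclose(
            self.stiffness[v], np.hypot(self.storage[v], self.loss[v]), rtol=1e-12
        ):
            raise ValueError("|G*| must equal sqrt(G'^2 + G''^2) at valid voxels")


@dataclass
class RoiStats:
    name: str
    n_voxels: int
    mean_storage: float
    sd_storage: float
    mean_loss: float
    sd_loss: float
    mean_stiffness: float
    sd_stiffness: float


@dataclass
class RoiReport:
    """Mean / sample-SD (n-1) of G', G'', |G*| over valid ROI voxels."""

    rois: list[RoiStats] = dc_field(default_factory=list)

    def __getitem__(self, name: str) -> RoiStats:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.rois)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rois])


def kpa(value_pa: float, decimals: int = 2) -> float:
    """Pa -> kPa at the reporting boundary."""
    return round(value_pa / 1e3, decimals)


def smooth_field(field: DisplacementField, sd: float) -> DisplacementField:
    """Gaussian-smooth real and imaginary parts per component; sd=0 is identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return field
    out = np.empty_like(field.amplitude)
    for j in range(3):
        out[..., j] = gaussian_filter(field.amplitude[..., j].real, sd) + 1j * gaussian_filter(
            field.amplitude[..., j].imag, sd
        )
    return DisplacementField(out, field.frequency, field.voxel_size)


def _second_difference(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Central 3-point second difference; edges are left at zero."""
    d2 = np.zeros_like(u)
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    mid = [slice(None)] * 3
    lo[axis], mid[axis], hi[axis] = slice(0, -2), slice(1, -1), slice(2, None)
    d2[tuple(mid)] = (u[tuple(hi)] - 2.0 * u[tuple(mid)] + u[tuple(lo)]) / h**2
    return d2


def _laplacian(u: np.ndarray, voxel_size, kind: str) -> np.ndarray:
    """Discrete Laplacian of one complex component.

    ``modified_wavenumber`` inverts the stencil's plane-wave symbol axis by
    axis: from m = -D2 u / u the local complex wavenumber is
    kappa = (2/h) asin(h sqrt(m) / 2) and the contribution -kappa^2 u is
    the exact second derivative of that plane wave. Voxels where u ~ 0 or
    the estimate is not finite fall back to the central value.
    """
    lap = np.zeros_like(u)
    if kind == "central":
        for a in range(3):
            lap += _second_difference(u, a, voxel_size[a])
        return lap

    tiny = np.abs(u).max() * 1e-300 if np.abs(u).max() > 0 else 1.0
    usable = np.abs(u) > tiny
    for a in range(3):
        h = voxel_size[a]
        d2 = _second_difference(u, a, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(usable, -d2 / np.where(usable, u, 1.0), 0.0)
            kappa = (2.0 / h) * np.arcsin((h / 2.0) * np.sqrt(m.astype(complex)))
            corrected = -(kappa**2) * u
        good = usable & np.isfinite(corrected)
        lap += np.where(good, corrected, d2)
    return lap


def ahi_invert(
    field: DisplacementField, cfg: InversionConfig, mask: np.ndarray
) -> ElastogramMaps:
    """Invert a displacement field to G', G'', |G*| maps.

    Validity: voxels survive only inside the mask eroded by
    ``edge_margin`` (stencil support), with a curvature denominator above
    ``denom_floor_rel`` times the interior maximum, and with finite maps.
    The recovered modulus is invariant under rescaling of the field.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid_shape:
        raise ValueError("mask shape must match the field grid")
    structure = generate_binary_structure(3, 1)
    interior = binary_erosion(mask, structure=structure, iterations=cfg.edge_margin)
    if not interior.any():
        raise ValueError("mask interior is empty after edge_margin erosion")

    if cfg.smoothing_sd > 0:
        field = smooth_field(field, cfg.smoothing_sd)

    num = np.zeros(field.grid_shape, dtype=complex)
    den = np.zeros(field.grid_shape, dtype=float)
    for j in range(3):
        u_j = field.amplitude[..., j]
        lap_j = _laplacian(u_j, field.voxel_size, cfg.laplacian)
        num += np.conj(lap_j) * u_j
        den += np.abs(lap_j) ** 2

    den_max = den[interior].max()
    if den_max == 0.0:
        raise FlatFieldError(
            "no voxel carries displacement curvature (flat field); nothing to invert"
        )
    floor = cfg.denom_floor_rel * den_max

    omega = 2.0 * np.pi * cfg.frequency
    valid = interior & (den > floor)
    g = np.full(field.grid_shape, np.nan + 0j)
    g[valid] = -cfg.density * omega**2 * num[valid] / den[valid]
    valid &= np.isfinite(g.real) & np.isfinite(g.imag)
    if not valid.any():
        raise FlatFieldError("all voxels invalid after inversion (flat field)")

    storage = np.where(valid, g.real, np.nan)
    loss = np.where(valid, g.imag, np.nan)
    stiffness = np.where(valid, np.hypot(storage, loss), np.nan)
    return ElastogramMaps(storage=storage, loss=loss, stiffness=stiffness, valid=valid)


def negative_loss_fraction(maps: ElastogramMaps) -> float:
    """QC metric: fraction of valid voxels with recovered G'' < 0."""
    v = maps.valid
    return float(np.count_nonzero(maps.loss[v] < 0) / np.count_nonzero(v))


def roi_statistics(
    maps: ElastogramMaps, masks: Mapping[str, np.ndarray]
) -> RoiReport:
    """Mean and sample SD of the three maps over valid & mask, per ROI.

    ROIs whose intersection with the valid map is empty are reported
    absent with a warning rather than as zero-count rows.
    """
    report = RoiReport()
    for name, roi in masks.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != maps.valid.shape:
            raise ValueError(f"ROI {name!r} shape mismatch")
        sel = roi & maps.valid
        n = int(np.count_nonzero(sel))
        if n == 0:
            warnings.warn(f"ROI {name!r} has no valid voxels; omitted", stacklevel=2)
            continue

        def _stats(vol: np.ndarray) -> tuple[float, float]:
            vals = vol[sel]
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            return float(np.mean(vals)), sd

        ms, ss = _stats(maps.storage)
        ml, sl = _stats(maps.loss)
        mg, sg = _stats(maps.stiffness)
        report.rois.append(
            RoiStats(name, n, ms, ss, ml, sl, mg, sg)
        )
    return report
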