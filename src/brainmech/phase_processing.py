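"""Wrapped phase -> complex harmonic displacement reconstruction.

Order of operations (pinned by tests): polarity differencing cancels the
static background phase, each differenced offset volume is spatially
unwrapped slice-by-slice, the fundamental temporal harmonic is extracted
across offsets, and the result is scaled to meters by the encoding
sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_2d

from ._util import TWO_PI, wrap_phase
from .synthetic_data import (
    AXES,
    DisplacementField,
    MegSpec,
    WaveAcquisition,
    parse_direction,
)


@dataclass
class ComplexPhaseField:
    """Complex fundamental-harmonic phase per encoding axis, radians.

    ``value`` has shape grid_shape + (3,), ordered (x, y, z); axes that were
    not encoded are zero.
    """

    value: np.ndarray
    frequency: float
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=complex)
        if self.value.ndim != 4 or self.value.shape[-1] != 3:
            raise ValueError("value must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("complex phase must be finite")


def polarity_difference(acq: WaveAcquisition) -> dict[str, list[np.ndarray]]:
    """Half-difference of +/- encoded phase per axis and offset.

    Returns wrap((phi_plus - phi_minus) / 2) for each encoded axis; any
    static background phase common to both polarities cancels exactly while
    the motion-encoded amplitude is preserved.
    """
    n_off = acq.meg.n_phase_offsets
    axes_present: dict[str, set[int]] = {}
    for (d, _t) in acq.phase:
        axis, sign = parse_direction(d)
        axes_present.setdefault(AXES[axis], set()).add(sign)

    out: dict[str, list[np.ndarray]] = {}
    for axis_name, signs in sorted(axes_present.items()):
        if signs != {1, -1}:
            raise ValueError(f"axis {axis_name!r} is missing its polarity partner")
        vols = []
        for t in range(n_off):
            plus = acq.phase[(axis_name + "+", t)]
            minus = acq.phase[(axis_name + "-", t)]
            vols.append(wrap_phase((plus - minus) / 2.0))
        out[axis_name] = vols
    return out


def unwrap_phase(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Spatially unwrap a wrapped phase volume inside ``mask``.

    Each slice (last axis) is unwrapped in 2D by reliability sorting;
    slices are then stitched by the median inter-slice offset and the
    global 2*pi multiple is normalized to the mask median. The output is
    congruent to the input modulo 2*pi at every masked voxel; outside the
    mask the input is returned untouched.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape or volume.ndim != 3:
        raise ValueError("volume and mask must be matching 3D arrays")
    if not mask.any():
        raise ValueError("mask is empty")
    if not np.all(np.isfinite(volume[mask])):
        raise ValueError("phase not finite inside mask")

    out = volume.copy()
    for s in range(volume.shape[2]):
        msk = mask[:, :, s]
        if not msk.any():
            continue
        if msk.all():
            out[:, :, s] = np.asarray(_unwrap_2d(volume[:, :, s]))
        else:
            ma = np.ma.array(volume[:, :, s], mask=~msk)
            un = _unwrap_2d(ma)
            out[:, :, s][msk] = np.asarray(un)[msk]

    # stitch successive slices: 2D unwrapping leaves one free 2pi multiple
    # per slice, estimated from the median inter-slice step
    prev = None
    for s in range(volume.shape[2]):
        msk = mask[:, :, s]
        if not msk.any():
            continue
        if prev is not None:
            both = mask[:, :, prev] & msk
            if both.any():
                step = np.median(out[:, :, s][both] - out[:, :, prev][both])
                out[:, :, s][msk] -= TWO_PI * np.round(step / TWO_PI)
        prev = s

    # normalize the remaining global constant to the mask-median multiple
    # (outer round: the median of an even count of integers can be x.5)
    shift = np.round(np.median(np.round((out[mask] - volume[mask]) / TWO_PI)))
    out[mask] -= TWO_PI * shift
    return out


def extract_harmonic(offset_volumes: Sequence[np.ndarray]) -> np.ndarray:
    """Fundamental temporal harmonic (2/N) sum_t phi_t exp(-2 pi i t / N).

    The DC (static) component is rejected by construction; for a pure
    sampled sinusoid phi_t = Re[c exp(-2 pi i t/N)] the result has the
    amplitude |c| (it equals conj(c) under this sign convention).
    """
    n = len(offset_volumes)
    if n < 3:
        raise ValueError("need >= 3 uniformly spaced phase offsets")
    vols = [np.asarray(v, dtype=float) for v in offset_volumes]
    acc = np.zeros(vols[0].shape, dtype=complex)
    for t, v in enumerate(vols):
        acc += v * np.exp(-2j * np.pi * t / n)
    return (2.0 / n) * acc


def harmonic_residual(offset_volumes: Sequence[np.ndarray]) -> np.ndarray:
    """RMS misfit of the DC + fundamental model across offsets.

    Large values flag content outside the fundamental (e.g. an aliased
    second harmonic at N = 4, which the fundamental cannot represent).
    """
    n = len(offset_volumes)
    harm = extract_harmonic(offset_volumes)
    vols = [np.asarray(v, dtype=float) for v in offset_volumes]
    dc = np.mean(vols, axis=0)
    sq = np.zeros(vols[0].shape)
    for t, v in enumerate(vols):
        model = dc + np.real(np.conj(harm) * np.exp(-2j * np.pi * t / n))
        sq += (v - model) ** 2
    return np.sqrt(sq / n)


def decode_displacement(cphase: ComplexPhaseField, meg: MegSpec) -> DisplacementField:
    """Scale the complex harmonic phase to displacement in meters.

    The harmonic extractor's exp(-2 pi i t/N) kernel applied to the encoded
    cosine yields xi * conj(u), so the conjugate is taken here; this makes
    the encode -> reconstruct round trip the identity and preserves the
    sign of the loss modulus downstream.
    """
    u = np.conj(cphase.value) / meg.encoding_sensitivity
    return DisplacementField(u, cphase.frequency, cphase.voxel_size)


def reconstruct_displacement(
    acq: WaveAcquisition, mask: np.ndarray | None = None
) -> DisplacementField:
    """Full reconstruction: polarity diff -> unwrap -> harmonic -> meters."""
    if mask is None:
        mask = np.ones(acq.grid_shape, dtype=bool)
    per_axis = polarity_difference(acq)
    value = np.zeros(acq.grid_shape + (3,), dtype=complex)
    for axis_name, vols in per_axis.items():
        unwrapped = [unwrap_phase(v, mask) for v in vols]
        value[..., AXES.index(axis_name)] = extract_harmonic(unwrapped)
    cphase = ComplexPhaseField(value, acq.frequency, acq.voxel_size)
    return decode_displacement(cphase, acq.meg)
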