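"""Synthetic data generators with known ground truth.

Two families of generators are provided:

* MRE: steady-state plane shear waves in a labeled viscoelastic phantom,
  encoded into wrapped phase volumes the way a motion-encoding gradient
  (MEG) sequence would record them (4 phase offsets, +/- encoding polarity
  per axis).
* AFM: spherical-indenter force curves obeying the Hertz contact law with
  cantilever compliance, drawn either singly or as seeded cell populations.

Everything is deterministic under an explicit integer seed; there is no
module-level random state.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from ._util import as_unit_vector, check_orthogonal, wrap_phase

AXES = ("x", "y", "z")
#: canonical encoding-direction order: +/- pairs along x, y, z
DEFAULT_DIRECTIONS = ("x+", "x-", "y+", "y-", "z+", "z-")


def parse_direction(direction: str) -> tuple[int, int]:
    """Split a direction token like ``"x+"`` into (axis_index, sign)."""
    if len(direction) != 2 or direction[0] not in AXES or direction[1] not in "+-":
        raise ValueError(f"bad direction token {direction!r}; expected e.g. 'x+'")
    return AXES.index(direction[0]), 1 if direction[1] == "+" else -1


# ---------------------------------------------------------------------------
# MRE phantom and wave field
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Ground-truth viscoelastic phantom geometry for wave simulation.

    ``region_moduli`` maps integer labels of ``region_labels`` to complex
    shear moduli G* = G' + iG'' in Pa. Label 0 is background (no tissue,
    zero displacement). The first Lame constant is deliberately absent:
    the medium is treated as incompressible and the simulated fields are
    divergence-free by construction (transverse polarization).
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # meters
    region_labels: np.ndarray
    region_moduli: Mapping[int, complex]
    density: float = 1000.0  # kg/m^3
    frequency: float = 1000.0  # Hz
    wave_amplitude: float = 5e-6  # meters
    propagation_direction: np.ndarray = (1.0, 0.0, 0.0)
    polarization: np.ndarray = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        self.voxel_size = tuple(float(h) for h in self.voxel_size)
        if len(self.voxel_size) != 3 or any(h <= 0 for h in self.voxel_size):
            raise ValueError("voxel sizes must all be > 0")
        self.region_labels = np.asarray(self.region_labels)
        if self.region_labels.shape != self.grid_shape:
            raise ValueError("region_labels shape must match grid_shape")
        if not np.issubdtype(self.region_labels.dtype, np.integer):
            raise ValueError("region_labels must be an integer volume")
        self.region_moduli = {int(k): complex(v) for k, v in self.region_moduli.items()}
        for label, g in self.region_moduli.items():
            if g.real <= 0:
                raise ValueError(f"region {label}: storage modulus G' must be > 0")
            if g.imag < 0:
                raise ValueError(f"region {label}: loss modulus G'' must be >= 0")
        present = set(np.unique(self.region_labels)) - {0}
        missing = present - set(self.region_moduli)
        if missing:
            raise ValueError(f"labels without moduli: {sorted(missing)}")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        self.propagation_direction = as_unit_vector(
            self.propagation_direction, "propagation_direction"
        )
        self.polarization = as_unit_vector(self.polarization, "polarization")
        check_orthogonal(self.propagation_direction, self.polarization)

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass
class MegSpec:
    """Lumped motion-encoding-gradient description.

    The full gradient-waveform integral is collapsed into a single
    sensitivity ``encoding_sensitivity`` (radians of image phase per meter
    of displacement amplitude). The default 1e5 rad/m keeps a 5 um wave
    within +/- pi before background phase is added.
    """

    encoding_sensitivity: float = 1e5  # rad per meter
    n_phase_offsets: int = 4
    directions: Sequence[str] = DEFAULT_DIRECTIONS
    background_phase: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.encoding_sensitivity <= 0:
            raise ValueError("encoding_sensitivity must be > 0")
        if self.n_phase_offsets < 3:
            raise ValueError("need >= 3 phase offsets to resolve the first harmonic")
        self.directions = tuple(self.directions)
        seen: dict[int, set[int]] = {}
        for d in self.directions:
            axis, sign = parse_direction(d)
            seen.setdefault(axis, set()).add(sign)
        for axis, signs in seen.items():
            if signs != {1, -1}:
                raise ValueError(
                    f"axis {AXES[axis]!r} encoded without its +/- partner"
                )

    @property
    def encoded_axes(self) -> tuple[int, ...]:
        return tuple(sorted({parse_direction(d)[0] for d in self.directions}))


@dataclass
class DisplacementField:
    """Complex harmonic displacement amplitude u(r), meters.

    ``amplitude`` has shape grid_shape + (3,); the physical displacement at
    phase-offset time t is Re[u * exp(-2*pi*i*t/N)].
    """

    amplitude: np.ndarray
    frequency: float
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 4 or self.amplitude.shape[-1] != 3:
            raise ValueError("amplitude must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("displacement amplitude must be finite everywhere")
        self.voxel_size = tuple(float(h) for h in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.amplitude.shape[:3]

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass
class WaveAcquisition:
    """Wrapped phase volumes per (direction, offset) plus magnitude and masks."""

    phase: dict[tuple[str, int], np.ndarray]
    magnitude: np.ndarray
    masks: dict[str, np.ndarray]
    meg: MegSpec
    frequency: float
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = self.magnitude.shape
        for key, vol in self.phase.items():
            if vol.shape != shape:
                raise ValueError(f"phase volume {key} shape mismatch")
            if vol.max(initial=-np.inf) > np.pi or vol.min(initial=np.inf) <= -np.pi:
                raise ValueError(f"phase volume {key} not wrapped to (-pi, pi]")
        for name, m in self.masks.items():
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape mismatch")
        self.voxel_size = tuple(float(h) for h in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape


def shear_wavenumber(modulus: complex, density: float, frequency: float) -> complex:
    """Complex shear wavenumber k = omega * sqrt(rho / G*).

    The principal square root is taken, giving Re(k) > 0 and Im(k) <= 0 for
    any passive medium (G'' >= 0). With the e^{-ik(n.r)} spatial convention
    used by :func:`simulate_wave_field` this makes amplitude decay along
    propagation while the field stays an exact solution of
    G* Lap(u) = -rho omega^2 u.
    """
    k = 2.0 * np.pi * frequency * np.sqrt(complex(density) / complex(modulus))
    assert k.real > 0 and k.imag <= 0
    return k


def simulate_wave_field(spec: PhantomSpec) -> DisplacementField:
    """Steady-state plane shear wave u(r) = A * p * exp(-i k n.r) per region.

    Each voxel uses the wavenumber of its own region, so the field is an
    exact plane-wave solution of G* Lap(u) = -rho omega^2 u at every voxel
    whose stencil neighbours share its label; voxels straddling a region
    boundary are only approximate and are excluded by the inversion's edge
    margin. Background (label 0) voxels carry zero displacement.
    """
    n = spec.propagation_direction
    p = spec.polarization
    idx = np.indices(spec.grid_shape, dtype=float)
    s = sum(idx[a] * spec.voxel_size[a] * n[a] for a in range(3))

    kmap = np.zeros(spec.grid_shape, dtype=complex)
    support = spec.region_labels != 0
    for label, g in spec.region_moduli.items():
        sel = spec.region_labels == label
        if sel.any():
            kmap[sel] = shear_wavenumber(g, spec.density, spec.frequency)

    scalar = np.zeros(spec.grid_shape, dtype=complex)
    scalar[support] = spec.wave_amplitude * np.exp(-1j * kmap[support] * s[support])
    amplitude = scalar[..., None] * p
    return DisplacementField(amplitude, spec.frequency, spec.voxel_size)


def encode_acquisition(
    field: DisplacementField,
    meg: MegSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    magnitude: np.ndarray | None = None,
    masks: Mapping[str, np.ndarray] | None = None,
) -> WaveAcquisition:
    """Encode a displacement field into wrapped MEG phase volumes.

    phase[d, t] = wrap(sign_d * xi * Re[u_axis * exp(-2 pi i t / N)]
                       + background + noise)

    With ``noise_sd`` = 0 and xi*|u| < pi the encoding is inverted exactly
    by the reconstruction stage. Noise is additive Gaussian on phase, the
    small-noise limit of complex MR signal noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    xi = meg.encoding_sensitivity
    n_off = meg.n_phase_offsets
    bg = meg.background_phase

    phase: dict[tuple[str, int], np.ndarray] = {}
    for d in meg.directions:
        axis, sign = parse_direction(d)
        u_d = field.amplitude[..., axis]
        for t in range(n_off):
            carrier = np.exp(-2j * np.pi * t / n_off)
            phi = sign * xi * np.real(u_d * carrier) + bg
            if noise_sd > 0:
                phi = phi + rng.normal(0.0, noise_sd, size=u_d.shape)
            phase[(d, t)] = wrap_phase(phi)

    speed = np.abs(field.amplitude).max()
    if magnitude is None:
        if speed > 0:
            magnitude = 1.0 + np.linalg.norm(field.amplitude, axis=-1) / speed
        else:
            magnitude = np.ones(field.grid_shape)
    if masks is None:
        support = np.linalg.norm(field.amplitude, axis=-1) > 0
        masks = {"support": support if support.any() else np.ones(field.grid_shape, bool)}
    return WaveAcquisition(
        phase=phase,
        magnitude=np.asarray(magnitude, dtype=float),
        masks={k: np.asarray(v, dtype=bool) for k, v in masks.items()},
        meg=meg,
        frequency=field.frequency,
        voxel_size=field.voxel_size,
    )


def simulate_mre_acquisition(
    spec: PhantomSpec,
    meg: MegSpec,
    noise_sd: float = 0.0,
    masks: Mapping[str, np.ndarray] | None = None,
) -> tuple[WaveAcquisition, DisplacementField]:
    """Simulate and encode in one step; magnitude gets region contrast.

    Returns the acquisition together with the ground-truth field (the
    oracle downstream tests reconstruct against).
    """
    from scipy.ndimage import gaussian_filter

    field = simulate_wave_field(spec)
    contrast = gaussian_filter((spec.region_labels > 0).astype(float), 1.0)
    magnitude = 0.2 + contrast + 0.1 * spec.region_labels
    if masks is None:
        masks = {"support": spec.region_labels != 0}
    acq = encode_acquisition(
        field, meg, noise_sd=noise_sd, seed=spec.seed, magnitude=magnitude, masks=masks
    )
    return acq, field


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeSpec:
    """Spherical colloidal probe and cantilever calibration."""

    radius: float = 6e-6  # meters
    spring_constant: float = 0.1  # N/m
    deflection_sensitivity: float | None = 33e-9  # meters per volt; None if uncalibrated
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.spring_constant <= 0:
            raise ValueError("probe radius and spring constant must be positive")
        if self.deflection_sensitivity is not None and self.deflection_sensitivity <= 0:
            raise ValueError("deflection_sensitivity must be positive when given")
        if not 0.0 < self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5]")


@dataclass
class ForceCurve:
    """Piezo extension vs. cantilever deflection samples for one indentation."""

    z: np.ndarray  # meters, strictly monotone
    deflection: np.ndarray  # meters or volts, per deflection_unit
    probe: ProbeSpec
    deflection_unit: str = "m"  # "m" or "V"
    true_E: float | None = None  # Pa, synthetic ground truth
    true_contact: float | None = None  # meters

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.shape != self.deflection.shape or self.z.ndim != 1:
            raise ValueError("z and deflection must be equal-length 1D arrays")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if not np.all(np.isfinite(self.deflection)):
            raise ValueError("deflection must be finite")
        if self.deflection_unit not in ("m", "V"):
            raise ValueError("deflection_unit must be 'm' or 'V'")


def hertz_force(E: float, delta, radius: float, poisson_ratio: float = 0.5):
    """Spherical Hertz contact force F = (4/3) E/(1-nu^2) sqrt(R) delta^{3/2}."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * E / (1.0 - poisson_ratio**2) * np.sqrt(radius) * delta**1.5


def generate_force_curve(
    E_true: float,
    probe: ProbeSpec,
    contact_z: float = 0.5e-6,
    ramp_size: float = 1.5e-6,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ForceCurve:
    """Synthesize a force curve from the compliance-coupled Hertz law.

    Past contact, the measured deflection d solves the coupled system

        F = k d,   delta = (z - contact_z) - d,   F = Hertz(E, delta)

    (unique positive root; solved by bracketed root finding to ~1e-12
    relative). Before contact the deflection is pure baseline noise.
    """
    if E_true <= 0:
        raise ValueError("E_true must be > 0")
    if n_points < 20:
        raise ValueError("need n_points >= 20")
    if ramp_size <= contact_z:
        raise ValueError("ramp must extend past the contact point")

    z = np.linspace(0.0, ramp_size, n_points)
    d = np.zeros(n_points)
    k = probe.spring_constant
    coef = (4.0 / 3.0) * E_true / (1.0 - probe.poisson_ratio**2) * np.sqrt(probe.radius)

    post = z > contact_z
    for i in np.nonzero(post)[0]:
        travel = z[i] - contact_z

        def balance(di: float, travel: float = travel) -> float:
            return k * di - coef * (travel - di) ** 1.5

        d[i] = brentq(balance, 0.0, travel, xtol=1e-22, rtol=8.9e-16)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, size=n_points)

    return ForceCurve(
        z=z,
        deflection=d,
        probe=probe,
        deflection_unit="m",
        true_E=float(E_true),
        true_contact=float(contact_z),
    )


def generate_cell_population(
    mean_E: float,
    sd_E: float,
    n_cells: int,
    probe: ProbeSpec,
    seed: int = 0,
    contact_z: float = 0.5e-6,
    ramp_size: float = 1.5e-6,
    n_points: int = 200,
    noise_sd: float = 0.0,
) -> list[ForceCurve]:
    """Draw ``n_cells`` moduli from N(mean_E, sd_E) truncated at E > 0.

    Truncation is by rejection (redraw), which is exact and keeps the
    sampler reproducible under the seed. Each curve receives its own
    sub-seed for deflection noise.
    """
    if mean_E <= 0:
        raise ValueError("mean_E must be > 0")
    if sd_E < 0:
        raise ValueError("sd_E must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    rng = np.random.default_rng(seed)
    moduli = np.empty(n_cells)
    for i in range(n_cells):
        if sd_E == 0:
            moduli[i] = mean_E
            continue
        e = rng.normal(mean_E, sd_E)
        while e <= 0:
            e = rng.normal(mean_E, sd_E)
        moduli[i] = e

    curve_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    return [
        generate_force_curve(
            float(moduli[i]),
            probe,
            contact_z=contact_z,
            ramp_size=ramp_size,
            n_points=n_points,
            noise_sd=noise_sd,
            seed=int(curve_seeds[i]),
        )
        for i in range(n_cells)
    ]
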