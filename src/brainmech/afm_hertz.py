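"""Hertz spherical-contact analysis of AFM force curves.

The estimator chain is: convert photodetector volts to meters if needed,
locate the contact point by two-regime (baseline + Hertz rise) residual
minimization, then fit Young's modulus by linear regression of force on
indentation^{3/2} — the linearized closed form, no iterative optimizer.
Indentation is compliance-corrected: delta = (z - z0) - deflection.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .synthetic_data import ForceCurve, ProbeSpec, hertz_force

_MIN_BASELINE = 10  # samples required before contact
_MIN_FIT_POINTS = 5


@dataclass
class ContactPoint:
    z0: float  # meters
    baseline: float  # deflection offset, meters
    converged: bool


@dataclass
class HertzFitResult:
    youngs_modulus: float  # Pa
    contact_point: float  # meters
    rms_residual: float  # N
    n_fit_points: int
    converged: bool


@dataclass
class GroupSummary:
    name: str
    n_total: int
    n_converged: int
    mean: float  # Pa
    sd: float  # Pa, sample SD (n-1)
    sem: float | None  # Pa; None when n_converged < 2


@dataclass
class GroupComparison:
    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    percent_difference: float  # (mean_b - mean_a) / mean_a * 100


def curve_to_physical(curve: ForceCurve) -> ForceCurve:
    """Convert a volts-deflection curve to meters via the probe sensitivity."""
    if curve.deflection_unit == "m":
        return curve
    if curve.probe.deflection_sensitivity is None:
        raise ValueError("deflection in volts but no deflection sensitivity given")
    return replace(
        curve,
        deflection=curve.deflection * curve.probe.deflection_sensitivity,
        deflection_unit="m",
    )


def force(curve: ForceCurve) -> np.ndarray:
    """Cantilever force F = k * deflection, newtons."""
    curve = curve_to_physical(curve)
    return curve.probe.spring_constant * curve.deflection


def _hertz_coefficient_fit(
    z: np.ndarray, d: np.ndarray, z0: float, baseline: float, probe: ProbeSpec
) -> tuple[float, float, int]:
    """Origin regression of F on delta^{3/2} past z0.

    Returns (coefficient, sum squared residual in N^2, n points). Points
    whose compliance-corrected indentation is nonpositive are skipped.
    """
    k = probe.spring_constant
    post = z > z0
    dd = d[post] - baseline
    delta = (z[post] - z0) - dd
    keep = delta > 0
    dd, delta = dd[keep], delta[keep]
    f = k * dd
    x = delta**1.5
    sxx = float(np.dot(x, x))
    if sxx == 0.0 or len(x) == 0:
        return 0.0, float(np.dot(f, f)), int(len(x))
    c = float(np.dot(x, f) / sxx)
    resid = f - c * x
    return c, float(np.dot(resid, resid)), int(len(x))


def _split_residual(
    z: np.ndarray, d: np.ndarray, z0: float, baseline: float, probe: ProbeSpec
) -> float:
    """Total squared force residual of the baseline + Hertz two-regime model."""
    k = probe.spring_constant
    pre = z <= z0
    res_pre = float(np.sum((k * (d[pre] - baseline)) ** 2))
    c, res_post, _n = _hertz_coefficient_fit(z, d, z0, baseline, probe)
    if c < 0:  # an unphysical pull-in branch must not look like a good fit
        res_post = float(np.sum((k * (d[~pre] - baseline)) ** 2))
    return res_pre + res_post


def detect_contact_point(curve: ForceCurve) -> ContactPoint:
    """Locate the piezo position where the probe first touches the sample.

    A coarse grid over candidate split samples is followed by continuous
    refinement of z0 between the neighbouring samples, so noiseless
    synthetic curves recover the true contact essentially exactly. Curves
    with no detectable rise return a non-converged result, not an error.
    """
    curve = curve_to_physical(curve)
    z, d = curve.z, curve.deflection
    if z[0] > z[-1]:  # retract ordering; analyze in extension order
        z, d = z[::-1].copy(), d[::-1].copy()
    n = len(z)
    if n < _MIN_BASELINE + _MIN_FIT_POINTS:
        return ContactPoint(float("nan"), float(np.mean(d)), False)

    best_i, best_res = None, np.inf
    for i in range(_MIN_BASELINE, n - _MIN_FIT_POINTS):
        baseline = float(np.mean(d[:i]))
        res = _split_residual(z, d, float(z[i]), baseline, curve.probe)
        if res < best_res:
            best_i, best_res = i, res

    baseline = float(np.mean(d[:best_i]))
    c, _res, n_fit = _hertz_coefficient_fit(
        z, d, float(z[best_i]), baseline, curve.probe
    )
    # no real contact: rise indistinguishable from the baseline scatter
    rise = float(np.max(d - baseline))
    scatter = float(np.std(d[:best_i] - baseline)) if best_i > 1 else 0.0
    if c <= 0 or n_fit < _MIN_FIT_POINTS or rise <= max(5.0 * scatter, 1e-13):
        return ContactPoint(float("nan"), baseline, False)

    lo = float(z[max(best_i - 1, 0)])
    hi = float(z[min(best_i + 1, n - 1)])
    if hi > lo:
        opt = minimize_scalar(
            lambda z0: _split_residual(z, d, z0, baseline, curve.probe),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-15},
        )
        z0 = float(opt.x)
    else:
        z0 = float(z[best_i])
    return ContactPoint(z0, baseline, True)


def fit_hertz(
    curve: ForceCurve,
    contact: float,
    baseline: float = 0.0,
    max_depth: float | None = None,
) -> HertzFitResult:
    """Closed-form Hertz fit past a known contact point.

    Regresses F = k*d on delta^{3/2} with delta = (z - contact) - d and
    converts the slope to E = (3/4) * c * (1 - nu^2) / sqrt(R). All
    post-contact points are used unless ``max_depth`` caps the indentation.
    """
    curve = curve_to_physical(curve)
    z, d = curve.z, curve.deflection
    if z[0] > z[-1]:
        z, d = z[::-1].copy(), d[::-1].copy()
    probe = curve.probe

    post = z > contact
    dd = d[post] - baseline
    delta = (z[post] - contact) - dd
    keep = delta > 0
    if max_depth is not None:
        keep &= delta <= max_depth
    dd, delta = dd[keep], delta[keep]
    n_fit = int(len(dd))
    if n_fit < _MIN_FIT_POINTS:
        return HertzFitResult(float("nan"), contact, float("nan"), n_fit, False)

    f = probe.spring_constant * dd
    x = delta**1.5
    c = float(np.dot(x, f) / np.dot(x, x))
    e = 0.75 * c * (1.0 - probe.poisson_ratio**2) / np.sqrt(probe.radius)
    resid = f - c * x
    rms = float(np.sqrt(np.mean(resid**2)))
    if e <= 0 or not np.isfinite(e):
        return HertzFitResult(e, contact, rms, n_fit, False)
    return HertzFitResult(e, contact, rms, n_fit, True)


def fit_curve(
    curve: ForceCurve,
    max_depth: float | None = None,
    detection_smooth_window: int | None = None,
) -> HertzFitResult:
    """Contact detection followed by the Hertz fit; never raises on bad data.

    ``detection_smooth_window`` (odd sample count) applies a quadratic
    Savitzky-Golay filter to the deflection for contact detection only; the
    modulus is always fitted on the raw samples.
    """
    detect_on = curve_to_physical(curve)
    if detection_smooth_window is not None:
        from scipy.signal import savgol_filter

        smoothed = savgol_filter(detect_on.deflection, detection_smooth_window, 2)
        detect_on = replace(detect_on, deflection=smoothed)
    cp = detect_contact_point(detect_on)
    if not cp.converged:
        return HertzFitResult(float("nan"), cp.z0, float("nan"), 0, False)
    return fit_hertz(curve, cp.z0, baseline=cp.baseline, max_depth=max_depth)


def analyze_group(
    results: Sequence[HertzFitResult], name: str = "group"
) -> GroupSummary:
    """Mean / SD / SEM over converged fits; non-converged fits are excluded."""
    e = np.array([r.youngs_modulus for r in results if r.converged])
    if e.size == 0:
        raise ValueError("no converged fits in group")
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    sem = float(sd / np.sqrt(e.size)) if e.size > 1 else None
    return GroupSummary(
        name=name,
        n_total=len(results),
        n_converged=int(e.size),
        mean=float(np.mean(e)),
        sd=sd,
        sem=sem,
    )


def _moduli(group) -> np.ndarray:
    vals = []
    for item in group:
        if isinstance(item, HertzFitResult):
            if item.converged:
                vals.append(item.youngs_modulus)
        else:
            vals.append(float(item))
    return np.asarray(vals, dtype=float)


def compare_groups(
    a, b, name_a: str = "a", name_b: str = "b"
) -> GroupComparison:
    """Welch two-sample unequal-variance t-test on per-cell moduli.

    Accepts raw modulus sequences or HertzFitResult lists (converged fits
    only). Degenerate zero-variance inputs follow the conventions: equal
    means -> p = 1, unequal means -> p = 0 (flagged by an infinite t).
    """
    ea, eb = _moduli(a), _moduli(b)
    if len(ea) < 2 or len(eb) < 2:
        raise ValueError("need n >= 2 converged values per group")

    def summarize(e: np.ndarray, name: str) -> GroupSummary:
        sd = float(np.std(e, ddof=1))
        return GroupSummary(name, len(e), len(e), float(np.mean(e)), sd, sd / np.sqrt(len(e)))

    sa, sb = summarize(ea, name_a), summarize(eb, name_b)
    if sa.sd == 0.0 and sb.sd == 0.0:
        if sa.mean == sb.mean:
            t, df, p = 0.0, float(len(ea) + len(eb) - 2), 1.0
        else:
            t, df, p = float("inf"), float(len(ea) + len(eb) - 2), 0.0
    else:
        res = stats.ttest_ind(ea, eb, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    pct = (sb.mean - sa.mean) / sa.mean * 100.0
    return GroupComparison(sa, sb, t, df, p, pct)
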