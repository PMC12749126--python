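"""Small shared numeric helpers."""
from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap angles to the half-open interval (-pi, pi].

    Uses the ceil form so that +pi maps to +pi (not -pi).
    """
    phi = np.asarray(phi, dtype=float)
    return phi - TWO_PI * np.ceil((phi - np.pi) / TWO_PI)


def as_unit_vector(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or norm == 0.0:
        raise ValueError(f"{name} must be a nonzero finite 3-vector")
    return v / norm


def check_orthogonal(a: np.ndarray, b: np.ndarray, tol: float = 1e-12) -> None:
    if abs(float(np.dot(a, b))) >= tol:
        raise ValueError(
            f"vectors not orthogonal: |a.b| = {abs(float(np.dot(a, b))):.3e} >= {tol:g}"
        )
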