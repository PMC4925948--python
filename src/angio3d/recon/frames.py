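"""Discrete Frenet frames, curvature and torsion along a 3D polyline."""

from __future__ import annotations

import numpy as np

#: below this curvature the Frenet normal is ill-defined; fall back to transport
STRAIGHT_KAPPA = 1e-8


def _diff(a: np.ndarray) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    return np.gradient(a, axis=0)


def frenet_frames(centerline3d: np.ndarray):
    """Per-point (T, N, B) frames plus curvature kappa and torsion tau.

    Derivatives use central differences at interior points and
    forward/backward differences at the ends.  Where the curve is locally
    straight (kappa below :data:`STRAIGHT_KAPPA`) the normal is parallel
    transported from the previous point instead of using the undefined
    Frenet normal, avoiding frame flips.

    Returns
    -------
    T, N, B : (n, 3) arrays, right-handed orthonormal triads
    kappa, tau : (n,) arrays
    """
    X = np.asarray(centerline3d, dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 centreline points")
    if np.any(np.linalg.norm(np.diff(X, axis=0), axis=1) == 0):
        raise ValueError("repeated consecutive points")

    d1 = _diff(X)
    d2 = _diff(d1)
    d3 = _diff(d2)
    speed = np.linalg.norm(d1, axis=1)
    T = d1 / speed[:, None]

    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    kappa = cross_norm / speed**3
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.einsum("ij,ij->i", cross, d3) / cross_norm**2
    tau[cross_norm**2 < 1e-24] = 0.0

    n = len(X)
    N = np.zeros_like(X)
    defined = kappa > STRAIGHT_KAPPA

    def _frenet_normal(i):
        ni = d2[i] - (d2[i] @ T[i]) * T[i]
        return ni / np.linalg.norm(ni)

    def _transport(prev, i):
        ni = prev - (prev @ T[i]) * T[i]
        return ni / np.linalg.norm(ni)

    if not defined.any():
        N[0] = _any_perpendicular(T[0])
        for i in range(1, n):
            N[i] = _transport(N[i - 1], i)
    else:
        i0 = int(np.argmax(defined))
        N[i0] = _frenet_normal(i0)
        for i in range(i0 - 1, -1, -1):  # transport back through a straight lead-in
            N[i] = _transport(N[i + 1], i)
        for i in range(i0 + 1, n):
            N[i] = _frenet_normal(i) if defined[i] else _transport(N[i - 1], i)
    B = np.cross(T, N)
    return T, N, B, kappa, tau


def _any_perpendicular(t: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = ref - (ref @ t) * t
    return p / np.linalg.norm(p)
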