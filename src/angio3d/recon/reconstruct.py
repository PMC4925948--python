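"""Two-view epipolar centreline reconstruction and radius estimation.

The correspondence between the two projected centrelines is built from
epipolar lines under a monotone (order-preserving) matching with bifurcation
points as hard anchors, then refined iteratively: the triangulated 3D curve is
re-projected into both views, re-matched to the observed curves by closest
approach in arc length, and re-triangulated until the update falls below a
tolerance.  This progressively removes foreshortening bias from the initial
matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..centerline import CenterlineCurve
from .geometry import ProjectionGeometry, epipolar_line, triangulate

DEFAULT_TOL_MM = 1e-3
DEFAULT_MAX_ITER = 20
#: reconstruction aborts when this fraction of points finds no epipolar match
MAX_MISS_FRACTION = 0.2


@dataclass
class VesselModel3D:
    """3D vessel: centreline samples, radii, frames, curvature/torsion, mesh."""

    centerline3d: np.ndarray                 # (n, 3) mm
    radii: np.ndarray | None = None          # (n,) mm
    T: np.ndarray | None = None
    N: np.ndarray | None = None
    B: np.ndarray | None = None
    kappa: np.ndarray | None = None
    tau: np.ndarray | None = None
    mesh: object | None = None
    residuals_mm: np.ndarray | None = None   # triangulation residual per point
    frac_a: np.ndarray | None = None         # matched fractional index on curve A
    frac_b: np.ndarray | None = None
    n_iterations: int = 0
    update_norms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centerline3d = np.asarray(self.centerline3d, dtype=float)

    @property
    def arc_length_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline3d, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_at_frac(pts: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Linear interpolation of a polyline at fractional vertex indices."""
    frac = np.clip(frac, 0, len(pts) - 1)
    i0 = np.floor(frac).astype(int)
    i0 = np.minimum(i0, len(pts) - 2)
    t = (frac - i0)[:, None]
    return (1 - t) * pts[i0] + t * pts[i0 + 1]


def _project_to_polyline(curve: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Fractional index of the closest point on ``curve`` for each query point."""
    p0 = curve[:-1]
    seg = curve[1:] - p0
    seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-30)
    diff = q[:, None, :] - p0[None, :, :]
    t = np.clip(np.einsum("qsk,sk->qs", diff, seg) / seg_len2, 0.0, 1.0)
    proj = p0[None] + t[..., None] * seg[None]
    d2 = ((q[:, None, :] - proj) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    return j + t[np.arange(len(q)), j]


def _orient_b(ptsA, ptsB, geomA, geomB):
    """Flip curve B if its endpoints disagree with A's under epipolar matching."""
    la = epipolar_line(geomA, geomB, ptsA[0])
    lb = epipolar_line(geomA, geomB, ptsA[-1])

    def dist(line, p):
        return abs(line[0] * p[0] + line[1] * p[1] + line[2])

    keep = dist(la, ptsB[0]) + dist(lb, ptsB[-1])
    flip = dist(la, ptsB[-1]) + dist(lb, ptsB[0])
    return (ptsB[::-1].copy(), True) if flip < keep else (ptsB, False)


def _anchor_pairs(curveA: CenterlineCurve, curveB: CenterlineCurve,
                  ptsB: np.ndarray, flipped: bool):
    """Bifurcation correspondences as (index on A, fractional index on B)."""
    bifA, bifB = curveA.bifurcations_on_path, curveB.bifurcations_on_path
    if not bifA or len(bifA) != len(bifB):
        return []
    fa = _project_to_polyline(curveA.points, np.asarray(bifA, dtype=float))
    bB = np.asarray(bifB, dtype=float)
    fb = _project_to_polyline(ptsB, bB[::-1] if flipped else bB)
    order = np.argsort(fa)
    fa, fb = fa[order], np.sort(fb)  # both ordered along the vessel
    return [(int(round(a)), b) for a, b in zip(fa, fb)]


def correspond_and_reconstruct(
    curveA: CenterlineCurve,
    curveB: CenterlineCurve,
    geomA: ProjectionGeometry,
    geomB: ProjectionGeometry,
    tol_mm: float = DEFAULT_TOL_MM,
    max_iter: int = DEFAULT_MAX_ITER,
    smooth_mm: float = 0.0,
) -> VesselModel3D:
    """Reconstruct the 3D centreline from its two projections.

    Returns a :class:`VesselModel3D` whose ``centerline3d`` is resampled to
    uniform arc length; ``frac_a``/``frac_b`` record for every 3D sample the
    matched fractional index on each projected centreline, which downstream
    radius estimation uses to index the wall curves.

    ``smooth_mm`` is the expected per-point noise of the triangulated curve;
    when positive, a smoothing spline at that scale regularizes the resampled
    centreline.  Off by default: the projected centrelines are already
    smoothed in 2D, and oversmoothing here flattens curvature and torsion.
    """
    ptsA = curveA.points
    ptsB, flipped = _orient_b(ptsA, curveB.points, geomA, geomB)
    nA, nB = len(ptsA), len(ptsB)
    anchors = ([(0, 0.0)]
               + _anchor_pairs(curveA, curveB, ptsB, flipped)
               + [(nA - 1, float(nB - 1))])

    # initial monotone epipolar matching, segment-wise between anchors
    frac_b = np.full(nA, np.nan)
    for (ia0, fb0), (ia1, fb1) in zip(anchors[:-1], anchors[1:]):
        if ia1 <= ia0:
            continue
        lo = fb0
        for i in range(ia0, ia1 + 1):
            a, b, c = epipolar_line(geomA, geomB, ptsA[i])
            g = a * ptsB[:, 0] + b * ptsB[:, 1] + c
            expected = fb0 + (fb1 - fb0) * (i - ia0) / (ia1 - ia0)
            cand = []
            for j in range(nB - 1):
                if g[j] == 0.0:
                    cand.append(float(j))
                elif g[j] * g[j + 1] < 0:
                    cand.append(j + g[j] / (g[j] - g[j + 1]))
            if g[-1] == 0.0:
                cand.append(float(nB - 1))
            cand = [f for f in cand if lo - 0.5 <= f <= fb1 + 0.5]
            if cand:
                best = min(cand, key=lambda f: abs(f - expected))
                frac_b[i] = best
                lo = max(lo, best)
    miss = np.isnan(frac_b)
    if miss.mean() > MAX_MISS_FRACTION:
        raise ValueError(
            f"epipolar lines miss curve B for {miss.mean():.0%} of points; "
            "check geometry or curve labelling")
    idx = np.arange(nA)
    if miss.any():
        frac_b[miss] = np.interp(idx[miss], idx[~miss], frac_b[~miss])
    frac_b = np.maximum.accumulate(frac_b)
    frac_a = idx.astype(float)

    def tri_all(pa, pb):
        out = np.empty((len(pa), 3))
        res = np.empty(len(pa))
        for i, (qa, qb) in enumerate(zip(pa, pb)):
            out[i], res[i] = triangulate(geomA, geomB, qa, qb)
        return out, res

    pA = _interp_at_frac(ptsA, frac_a)
    pB = _interp_at_frac(ptsB, frac_b)
    X, res = tri_all(pA, pB)

    updates = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        projA = geomA.project_points(X)
        projB = geomB.project_points(X)
        frac_a = np.maximum.accumulate(_project_to_polyline(ptsA, projA))
        frac_b = np.maximum.accumulate(_project_to_polyline(ptsB, projB))
        pA = _interp_at_frac(ptsA, frac_a)
        pB = _interp_at_frac(ptsB, frac_b)
        X_new, res = tri_all(pA, pB)
        change = float(np.max(np.linalg.norm(X_new - X, axis=1)))
        updates.append(change)
        X = X_new
        if change < tol_mm:
            break

    # uniform arc-length resampling, carrying the view correspondences along
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(X, axis=0), axis=1))])
    target = np.linspace(0.0, arc[-1], nA)
    if smooth_mm > 0:
        from scipy import interpolate as _interp

        tck, _ = _interp.splprep(X.T, u=arc / arc[-1], s=len(X) * smooth_mm**2, k=3)
        X_s = np.column_stack(_interp.splev(arc / arc[-1], tck))
    else:
        X_s = X
    X_u = np.column_stack([np.interp(target, arc, X_s[:, k]) for k in range(3)])
    fa_u = np.interp(target, arc, frac_a)
    fb_u = np.interp(target, arc, frac_b)
    res_u = np.interp(target, arc, res)
    if flipped:
        fb_u = (nB - 1) - fb_u
    return VesselModel3D(X_u, residuals_mm=res_u, frac_a=fa_u, frac_b=fb_u,
                         n_iterations=n_iter, update_norms=updates)


def _wall_radius_samples(X, frac, walls, geom):
    """Radius samples (n, 2) from one view's wall pair at matched fractions."""
    beam = geom._beam
    out = np.full((len(X), len(walls)), np.nan)
    for w, wall in enumerate(walls):
        wp = _interp_at_frac(np.asarray(wall.points, dtype=float), frac)
        for i in range(len(X)):
            origin, d = geom.backproject_ray(wp[i])
            denom = d @ beam
            if abs(denom) < 1e-12:
                continue
            t = ((X[i] - origin) @ beam) / denom  # depth of the centreline point
            out[i, w] = np.linalg.norm(origin + t * d - X[i])
    return out


def estimate_radii(model: VesselModel3D, wallsA, wallsB,
                   geomA: ProjectionGeometry, geomB: ProjectionGeometry,
                   smooth_window: int = 1) -> np.ndarray:
    """Per-point radius: mean distance to the back-projected wall curves.

    Every wall point is lifted to 3D at the depth of its centreline point and
    the (up to four) centreline-to-wall distances are averaged; non-positive
    or missing samples are excluded, and points with no valid sample are
    filled by linear interpolation from their neighbours.  Assumes a circular
    cross-section.

    ``smooth_window`` (odd, in samples) optionally applies a moving average
    to the radius profile, damping the node-quantization jitter of the wall
    curves; 1 disables it.
    """
    X = model.centerline3d
    samples = np.hstack([
        _wall_radius_samples(X, model.frac_a, wallsA, geomA),
        _wall_radius_samples(X, model.frac_b, wallsB, geomB),
    ])
    samples[samples <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        radii = np.nanmean(samples, axis=1)
    bad = ~np.isfinite(radii)
    if bad.all():
        raise ValueError("no valid radius samples anywhere on the vessel")
    if bad.any():
        idx = np.arange(len(radii))
        radii[bad] = np.interp(idx[bad], idx[~bad], radii[~bad])
    if smooth_window > 1:
        w = int(smooth_window) | 1  # force odd
        padded = np.pad(radii, w // 2, mode="reflect")
        radii = np.convolve(padded, np.full(w, 1.0 / w), mode="valid")
    model.radii = radii
    return radii
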