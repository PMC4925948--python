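"""Skeleton path extraction between user points and sub-pixel smoothing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import interpolate

from .enhance import SkeletonMap

SQRT2 = float(np.sqrt(2.0))

#: pixels this close to a bifurcation are dropped from the spline support
BIFURCATION_EXCLUSION_RADIUS = 2.0


@dataclass
class CenterlineCurve:
    """Ordered sub-pixel centreline with arc-length parameterization.

    ``points`` is an (N, 2) float array of (row, col) coordinates resampled at
    near-uniform arc-length steps; ``arc_length`` the cumulative length in px.
    Bifurcation coordinates encountered along the raw path are kept for the 3D
    correspondence stage.
    """

    points: np.ndarray
    arc_length: np.ndarray
    bifurcations_on_path: list[tuple[int, int]] = field(default_factory=list)
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if len(self.points) < 4:
            raise ValueError("centreline needs at least 4 points")
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length_mm(self) -> np.ndarray:
        # isotropic spacing assumed for the mm scale
        return self.arc_length * float(self.pixel_spacing_mm[0])


def snap_to_skeleton(point: tuple[float, float], skel: SkeletonMap) -> tuple[int, int]:
    """Closest skeleton pixel to ``point`` (Euclidean); ties -> smallest (row, col)."""
    coords = np.argwhere(skel.skeleton)  # argwhere is lexicographically sorted
    if coords.size == 0:
        raise ValueError("empty skeleton")
    d2 = ((coords - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    best = coords[int(np.argmin(d2))]  # argmin returns first (lexicographic) minimum
    return int(best[0]), int(best[1])


def extract_path(
    skel: SkeletonMap, start: tuple[int, int], end: tuple[int, int]
) -> np.ndarray:
    """Shortest 8-connected path along skeleton pixels from start to end.

    Diagonal steps cost sqrt(2), axial steps 1.  Returns an (N, 2) int array
    ordered start -> end.
    """
    sk = skel.skeleton
    start, end = (int(start[0]), int(start[1])), (int(end[0]), int(end[1]))
    for name, p in (("start", start), ("end", end)):
        if not sk[p]:
            raise ValueError(f"{name} point {p} is not on the skeleton")
    if start == end:
        return np.array([start])
    g = nx.Graph()
    coords = np.argwhere(sk)
    pix = {(int(r), int(c)) for r, c in coords}
    for r, c in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    g.add_edge((r, c), q, weight=SQRT2 if dr and dc else 1.0)
    try:
        path = nx.dijkstra_path(g, start, end)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise ValueError(f"no skeleton path between {start} and {end}") from exc
    return np.array(path)


def smooth_centerline(
    path: np.ndarray,
    skel: SkeletonMap,
    sample_step: float = 1.0,
    smoothing: float | None = None,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> CenterlineCurve:
    """Cubic-spline smoothing of a pixel path, excluding bifurcation pixels.

    Pixels within :data:`BIFURCATION_EXCLUSION_RADIUS` of a bifurcation point
    are dropped from the spline support (they sit off the true vessel axis at
    branchings); the bifurcation coordinates themselves are retained on the
    output for use as correspondence anchors.  The fitted curve is resampled
    at a uniform arc-length step.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 4:
        raise ValueError("path must contain at least 4 pixels")
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")

    on_path: list[tuple[int, int]] = []
    keep = np.ones(len(path), dtype=bool)
    for b in skel.bifurcation_points:
        d = np.hypot(path[:, 0] - b[0], path[:, 1] - b[1])
        near = d <= BIFURCATION_EXCLUSION_RADIUS
        if near.any():
            on_path.append((int(b[0]), int(b[1])))
            keep &= ~near
    keep[0] = keep[-1] = True  # endpoints always anchor the fit
    support = path[keep]
    if len(support) < 4:
        warnings.warn("fewer than 4 support points after bifurcation exclusion; "
                      "using the full path", stacklevel=2)
        support = path

    # chord-length parameter; heavy endpoint weights pin the curve ends
    seg = np.linalg.norm(np.diff(support, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    w = np.ones(len(support))
    w[0] = w[-1] = 1e3
    if smoothing is None:
        smoothing = 0.5 * len(support)  # light smoothing of pixel jitter
    k = min(3, len(support) - 1)
    tck, _ = interpolate.splprep(support.T, u=u, w=w, s=smoothing, k=k)

    # resample at uniform arc length
    dense_u = np.linspace(0.0, 1.0, max(20 * len(support), 400))
    dense = np.column_stack(interpolate.splev(dense_u, tck))
    darc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    total = darc[-1]
    n_out = max(int(round(total / sample_step)) + 1, 4)
    target = np.linspace(0.0, total, n_out)
    pts = np.column_stack([np.interp(target, darc, dense[:, i]) for i in range(2)])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return CenterlineCurve(pts, arc, on_path, pixel_spacing_mm)
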