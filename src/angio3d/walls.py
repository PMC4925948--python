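"""Vessel wall delineation by dynamic programming on centreline-normal grids.

For every centreline sample a normal is built and K candidate nodes are placed
at equal spacing on each side.  Each node carries a gradient-magnitude reward
``e_m``, raw gradient magnitude ``e_gm``, second-derivative magnitude ``e_hm``
and edge orientation ``e_gd``.  The wall is the node-per-stage path maximizing

    C = sum_i e_m(o_i)
        - beta     * sum_i | e_gm(o_i)/(e_hm(o_i)+eps) - e_gm(o_{i-1})/(e_hm(o_{i-1})+eps) |
        - (1-beta) * sum_i (e_gd(o_i) - e_gd(o_{i-1}))^2

solved exactly by the standard stage-wise recursion, with the first and last
stage fixed to the max-gradient node on their normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .centerline import CenterlineCurve
from .image import Image2D

#: nodes per side of the centreline
DEFAULT_HALF_WIDTH = 10
DEFAULT_BETA = 0.75
#: stability floor for the e_gm/(e_hm + eps) ratio.  Features are normalized
#: to [0, 1], and the second-derivative magnitude vanishes exactly at ideal
#: edges (the zero crossing coincides with the gradient peak), so a tiny eps
#: makes the ratio consistency penalty divergent precisely on good walls; a
#: floor of 0.25 on the normalized scale keeps the term bounded.
DEFAULT_EPSILON = 0.25

#: Gaussian scale (px) for the image derivative estimates
DERIVATIVE_SIGMA = 1.0


@dataclass
class DPParams:
    """Trade-off weight and numerical-stability floor for the wall objective."""

    beta: float = DEFAULT_BETA
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class NormalGrid:
    """Candidate wall nodes on one side of the centreline.

    All per-node arrays have shape (N stages, K nodes); node k sits at offset
    ``(k+1) * spacing`` px from the centreline along the stage normal.
    """

    positions: np.ndarray  # (N, K, 2) sub-pixel (row, col)
    normals: np.ndarray    # (N, 2) unit normal per stage
    e_m: np.ndarray        # node reward, normalized gradient magnitude in [0, 1]
    e_gm: np.ndarray       # gradient magnitude, scaled to [0, 1] over the grid
    e_hm: np.ndarray       # second-derivative magnitude, scaled to [0, 1]
    e_gd: np.ndarray       # edge orientation in [0, pi)
    side: str = "left"
    clamped: np.ndarray | None = None  # nodes moved back inside the image

    @property
    def n_stages(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[1]


@dataclass
class WallCurve:
    """One delineated vessel wall: a sub-pixel point per centreline index."""

    points: np.ndarray           # (N, 2) (row, col)
    side: str
    objective: float
    node_indices: np.ndarray | None = None


def _orientation_diff(a, b):
    """Difference of edge orientations (mod pi), wrapped to (-pi/2, pi/2]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.mod(d + np.pi / 2, np.pi) - np.pi / 2
    return np.where(d == -np.pi / 2, np.pi / 2, d)


def _scale01(a: np.ndarray) -> np.ndarray:
    m = a.max()
    if m < 1e-12:  # numerically flat: do not amplify noise
        return np.zeros_like(a)
    return a / m


def build_normal_grid(
    image: Image2D,
    centerline: CenterlineCurve,
    half_width: int = DEFAULT_HALF_WIDTH,
    spacing: float = 1.0,
    derivative_sigma: float = DERIVATIVE_SIGMA,
) -> tuple[NormalGrid, NormalGrid]:
    """Sample candidate wall nodes and their derivative features on both sides.

    Normals come from central-difference tangents of the centreline; node
    features are bilinear samples of Gaussian-derivative images.  Nodes
    falling outside the image are clamped to the border and flagged; a stage
    whose nodes are all outside raises.
    """
    if len(centerline) < 4:
        raise ValueError("centreline must have at least 4 points")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = centerline.points
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])  # 90 deg CCW in (row, col)

    # centering removes the DC leak of the truncated 2nd-derivative kernel
    pix = image.pixels - image.pixels.mean()
    gr = ndimage.gaussian_filter(pix, derivative_sigma, order=(1, 0))
    gc = ndimage.gaussian_filter(pix, derivative_sigma, order=(0, 1))
    grr = ndimage.gaussian_filter(pix, derivative_sigma, order=(2, 0))
    gcc = ndimage.gaussian_filter(pix, derivative_sigma, order=(0, 2))
    grc = ndimage.gaussian_filter(pix, derivative_sigma, order=(1, 1))
    gm_img = np.hypot(gr, gc)
    hm_img = np.sqrt(grr**2 + 2 * grc**2 + gcc**2)

    offsets = spacing * np.arange(1, half_width + 1)
    grids = []
    for sign, side in ((+1.0, "left"), (-1.0, "right")):
        pos = pts[:, None, :] + sign * offsets[None, :, None] * normals[:, None, :]
        lo = np.zeros(2)
        hi = np.array(pix.shape, dtype=float) - 1.0
        clamped = np.any((pos < lo) | (pos > hi), axis=2)
        if clamped.all(axis=1).any():
            raise ValueError(f"a normal on the {side} side lies fully outside the image")
        pos = np.clip(pos, lo, hi)
        coords = [pos[..., 0].ravel(), pos[..., 1].ravel()]
        shape = pos.shape[:2]

        def _sample(img):
            return ndimage.map_coordinates(img, coords, order=1, mode="nearest").reshape(shape)

        e_gm = _scale01(_sample(gm_img))
        e_hm = _scale01(_sample(hm_img))
        e_gd = np.mod(np.arctan2(_sample(gc), _sample(gr)), np.pi)
        grids.append(
            NormalGrid(pos, normals.copy(), e_gm.copy(), e_gm, e_hm, e_gd, side, clamped)
        )
    return grids[0], grids[1]


def transition_score(prev: dict, cur: dict, params: DPParams) -> float:
    """Stage-to-stage merit of moving from node ``prev`` to node ``cur``.

    Nodes are mappings with keys ``e_m``, ``e_gm``, ``e_hm``, ``e_gd``.
    """
    b, eps = params.beta, params.epsilon
    ratio_cur = cur["e_gm"] / (cur["e_hm"] + eps)
    ratio_prev = prev["e_gm"] / (prev["e_hm"] + eps)
    ddir = float(_orientation_diff(cur["e_gd"], prev["e_gd"]))
    return float(cur["e_m"] - b * abs(ratio_cur - ratio_prev) - (1 - b) * ddir**2)


def dp_optimal_path(grid: NormalGrid, params: DPParams | None = None) -> WallCurve:
    """Exact maximization of the wall objective by dynamic programming.

    First and last stage are fixed to the node of maximum gradient magnitude
    on their normals.  Ties (in the endpoint choice and in the per-stage
    argmax) break toward the smaller node index, i.e. closer to the
    centreline.  Complexity O(N * K^2).
    """
    params = params or DPParams()
    N, K = grid.n_stages, grid.n_nodes
    if N < 2:
        raise ValueError("need at least 2 stages")
    if K < 1:
        raise ValueError("each stage needs at least 1 node")
    b, eps = params.beta, params.epsilon

    ratio = grid.e_gm / (grid.e_hm + eps)  # (N, K)
    first = int(np.argmax(grid.e_gm[0]))   # argmax returns the first maximum
    last = int(np.argmax(grid.e_gm[-1]))

    score = np.full((N, K), -np.inf)
    back = np.zeros((N, K), dtype=int)
    score[0, first] = grid.e_m[0, first]
    for i in range(1, N):
        # pairwise transition terms, shape (K_prev, K_cur)
        dr = np.abs(ratio[i][None, :] - ratio[i - 1][:, None])
        dd = _orientation_diff(grid.e_gd[i][None, :], grid.e_gd[i - 1][:, None])
        f = grid.e_m[i][None, :] - b * dr - (1 - b) * dd**2
        tot = score[i - 1][:, None] + f
        back[i] = np.argmax(tot, axis=0)
        score[i] = tot[back[i], np.arange(K)]
    idx = np.empty(N, dtype=int)
    idx[-1] = last
    for i in range(N - 1, 0, -1):
        idx[i - 1] = back[i, idx[i]]
    pts = grid.positions[np.arange(N), idx]
    return WallCurve(pts, grid.side, float(score[-1, last]), idx)


def extract_vessel_walls(
    image: Image2D,
    centerline: CenterlineCurve,
    params: DPParams | None = None,
    half_width: int = DEFAULT_HALF_WIDTH,
    spacing: float = 1.0,
) -> tuple[WallCurve, WallCurve]:
    """Delineate the two vessel walls, one DP solve per side of the centreline."""
    params = params or DPParams()
    left, right = build_normal_grid(image, centerline, half_width, spacing)
    return dp_optimal_path(left, params), dp_optimal_path(right, params)
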