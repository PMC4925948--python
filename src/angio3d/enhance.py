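"""Tubular-structure enhancement, binarization, skeletonization and node detection.

The enhancement chain is: multiscale Hessian-eigenvalue vesselness ->
hysteresis thresholding -> optional morphological cleanup -> topology
preserving thinning -> bifurcation / end point classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.morphology import skeletonize as _skimage_skeletonize

from .image import Image2D, normalize_intensities

#: default detection scales in pixels
DEFAULT_SCALES = (1.0, 2.0, 3.0, 5.0, 8.0)

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class SkeletonMap:
    """1-px-wide skeleton with classified bifurcation and end points."""

    skeleton: np.ndarray
    bifurcation_points: list[tuple[int, int]] = field(default_factory=list)
    end_points: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=bool)


def vesselness_filter(
    image: Image2D,
    scales=DEFAULT_SCALES,
    contrast_params: tuple[float, float | None] = (0.5, None),
    dark_ridges: bool = True,
) -> Image2D:
    """Multiscale 2D Hessian-eigenvalue vesselness.

    At each scale ``sigma`` the Hessian is computed with Gaussian derivatives
    (gamma-normalized by ``sigma**2``); the eigenvalues ``|l1| <= |l2|`` give a
    blobness ratio ``Rb = l1/l2`` and structureness ``S = sqrt(l1^2+l2^2)``,
    combined into ``exp(-Rb^2/2b^2) * (1 - exp(-S^2/2c^2))`` where the ridge
    polarity matches (``l2 > 0`` for dark vessels on a bright background).
    The per-pixel maximum over scales is returned, normalized to [0, 1].

    Parameters
    ----------
    scales : sequence of float
        Gaussian scales in pixels, at least one.
    contrast_params : (b, c)
        Blobness sensitivity ``b`` and structureness sensitivity ``c``; when
        ``c`` is None it defaults to half the maximum structureness per scale.
    dark_ridges : bool
        True enhances dark vessels on bright background (X-ray angiograms).
    """
    scales = tuple(float(s) for s in np.atleast_1d(scales))
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    b, c = contrast_params
    if b <= 0 or (c is not None and c <= 0):
        raise ValueError("contrast parameters must be positive")
    pix = image.pixels
    if not np.all(np.isfinite(pix)):
        raise ValueError("input image has non-finite pixels")
    pix = pix - pix.mean()  # removes the DC leak of truncated derivative kernels

    best = np.zeros_like(pix)
    for sigma in scales:
        H = hessian_matrix(pix, sigma=sigma, order="rc", mode="reflect",
                           use_gaussian_derivatives=True)
        l1, l2 = hessian_matrix_eigvals([h * sigma**2 for h in H])
        # order by absolute value: |l1| <= |l2|
        swap = np.abs(l1) > np.abs(l2)
        l1, l2 = np.where(swap, l2, l1), np.where(swap, l1, l2)
        signed = l2 if dark_ridges else -l2
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / np.where(l2 == 0, 1, l2)) ** 2, 0.0)
        s2 = l1**2 + l2**2
        c_eff = c if c is not None else max(0.5 * np.sqrt(s2.max()), 1e-12)
        v = np.exp(-rb2 / (2 * b**2)) * (1 - np.exp(-s2 / (2 * c_eff**2)))
        v[signed <= 0] = 0.0
        np.maximum(best, v, out=best)
    if best.max() < 1e-10:  # flat image: do not amplify numerical noise
        best[:] = 0.0
    return Image2D(normalize_intensities(best), image.pixel_spacing_mm)


def hysteresis_threshold(vesselness: Image2D, low: float, high: float) -> np.ndarray:
    """Two-threshold binarization with 8-connected propagation.

    Pixels ``>= high`` are kept; pixels ``>= low`` are kept iff 8-connected to
    a kept pixel.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    pix = vesselness.pixels
    weak = pix >= low
    strong = pix >= high
    if not strong.any():
        return np.zeros_like(weak)
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    keep = np.unique(labels[strong])
    return np.isin(labels, keep[keep > 0])


def quantile_thresholds(vesselness: Image2D, q_low=0.80, q_high=0.95) -> tuple[float, float]:
    """Low/high hysteresis levels as intensity quantiles of the nonzero response."""
    vals = vesselness.pixels[vesselness.pixels > 0]
    if vals.size == 0:
        return 1.0, 1.0
    return float(np.quantile(vals, q_low)), float(np.quantile(vals, q_high))


def clean_mask(mask: np.ndarray, min_size: int = 64, closing_radius: int = 1) -> np.ndarray:
    """Small-object removal followed by binary closing."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        mask = np.isin(labels, keep)
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=closing_radius)
    return mask


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def skeletonize_and_label(mask: np.ndarray) -> SkeletonMap:
    """Thin a binary mask to 1 px and classify bifurcation / end points.

    A skeleton pixel with >= 3 skeleton neighbors (8-connectivity) is a
    bifurcation candidate, one with exactly 1 neighbor an end point, and an
    isolated pixel counts as an end point.  8-adjacent bifurcation candidates
    are merged into a single point (cluster centroid snapped onto the
    skeleton).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to skeletonize")
    skel = _skimage_skeletonize(mask)
    counts = _neighbor_counts(skel)
    bif_mask = skel & (counts >= 3)
    end_mask = skel & (counts <= 1)

    bifurcations: list[tuple[int, int]] = []
    if bif_mask.any():
        labels, n = ndimage.label(bif_mask, structure=np.ones((3, 3), dtype=int))
        for lab in range(1, n + 1):
            pts = np.argwhere(labels == lab)
            centroid = pts.mean(axis=0)
            best = pts[np.argmin(((pts - centroid) ** 2).sum(axis=1))]
            bifurcations.append((int(best[0]), int(best[1])))
    ends = [(int(r), int(c)) for r, c in np.argwhere(end_mask)]
    return SkeletonMap(skel, bifurcations, ends)
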