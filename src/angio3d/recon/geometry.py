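"""Cone-beam C-arm projection geometry: projection, back-projection, triangulation.

World frame: patient LPS-like right-handed axes with the isocenter at the
origin.  At zero gantry angles the source sits at ``(0, -SOD, 0)`` and the
beam travels along +y toward the detector; detector columns run along +x and
detector rows along -z.  The primary (LAO/RAO) angle rotates the gantry about
the patient long axis z, the secondary (cranial/caudal) angle about the
rotated x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass
class ProjectionGeometry:
    """One view of a monoplane C-arm acquisition.

    Parameters
    ----------
    sid_mm : float
        Source-to-intensifier (detector) distance.
    sod_mm : float
        Source-to-isocenter distance (< sid_mm).
    pixel_size_mm : float
        Detector pixel pitch.
    primary_angle_deg, secondary_angle_deg : float
        Gantry LAO/RAO and cranial/caudal rotations.
    image_shape : (rows, cols)
        Detector raster size; the principal point is the raster center.
    translation_mm : 3-vector
        Optional world-frame shift of this view (table motion between views).
    """

    sid_mm: float
    pixel_size_mm: float
    primary_angle_deg: float = 0.0
    secondary_angle_deg: float = 0.0
    sod_mm: float | None = None
    image_shape: tuple[int, int] = (512, 512)
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.sid_mm <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("SID and pixel size must be positive")
        if self.sod_mm is None:
            self.sod_mm = 0.7 * self.sid_mm  # typical C-arm isocenter placement
        if not 0 < self.sod_mm < self.sid_mm:
            raise ValueError("need 0 < SOD < SID")
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        R = _rot_z(self.primary_angle_deg) @ _rot_x(self.secondary_angle_deg)
        self._beam = R @ np.array([0.0, 1.0, 0.0])   # unit source -> detector
        self._u = R @ np.array([1.0, 0.0, 0.0])      # detector column axis
        self._v = R @ np.array([0.0, 0.0, -1.0])     # detector row axis
        self.source = -self.sod_mm * self._beam + self.translation_mm
        self.detector_center = self.source + self.sid_mm * self._beam

    @property
    def principal_point(self) -> tuple[float, float]:
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)

    def project_point(self, X3) -> tuple[float, float]:
        """Perspective projection of a 3D point (mm) to pixel (row, col)."""
        X3 = np.asarray(X3, dtype=float)
        depth = float((X3 - self.source) @ self._beam)
        if depth <= 0 or depth >= self.sid_mm:
            raise ValueError("point must lie strictly between source and detector")
        p = self.source + (self.sid_mm / depth) * (X3 - self.source)
        d = p - self.detector_center
        r0, c0 = self.principal_point
        return (r0 + float(d @ self._v) / self.pixel_size_mm,
                c0 + float(d @ self._u) / self.pixel_size_mm)

    def project_points(self, X: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`project_point` for an (N, 3) array -> (N, 2) px."""
        X = np.asarray(X, dtype=float)
        rel = X - self.source
        depth = rel @ self._beam
        if np.any(depth <= 0) or np.any(depth >= self.sid_mm):
            raise ValueError("all points must lie strictly between source and detector")
        p = self.source + (self.sid_mm / depth)[:, None] * rel
        d = p - self.detector_center
        r0, c0 = self.principal_point
        return np.column_stack([r0 + d @ self._v / self.pixel_size_mm,
                                c0 + d @ self._u / self.pixel_size_mm])

    def pixel_to_detector(self, px) -> np.ndarray:
        """3D world position of a (row, col) detector pixel."""
        r0, c0 = self.principal_point
        return (self.detector_center
                + (px[1] - c0) * self.pixel_size_mm * self._u
                + (px[0] - r0) * self.pixel_size_mm * self._v)

    def backproject_ray(self, px) -> tuple[np.ndarray, np.ndarray]:
        """Ray (origin, unit direction) from the source through a pixel."""
        d = self.pixel_to_detector(px) - self.source
        return self.source, d / np.linalg.norm(d)


def project_point(geom: ProjectionGeometry, X3) -> tuple[float, float]:
    return geom.project_point(X3)


def triangulate(geomA: ProjectionGeometry, geomB: ProjectionGeometry, pA, pB,
                min_angle_rad: float = 1e-6) -> tuple[np.ndarray, float]:
    """Midpoint of the common perpendicular of the two back-projected rays.

    Returns ``(X3, residual)`` with residual = half the length of the common
    perpendicular (0 mm for exact correspondences).  Near-parallel rays raise.
    """
    o1, d1 = geomA.backproject_ray(pA)
    o2, d2 = geomB.backproject_ray(pB)
    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < min_angle_rad:
        raise ValueError("degenerate geometry: back-projected rays are near-parallel")
    # solve o1 + t1 d1 and o2 + t2 d2 at closest approach
    b = o2 - o1
    d12 = d1 @ d2
    t1 = (b @ d1 - (b @ d2) * d12) / (1 - d12**2)
    t2 = ((b @ d1) * d12 - b @ d2) / (1 - d12**2)
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return 0.5 * (p1 + p2), 0.5 * float(np.linalg.norm(p1 - p2))


def epipolar_line(geom_src: ProjectionGeometry, geom_dst: ProjectionGeometry,
                  px_src) -> tuple[float, float, float]:
    """Line coefficients (a, b, c) in destination pixel coords (row, col).

    The back-projection ray of ``px_src`` is sampled near the isocenter and
    projected into the destination view; ``a*row + b*col + c = 0`` on the
    epipolar line, with (a, b) normalized to unit length so the line function
    is a signed pixel distance.
    """
    o, d = geom_src.backproject_ray(px_src)
    depth0 = geom_src.sod_mm
    p1 = geom_dst.project_point(o + 0.7 * depth0 * d)
    p2 = geom_dst.project_point(o + 1.3 * depth0 * d)
    a = p2[1] - p1[1]
    b = -(p2[0] - p1[0])
    n = float(np.hypot(a, b))
    if n < 1e-12:
        raise ValueError("degenerate epipolar line")
    a, b = a / n, b / n
    c = -(a * p1[0] + b * p1[1])
    return float(a), float(b), float(c)
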