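import numpy as np
import pytest

from angio3d.image import Image2D
from angio3d.phantom import make_phantom, render_views
from angio3d.recon.geometry import ProjectionGeometry


@pytest.fixture(scope="session")
def geom_pair():
    """Two C-arm views 90 degrees apart (AP and lateral-ish)."""
    geomA = ProjectionGeometry(1000.0, 0.3, 0.0, 0.0, image_shape=(256, 256))
    geomB = ProjectionGeometry(1000.0, 0.3, 90.0, 0.0, image_shape=(256, 256))
    return geomA, geomB


@pytest.fixture(scope="session")
def geom_pair_30():
    geomA = ProjectionGeometry(1000.0, 0.3, 0.0, 0.0, image_shape=(256, 256))
    geomB = ProjectionGeometry(1000.0, 0.3, 30.0, 0.0, image_shape=(256, 256))
    return geomA, geomB


@pytest.fixture(scope="session")
def helix_scene(geom_pair):
    """Rendered stenosed helix phantom with ground truth (shared; read-only)."""
    geomA, geomB = geom_pair
    vessel = make_phantom("helix", a=6.0, b=10.0, turns=0.6, r0=1.5,
                          stenosis={"severity": 0.5})
    imgA, imgB, gt = render_views(vessel, geomA, geomB, seed=1, noise_sigma=0.01)
    return vessel, imgA, imgB, gt


@pytest.fixture()
def ridge_image():
    """Single vertical Gaussian ridge of width sigma=3 px at col=40."""
    rr, cc = np.mgrid[0:80, 0:80]
    pix = 0.9 - 0.6 * np.exp(-0.5 * ((cc - 40) / 3.0) ** 2)
    return Image2D(pix)


def extract_view_centerline(img, gt, view, scales=(2, 3, 5)):
    """Shared helper: enhancement -> skeleton -> snapped path -> smooth curve."""
    from angio3d import enhance as enh
    from angio3d.centerline import extract_path, smooth_centerline, snap_to_skeleton

    ves = enh.vesselness_filter(img, scales=list(scales))
    low, high = enh.quantile_thresholds(ves)
    mask = enh.clean_mask(enh.hysteresis_threshold(ves, low, high))
    skel = enh.skeletonize_and_label(mask)
    s = snap_to_skeleton(gt.centerline_px[view][0], skel)
    e = snap_to_skeleton(gt.centerline_px[view][-1], skel)
    return smooth_centerline(extract_path(skel, s, e), skel)
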