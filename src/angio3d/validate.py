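"""Evaluation utilities: Hausdorff curve distance and multi-annotator
maximum-likelihood label fusion (two-class confusion-matrix EM)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

EM_TOL = 1e-6
EM_MAX_ITER = 100
EM_PSEUDOCOUNT = 0.5
#: default resampling step (px) when comparing curves as point sets
CURVE_RESAMPLE_STEP = 0.25


def hausdorff_distance(X, Y) -> float:
    """Symmetric Hausdorff distance between two Euclidean point sets.

    ``max( max_x min_y d(x,y), max_y min_x d(x,y) )``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise ValueError("point sets must be nonempty")
    d_xy = cKDTree(Y).query(X)[0].max()
    d_yx = cKDTree(X).query(Y)[0].max()
    return float(max(d_xy, d_yx))


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return pts[:1]
    n = max(int(np.ceil(arc[-1] / step)) + 1, 2)
    t = np.linspace(0.0, arc[-1], n)
    return np.column_stack([np.interp(t, arc, pts[:, k]) for k in range(pts.shape[1])])


def compare_walls(extracted, reference, step: float = CURVE_RESAMPLE_STEP,
                  pixel_spacing_mm: float | None = None):
    """Hausdorff distance between two curves, densely resampled as point sets.

    Returns the distance in px, or ``(px, mm)`` when a pixel spacing is given.
    """
    pe = getattr(extracted, "points", extracted)
    pr = getattr(reference, "points", reference)
    d_px = hausdorff_distance(_resample_polyline(pe, step), _resample_polyline(pr, step))
    if pixel_spacing_mm is None:
        return d_px
    return d_px, d_px * pixel_spacing_mm


def wall_report(rows: list[dict]) -> pd.DataFrame:
    """Tabulate per-vessel, per-projection wall discrepancies."""
    return pd.DataFrame(rows, columns=["vessel", "projection", "hausdorff_px", "hausdorff_mm"])


@dataclass
class LabelSet:
    """Binary labels (1 edge / 0 nonedge) from several annotators.

    ``labels`` has shape (items, annotators); every annotator labels every
    item.
    """

    labels: np.ndarray
    annotator_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be items x annotators")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not self.annotator_ids:
            self.annotator_ids = [f"annotator_{k}" for k in range(self.labels.shape[1])]

    @classmethod
    def from_csv(cls, path) -> "LabelSet":
        """Load long-format CSV with columns item, annotator, label."""
        df = pd.read_csv(path)
        wide = df.pivot(index="item", columns="annotator", values="label").sort_index()
        if wide.isna().any().any():
            raise ValueError("every annotator must label every item")
        return cls(wide.to_numpy(), [str(a) for a in wide.columns])


@dataclass
class ConsensusResult:
    posteriors: np.ndarray          # (items,) P(true label = 1)
    labels: np.ndarray              # hard consensus labels
    confusion: np.ndarray           # (annotators, 2, 2), rows = true class
    error_rates: np.ndarray         # prior-weighted off-diagonal mass
    priors: np.ndarray              # (2,)
    log_likelihood: list[float]
    n_iterations: int


def ml_consensus(labels: LabelSet | np.ndarray, max_iter: int = EM_MAX_ITER,
                 tol: float = EM_TOL) -> ConsensusResult:
    """EM estimate of true labels and per-annotator confusion matrices.

    Initialization is the per-item majority vote; the E-step computes the
    posterior of each item's true label under the current confusion matrices
    and class priors, the M-step re-estimates both from the posteriors
    (pseudocount-regularized).  Iterates until the maximum posterior change
    drops below ``tol``.  The scalar quality score per annotator is the
    prior-weighted sum of off-diagonal confusion entries.
    """
    ls = labels if isinstance(labels, LabelSet) else LabelSet(np.asarray(labels))
    L = ls.labels
    n_items, n_ann = L.shape
    if n_ann < 2 or n_items < 2:
        raise ValueError("need at least 2 annotators and 2 items")

    post = L.mean(axis=1)  # majority vote soft init; exact ties stay at 0.5
    loglik: list[float] = []
    n_iter = 0
    conf = np.empty((n_ann, 2, 2))
    priors = np.array([0.5, 0.5])
    for n_iter in range(1, max_iter + 1):
        # M-step
        w1, w0 = post, 1.0 - post
        priors = np.array([w0.sum(), w1.sum()]) + EM_PSEUDOCOUNT
        priors = priors / priors.sum()
        for k in range(n_ann):
            ones = L[:, k] == 1
            n1_true = w1.sum()
            n0_true = w0.sum()
            conf[k, 1, 1] = (w1[ones].sum() + EM_PSEUDOCOUNT) / (n1_true + 2 * EM_PSEUDOCOUNT)
            conf[k, 1, 0] = 1.0 - conf[k, 1, 1]
            conf[k, 0, 1] = (w0[ones].sum() + EM_PSEUDOCOUNT) / (n0_true + 2 * EM_PSEUDOCOUNT)
            conf[k, 0, 0] = 1.0 - conf[k, 0, 1]
        degenerate = (conf <= 0).any(axis=(1, 2))
        if degenerate.any():  # pragma: no cover - pseudocount prevents this
            warnings.warn("degenerate confusion row regularized", stacklevel=2)
            conf = np.clip(conf, 1e-9, 1 - 1e-9)
        # E-step
        ann_idx = np.arange(n_ann)[:, None]
        log_p1 = np.log(priors[1]) + np.log(conf[:, 1, :][ann_idx, L.T]).sum(axis=0)
        log_p0 = np.log(priors[0]) + np.log(conf[:, 0, :][ann_idx, L.T]).sum(axis=0)
        m = np.maximum(log_p1, log_p0)
        denom = np.exp(log_p1 - m) + np.exp(log_p0 - m)
        new_post = np.exp(log_p1 - m) / denom
        loglik.append(float(np.sum(m + np.log(denom))))
        change = float(np.max(np.abs(new_post - post)))
        post = new_post
        if change < tol:
            break

    err = priors[1] * conf[:, 1, 0] + priors[0] * conf[:, 0, 1]
    return ConsensusResult(post, (post >= 0.5).astype(int), conf.copy(), err,
                           priors, loglik, n_iter)


def roc_point(confusion: np.ndarray) -> tuple[float, float]:
    """(FPR, TPR) of one annotator's 2x2 confusion matrix (rows = true class)."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (2, 2) or not np.allclose(confusion.sum(axis=1), 1.0):
        raise ValueError("confusion matrix rows must sum to 1")
    return float(confusion[0, 1]), float(confusion[1, 1])
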