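"""Fully automatic left/right breast segmentation.

The frontal acquisition protocol (subject seated, hands in the nape, thermally
stabilized) makes two anatomical landmarks reliable:

* the **inframammary fold** under each breast is among the hottest skin
  regions, so a high threshold — the maximum gray level inside the body minus
  a small offset — isolates it; among the supra-threshold blobs the fold is
  the *thickest* one, which a Euclidean distance transform ranks directly;
* the **armpits** show an abrupt slope change along the lateral body contour,
  found by numerical differentiation of the contour line.

The per-column top pixels of the fold blobs are completed into two
second-degree polynomials ``y = a0 + a1 x + a2 x^2`` by least squares; their
intersection near the midline splits the chest into the two sides.  Straight
segments from each armpit point to the intersection close the region from
above; the polynomials bound it from below.

Coordinates: origin top-left, x = column, y = row, 0-based; "above" means
smaller y.  Side naming is anatomical: the patient's right breast is the
viewer's left half (smaller x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import SegmentationError, Thermogram
from .preprocessing import BodyMask


@dataclass(frozen=True)
class FoldEvidence:
    """Supra-threshold fold pixels and the per-column ridge points they yield.

    Ridge points are (x, y) pixel coordinates; ``right`` is the patient's
    right side (viewer's left, smaller x).
    """

    ridge_points_right: np.ndarray  # (n, 2) array of (x, y)
    ridge_points_left: np.ndarray
    hot_mask: np.ndarray


@dataclass(frozen=True)
class Polynomial2:
    """y = a0 + a1*x + a2*x^2, fitted by least squares; RMS residual recorded."""

    a0: float
    a1: float
    a2: float
    rms: float = 0.0

    def __call__(self, x):
        return self.a0 + self.a1 * np.asarray(x, float) + self.a2 * np.asarray(x, float) ** 2

    @property
    def coeffs(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)


@dataclass(frozen=True)
class SplitPoint:
    """Intersection of the two fold polynomials (the left/right control point)."""

    x: float
    y: float
    low_confidence: bool = False


@dataclass(frozen=True)
class ArmpitPoints:
    """Detected armpit landmarks, one per side, with their slope profiles."""

    right: tuple[float, float]   # (x, y), viewer-left contour
    left: tuple[float, float]
    slope_profile_right: np.ndarray
    slope_profile_left: np.ndarray


@dataclass(frozen=True)
class BreastSegmentation:
    left_mask: np.ndarray
    right_mask: np.ndarray
    fold_left: Polynomial2
    fold_right: Polynomial2
    split_point: SplitPoint
    armpits: ArmpitPoints


def detect_fold_candidates(
    thermogram: Thermogram, body: BodyMask, offset: int = 10
) -> FoldEvidence:
    """Isolate the inframammary-fold ridges.

    Threshold = (max gray inside the body) − ``offset``; the connected
    components above it are ranked by their maximum interior Euclidean
    distance (thickness, with area as tie-break) and the top component per
    lateral half is kept.  Ridge points are the per-column topmost pixels of
    the kept components.
    """
    mask = body.mask
    px = thermogram.pixels
    gmax = int(px[mask].max())
    if offset >= gmax:
        raise SegmentationError(f"offset {offset} >= maximum body gray {gmax}")
    thr = gmax - offset
    supra = (px > thr) & mask
    if not supra.any():
        raise SegmentationError("no pixels above the fold threshold")

    labels, n = ndi.label(supra, structure=np.ones((3, 3), dtype=int))
    dist = ndi.distance_transform_edt(supra)
    mid_x = float(np.nonzero(mask)[1].mean())

    # rank components per lateral half by (max interior distance, area)
    best: dict[str, tuple[tuple[float, int], int]] = {}
    for k in range(1, n + 1):
        comp = labels == k
        cols = np.nonzero(comp)[1]
        score = (float(dist[comp].max()), int(comp.sum()))
        halves = []
        if (cols < mid_x).any():
            halves.append("right")
        if (cols >= mid_x).any():
            halves.append("left")
        for half in halves:
            if half not in best or score > best[half][0]:
                best[half] = (score, k)
    keep = {k for _, k in best.values()}

    pts_r, pts_l = [], []
    kept_mask = np.isin(labels, list(keep))
    rows, cols = np.nonzero(kept_mask)
    for x in np.unique(cols):
        y = rows[cols == x].min()  # topmost pixel of the ridge band
        (pts_r if x < mid_x else pts_l).append((float(x), float(y)))
    return FoldEvidence(
        ridge_points_right=np.asarray(pts_r, float).reshape(-1, 2),
        ridge_points_left=np.asarray(pts_l, float).reshape(-1, 2),
        hot_mask=supra,
    )


def fit_fold_polynomial(points: np.ndarray) -> Polynomial2:
    """Least-squares second-degree fit y = a0 + a1 x + a2 x^2."""
    pts = np.asarray(points, float).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values for a quadratic fit")
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return Polynomial2(float(coef[0]), float(coef[1]), float(coef[2]),
                       rms=float(np.sqrt(np.mean(resid ** 2))))


def intersect_folds(
    p_left: Polynomial2, p_right: Polynomial2, x_range: tuple[float, float]
) -> SplitPoint:
    """Real root of ``p_left - p_right`` inside ``x_range``.

    With several in-range roots the one nearest the range midpoint (the image
    midline) wins.  With none, the midpoint at the mean fold height is
    returned flagged low-confidence.
    """
    lo, hi = x_range
    mid = 0.5 * (lo + hi)
    d = np.array([p_left.a2 - p_right.a2, p_left.a1 - p_right.a1, p_left.a0 - p_right.a0])
    if np.allclose(d, 0.0):
        return SplitPoint(mid, float(p_left(mid)), low_confidence=True)
    roots = np.roots(np.trim_zeros(d, "f") if np.any(d) else d)
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
    if not real:
        y = 0.5 * (float(p_left(mid)) + float(p_right(mid)))
        return SplitPoint(mid, y, low_confidence=True)
    x = min(real, key=lambda r: abs(r - mid))
    return SplitPoint(x, float(p_left(x)), low_confidence=False)


def secant_slopes(f: np.ndarray, h: int) -> np.ndarray:
    """Two-point secant slope (f(i+h) - f(i-h)) / 2h along a sampled contour.

    Near the ends the step is clamped to the available samples (forward /
    backward differences) rather than discarding points.
    """
    f = np.asarray(f, float)
    n = len(f)
    if n < 2:
        raise ValueError("contour too short")
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    span = hi - lo
    span[span == 0] = 1
    return (f[hi] - f[lo]) / span


def _slope_break(f: np.ndarray, h: int) -> tuple[int, float]:
    """Index of the sharpest slope change: max |forward - backward| secant.

    The forward/backward secant difference (f(i+h)-f(i))/h - (f(i)-f(i-h))/h
    peaks exactly at a contour corner, unlike differencing two centered
    secants, which peaks h samples to either side.  Index plateaus (a corner
    smeared over a few samples) resolve to their center.
    """
    n = len(f)
    if n < 2 * h + 1:
        raise SegmentationError(f"contour has {n} samples, need at least {2 * h + 1}")
    i = np.arange(h, n - h)
    fwd = (f[i + h] - f[i]) / h
    bwd = (f[i] - f[i - h]) / h
    change = np.abs(fwd - bwd)
    peak = float(change.max())
    # exact ties (crisp corner seen through a window of width h) form
    # plateaus symmetric about the corner: resolve to their center
    winners = np.nonzero(change >= peak - 1e-9)[0]
    return int(i[int(round(float(winners.mean())))]), peak


def find_armpit_points(body: BodyMask, fold_y: float, h: int = 10) -> ArmpitPoints:
    """Locate the armpit landmark on each lateral contour.

    The contour comes from the morphological gradient of the body mask (mask
    minus its erosion); each side's lateral line is parameterized top-to-bottom
    as x(y) over the rows above ``fold_y``.  The armpit is the point with the
    most significant slope variation.

    Raises
    ------
    SegmentationError
        If a contour is shorter than ``2h+1`` rows or shows no slope break
        (straight contour).
    """
    mask = body.mask
    grad = mask & ~ndi.binary_erosion(mask, structure=np.ones((3, 3), bool))
    top = int(np.nonzero(mask.any(axis=1))[0].min())
    y_stop = min(int(fold_y), mask.shape[0])
    rows = np.arange(top, y_stop)
    rows = rows[[grad[y].any() for y in rows]]
    if len(rows) < 2 * h + 1:
        raise SegmentationError("lateral contour above the fold is too short")

    profiles, points = {}, {}
    for side in ("right", "left"):
        xs = []
        for y in rows:
            cols = np.nonzero(grad[y])[0]
            xs.append(float(cols.min() if side == "right" else cols.max()))
        f = np.asarray(xs)
        profiles[side] = secant_slopes(f, h)
        idx, peak = _slope_break(f, h)
        if peak < 0.05:
            raise SegmentationError(f"no slope break on the {side} contour")
        points[side] = (f[idx], float(rows[idx]))
    return ArmpitPoints(
        right=points["right"],
        left=points["left"],
        slope_profile_right=profiles["right"],
        slope_profile_left=profiles["left"],
    )


def assemble_breast_masks(
    body: BodyMask,
    folds: tuple[Polynomial2, Polynomial2],
    split: SplitPoint,
    armpits: ArmpitPoints,
    fold_margin: int = 4,
) -> BreastSegmentation:
    """Build the left/right breast masks from the geometric evidence.

    Upper boundary: straight segments from each armpit point to the split
    point.  Lower boundary: the fitted fold polynomials, with ``fold_margin``
    rows excluded just above them so the hot fold crease itself (the
    segmentation landmark, not breast tissue) does not leak into the region
    statistics.  The region is clipped to the body mask and divided at the
    split column into the patient's right (viewer-left) and left halves.
    """
    fold_right, fold_left = folds
    mask = body.mask
    H, W = mask.shape
    sx, sy = split.x, split.y
    if not (0 <= int(round(sx)) < W and 0 <= int(round(sy)) < H) or not mask[
        int(round(sy)), int(round(sx))
    ]:
        raise SegmentationError("split point falls outside the body")

    yy, xx = np.mgrid[0:H, 0:W]
    out = {}
    for side, fold, arm in (("right", fold_right, armpits.right),
                            ("left", fold_left, armpits.left)):
        ax, ay = arm
        if abs(sx - ax) < 1e-9:
            raise SegmentationError("armpit and split point share a column")
        upper = ay + (yy * 0.0 + (xx - ax)) * (sy - ay) / (sx - ax)
        lower = fold(xx) - fold_margin
        in_cols = (xx >= min(ax, sx)) & (xx <= max(ax, sx))
        strict = (xx < sx) if side == "right" else (xx > sx)
        m = mask & in_cols & strict & (yy > upper) & (yy < lower)
        if not m.any():
            raise SegmentationError(f"empty {side} breast mask")
        out[side] = m
    return BreastSegmentation(
        left_mask=out["left"],
        right_mask=out["right"],
        fold_left=fold_left,
        fold_right=fold_right,
        split_point=split,
        armpits=armpits,
    )


def segment_breasts(
    thermogram: Thermogram,
    body: BodyMask,
    offset: int = 10,
    h: int = 10,
    fold_margin: int = 4,
) -> BreastSegmentation:
    """Run the full geometric segmentation on a body-masked thermogram."""
    ev = detect_fold_candidates(thermogram, body, offset=offset)
    if len(ev.ridge_points_right) < 3 or len(ev.ridge_points_left) < 3:
        raise SegmentationError("too few ridge points on one side")
    try:
        fold_right = fit_fold_polynomial(ev.ridge_points_right)
        fold_left = fit_fold_polynomial(ev.ridge_points_left)
    except ValueError as exc:
        raise SegmentationError(str(exc)) from exc
    all_x = np.concatenate([ev.ridge_points_right[:, 0], ev.ridge_points_left[:, 0]])
    split = intersect_folds(fold_left, fold_right, (float(all_x.min()), float(all_x.max())))
    armpits = find_armpit_points(body, fold_y=split.y, h=h)
    return assemble_breast_masks(
        body, (fold_right, fold_left), split, armpits, fold_margin=fold_margin
    )
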