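"""Patient/background separation.

The subject is warmer than the room, so on a well-acquired frontal thermogram
the body is the bright class of the gray histogram.  Otsu's criterion picks
the threshold t* maximizing the between-class variance

    sigma_B^2(t) = w1(t) (mu1(t) - muT)^2 + w2(t) (mu2(t) - muT)^2

where w1, w2 are the class probabilities of the pixels at or below / above t,
mu1, mu2 their mean gray values and muT the global mean.  Hamadani's global
threshold (k1*muT + k2*sigmaT) is included as an alternative.  The body mask
is the bright class, reduced to its largest connected component with holes
filled so downstream contour tracing sees a simply-connected silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import DegenerateInputError, SegmentationError, Thermogram

# rectangle as (x0, y0, x1, y1), half-open: columns [x0, x1), rows [y0, y1)
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class OtsuResult:
    """Threshold plus the full between-class-variance evidence."""

    threshold: int
    criterion: np.ndarray          # sigma_B^2(t) for t = 0 .. L-1
    class_probs: tuple[float, float]   # (w1, w2) at t*
    class_means: tuple[float, float]   # (mu1, mu2) at t*
    global_mean: float


@dataclass(frozen=True)
class BodyMask:
    """Binary patient silhouette (True = patient)."""

    mask: np.ndarray
    scale_bar_box: Rect | None = None


def _histogram(thermogram: Thermogram) -> np.ndarray:
    return np.bincount(thermogram.pixels.ravel(), minlength=thermogram.levels).astype(float)


def otsu_criterion(thermogram: Thermogram) -> np.ndarray:
    """sigma_B^2(t) for every candidate threshold t in 0..L-1.

    Class 1 is gray <= t, class 2 is gray > t; an empty class contributes 0.
    """
    hist = _histogram(thermogram)
    p = hist / hist.sum()
    levels = np.arange(thermogram.levels, dtype=float)
    w1 = np.cumsum(p)
    m1 = np.cumsum(p * levels)
    mu_t = m1[-1]
    w2 = 1.0 - w1
    crit = np.zeros(thermogram.levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
        mu2 = np.where(w2 > 0, (mu_t - m1) / w2, 0.0)
    crit = w1 * (mu1 - mu_t) ** 2 + w2 * (mu2 - mu_t) ** 2
    crit[w1 == 0] = 0.0
    crit[w2 == 0] = 0.0
    return crit


def otsu_threshold(thermogram: Thermogram) -> OtsuResult:
    """Maximize the between-class variance over all thresholds.

    Ties are broken toward the lowest threshold.

    Raises
    ------
    DegenerateInputError
        For a constant image (a single gray level cannot be split).
    """
    px = thermogram.pixels
    if px.min() == px.max():
        raise DegenerateInputError("constant image has no threshold")
    crit = otsu_criterion(thermogram)
    t_star = int(np.argmax(crit))  # argmax returns the first (lowest) maximizer

    hist = _histogram(thermogram)
    p = hist / hist.sum()
    levels = np.arange(thermogram.levels, dtype=float)
    w1 = float(p[: t_star + 1].sum())
    w2 = 1.0 - w1
    mu_t = float((p * levels).sum())
    mu1 = float((p[: t_star + 1] * levels[: t_star + 1]).sum() / w1) if w1 > 0 else 0.0
    mu2 = float((p[t_star + 1:] * levels[t_star + 1:]).sum() / w2) if w2 > 0 else 0.0
    return OtsuResult(
        threshold=t_star,
        criterion=crit,
        class_probs=(w1, w2),
        class_means=(mu1, mu2),
        global_mean=mu_t,
    )


def hamadani_threshold(thermogram: Thermogram, k1: float = 1.0, k2: float = 1.0) -> float:
    """Global threshold k1*mean + k2*SD of the gray levels."""
    px = thermogram.pixels
    if px.min() == px.max():
        raise DegenerateInputError("constant image has no threshold")
    vals = px.astype(float).ravel()
    return k1 * float(vals.mean()) + k2 * float(vals.std(ddof=0))


def extract_body_mask(
    thermogram: Thermogram,
    scale_bar_box: Rect | None = None,
    invert: bool = False,
) -> BodyMask:
    """Segment the patient from the background.

    The temperature-scale bar (when the camera burns one into the frame) sits
    at a fixed position and is zeroed before thresholding.  Pixels brighter
    than the Otsu threshold form the body; the largest connected component is
    kept and its holes filled.

    Parameters
    ----------
    invert:
        Set for palettes where hot renders dark.

    Raises
    ------
    SegmentationError
        If the foreground is empty or fills more than 95% of the frame.
    """
    work = thermogram.pixels.copy()
    if invert:
        work = (thermogram.levels - 1) - work
    if scale_bar_box is not None:
        x0, y0, x1, y1 = scale_bar_box
        work[y0:y1, x0:x1] = 0
    try:
        res = otsu_threshold(Thermogram(work, thermogram.meta, thermogram.levels))
    except DegenerateInputError as exc:
        raise SegmentationError(str(exc)) from exc
    mask = work > res.threshold
    frac = mask.mean()
    if frac == 0 or frac > 0.95:
        raise SegmentationError(
            f"foreground covers {frac:.1%} of the frame; thresholding failed"
        )
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    return BodyMask(mask=mask, scale_bar_box=scale_bar_box)
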