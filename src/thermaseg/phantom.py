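"""Synthetic frontal-torso thermogram phantoms with ground truth.

The generator emulates the image structure the pipeline consumes, for a
seated frontal acquisition with the hands in the nape:

* a warm body silhouette (raised-arm bars flanking a head/neck block over a
  torso) on a cold background, with soft edges;
* a hot Gaussian ridge along each inframammary fold — the fold crease is
  among the warmest skin regions and is the method's lower landmark;
* an abrupt slope change where the arm contour meets the torso (armpit);
* optionally a warm lesion (broad elliptical plateau with a small focal peak
  — a vascularized tumor region raises the temperature of much of the
  breast, not a single pixel) or a vessel-like warm arc;
* additive Gaussian noise at the camera-sensitivity scale.

The °C field is quantized to 8-bit gray against the scene extremes, so each
phantom is self-calibrating: its sidecar t_min/t_max are the field extremes
and the gray->°C conversion round-trips within half a quantization step.

No bioheat physics is attempted: the phantom targets the geometry and
contrast structure the algorithms rely on, not tissue thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .core import (
    RadiometricMeta,
    SegmentationError,
    ThermalMatrix,
    Thermogram,
)
from .evaluation import compare_sides
from .metrics import ConfusionTable
from .pipeline import PipelineConfig, analyze
from .preprocessing import BodyMask
from .segmentation import ArmpitPoints, Polynomial2, assemble_breast_masks, intersect_folds

from .core import region_stats


@dataclass(frozen=True)
class Lesion:
    """Warm region: elliptical plateau (semi-major ``radius``, aspect ratio
    ``aspect`` vertically) of height ``delta_t`` °C plus a small focal peak."""

    center: tuple[float, float]   # (x, y)
    radius: float                 # px, semi-major (horizontal)
    delta_t: float                # °C above the surrounding body
    aspect: float = 0.7           # vertical semi-axis = aspect * radius

    def __post_init__(self) -> None:
        if self.radius < 3:
            raise ValueError("lesion radius must be >= 3 px (MFOV-scale target)")
        if self.delta_t <= 0:
            raise ValueError("lesion delta_t must be positive")


@dataclass(frozen=True)
class VesselArc:
    """Warm curved tube through ``points`` (vessel-like pattern)."""

    points: tuple[tuple[float, float], ...]
    width: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_t <= 0 or self.width <= 0:
            raise ValueError("vessel width and delta_t must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters of one synthetic thermogram.

    Geometry is in pixels (origin top-left, x = column); temperatures in °C.
    Fold curves are (a0, a1, a2) triples of y = a0 + a1 x + a2 x^2; "right"
    is the patient's right (viewer's left, smaller x).
    """

    image_size: tuple[int, int] = (240, 320)   # (rows, cols)
    background_t: float = 22.0
    body_t: float = 33.0
    arm_halfwidth: float = 75.0      # |x - cx| of the outer arm edge
    arm_band: float = 22.0           # arm thickness
    torso_halfwidth: float = 55.0
    neck_halfwidth: float = 20.0
    armpit_right_row: float = 90.0
    armpit_left_row: float = 90.0
    notch_rows: float = 4.0          # rows of the arm->torso transition
    fold_right: tuple[float, float, float] = ()  # set by default()
    fold_left: tuple[float, float, float] = ()
    fold_extent_right: tuple[float, float] = ()
    fold_extent_left: tuple[float, float] = ()
    ridge_dt: float = 4.0            # fold ridge height above body, °C
    ridge_sigma: float = 3.0         # ridge Gaussian half-thickness, px
    lesion: Lesion | VesselArc | None = None
    noise_sd: float = 0.05           # °C, camera-sensitivity scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_t >= self.body_t:
            raise ValueError("background must be colder than the body")
        if self.ridge_dt <= 0:
            raise ValueError("ridge_dt must be positive")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        image_size: tuple[int, int] = (240, 320),
        lesion: Lesion | VesselArc | None = None,
        lesion_side: Literal["left", "right"] | None = None,
        lesion_delta_t: float = 2.0,
        **overrides,
    ) -> "PhantomSpec":
        """Canonical symmetric phantom, scaled to ``image_size``.

        ``lesion_side`` builds a default lesion in that breast; an explicit
        ``lesion`` object wins over it.
        """
        rows, cols = image_size
        s = cols / 320.0
        cx = cols / 2.0
        breast_dx = 35.0 * s
        fold_vertex_y = 160.0 * s * (rows / (240.0 * s))  # scale with rows
        rise = 22.0 * s
        curv = rise / breast_dx**2
        folds, extents = {}, {}
        for side, sgn in (("right", -1), ("left", +1)):
            bx = cx + sgn * breast_dx
            a2 = -curv
            a1 = 2 * curv * bx
            a0 = fold_vertex_y - curv * bx**2
            folds[side] = (a0, a1, a2)
            extents[side] = tuple(sorted((bx - 28.0 * s, bx + 28.0 * s)))
        if lesion is None and lesion_side is not None:
            sgn = -1 if lesion_side == "right" else +1
            lesion = Lesion(
                center=(cx + sgn * breast_dx, 133.0 * s * (rows / (240.0 * s))),
                radius=24.0 * s,
                delta_t=lesion_delta_t,
            )
        kw = dict(
            image_size=image_size,
            arm_halfwidth=75.0 * s,
            arm_band=22.0 * s,
            torso_halfwidth=55.0 * s,
            neck_halfwidth=20.0 * s,
            armpit_right_row=90.0 * s,
            armpit_left_row=90.0 * s,
            fold_right=folds["right"],
            fold_left=folds["left"],
            fold_extent_right=extents["right"],
            fold_extent_left=extents["left"],
            lesion=lesion,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        lesion_delta_t: float | None = None,
    ) -> "PhantomSpec":
        """Randomized anatomy within the acquisition-protocol envelope."""
        cols = int(rng.integers(288, 353))
        rows = int(round(cols * 0.75))
        s = cols / 320.0
        side: Literal["left", "right"] | None = None
        if lesion_delta_t is not None:
            side = "right" if rng.random() < 0.5 else "left"
        spec = cls.default(
            seed=int(rng.integers(0, 2**31 - 1)),
            image_size=(rows, cols),
            lesion_side=side,
            lesion_delta_t=lesion_delta_t if lesion_delta_t is not None else 2.0,
            background_t=float(rng.uniform(20.0, 23.0)),
            body_t=float(rng.uniform(32.0, 34.0)),
            ridge_dt=float(rng.uniform(3.5, 4.5)),
            ridge_sigma=float(rng.uniform(2.5, 3.5)),
            armpit_right_row=float((90.0 + rng.uniform(-8, 8)) * s),
            armpit_left_row=float((90.0 + rng.uniform(-8, 8)) * s),
            torso_halfwidth=float(rng.uniform(50.0, 60.0) * s),
            noise_sd=float(rng.uniform(0.02, 0.08)),
        )
        # jitter the fold vertices a little, keeping left/right near-symmetric
        dy = float(rng.uniform(-6, 6))
        jit = {}
        for name in ("fold_right", "fold_left"):
            a0, a1, a2 = getattr(spec, name)
            jit[name] = (a0 + dy + float(rng.uniform(-2, 2)), a1, a2)
        return replace(spec, **jit)


@dataclass(frozen=True)
class PhantomTruth:
    body_mask: np.ndarray
    left_breast_mask: np.ndarray
    right_breast_mask: np.ndarray
    ridge_curves: dict[str, np.ndarray]      # side -> (n, 2) crest (x, y)
    armpit_points: dict[str, tuple[float, float]]
    lesion_mask: np.ndarray | None
    expected_verdict: Literal["no_problem", "problem_detected"]


def _silhouette(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.image_size
    cx = cols / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    dx = np.abs(xx - cx)
    body = np.zeros((rows, cols), bool)
    for side, ya in (("right", spec.armpit_right_row), ("left", spec.armpit_left_row)):
        half = (xx < cx) if side == "right" else (xx >= cx)
        # raised arm: outer bar from the frame top down to the notch end
        arm = half & (dx <= spec.arm_halfwidth) & (dx >= spec.arm_halfwidth - spec.arm_band)
        arm &= yy <= ya
        # torso lateral half-width: ramps from the arm edge to the torso edge
        # across the notch, then widens very gently toward the hips
        t = np.clip((yy - ya) / spec.notch_rows, 0.0, 1.0)
        w = spec.arm_halfwidth + t * (spec.torso_halfwidth - spec.arm_halfwidth)
        w = w + np.clip(yy - (ya + spec.notch_rows), 0, None) * 0.08
        torso = half & (yy >= ya) & (dx <= w)
        body |= arm | torso
    # head/neck block down the middle, hands behind the nape at the frame top
    body |= dx <= spec.neck_halfwidth
    return body


def _lesion_field(spec: PhantomSpec, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    les = spec.lesion
    assert les is not None
    if isinstance(les, Lesion):
        lx, ly = les.center
        d = np.hypot((xx - lx) / les.radius, (yy - ly) / (les.aspect * les.radius))
        edge = 0.15
        plateau = np.clip((1.0 + edge - d) / (2 * edge), 0.0, 1.0)
        plateau = plateau * plateau * (3 - 2 * plateau)  # smoothstep shoulder
        focal = 0.3 * np.exp(-(d * les.radius) ** 2 / (2 * (les.radius / 4.0) ** 2))
        return les.delta_t * plateau + focal
    # vessel arc: distance to the polyline
    pts = np.asarray(les.points, float)
    dmin = np.full(yy.shape, np.inf)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        vx, vy = x1 - x0, y1 - y0
        L2 = vx * vx + vy * vy
        t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / L2, 0.0, 1.0)
        dmin = np.minimum(dmin, np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy)))
    return les.delta_t * np.exp(-(dmin**2) / (2 * (les.width / 2.0) ** 2))


def _truth_geometry(spec: PhantomSpec, body: np.ndarray):
    rows, cols = spec.image_size
    cx = cols / 2.0
    p_right = Polynomial2(*spec.fold_right)
    p_left = Polynomial2(*spec.fold_left)
    split = intersect_folds(
        p_left, p_right,
        (spec.fold_extent_right[0], spec.fold_extent_left[1]),
    )
    # the armpit landmark is the inner notch corner where the arm contour
    # meets the torso contour
    armpits = ArmpitPoints(
        right=(cx - spec.torso_halfwidth, spec.armpit_right_row + spec.notch_rows),
        left=(cx + spec.torso_halfwidth, spec.armpit_left_row + spec.notch_rows),
        slope_profile_right=np.empty(0),
        slope_profile_left=np.empty(0),
    )
    seg = assemble_breast_masks(BodyMask(body), (p_right, p_left), split, armpits)
    curves = {}
    for side, poly in (("right", p_right), ("left", p_left)):
        x0, x1 = getattr(spec, f"fold_extent_{side}")
        xs = np.arange(int(np.ceil(x0)), int(np.floor(x1)) + 1, dtype=float)
        curves[side] = np.column_stack([xs, poly(xs)])
    return seg, curves, armpits


def generate(spec: PhantomSpec) -> tuple[Thermogram, ThermalMatrix, PhantomTruth]:
    """Render the phantom; identical seeds give bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    yy, xx = np.mgrid[0:rows, 0:cols]
    body = _silhouette(spec)
    seg, curves, armpits = _truth_geometry(spec, body)

    soft = ndi.gaussian_filter(body.astype(float), 1.0)
    temps = spec.background_t + (spec.body_t - spec.background_t) * soft

    elevation = np.zeros((rows, cols))
    for side in ("right", "left"):
        poly = Polynomial2(*getattr(spec, f"fold_{side}"))
        x0, x1 = getattr(spec, f"fold_extent_{side}")
        in_x = (xx >= x0) & (xx <= x1)
        taper = np.clip((xx - x0) / 4.0, 0, 1) * np.clip((x1 - xx) / 4.0, 0, 1)
        ridge = spec.ridge_dt * np.exp(
            -((yy - poly(xx)) ** 2) / (2 * spec.ridge_sigma**2)
        )
        elevation += np.where(in_x, ridge * taper, 0.0)

    lesion_mask = None
    if spec.lesion is not None:
        field = _lesion_field(spec, yy, xx)
        if isinstance(spec.lesion, Lesion):
            lx, ly = spec.lesion.center
            if not (0 <= int(ly) < rows and 0 <= int(lx) < cols) or not body[int(ly), int(lx)]:
                raise ValueError("lesion center lies outside the body")
            # ground-truth "lesion disk": the stated radius around the center
            lesion_mask = (np.hypot(xx - lx, yy - ly) <= spec.lesion.radius) & body
        else:
            lesion_mask = (field >= 0.5 * spec.lesion.delta_t) & body
        if not lesion_mask.any():
            raise ValueError("lesion has no pixels inside the body")
        elevation += field
    temps = temps + np.where(body, elevation, 0.0)

    if spec.noise_sd > 0:
        temps = temps + rng.normal(0.0, spec.noise_sd, temps.shape)

    t_min, t_max = float(temps.min()), float(temps.max())
    meta = RadiometricMeta(t_min_c=t_min, t_max_c=t_max)
    gray = np.rint((temps - t_min) / (t_max - t_min) * 255).astype(int)
    thermogram = Thermogram(pixels=gray, meta=meta)
    thermal = ThermalMatrix(temps=temps, meta=meta)

    left_st = region_stats(thermal, seg.left_mask)
    right_st = region_stats(thermal, seg.right_mask)
    expected = compare_sides(left_st, right_st).verdict
    truth = PhantomTruth(
        body_mask=body,
        left_breast_mask=seg.left_mask,
        right_breast_mask=seg.right_mask,
        ridge_curves=curves,
        armpit_points={"right": armpits.right, "left": armpits.left},
        lesion_mask=lesion_mask,
        expected_verdict=expected,
    )
    return thermogram, thermal, truth


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


@dataclass(frozen=True)
class PhantomOutcome:
    sick: bool                       # ground truth: lesion present
    predicted: Literal["healthy", "sick", "unknown"]
    iou_left: float
    iou_right: float
    hotspot_in_lesion: bool | None   # None when not applicable
    diff_avg: float | None


@dataclass(frozen=True)
class SweepResult:
    outcomes: list[PhantomOutcome]
    table: ConfusionTable

    @property
    def segmentation_success_rate(self) -> float:
        ok = sum(o.predicted != "unknown" for o in self.outcomes)
        return ok / len(self.outcomes)

    @property
    def mean_iou(self) -> float:
        vals = [
            0.5 * (o.iou_left + o.iou_right)
            for o in self.outcomes if o.predicted != "unknown"
        ]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def hotspot_hit_rate(self) -> float:
        vals = [o.hotspot_in_lesion for o in self.outcomes if o.hotspot_in_lesion is not None]
        return float(np.mean(vals)) if vals else 0.0


def run_one(
    spec: PhantomSpec, config: PipelineConfig = PipelineConfig()
) -> PhantomOutcome:
    """Generate one phantom and push it through the full pipeline."""
    thermogram, _, truth = generate(spec)
    report = analyze(thermogram, config=config)
    if report.evaluation is None:
        return PhantomOutcome(
            sick=spec.lesion is not None,
            predicted="unknown",
            iou_left=0.0,
            iou_right=0.0,
            hotspot_in_lesion=None,
            diff_avg=None,
        )
    seg = report.segmentation
    assert seg is not None
    hit = None
    if spec.lesion is not None and report.hotspot is not None and truth.lesion_mask is not None:
        cx, cy = report.hotspot.centroid
        iy, ix = int(round(cy)), int(round(cx))
        H, W = truth.lesion_mask.shape
        hit = bool(0 <= iy < H and 0 <= ix < W and truth.lesion_mask[iy, ix])
    return PhantomOutcome(
        sick=spec.lesion is not None,
        predicted="sick" if report.evaluation.verdict == "problem_detected" else "healthy",
        iou_left=iou(seg.left_mask, truth.left_breast_mask),
        iou_right=iou(seg.right_mask, truth.right_breast_mask),
        hotspot_in_lesion=hit,
        diff_avg=report.evaluation.diff_avg,
    )


def sweep(
    n: int,
    seed: int = 0,
    lesion_fraction: float = 0.5,
    delta_t_range: tuple[float, float] = (1.5, 3.0),
    config: PipelineConfig = PipelineConfig(),
) -> SweepResult:
    """Monte-Carlo validation sweep: randomized phantoms through the pipeline.

    Half the phantoms (by default) carry a lesion with delta-T drawn uniformly
    from ``delta_t_range`` °C; outcomes are tabulated into a confusion table
    with the "unknown" column fed by segmentation failures.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    outcomes = []
    for i in range(n):
        sick = rng.random() < lesion_fraction
        dt = float(rng.uniform(*delta_t_range)) if sick else None
        spec = PhantomSpec.random(rng, lesion_delta_t=dt)
        outcomes.append(run_one(spec, config=config))
    counts = {"healthy": {"healthy": 0, "sick": 0, "unknown": 0},
              "sick": {"healthy": 0, "sick": 0, "unknown": 0}}
    for o in outcomes:
        counts["sick" if o.sick else "healthy"][o.predicted] += 1
    table = ConfusionTable(
        healthy_as_healthy=counts["healthy"]["healthy"],
        healthy_as_sick=counts["healthy"]["sick"],
        healthy_unknown=counts["healthy"]["unknown"],
        sick_as_healthy=counts["sick"]["healthy"],
        sick_as_sick=counts["sick"]["sick"],
        sick_unknown=counts["sick"]["unknown"],
    )
    return SweepResult(outcomes=outcomes, table=table)
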