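"""End-to-end screening pipeline: mask -> segment -> evaluate -> hotspot.

The hotspot stage runs only when the asymmetry rule fires; a segmentation
failure at any stage yields the "unknown" outcome rather than a crash, since
an automatic screen must report its own inability to decide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from . import io as tio
from .core import SegmentationError, ThermalMatrix, Thermogram, to_thermal
from .evaluation import EvaluationResult, evaluate
from .hotspot import HotspotResult, describe_pattern, locate_hotspot, watershed_segment
from .preprocessing import BodyMask, Rect, extract_body_mask
from .segmentation import BreastSegmentation, segment_breasts

logger = logging.getLogger("thermaseg")

VERDICT_MESSAGES = {
    "no_problem": "no problem detected",
    "problem_detected": "problem detected",
    "unknown": "unknown",
}
EXIT_CODES = {"no_problem": 0, "problem_detected": 2, "unknown": 3}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables in one place; every run logs them.

    fold_offset: gray levels below the body maximum for the fold threshold.
    slope_step_h: pixel step of the two-point secant on the armpit contour.
    basin_depth_c: h-maxima suppression depth (°C) for the watershed.
    delta_t_c: asymmetry verdict threshold (°C).
    fold_margin_px: rows excluded just above the fitted fold polynomial.
    """

    fold_offset: int = 10
    slope_step_h: int = 10
    basin_depth_c: float = 0.5
    delta_t_c: float = 1.0
    fold_margin_px: int = 4
    invert: bool = False
    scale_bar_box: Rect | None = None


@dataclass
class PipelineReport:
    input_path: str
    stages: dict = field(default_factory=dict)
    body: BodyMask | None = None
    segmentation: BreastSegmentation | None = None
    evaluation: EvaluationResult | None = None
    hotspot: HotspotResult | None = None
    hotspot_shape: dict | None = None
    message: str = "unknown"
    artifacts: list = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        if self.evaluation is None:
            return EXIT_CODES["unknown"]
        return EXIT_CODES[self.evaluation.verdict]

    def to_dict(self) -> dict:
        out = {
            "input": self.input_path,
            "stages": self.stages,
            "message": self.message,
            "artifacts": self.artifacts,
        }
        if self.evaluation is not None:
            ev = self.evaluation
            out["evaluation"] = {
                "verdict": ev.verdict,
                "hotter_side": ev.hotter_side,
                "diff_avg": round(ev.diff_avg, 4),
                "diff_max": round(ev.diff_max, 4),
                "diff_min": round(ev.diff_min, 4),
                "diff_sd": round(ev.diff_sd, 4),
                "threshold_c": ev.threshold_c,
            }
        if self.hotspot is not None:
            hs = self.hotspot
            out["hotspot"] = {
                "basin_id": hs.basin_id,
                "centroid_xy": [round(v, 2) for v in hs.centroid],
                "area_px": hs.area_px,
                "mean_temp": round(hs.mean_temp, 4),
                "max_temp": round(hs.max_temp, 4),
                "shape": self.hotspot_shape,
            }
        return out


def analyze(
    thermogram: Thermogram,
    config: PipelineConfig = PipelineConfig(),
    input_path: str = "<memory>",
) -> PipelineReport:
    """Run the full pipeline on an in-memory thermogram."""
    report = PipelineReport(input_path=input_path)
    logger.info("config: %s", config)
    try:
        body = extract_body_mask(
            thermogram, scale_bar_box=config.scale_bar_box, invert=config.invert
        )
        report.body = body
        report.stages["body_mask_px"] = int(body.mask.sum())

        seg = segment_breasts(
            thermogram,
            body,
            offset=config.fold_offset,
            h=config.slope_step_h,
            fold_margin=config.fold_margin_px,
        )
        report.segmentation = seg
        report.stages["left_px"] = int(seg.left_mask.sum())
        report.stages["right_px"] = int(seg.right_mask.sum())
        report.stages["split_xy"] = [round(seg.split_point.x, 2), round(seg.split_point.y, 2)]
        report.stages["split_low_confidence"] = bool(seg.split_point.low_confidence)
    except SegmentationError as exc:
        logger.warning("segmentation failed: %s", exc)
        report.stages["failure"] = str(exc)
        report.message = VERDICT_MESSAGES["unknown"]
        return report

    thermal = to_thermal(thermogram)
    ev = evaluate(thermal, seg, threshold_c=config.delta_t_c)
    report.evaluation = ev
    report.message = VERDICT_MESSAGES[ev.verdict]

    if ev.verdict == "problem_detected":
        side_mask = seg.left_mask if ev.hotter_side == "left" else seg.right_mask
        ws = watershed_segment(thermal, side_mask, delta=config.basin_depth_c)
        hs = locate_hotspot(thermal, ws)
        report.hotspot = hs
        report.hotspot_shape = describe_pattern(hs, ws)
        report.stages["basins"] = len(ws.basin_stats)
    return report


def run_pipeline(
    image_path: str | Path,
    sidecar_path: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineReport:
    """File-based entry point: load, analyze, write artifacts."""
    try:
        tg = tio.load_thermogram(image_path, sidecar_path)
    except (OSError, ValueError) as exc:
        report = PipelineReport(input_path=str(image_path))
        report.stages["failure"] = f"unreadable input: {exc}"
        report.message = VERDICT_MESSAGES["unknown"]
        return report
    try:
        report = analyze(tg, config=config, input_path=str(image_path))
    except SegmentationError as exc:
        report = PipelineReport(input_path=str(image_path))
        report.stages["failure"] = str(exc)
        report.message = VERDICT_MESSAGES["unknown"]
    if out_dir is not None:
        _write_artifacts(report, tg, Path(out_dir))
    return report


def _overlay_png(tg: Thermogram, hotspot: HotspotResult, path: Path) -> None:
    img = Image.fromarray(tg.pixels.astype(np.uint8), mode="L").convert("RGB")
    draw = ImageDraw.Draw(img)
    cx, cy = hotspot.centroid
    r = max(6.0, np.sqrt(hotspot.area_px / np.pi))
    draw.ellipse([cx - r, cy - r, cx + r, cy + r], outline=(255, 0, 0), width=2)
    img.save(path)


def _write_artifacts(report: PipelineReport, tg: Thermogram, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if report.body is not None:
        p = out_dir / "body_mask.png"
        tio.save_mask_png(report.body.mask, p)
        report.artifacts.append(p.name)
    if report.segmentation is not None:
        for side in ("left", "right"):
            p = out_dir / f"{side}_mask.png"
            tio.save_mask_png(getattr(report.segmentation, f"{side}_mask"), p)
            report.artifacts.append(p.name)
    if report.evaluation is not None:
        p = out_dir / "stats.csv"
        report.evaluation.to_frame().to_csv(p)
        report.artifacts.append(p.name)
    if report.hotspot is not None:
        p = out_dir / "overlay.png"
        _overlay_png(tg, report.hotspot, p)
        report.artifacts.append(p.name)
    p = out_dir / "report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    report.artifacts.append(p.name)
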