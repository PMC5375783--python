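"""Bilateral asymmetry evaluation.

A temperature difference between contralateral breast regions is the screening
signal: tumors and angiogenesis raise the local metabolic rate and skin
temperature.  With mean side temperatures T̄_left and T̄_right, the rule is

    |T̄_right - T̄_left| <  threshold  ->  no problem detected
    |T̄_right - T̄_left| >= threshold  ->  problem detected

with a 1.0 °C default threshold (literature ranges span 1–2.5 °C).  Only the
mean drives the verdict; max/min/SD differences are reported for context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .core import RegionStats, ThermalMatrix, region_stats
from .segmentation import BreastSegmentation

Verdict = Literal["no_problem", "problem_detected"]
Side = Literal["left", "right", "none"]


@dataclass(frozen=True)
class EvaluationResult:
    left: RegionStats
    right: RegionStats
    diff_avg: float
    diff_max: float
    diff_min: float
    diff_sd: float
    verdict: Verdict
    hotter_side: Side
    threshold_c: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        """Per-side statistics table (rows Average/Max/Min/SD, °C, 2 decimals)."""
        rows = {
            "Average": (self.left.avg, self.right.avg, self.diff_avg),
            "Max": (self.left.max, self.right.max, self.diff_max),
            "Min": (self.left.min, self.right.min, self.diff_min),
            "SD": (self.left.sd, self.right.sd, self.diff_sd),
        }
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["Left", "Right", "Difference"]
        )
        return df.round(2)

    def verdict_json(self) -> str:
        return json.dumps(
            {
                "verdict": self.verdict,
                "hotter_side": self.hotter_side,
                "diff_avg": round(self.diff_avg, 4),
            }
        )


def compare_sides(
    left: RegionStats, right: RegionStats, threshold_c: float = 1.0
) -> EvaluationResult:
    """Apply the asymmetry rule to per-side statistics."""
    diff_avg = abs(left.avg - right.avg)
    problem = diff_avg >= threshold_c
    if problem:
        hotter: Side = "left" if left.avg > right.avg else "right"
    else:
        hotter = "none"
    return EvaluationResult(
        left=left,
        right=right,
        diff_avg=diff_avg,
        diff_max=abs(left.max - right.max),
        diff_min=abs(left.min - right.min),
        diff_sd=abs(left.sd - right.sd),
        verdict="problem_detected" if problem else "no_problem",
        hotter_side=hotter,
        threshold_c=threshold_c,
    )


def evaluate(
    thermal: ThermalMatrix, seg: BreastSegmentation, threshold_c: float = 1.0
) -> EvaluationResult:
    """Compute per-side statistics on the thermal matrix and apply the rule."""
    left = region_stats(thermal, seg.left_mask)
    right = region_stats(thermal, seg.right_mask)
    return compare_sides(left, right, threshold_c=threshold_c)
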