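"""Screening-performance bookkeeping.

A screening run classifies each truly healthy or sick case as healthy, sick,
or *unknown* (the automatic segmentation failed and no verdict was issued).
Rates are computed over the resolved (non-unknown) cases only; the unknown
rate is reported separately, since an automatic tool's refusals are a
first-class outcome, not an error term.

Values are truncated (not rounded) to 4 decimals, matching conventions such
as reporting 5/23 = 0.21739... as 0.2173.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


def _trunc4(x: float) -> float:
    return math.floor(round(x * 10000, 6)) / 10000


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of classified outcomes per true class."""

    healthy_as_healthy: int
    healthy_as_sick: int
    healthy_unknown: int
    sick_as_healthy: int
    sick_as_sick: int
    sick_unknown: int

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return (self.healthy_as_healthy + self.healthy_as_sick + self.healthy_unknown
                + self.sick_as_healthy + self.sick_as_sick + self.sick_unknown)

    def to_frame(self) -> pd.DataFrame:
        h_tot = self.healthy_as_healthy + self.healthy_as_sick + self.healthy_unknown
        s_tot = self.sick_as_healthy + self.sick_as_sick + self.sick_unknown
        return pd.DataFrame(
            {
                "Healthy": [self.healthy_as_healthy, self.sick_as_healthy],
                "Sick": [self.healthy_as_sick, self.sick_as_sick],
                "Unknown": [self.healthy_unknown, self.sick_unknown],
            },
            index=[f"Healthy ({h_tot})", f"Sick ({s_tot})"],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionTable":
        """Read the tabular layout written by :meth:`to_frame`."""
        df = pd.read_csv(path, index_col=0)
        rows = {str(i).split(" ")[0].lower(): r for i, r in df.iterrows()}
        return cls(
            healthy_as_healthy=int(rows["healthy"]["Healthy"]),
            healthy_as_sick=int(rows["healthy"]["Sick"]),
            healthy_unknown=int(rows["healthy"]["Unknown"]),
            sick_as_healthy=int(rows["sick"]["Healthy"]),
            sick_as_sick=int(rows["sick"]["Sick"]),
            sick_unknown=int(rows["sick"]["Unknown"]),
        )


def screening_metrics(table: ConfusionTable) -> dict[str, float]:
    """Sensitivity, specificity, FPR, FNR, per-class match and unknown rate.

    tpr (sensitivity) = sick->sick / resolved sick; fpr = healthy->sick /
    resolved healthy; fnr = 1 - tpr; specificity = 1 - fpr; per-class match is
    the resolved diagonal fraction; mean_match is the unweighted mean of the
    two per-class matches; unknown_rate = unknowns / all cases.  All values
    truncated to 4 decimals.
    """
    res_h = table.healthy_as_healthy + table.healthy_as_sick
    res_s = table.sick_as_healthy + table.sick_as_sick
    if res_h == 0 or res_s == 0:
        raise ValueError("need at least one resolved case per class")
    tpr = _trunc4(table.sick_as_sick / res_s)
    fpr = _trunc4(table.healthy_as_sick / res_h)
    fnr = _trunc4(table.sick_as_healthy / res_s)
    specificity = _trunc4(table.healthy_as_healthy / res_h)
    match_h = _trunc4(table.healthy_as_healthy / res_h)
    match_s = _trunc4(table.sick_as_sick / res_s)
    return {
        "tpr": tpr,
        "fpr": fpr,
        "fnr": fnr,
        "specificity": specificity,
        "per_class_match": {"healthy": match_h, "sick": match_s},
        "mean_match": (match_h + match_s) / 2,
        "unknown_rate": _trunc4((table.healthy_unknown + table.sick_unknown) / table.total),
    }
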