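"""Adaptive-optics arteriolar wall morphometry.

Works from per-ROI outer (total vessel) and inner (lumen) diameter
measurements — three 100-um regions of interest per arteriole — and
derives the wall metrics:

    WT   = (TVD - LD) / 2          mean single-wall thickness, um
    WLR  = (TVD - LD) / LD         wall-to-lumen ratio (two walls / lumen)
    WCSA = (pi/4) (TVD^2 - LD^2)   wall cross-sectional area, um^2

Per-ROI metrics are derived first and then averaged across the ROIs
(mean of per-ROI ratios, not the ratio of mean diameters).  The WLR uses
the two-wall convention (TVD - LD)/LD = 2 WT / LD: it is the one
consistent with clinical AO software output, where e.g. TVD 100.341 um
and LD 81.085 um give WLR 0.237 (whereas single-wall WT/LD would give
0.119).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .faz import AxialLengthCorrection

__all__ = [
    "AoRoiMeasurement",
    "AoVesselMetrics",
    "derive_wall_metrics",
    "aggregate_rois",
    "ao_axial_length_adjust",
]


@dataclass(frozen=True)
class AoRoiMeasurement:
    """One ROI's total-vessel and lumen diameter pair (um)."""

    tvd_um: float
    ld_um: float
    roi_index: int = 1

    def __post_init__(self) -> None:
        if not self.tvd_um > self.ld_um > 0:
            raise ValueError(
                f"need TVD > LD > 0, got TVD={self.tvd_um}, LD={self.ld_um}"
            )


@dataclass(frozen=True)
class AoVesselMetrics:
    tvd_um: float
    ld_um: float
    wt_um: float
    wlr: float
    wcsa_um2: float
    n_rois: int = 1
    al_adjusted: bool = False


def derive_wall_metrics(roi: AoRoiMeasurement) -> AoVesselMetrics:
    """Wall metrics of a single ROI from its TVD/LD pair."""
    tvd, ld = roi.tvd_um, roi.ld_um
    wt = (tvd - ld) / 2.0
    wlr = (tvd - ld) / ld
    wcsa = (math.pi / 4.0) * (tvd * tvd - ld * ld)
    return AoVesselMetrics(tvd_um=tvd, ld_um=ld, wt_um=wt, wlr=wlr, wcsa_um2=wcsa)


def aggregate_rois(rois: Sequence[AoRoiMeasurement]) -> AoVesselMetrics:
    """Average per-ROI derived metrics over (nominally three) ROIs.

    Each parameter is derived per ROI first and then arithmetically
    averaged, so the aggregate WLR is the mean of per-ROI WLRs rather
    than the WLR of mean diameters.
    """
    if len(rois) == 0:
        raise ValueError("at least one ROI measurement is required")
    if len(rois) != 3:
        warnings.warn(
            f"expected 3 ROIs per vessel, got {len(rois)}; averaging what is given",
            stacklevel=2,
        )
    per = [derive_wall_metrics(r) for r in rois]
    n = len(per)
    return AoVesselMetrics(
        tvd_um=sum(m.tvd_um for m in per) / n,
        ld_um=sum(m.ld_um for m in per) / n,
        wt_um=sum(m.wt_um for m in per) / n,
        wlr=sum(m.wlr for m in per) / n,
        wcsa_um2=sum(m.wcsa_um2 for m in per) / n,
        n_rois=n,
    )


def ao_axial_length_adjust(
    metrics: AoVesselMetrics, correction: AxialLengthCorrection
) -> AoVesselMetrics:
    """Scale AO metrics for ocular magnification.

    Lengths (TVD, LD, WT) scale by the linear factor, areas (WCSA) by its
    square; WLR is a ratio of lengths and is left untouched.
    """
    f = correction.linear_factor
    return AoVesselMetrics(
        tvd_um=metrics.tvd_um * f,
        ld_um=metrics.ld_um * f,
        wt_um=metrics.wt_um * f,
        wlr=metrics.wlr,
        wcsa_um2=metrics.wcsa_um2 * f * f,
        n_rois=metrics.n_rois,
        al_adjusted=True,
    )
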