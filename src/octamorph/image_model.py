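"""Calibrated en-face raster model, polygon rasterization and table I/O.

Coordinate convention used throughout the package: pixel (col=x, row=y),
0-based indices, with the *center* of pixel (row, col) at continuous
coordinates (x, y) = (col + 0.5, row + 0.5).  All geometric predicates
(point-in-polygon, disc membership) are evaluated at pixel centers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely

__all__ = [
    "EnFaceAngiogram",
    "ScanMetadata",
    "PolygonOutline",
    "GROUPS",
    "load_enface_image",
    "rescale_intensity",
    "rgb_to_gray",
    "rasterize_polygon",
    "load_polygon",
    "write_metrics_table",
    "read_metrics_table",
]

#: The four study group labels, in severity order.
GROUPS = ("control", "no_DR", "NPDR", "PDR")

#: Rec. 601 luminance weights used for RGB -> gray collapse.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class EnFaceAngiogram:
    """A calibrated square en-face angiogram.

    The standard acquisition is a 4.5 x 4.5 mm field sampled as 320 x 320
    pixels, giving a pixel pitch of 0.0140625 mm/px.  Intensities are
    min-max rescaled to [0, 1] on load.
    """

    pixels: np.ndarray
    extent_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale grid, got ndim={px.ndim}")
        if px.shape[0] != px.shape[1]:
            raise ValueError(f"en-face frame must be square, got shape {px.shape}")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ValueError("intensities must lie in [0, 1]; rescale on load")
        object.__setattr__(self, "pixels", px)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one pixel (mm/px) = extent_mm / width_px."""
        return self.extent_mm / self.width_px


@dataclass(frozen=True)
class ScanMetadata:
    """Per-eye scan metadata feeding the metrics table."""

    eye_id: str
    group: str
    axial_length_mm: float
    laterality: str = "right"
    bcva: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 15.0 < self.axial_length_mm < 35.0:
            raise ValueError(
                f"axial length {self.axial_length_mm} mm outside plausible (15, 35) range"
            )
        if self.laterality not in ("right", "left"):
            raise ValueError("laterality must be 'right' or 'left'")
        if not 0 < self.bcva <= 1:
            raise ValueError("decimal BCVA must lie in (0, 1]")


@dataclass(frozen=True)
class PolygonOutline:
    """Closed polygon given as an ordered (x, y) vertex list in pixel coords.

    Sub-pixel vertices are allowed; the last vertex implicitly joins the
    first.  Used to carry the manually drawn FAZ outline.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon outline is self-intersecting or degenerate")
        return poly


def rgb_to_gray(px: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to luminance with Rec. 601 weights."""
    if px.ndim == 2:
        return px.astype(float)
    if px.ndim == 3 and px.shape[2] in (3, 4):
        r, g, b = (px[..., i].astype(float) for i in range(3))
        w = LUMA_WEIGHTS
        return w[0] * r + w[1] * g + w[2] * b
    raise ValueError(f"cannot interpret raster of shape {px.shape} as an image")


def rescale_intensity(px: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a flat image maps to all-zero (idempotent)."""
    px = np.asarray(px, dtype=float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def load_enface_image(path: str | Path, extent_mm: float = 4.5) -> EnFaceAngiogram:
    """Read a PNG/TIFF en-face frame and wrap it as a calibrated angiogram.

    RGB input is collapsed to luminance; intensities are min-max rescaled
    to [0, 1].  Non-square frames are rejected.
    """
    if extent_mm <= 0:
        raise ValueError("extent_mm must be positive")
    raw = iio.imread(path)
    gray = rescale_intensity(rgb_to_gray(np.asarray(raw)))
    return EnFaceAngiogram(pixels=gray, extent_mm=extent_mm)


def rasterize_polygon(outline: PolygonOutline, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon to a boolean mask.

    A pixel is foreground iff its center (col+0.5, row+0.5) lies inside the
    closed polygon; centers exactly on the boundary count as inside
    (``shapely.covers`` semantics).
    """
    poly = outline.as_shapely()
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = shapely.points(cols.ravel() + 0.5, rows.ravel() + 0.5)
    inside = shapely.covers(poly, pts).reshape(h, w)
    if not inside.any():
        warnings.warn("polygon covers no pixel centers; mask is empty", stacklevel=2)
    return inside


def load_polygon(path: str | Path) -> PolygonOutline:
    """Read a FAZ outline from a JSON vertex list or ImageJ-style XY text.

    JSON form: ``[[x, y], ...]`` or ``{"vertices": [[x, y], ...]}``.
    Text form: one ``x<whitespace>y`` pair per line (ImageJ XY export).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith(("[", "{")):
        obj = json.loads(text)
        verts = obj["vertices"] if isinstance(obj, dict) else obj
        return PolygonOutline(tuple((v[0], v[1]) for v in verts))
    verts = []
    for line in text.splitlines():
        parts = line.replace(",", " ").split()
        if len(parts) >= 2:
            verts.append((float(parts[0]), float(parts[1])))
    return PolygonOutline(tuple(verts))


def write_metrics_table(records: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write per-eye metric records to CSV, one row per eye, full precision."""
    if len(records) == 0:
        raise ValueError("no records to write")
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
    return df


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
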