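"""Orchestration of the per-eye analyses and the cohort statistics stage.

`run_octa_eye` executes the full en-face workflow in order: rasterize the
drawn FAZ polygon -> centroid -> 3-mm analysis disc -> FAZ morphometry
(with axial-length adjustment) -> mask the FAZ out -> Frangi vesselness
-> Phansalkar binarization -> vessel density -> skeletonize -> vessel
length density -> box-counting fractal dimension.  `run_ao_eye` averages
per-ROI wall metrics; `run_cohort` runs the group comparison over the
standard parameter set.  `run_batch` drives a manifest of eyes,
quarantining per-eye failures without aborting the batch.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ao as ao_mod
from .cohort_stats import run_full_comparison, render_pairwise_table
from .enhancement import (ThresholdParams, VesselnessParams, frangi_vesselness,
                          invert_vesselness, phansalkar_threshold)
from .faz import (DEFAULT_REFERENCE_AL_MM, axial_length_correction,
                  crop_analysis_disc, delineate_faz)
from .image_model import (EnFaceAngiogram, PolygonOutline, ScanMetadata,
                          load_enface_image, load_polygon)
from .perfusion import measure_perfusion

__all__ = ["PipelineConfig", "run_octa_eye", "run_ao_eye", "run_cohort", "run_batch",
           "COHORT_PARAMETERS"]

log = logging.getLogger("octamorph")

#: The vascular parameters compared across groups (the published set plus BCVA).
COHORT_PARAMETERS = (
    "faz_area_mm2", "faz_perimeter_mm", "faz_circularity",
    "scp_density_pct", "vld_pct", "fd",
    "tvd_um", "ld_um", "wt_um", "wlr", "wcsa_um2",
    "bcva",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the per-eye and cohort stages, with defaults."""

    extent_mm: float = 4.5
    disc_diameter_mm: float = 3.0
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM
    perimeter_weights: str = "corner"
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    apply_inversion: bool = False
    skeleton_length: str = "count"
    fd_box_sizes: tuple[int, ...] | None = None
    stats_alpha: float = 0.05
    dunn_adjust: str = "bonferroni"
    adjust_ao_for_axial_length: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a TOML config; unknown keys are rejected."""
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        if "vesselness" in raw:
            v = raw.pop("vesselness")
            if "scales" in v:
                v["scales"] = tuple(v["scales"])
            kwargs["vesselness"] = VesselnessParams(**v)
        if "threshold" in raw:
            kwargs["threshold"] = ThresholdParams(**raw.pop("threshold"))
        if "fd_box_sizes" in raw:
            raw["fd_box_sizes"] = tuple(raw["fd_box_sizes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def log_header(self) -> None:
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))


def run_octa_eye(
    image: EnFaceAngiogram | str | Path,
    faz_outline: PolygonOutline | str | Path,
    metadata: ScanMetadata,
    config: PipelineConfig | None = None,
    debug_dir: str | Path | None = None,
) -> dict:
    """Full per-eye en-face analysis; returns the per-eye metric record."""
    cfg = config or PipelineConfig()
    if not isinstance(image, EnFaceAngiogram):
        image = load_enface_image(image, extent_mm=cfg.extent_mm)
    if not isinstance(faz_outline, PolygonOutline):
        faz_outline = load_polygon(faz_outline)

    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        faz = delineate_faz(
            faz_outline, image,
            axial_length_mm=metadata.axial_length_mm,
            reference_al_mm=cfg.reference_al_mm,
            perimeter_weights=cfg.perimeter_weights,
        )
        log.info("eye %s: FAZ area %.4f mm^2, perimeter %.4f mm, circularity %.4f",
                 metadata.eye_id, faz.area_mm2, faz.perimeter_mm, faz.circularity)
        region = crop_analysis_disc(image, faz.centroid_px,
                                    diameter_mm=cfg.disc_diameter_mm,
                                    excluded_mask=faz.mask)
        vesselness = frangi_vesselness(image.pixels, cfg.vesselness)
        if cfg.apply_inversion:
            # mirror of the display pipeline: binarize 1 - v with dark polarity
            vesselness = invert_vesselness(vesselness)
            vessel_mask = ~phansalkar_threshold(vesselness, cfg.threshold) \
                & region.effective_mask
        else:
            vessel_mask = phansalkar_threshold(vesselness, cfg.threshold,
                                               region.effective_mask)
        perfusion = measure_perfusion(vessel_mask, region,
                                      skeleton_length=cfg.skeleton_length,
                                      box_sizes=cfg.fd_box_sizes)
    flags.extend(str(w.message) for w in caught)

    if debug_dir is not None:
        import imageio.v3 as iio
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(debug_dir / f"{metadata.eye_id}_vesselness.png",
                    (vesselness * 255).astype(np.uint8))
        iio.imwrite(debug_dir / f"{metadata.eye_id}_binary.png",
                    vessel_mask.astype(np.uint8) * 255)

    log.info("eye %s: VD %.4f, VLD %.4f, FD %.4f", metadata.eye_id,
             perfusion.vessel_density, perfusion.vessel_length_density,
             perfusion.fractal_dimension)
    return {
        "eye_id": metadata.eye_id,
        "group": metadata.group,
        "axial_length_mm": metadata.axial_length_mm,
        "faz_area_mm2": faz.area_mm2,
        "faz_perimeter_mm": faz.perimeter_mm,
        "faz_circularity": faz.circularity,
        "faz_area_mm2_adjusted": faz.area_mm2_adjusted,
        "faz_perimeter_mm_adjusted": faz.perimeter_mm_adjusted,
        "scp_density_pct": 100.0 * perfusion.vessel_density,
        "vld_pct": 100.0 * perfusion.vessel_length_density,
        "fd": perfusion.fractal_dimension,
        "effective_area_px": perfusion.effective_area_px,
        "clipped_fraction": region.clipped_fraction,
        "flags": "; ".join(flags),
    }


def run_ao_eye(
    roi_rows: pd.DataFrame,
    metadata: ScanMetadata | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Aggregate one eye's per-ROI TVD/LD rows into wall metrics."""
    cfg = config or PipelineConfig()
    rois = [
        ao_mod.AoRoiMeasurement(tvd_um=float(r.tvd_um), ld_um=float(r.ld_um),
                                roi_index=int(getattr(r, "roi_index", i + 1)))
        for i, r in enumerate(roi_rows.itertuples())
    ]
    metrics = ao_mod.aggregate_rois(rois)
    if cfg.adjust_ao_for_axial_length and metadata is not None:
        corr = axial_length_correction(metadata.axial_length_mm, cfg.reference_al_mm)
        metrics = ao_mod.ao_axial_length_adjust(metrics, corr)
    rec = {
        "tvd_um": metrics.tvd_um, "ld_um": metrics.ld_um, "wt_um": metrics.wt_um,
        "wlr": metrics.wlr, "wcsa_um2": metrics.wcsa_um2, "n_rois": metrics.n_rois,
        "ao_al_adjusted": metrics.al_adjusted,
    }
    if metadata is not None:
        rec = {"eye_id": metadata.eye_id, "group": metadata.group, **rec}
    return rec


def run_cohort(
    table: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    parameters: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Group comparison over the standard parameter set; long-format table."""
    cfg = config or PipelineConfig()
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    params = parameters or tuple(p for p in COHORT_PARAMETERS if p in table.columns)
    missing = [p for p in (parameters or ()) if p not in table.columns]
    if missing:
        raise KeyError(f"metric columns missing from table: {missing}")
    report = run_full_comparison(table, params, alpha=cfg.stats_alpha,
                                 dunn_adjust=cfg.dunn_adjust)
    return render_pairwise_table(report)


def run_batch(
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Analyze every eye in a manifest (eye_id, image, polygon, group,
    axial_length_mm); failed eyes are quarantined and listed, not fatal."""
    cfg = config or PipelineConfig()
    records, failed = [], []
    for row in manifest.itertuples():
        meta = ScanMetadata(eye_id=str(row.eye_id), group=str(row.group),
                            axial_length_mm=float(row.axial_length_mm))
        try:
            records.append(run_octa_eye(row.image, row.polygon, meta, cfg))
        except Exception as exc:  # noqa: BLE001 - quarantine, keep the batch alive
            log.error("eye %s failed: %s", row.eye_id, exc)
            failed.append(str(row.eye_id))
    return pd.DataFrame(records), failed
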