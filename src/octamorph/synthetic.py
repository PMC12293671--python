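"""Synthetic stand-ins for the study's patient data.

Three generators, all fully deterministic under a seed:

* a vascular angiogram phantom — a 320 x 320, 4.5 mm en-face frame with a
  central avascular zone (radially perturbed circle) and a space-filling
  branching capillary network grown to a controllable vessel density,
  returned together with its ground-truth masks;
* a degradation operator emulating retinopathy-like capillary dropout and
  avascular-zone boundary irregularity;
* a cohort generator drawing per-eye metric records for the four study
  groups (control / no DR / NPDR / PDR; 17/14/18/20 eyes) from the
  published group means and SDs, via truncated Gaussians respecting each
  metric's domain.

The angiogram phantom emulates the geometry and first-order statistics of
an en-face capillary image (tubular bright structures of ~1-3 px caliber,
an avascular zone, additive noise) but not OCTA speckle, projection
artifacts, or real capillary anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .faz import compute_centroid, crop_analysis_disc
from .image_model import GROUPS, EnFaceAngiogram, PolygonOutline, rasterize_polygon
from .perfusion import skeletonize

__all__ = [
    "VascularPhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "TABLE_PARAMS",
    "GROUP_SIZES",
    "generate_vascular_phantom",
    "degrade_phantom",
    "generate_cohort",
    "generate_ao_roi_table",
]

#: Published per-group cohort sizes (eyes).
GROUP_SIZES = {"control": 17, "no_DR": 14, "NPDR": 18, "PDR": 20}

#: Per-metric (mean, SD) by group, with the sampling domain of each metric.
#: OCTA densities are percentages as reported; FD is the box-counting slope.
TABLE_PARAMS: dict[str, dict] = {
    "faz_area_mm2": {
        "control": (0.226, 0.100), "no_DR": (0.214, 0.060),
        "NPDR": (0.248, 0.084), "PDR": (0.248, 0.087),
        "bounds": (0.01, np.inf),
    },
    "faz_perimeter_mm": {
        "control": (1.774, 0.446), "no_DR": (1.772, 0.293),
        "NPDR": (1.933, 0.354), "PDR": (1.958, 0.378),
        "bounds": (0.1, np.inf),
    },
    "faz_circularity": {
        "control": (0.853, 0.028), "no_DR": (0.845, 0.054),
        "NPDR": (0.816, 0.062), "PDR": (0.792, 0.081),
        "bounds": (0.0, 1.0),
    },
    "scp_density_pct": {
        "control": (37.693, 1.950), "no_DR": (38.274, 3.799),
        "NPDR": (35.685, 3.455), "PDR": (34.338, 3.670),
        "bounds": (0.0, 100.0),
    },
    "vld_pct": {
        "control": (29.385, 1.711), "no_DR": (29.586, 3.020),
        "NPDR": (27.049, 2.837), "PDR": (25.971, 2.992),
        "bounds": (0.0, 100.0),
    },
    "fd": {
        "control": (1.771, 0.009), "no_DR": (1.770, 0.013),
        "NPDR": (1.753, 0.018), "PDR": (1.745, 0.018),
        "bounds": (1.0, 2.0),
    },
    "ld_um": {
        "control": (81.085, 16.323), "no_DR": (68.542, 12.510),
        "NPDR": (73.820, 25.796), "PDR": (60.787, 17.906),
        "bounds": (10.0, np.inf),
    },
    "wlr": {
        "control": (0.237, 0.048), "no_DR": (0.305, 0.054),
        "NPDR": (0.320, 0.080), "PDR": (0.390, 0.090),
        "bounds": (0.01, np.inf),
    },
    "bcva": {
        "control": (0.976, 0.007), "no_DR": (0.921, 0.142),
        "NPDR": (0.916, 0.133), "PDR": (0.685, 0.271),
        "bounds": (0.05, 1.0),
    },
    "axial_length_mm": {
        "control": (23.68, 1.00), "no_DR": (23.89, 0.79),
        "NPDR": (23.34, 0.38), "PDR": (23.42, 0.74),
        "bounds": (15.1, 34.9),
    },
    "age_years": {
        "control": (52.29, 13.13), "no_DR": (54.07, 21.36),
        "NPDR": (50.27, 12.31), "PDR": (56.0, 13.33),
        "bounds": (18.0, 100.0),
    },
}


# --------------------------------------------------------------------------
# vascular phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VascularPhantomSpec:
    """Parameters of the angiogram phantom.

    Defaults emulate a healthy-eye acquisition: the standard 4.5 mm /
    320 px field, an avascular zone of ~0.27 mm mean radius (area ~0.23
    mm^2) with mild boundary irregularity, mean capillary caliber ~2.5 px
    (~35 um), and a target in-region vessel density of 0.35.
    """

    seed: int = 0
    frame_px: int = 320
    extent_mm: float = 4.5
    faz_radius_mm: float = 0.27
    faz_irregularity: float = 0.06
    n_seed_vessels: int = 24
    branching_prob: float = 0.08
    vessel_width_px: float = 2.5
    target_density: float = 0.35
    noise_sigma: float = 0.05
    dropout_fraction: float = 0.0
    disc_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        for name in ("branching_prob", "target_density", "dropout_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.target_density > 0.85:
            raise ValueError("target_density > 0.85 is not reachable by the growth model")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a phantom frame."""

    vessel_mask: np.ndarray
    faz_mask: np.ndarray
    true_skeleton: np.ndarray
    true_density: float
    faz_polygon: PolygonOutline
    branches: tuple[np.ndarray, ...]          # centerline polylines, (n, 2) row/col
    spec: VascularPhantomSpec


def _faz_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius_px: float,
    irregularity: float,
    n_vertices: int = 180,
    harmonics: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
) -> PolygonOutline:
    """Radial-Fourier-perturbed circle: r(t) = r0 (1 + sum a_k cos(k t + p_k))."""
    amps = rng.uniform(0.3, 1.0, size=len(harmonics))
    amps *= irregularity / amps.sum() if amps.sum() > 0 else 0.0
    phases = rng.uniform(0, 2 * math.pi, size=len(harmonics))
    t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    r = radius_px * (1.0 + sum(a * np.cos(k * t + p)
                               for a, k, p in zip(amps, harmonics, phases)))
    r = np.maximum(r, 1.0)
    xs = center[0] + r * np.cos(t)
    ys = center[1] + r * np.sin(t)
    return PolygonOutline(tuple(zip(xs, ys)))


def _stamp_offsets(width_px: float) -> np.ndarray:
    """Integer offsets of a disc stamp of diameter ``width_px``."""
    r = max(width_px / 2.0, 0.5)
    n = int(math.ceil(r))
    dr, dc = np.mgrid[-n:n + 1, -n:n + 1]
    keep = dr ** 2 + dc ** 2 <= r ** 2
    return np.stack([dr[keep], dc[keep]], axis=1)


def _grow_network(
    rng: np.random.Generator,
    spec: VascularPhantomSpec,
    faz_mask: np.ndarray,
    effective_mask: np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Grow branching centerlines until the effective region reaches the
    target density; returns (branch polylines, dilated vessel mask)."""
    n = spec.frame_px
    canvas = np.zeros((n, n), dtype=bool)
    offsets = _stamp_offsets(spec.vessel_width_px)
    n_eff = int(effective_mask.sum())
    target_count = int(round(spec.target_density * n_eff))
    covered = 0
    branches: list[np.ndarray] = []
    max_branch_steps = 300
    center = np.array([n / 2.0, n / 2.0])

    def stamp(r: int, c: int) -> int:
        nonlocal covered
        rr = offsets[:, 0] + r
        cc = offsets[:, 1] + c
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        rr, cc = rr[ok], cc[ok]
        new = ~canvas[rr, cc]
        canvas[rr[new], cc[new]] = True
        return int(effective_mask[rr[new], cc[new]].sum())

    def spawn_edge_walker() -> tuple[np.ndarray, np.ndarray]:
        side = rng.integers(4)
        u = rng.uniform(0, n)
        pos = {0: [0.0, u], 1: [n - 1.0, u], 2: [u, 0.0], 3: [u, n - 1.0]}[int(side)]
        pos = np.asarray(pos, float)
        aim = center + rng.normal(0, n / 6.0, size=2)
        d = aim - pos
        return pos, d / np.linalg.norm(d)

    queue: list[tuple[np.ndarray, np.ndarray]] = [
        spawn_edge_walker() for _ in range(spec.n_seed_vessels)
    ]
    guard = 0
    while covered < target_count:
        guard += 1
        if guard > 50_000:
            raise RuntimeError(
                f"growth stalled at density {covered / n_eff:.3f} "
                f"(target {spec.target_density})"
            )
        if not queue:
            # re-seed from a random point on the existing network (or an edge)
            ridx, cidx = np.nonzero(canvas)
            if ridx.size:
                j = int(rng.integers(ridx.size))
                pos = np.array([float(ridx[j]), float(cidx[j])])
                ang = rng.uniform(0, 2 * math.pi)
                queue.append((pos, np.array([math.sin(ang), math.cos(ang)])))
            else:
                queue.append(spawn_edge_walker())
        pos, direction = queue.pop()
        poly = [pos.copy()]
        for _ in range(max_branch_steps):
            direction = direction + rng.normal(0, 0.35, size=2)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < n and 0 <= c < n) or faz_mask[r, c]:
                break
            poly.append(pos.copy())
            covered += stamp(r, c)
            if covered >= target_count:
                break
            if rng.random() < spec.branching_prob:
                ang = math.radians(rng.uniform(25, 65)) * (1 if rng.random() < 0.5 else -1)
                rot = np.array([[math.cos(ang), -math.sin(ang)],
                                [math.sin(ang), math.cos(ang)]])
                queue.append((pos.copy(), rot @ direction))
        if len(poly) > 1:
            branches.append(np.asarray(poly))
    return branches, canvas


def _render_mask(branches: list[np.ndarray], frame_px: int, width_px: float) -> np.ndarray:
    canvas = np.zeros((frame_px, frame_px), dtype=bool)
    offsets = _stamp_offsets(width_px)
    for poly in branches:
        pts = np.round(poly).astype(int)
        for r, c in pts:
            rr = offsets[:, 0] + r
            cc = offsets[:, 1] + c
            ok = (rr >= 0) & (rr < frame_px) & (cc >= 0) & (cc < frame_px)
            canvas[rr[ok], cc[ok]] = True
    return canvas


def _render_intensity(
    rng: np.random.Generator, vessel_mask: np.ndarray, noise_sigma: float,
    blur_sigma: float = 0.8,
) -> np.ndarray:
    img = ndimage.gaussian_filter(vessel_mask.astype(float), blur_sigma)
    img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _truth_from(
    spec: VascularPhantomSpec,
    faz_poly: PolygonOutline,
    branches: list[np.ndarray],
    vessel_mask: np.ndarray,
) -> PhantomTruth:
    n = spec.frame_px
    faz_mask = rasterize_polygon(faz_poly, (n, n))
    frame = EnFaceAngiogram(pixels=np.zeros((n, n)), extent_mm=spec.extent_mm)
    region = crop_analysis_disc(frame, compute_centroid(faz_mask),
                                diameter_mm=spec.disc_diameter_mm,
                                excluded_mask=faz_mask)
    eff = region.effective_mask
    vessel = vessel_mask & ~faz_mask
    density = float((vessel & eff).sum()) / int(eff.sum())
    return PhantomTruth(
        vessel_mask=vessel,
        faz_mask=faz_mask,
        true_skeleton=skeletonize(vessel),
        true_density=density,
        faz_polygon=faz_poly,
        branches=tuple(branches),
        spec=spec,
    )


def generate_vascular_phantom(
    spec: VascularPhantomSpec | None = None,
) -> tuple[EnFaceAngiogram, PhantomTruth]:
    """Grow a synthetic en-face angiogram with known ground truth.

    Seed vessels enter from the frame edges and random-walk with momentum,
    branching stochastically and terminating at the avascular zone;
    centerlines are dilated to the mean caliber and growth stops when the
    3-mm-disc-minus-FAZ coverage reaches the target density.  The
    intensity frame is the blurred vessel mask plus Gaussian noise; truth
    masks are returned pre-noise.
    """
    if spec is None:
        spec = VascularPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.frame_px
    pitch = spec.extent_mm / n
    center = (n / 2.0, n / 2.0)
    faz_poly = _faz_polygon(rng, center, spec.faz_radius_mm / pitch,
                            spec.faz_irregularity)
    faz_mask = rasterize_polygon(faz_poly, (n, n))
    frame0 = EnFaceAngiogram(pixels=np.zeros((n, n)), extent_mm=spec.extent_mm)
    region = crop_analysis_disc(frame0, compute_centroid(faz_mask),
                                diameter_mm=spec.disc_diameter_mm,
                                excluded_mask=faz_mask)
    branches, canvas = _grow_network(rng, spec, faz_mask, region.effective_mask)
    if spec.dropout_fraction > 0:
        keep = rng.random(len(branches)) >= spec.dropout_fraction
        branches = [b for b, k in zip(branches, keep) if k]
        canvas = _render_mask(branches, n, spec.vessel_width_px)
    truth = _truth_from(spec, faz_poly, branches, canvas)
    img = _render_intensity(rng, truth.vessel_mask, spec.noise_sigma)
    return EnFaceAngiogram(pixels=img, extent_mm=spec.extent_mm), truth


def degrade_phantom(
    truth: PhantomTruth,
    dropout_fraction: float,
    irregularity_boost: float = 0.0,
    seed: int = 0,
) -> tuple[EnFaceAngiogram, PhantomTruth]:
    """Retinopathy-like degradation of an existing phantom.

    Deletes a seeded random subset of branches (capillary dropout) and
    optionally re-perturbs the avascular-zone boundary with extra radial
    harmonics (reduced circularity), then re-renders the intensity frame.
    """
    if not 0 <= dropout_fraction <= 1:
        raise ValueError("dropout_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spec = truth.spec
    keep = rng.random(len(truth.branches)) >= dropout_fraction
    branches = [b for b, k in zip(truth.branches, keep) if k]
    faz_poly = truth.faz_polygon
    if irregularity_boost > 0:
        verts = np.asarray(faz_poly.vertices)
        cx, cy = verts[:, 0].mean(), verts[:, 1].mean()
        dx, dy = verts[:, 0] - cx, verts[:, 1] - cy
        r = np.hypot(dx, dy)
        t = np.arctan2(dy, dx)
        # higher frequencies than the base shape (3-8): localized notching,
        # which cannot phase-cancel the existing low-order perturbation
        harmonics = (9, 10, 11, 12, 13, 14)
        amps = rng.uniform(0.3, 1.0, size=len(harmonics))
        amps *= irregularity_boost / amps.sum()
        phases = rng.uniform(0, 2 * math.pi, size=len(harmonics))
        r = r * (1.0 + sum(a * np.cos(k * t + p)
                           for a, k, p in zip(amps, harmonics, phases)))
        r = np.maximum(r, 1.0)
        faz_poly = PolygonOutline(tuple(zip(cx + r * np.cos(t), cy + r * np.sin(t))))
    canvas = _render_mask(branches, spec.frame_px, spec.vessel_width_px)
    new_truth = _truth_from(spec, faz_poly, branches, canvas)
    img = _render_intensity(rng, new_truth.vessel_mask, spec.noise_sigma)
    return EnFaceAngiogram(pixels=img, extent_mm=spec.extent_mm), new_truth


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort sampling plan: group sizes plus per-group metric means/SDs.

    AO diameters are generated self-consistently: lumen diameter and WLR
    are drawn from their group marginals and TVD = LD (1 + WLR),
    WT = WLR * LD / 2, WCSA = pi * WT * (LD + WT) are derived, which keeps
    TVD > LD > 0 and the wall identities exact for every record.
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    params: dict = field(default_factory=lambda: TABLE_PARAMS)
    ao_roi_jitter_um: float = 2.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float,
    bounds: tuple[float, float], size: int,
) -> np.ndarray:
    lo, hi = bounds
    if hi < mean - 4 * sd or lo > mean + 4 * sd:
        raise ValueError(
            f"truncation bounds {bounds} exclude mean {mean} +/- 4 SD"
        )
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a per-eye cohort table with the published group structure.

    Metrics are sampled independently per eye from truncated Gaussians at
    their group's published mean/SD (cross-metric covariance is not
    modeled), except the AO block, which is derived from LD and WLR draws
    so the wall identities hold by construction.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    prefix = {"control": "C", "no_DR": "D", "NPDR": "N", "PDR": "P"}
    frames = []
    for group in GROUPS:
        n = spec.group_sizes[group]
        cols: dict[str, np.ndarray] = {}
        for metric, table in spec.params.items():
            mean, sd = table[group]
            cols[metric] = _draw_truncated(rng, mean, sd, table["bounds"], n)
        ld = cols.pop("ld_um")
        wlr = cols.pop("wlr")
        wt = wlr * ld / 2.0
        df = pd.DataFrame({
            "eye_id": [f"{prefix[group]}{i + 1:02d}" for i in range(n)],
            "group": group,
            "laterality": rng.choice(["right", "left"], size=n),
            **cols,
            "ld_um": ld,
            "wlr": wlr,
            "tvd_um": ld * (1.0 + wlr),
            "wt_um": wt,
            "wcsa_um2": math.pi * wt * (ld + wt),
        })
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_ao_roi_table(
    cohort: pd.DataFrame, seed: int = 0, jitter_um: float = 2.0
) -> pd.DataFrame:
    """Per-eye AO ROI triplets whose ROI means reproduce the cohort's
    drawn TVD/LD exactly (zero-sum jitter of SD ~``jitter_um`` across the
    three ROIs)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort.itertuples():
        jt = rng.normal(0, jitter_um, 3)
        jl = rng.normal(0, jitter_um, 3)
        jt -= jt.mean()
        jl -= jl.mean()
        for i in range(3):
            tvd = rec.tvd_um + jt[i]
            ld = rec.ld_um + jl[i]
            ld = min(ld, tvd - 0.5)         # keep TVD > LD under extreme jitter
            rows.append({
                "eye_id": rec.eye_id, "vessel_id": 1, "roi_index": i + 1,
                "tvd_um": tvd, "ld_um": max(ld, 0.5),
            })
    return pd.DataFrame(rows)
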