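# octamorph

Quantification of retinal microvasculature from en-face OCT angiography
(OCTA) and adaptive-optics (AO) arteriolar imaging, with cohort-level
statistics for diabetic-retinopathy (DR) severity studies.

## What it computes

**OCTA, superficial capillary plexus.** Given a 4.5 × 4.5 mm (320 × 320 px)
en-face angiogram and a manually drawn foveal avascular zone (FAZ) outline,
the per-eye workflow measures:

- **FAZ morphometry** — area *A* by pixel counting, perimeter *P* by
  boundary-chain tracing, and circularity
  `C = 4πA / P²` (1.0 for a perfect circle, lower for irregular FAZ
  shapes); area and perimeter are adjusted for ocular magnification with
  the Littmann–Bennett factor `q(AL) = 0.01306 (AL − 1.82)`.
- **Vessel density (VD)** — vessel pixels / region area inside a 3-mm
  disc centred on the FAZ centroid with the FAZ masked out, after Frangi
  vesselness enhancement and Phansalkar local thresholding.
- **Vessel length density (VLD)** — the same ratio on the skeletonized
  (1-px-wide) vessel map.
- **Fractal dimension (FD)** — box-counting slope of the skeleton,
  `FD = −d log N(ε) / d log ε`.

**AO arteriolar wall morphometry.** From per-ROI total vessel diameter
(TVD) and lumen diameter (LD), three ROIs per arteriole:
`WT = (TVD − LD)/2`, `WLR = (TVD − LD)/LD`, `WCSA = (π/4)(TVD² − LD²)`,
derived per ROI and then averaged.

**Cohort statistics.** Per metric: Shapiro–Wilk per group routes to
one-way ANOVA + Tukey, or Kruskal–Wallis + Dunn (Bonferroni-adjusted);
Spearman correlation for metric-function association.

**Synthetic data.** Seeded generators supply (a) angiogram phantoms with
ground-truth vessel/FAZ masks and a controllable capillary dropout /
FAZ-irregularity severity knob, and (b) four-group cohort tables
(control, no DR, NPDR, PDR; 17/14/18/20 eyes) drawn from published group
means and SDs.

## Worked example

```python
from octamorph import ScanMetadata, run_octa_eye
from octamorph.synthetic import VascularPhantomSpec, generate_vascular_phantom

img, truth = generate_vascular_phantom(VascularPhantomSpec(seed=1))
meta = ScanMetadata(eye_id="p1", group="control", axial_length_mm=24.0)
rec = run_octa_eye(img, truth.faz_polygon, meta)
print(f"FAZ area {rec['faz_area_mm2']:.3f} mm^2, "
      f"circularity {rec['faz_circularity']:.3f}")
print(f"VD {rec['scp_density_pct']:.1f}%  (truth {100*truth.true_density:.1f}%), "
      f"VLD {rec['vld_pct']:.1f}%, FD {rec['fd']:.3f}")
```

prints

```
FAZ area 0.229 mm^2, circularity 1.042
VD 34.1%  (truth 35.0%), VLD 9.9%, FD 1.466
```

i.e. the phantom's avascular zone measures 0.229 mm² (a healthy-eye
scale), the measured vessel density recovers the generator's ground-truth
35% to within one percentage point, and the skeleton metrics are in the
expected ranges for this phantom class. (Circularity slightly above 1
reflects the perimeter estimator's small-object tolerance; see
`docs/methods.md`.)

The same workflow is scriptable from the shell:

```bash
octamorph simulate cohort --seed 3 --out-dir sim/
octamorph stats sim/cohort.csv --out sim/stats.csv
```

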