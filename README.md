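# drillct

Bone-density profiling along drilled trans-pedicular canals from paired
pre/post-interventional CT, with drilling-force correlation.

## The problem

Minimally invasive spine procedures (pedicle screws, kypho-/vertebroplasty,
biopsy) drill through the pedicle into the vertebral body. Robotic
assistance needs *expected* axial forces along the planned trajectory,
derived from pre-interventional CT, to validate what its force sensors
measure during drilling. Ex-vivo studies address this by drilling cadaveric
vertebrae at constant feed (2 mm/s, forces sampled at 1 kHz), CT-scanning
each vertebra before and after, and asking how strongly the local
CT-derived bone density along the actual canal correlates with the recorded
axial force.

This package implements that whole evaluation chain as a tested library for
researchers running such studies:

1. **Register** — rigid alignment of the post-interventional volume onto the
   pre volume (masked mean-squared-difference metric, multi-resolution
   Powell search; both scans are same-scanner HU).
2. **Set drilling pathway** — the carved canal appears as a tube of large
   positive values in `pre − post`; it is segmented by thresholding and
   connected components, and its axis estimated by weighted principal
   component analysis of the voxel cloud (weights = difference magnitude).
   Endpoints are refined to sub-voxel precision by a half-maximum edge rule.
3. **Show drilling pathway** — a virtual cylinder of the drill's outer
   diameter (11 G = 3.05 mm) around the axis; HU profiles are sampled on a
   13-point cross-section stencil every Δs = 0.1 mm of arc length.
4. **Modify** — HU are shifted to gray values, GV = clamp(HU + 1026,
   [0, 4096]), and a sliding ±0.2 mm window records local min/max/mean.
   All correlations are provably invariant to this affine step.
5. **Transform / Shift** — the force trace converts to displacement
   (x = v·t), both series are aligned at the insertion point (first
   sustained rise above baseline = first bone contact), interpolated onto a
   common arc grid, and min-max normalized.
6. **Correlate** — Spearman rank correlation r (average ranks; exact
   permutation p for n ≤ 9, t-approximation above), Pearson r and
   R² = r² with the least-squares line, strength classes on |r|
   (poor < 0.3 ≤ fair < 0.6 ≤ moderately strong < 0.8 ≤ very strong), and
   pooled tables per region (T/L), individual, region × individual and
   overall, at significance p ≤ 0.01.

Because the cadaver scans of such studies are typically not deposited, the
package ships a first-class **synthetic phantom generator**: a
vertebra-like body (cortical shell ≈ 1200 HU around trabecular texture
≈ 300 ± 30 HU, air background, CT-like point spread) with a carved
air-filled canal of known oblique axis, a known rigid misalignment between
pre and post, and force traces generated from the ground-truth density
profile through a declared monotone link plus AR(1) noise. Every stage is
scored against recorded truth.

## Worked example

Generate a phantom and run the whole chain from the shell:

```sh
drillct phantom demo --seed 4 --size 96
cd demo
drillct register pre.nii post.nii --out transform.json
drillct extract pre.nii post.nii --transform transform.json
drillct align profile.csv force.csv --out A_T11_pair.csv
drillct correlate A_T11_pair.csv --out results
```

which prints

```
phantom written to demo (canal 26.8 mm)
transform written to transform.json: [2.7457, 1.56, 2.03, 0.316, 1.5291, 0.3275]
pathway 26.9 mm; profile (319 steps) written to profile.csv
aligned pair (n=278, shift -1.94 mm) written to A_T11_pair.csv
1 result rows written to results.csv / results.json
```

The recovered transform is the phantom's misalignment (degrees x-y-z, then
mm); the estimated pathway length 26.9 mm matches the carved 26.8 mm canal;
the −1.94 mm shift is the recovered insertion offset (truth: 2 mm of air
travel before bone contact). The result row

```
group,n,r_spearman,p,r_pearson,R2,strength,significant,length_mm
A_T11,278,0.454851984846378,1.33479158407931e-15,0.940818780865874,0.885139978429949,fair,True,27.7
```

reports n = 278 force/density pairs along the canal with Spearman r = 0.45
("fair", significant at p ≤ 0.01) under the phantom's default noise — the
regime the cadaver literature reports for most lumbar vertebrae.

The same flow is available programmatically (`drillct.pipeline.run_pipeline`)
and as narrative analyses under `analysis/`:

* `01_tabulate_published.py` — pooled pair counts and strength-class
  tallies recomputed from the published per-specimen summary table of the
  cadaver study (13 thoraco-lumbar vertebrae, two donors).
* `02_phantom_pipeline_demo.py` — the end-to-end phantom run above, with
  grouped result rows.
* `03_recovery_studies.py` — axis and registration recovery scored against
  phantom ground truth.
* `04_correlation_recovery.py` — recovery of known population Spearman
  correlations through the simulator's monotone link.

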