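# Methods

This note documents the models, conventions and numerical choices behind
`drillct`, and what the synthetic phantom does and does not establish about
real cadaver data.

## Geometry conventions

World coordinates are millimetres; voxel indices are 0-based; a voxel's
value lives at its centre (`world = origin + index · spacing`); volumes are
axis-aligned (oblique DICOM/NIfTI orientations are rejected rather than
silently resampled). Continuous positions are interpolated trilinearly.
Rigid transforms are Euler rotations in degrees applied x-then-y-then-z
(`R = Rz·Ry·Rx`) about a stated centre, plus a translation; the
registration stage always rotates about the fixed volume's centre. No
convention is standard across imaging toolkits, so this one is fixed and
asserted by tests (inverse composition to 1e-9, re-centering identity).

## Registration

Both scans of a specimen come from the same scanner and protocol, so the
metric is the mean squared HU difference over the fixed volume's body mask
(HU > −500) — mutual information buys nothing for monomodal pairs and
costs testability. The search is a three-level pyramid (downsample factors
4, 2, 1; Gaussian pre-smoothing at σ = factor/2 voxels, stride decimation
so voxel centres are preserved) with derivative-free Powell minimisation at
each level, sampling at most 20 000 mask voxels per level. The search is
bounded to ±15° / ±20 mm around the initialisation: repeat scans of a
clamped specimen cannot be further apart, and an unbounded search can fall
into the near-symmetric 180°-flip minimum of a smooth body. The optional
initial transform stands in for the manual coarse pre-alignment an operator
would perform. Non-convergence returns the best transform found plus a
warning rather than failing the run.

Recovery is scored convention-free: the residual `recovered ∘ truth⁻¹`
should be identity, and its rotation angle / translation magnitude are the
errors. On 128³ phantoms at 0.5 mm with 30 HU texture and misalignments up
to 5° / 5 mm, median residuals are ≈ 0.2° and ≈ 0.01 mm (see
`analysis/03_recovery_studies.py`).

## Canal estimation

`pre − post` is positive where bone was removed. Segmentation keeps voxels
with difference ≥ 400 HU (default; well above trabecular/partial-volume
noise, well below the ≥ 1300 HU bone-minus-air contrast of the canal core)
and retains the largest 26-connected component, discarding detached
segmentation artifacts. The axis is the dominant eigenvector of the
weighted covariance of voxel coordinates, weights = difference magnitude,
which down-weights rim artifacts; a first-to-second eigenvalue ratio below
4 raises "no dominant axis" instead of returning a meaningless direction.
Provisional endpoints are the 0.5 % / 99.5 % weighted quantiles (inverse
empirical CDF, so trimming less than one voxel's weight keeps the extreme
voxels) of the axial projections, oriented so the start is the endpoint
nearer the volume boundary — the entry side, replacing anatomical knowledge
of the dorsal entry point, which is out of scope.

Endpoint refinement emulates an operator's sub-voxel fine-tuning with a
half-maximum edge rule: walking each endpoint ±2 mm along the axis in
0.05 mm steps, the endpoint is placed at the interpolated position where
the disk-mean of the difference first falls below 50 % of the canal's
interior median. If no crossing occurs within the cap the provisional
endpoint is kept with a warning.

Profiles are sampled every Δs = 0.1 mm — chosen to reproduce the
pairs-per-millimetre of published canal tables (≈ n = length/0.1) — on a
13-point stencil (axis point plus 6-point rings at r/2 and r) in the plane
perpendicular to the axis; mean, min and max over the stencil form the
channels. A single-point stencil is available where a pure axis sample is
wanted.

## Gray values and the window filter

GV = clamp(HU + 1026, [0, 4096]), anchored at −1025 HU ↔ 1 GV with unit
slope. The offset only places the scale (air ≈ 26 GV, dense cortical bone
near the top); Spearman correlations are invariant to any rank-preserving
map and Pearson r to any affine map, which the suite asserts numerically to
1e-12. The ±0.2 mm sliding window outputs the window max of the max
channel, min of min, and mean of mean — i.e. local extrema over *all*
recorded cross-section samples; windows truncate at the profile ends
(shrinking the output would misalign the arc grid). The windowed **max** is
the default correlation channel: the densest material in the cross-section
dominates drilling resistance, and it empirically yields the stronger
correlations.

## Force alignment

Displacement is x = v·t at the constant feed velocity (2 mm/s, 1 kHz
sampling ⇒ one sample per 2 µm). The insertion point of each series is the
first sustained rise above baseline: baseline = mean of the leading 5 % of
samples, threshold = baseline + 5 % of (max − baseline), sustained over 3
intensity steps (0.3 mm — the sustain requirement is expressed as a
physical length so the dense force grid demands the same evidence as the
coarse intensity grid). Within the sustain window 80 % of samples above
threshold suffice: on a noisy rising edge momentary dips below threshold
otherwise push the detected onset systematically late. The returned onset
is the linearly interpolated threshold crossing, not the integer sample:
two series that are affine images of one another then yield exactly
corresponding positions regardless of their grids, which is what makes the
noise-free end-to-end pipeline recover Spearman r = 1 (to ≈ 1e-6; the last
few ulps go to rank tie-breaks where the normalized plateau maximum is
reproduced to 1 part in 10¹⁶). The force record is shifted by the onset
difference, linearly interpolated onto the profile's arc grid over the
in-bone overlap (pre-contact air is excluded, so n counts only in-bone
pairs), and both channels are min-max normalized. Recovered shifts are
within ≈ 0.05 mm of the simulated insertion offset at the default noise.

## Statistics

Spearman r is the Pearson correlation of average-ranked data (ties →
average ranks), with an exact +1/−1 shortcut for perfectly concordant or
discordant rankings. For n ≤ 9 the two-sided p enumerates all n!
permutations (vectorised, cached); above, the t-approximation
`t = r√((n−2)/(1−r²))` with n−2 degrees of freedom. The diagnostic that
compares the two uses the mid-p convention (half weight on the point mass
at the observed |r|), the appropriate form when comparing a discrete
distribution against a continuous approximation; so measured, they agree
within 0.013 at n = 8–9 over all achievable r, whereas the conservative
convention's worst case is 0.024 by construction, not by implementation
error. Strength classes are left-closed bands on |r| (0.3 / 0.6 / 0.8);
significance is fixed at p ≤ 0.01; no multiple-testing correction is
applied, matching the study design this pipeline serves. Pooled rows
concatenate per-specimen-normalized pairs, so pooled n is exactly additive
(the per-specimen-then-concatenate order matches the published subtotal
sums); joint renormalisation is deliberately not the default.

## The synthetic phantom

The phantom emulates the features the pipeline depends on: an ellipsoidal
body of trabecular texture (mean 300 HU, sd 30 HU, correlation length
0.8 mm) inside a 1.5 mm cortical shell at 1200 HU, a pedicle-like
cylindrical boss around the canal entry so the drill crosses one cortical
wall obliquely, air background at −1000 HU, and a 0.4 mm Gaussian
point-spread emulating the scanner (without it, ±2000 HU step edges make
resampling round-trips unrealistically lossy). The canal (default 3.05 mm
diameter, ≈ 28 mm long, tilted 18–35° off-axis) starts at the boss's outer
face and is carved with one-voxel partial-volume softening; the post volume
is then resampled through the inverse of a recorded rigid misalignment
(default up to 3° / 2 mm; the validation studies draw up to 5° / 5 mm).
HU bands are placed so the GV conversion lands inside [0, 4096] with
cortical bone at the maximum.

Force traces follow `F(t) = a + b·GV(v·t − s₀) + ε(t)` with a = 0 N,
b = 1.2·10⁻³ N/GV (trabecular ≈ 1.6 N, cortical ≈ 2.7 N, in the few-newton
range such experiments record), insertion offset s₀ = 2 mm, and AR(1)
noise (sd 0.1 N, φ = 0.8 at 1 kHz). The link is applied across the covered
range, so pre-contact force sits at a + b·GV_air ≈ 0.03 N. This is a
declared statistical link for parameter recovery, **not** a biomechanical
drilling model — torque, chip evacuation and tool wear are intentionally
absent, and nothing here should be read as predicting absolute forces. For
studies at a known population Spearman ρ, gray values are mapped to normal
scores (a strictly monotone, hence Spearman-preserving transform) and the
force built at Pearson ρ_p = 2·sin(πρ/6), the Gaussian-copula value whose
Spearman correlation is exactly ρ.

What phantom-based passing tests show: the geometry pipeline recovers axes,
endpoints, transforms and shifts to well inside a voxel, and the
correlation stage is unbiased against a known monotone link. What they do
not show: performance on real anatomy (irregular cortical thickness,
degenerative sclerosis, metal artifacts), real drilling physics, or
scanner-specific HU calibration — HU is used as a density surrogate
without conversion to mg/cm³.

## Problem sizes and numerics

Validation studies use 20 phantoms at 128³ × 0.5 mm (the published scans'
in-plane order of magnitude) and 50 replicates per correlation target at
n = 400, sizes at which the medians are stable; the narrative analysis
scripts default to smaller n with a flag to scale up. All randomness flows
from explicit seeds (`numpy.random.default_rng` with derived sub-streams;
no global state). Degenerate inputs raise informative errors rather than
returning NaN: constant series (undefined ranks / zero range), empty masks
and clouds, non-uniform sampling, sub-voxel radii (warning), missing
onsets. The NIfTI affine is float32 by format, so volume geometry
round-trips to ~1e-7 while the float64 voxel payload is bit-exact.

## Known limitations

* Only axis-aligned volumes; oblique acquisitions must be resampled
  upstream.
* Rigid registration only — appropriate for cadaveric vertebrae between
  two scans, wrong for intra-operative deformation.
* The insertion-point rule assumes a quiet pre-contact baseline; records
  started after bone contact will mis-align and typically fail the overlap
  check rather than mis-correlate silently.
* Pooled correlations inherit Simpson-type behaviour: a pooled r is not an
  average of member r's, and the package makes no claim that it is.
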