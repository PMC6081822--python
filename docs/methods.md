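# Methods

`octa-compare` quantifies how a spectral-domain (SD, ~840 nm) and a
swept-source (SS, ~1050 nm) OCT/OCTA instrument compare when imaging the
same eyes, using central serous retinopathy (CSR) as the test case: the
serous fluid dome lengthens the optical path to everything beneath it, and
the question is how much each device's returns from the deep layers suffer
as the fluid volume grows.  Because the underlying clinical data are not
public, the package pairs the analysis pipeline with a synthetic-acquisition
generator that has exact, analytically known ground truth; every claim the
test suite makes is a claim about recovering that ground truth.

## The comparison metrics

**Total-energy normalization.**  Raw intensities from two instruments are
not commensurable.  Assuming negligible absorption, the summed backscattered
signal of a scan is proportional to the light energy delivered, so each
volume is rescaled to unit total signal:

    S_norm(x, y, z) = S_m(x, y, z) / S_sum,     S_sum = Σ_xyz S_m(x, y, z)

with the sum over the entire scanned volume, all depths.  Intensities are
linear-scale (never dB): the summation semantics require it.  One useful
consequence: any per-scan global gain — incident power, detector
sensitivity, and a pure-exponential axial repositioning — cancels exactly.

**Per-layer signal strength.**  For each anatomical slab the strength is
the mean normalized signal per voxel,

    S_dev = S_layer_sum / N_layer_voxel,

and the inter-device difference for a subject, layer and scan pattern is
ΔS = S_ss − S_sd.  Per-voxel means are compared directly across the two
instruments' different grid sizes (no resampling); since the normalized
mean voxel value is 1/N_total, ΔS carries a constant negative offset that
affects neither the paired tests nor the regressions.

**Slabs.**  Superficial retina [ILM, IPL] (top-inclusive), deep retina
(IPL, OPL], and fixed-thickness choroidal bands below Bruch's membrane:
Sattler (BM, BM+100 µm], Haller (BM+100, BM+300 µm].  Fixed thicknesses are
used because automated choroidal sublayer segmentation is not reproducible
across devices; 100/200 µm sit within published ranges and are
configurable.  A voxel belongs to a slab when its centre depth
`k·axial_spacing` lies in the half-open interval — adjacent slabs never
share voxels.

**Central serous volume (CSV).**  The detachment region is the IS/OS-to-RPE
gap wherever it exceeds 10 µm (two axial samples; separates detachment from
apposition), and CSV is whole-voxel counting times the voxel volume.  No
partial-volume weighting.

**Vessel density.**  En-face angiograms from the two devices are brought
into one physical frame (the pixel-pitch ratio is known from the scan
metadata; the residual translation is the normalized-cross-correlation
peak, with a 0.2 correlation floor), the largest circle contained in both
fields is centred on the fovea (FAZ centroid of the SS image, which has the
finer grid), vessels are binarized by Otsu's between-class-variance
threshold on percentile-stretched intensities (invariant to affine
intensity rescaling; the method is pluggable), the foveal avascular zone is
removed (connected avascular component at the circle centre after
morphological closing at 30 µm, falling back to a fixed 0.25 mm disk with a
warning when no enclosing capillary ring exists), and density is the
vessel-pixel percentage of the remaining area.  Area density, not
skeletonized density.

**Statistics.**  Two-sided paired t-tests (differences d = y − x, sample
SD), ordinary least squares with R² and the slope's t-test, and
Bland-Altman limits mean(d) ± 1.96·sd(d) — exactly 1.96, not a t quantile.
α = 0.05, no multiple-testing correction (a Bonferroni helper exists but is
off by default).

## The synthetic acquisition model

**Geometry.**  A flat layered retina (ILM 132.5, IPL 232.5, OPL 302.5,
IS/OS = RPE 482.5, BM 497.5 µm from the window top; 2 mm window at 5 µm
axial pitch, 400 samples).  Flat boundaries sit halfway between axial
samples: a boundary on a sample centre would bias whole-voxel volumetry by
half a voxel per A-line.  The CSR detachment is a half-ellipsoid dome of
semi-axes (a, b) and height c whose volume is exactly (2/3)·π·a·b·c; the
IS/OS surface is displaced anteriorly by the dome height while RPE and BM
stay put, so the gap equals the dome height everywhere.  The outer nuclear
layer absorbs the displacement (the inner retina does not move for domes up
to the ONL thickness of 180 µm; taller domes push the inner boundaries just
enough to preserve ordering).  This pinning is a synthetic convention, not
anatomy — it makes the inner-retinal slabs structurally independent of the
lesion, which is the regime in which the deep retina genuinely carries no
fluid-volume information.

**Reflectivities** (linear, arbitrary units): superficial 1.0, deep
retina 0.35 (INL-dominated), ONL 0.10, serous fluid 0.05, RPE band 0.3,
Sattler 0.07, Haller 0.06, sclera 0.01, vitreous 0.05.  The choroid and
sclera are deliberately dim — on these devices the deep choroid sits near
the edge of detectability, which is the premise of the whole comparison —
and this keeps the below-IS/OS share of total signal (β ≈ 0.1) small, so
that the fluid mechanism couples only weakly into the retinal layers
through the normalization denominator.

**Device models** (rates per mm): sensitivity roll-off exp(−r·z) with
r = 0.6 (SD) vs 0.2 (SS); tissue attenuation 1.0 for both; fluid
attenuation replaces tissue attenuation along the fluid path at 1.5 (SD)
vs 0.5 (SS) — so fluid is effectively +0.5/mm *more* attenuating than
tissue for SD and 0.5/mm *less* for SS, the hypothesised mechanism by which
a large detachment disadvantages the shorter-wavelength device.  Additive
Gaussian noise with SD 0.02 of mean reflectivity, clipped at zero.  All
values are synthetic conventions chosen to reproduce the qualitative
ordering of the two technologies; none is a measured instrument constant.

**Variability.**  Three seeded per-subject anatomy jitters (layer
thicknesses σ = 0.5 µm, retinal elevation σ = 0.7 µm, log-reflectivity
σ = 0.004) are kept deliberately small: ΔS is a within-eye difference, so
anatomy is common-mode between the paired scans, and the only way anatomy
jitter reaches ΔS in this model is through the asymmetric sampling of the
two devices' grids — a discretization leak, not a physical effect.  The dominant variability
is per-scan segmentation error: each scan's ILM/IPL/OPL boundary maps carry
an independent N(0, 4 µm) placement offset, emulating the imperfect
cross-device reproducibility of inner-boundary segmentation.  The bright
IS/OS, RPE and BM are returned exactly — fluid volumetry and the
BM-anchored choroidal slabs are unaffected, and mask errors never touch
S_sum.  This channel scatters retinal-layer ΔS an order of magnitude more
strongly than choroidal ΔS, which is what decorrelates the deep retina from
CSV while leaving the sub-dome mechanism detectable.

**Vasculature.**  A binary vessel map on a 2 µm reference grid: a seeded
bifurcating arteriolar tree entering from the field edge, over a capillary
mesh formed as the sub-level band |F| < 0.5·sd of a Gaussian-smoothed
(40 µm) noise field — a pure tree cannot reach the ~40-50 % area density of
real en-face angiograms at calibres the 17.1 µm grid can resolve.  A
perifoveal capillary ring encircles a cleared 0.25 mm FAZ disk, so the true
avascular zone is exactly a disk and the true vessel fraction is exactly
pixel-countable.  Angiograms are rendered by area-averaging the map onto
the device grid (summed-area box filter) and scaling between background
(0.05) and vessel (1.0) intensity plus noise; no flow-decorrelation physics
is simulated.

**Cohorts.**  The default study: 7 normal eyes, 7 CSR eyes with dome
heights 60-170 µm and semi-axes 0.7-1.35 mm increasing together (analytic
volumes ≈ 0.06-0.5 mm³, strictly increasing, all contained in the 3×3 mm
field), plus an optional truncation case (a = 2.0, b = 1.8 mm) that
overflows the 3×3 mm raster but fits 6×6 mm.  Sub-seeds spawn
deterministically from the master seed; the same master seed reproduces the
dataset bit-for-bit.

## What the synthetic data do and do not show

Passing tests demonstrate that the pipeline recovers known volumes to the
discretization limit, measures vessel density to within two percentage
points of a countable truth across both devices' grids, detects the
programmed fluid-differential mechanism, and is deterministic end to end.
They do not validate the forward model against real OCT physics: there is
no speckle, no interferometric or k-space simulation, no OMAG flow
contrast, no projection artifacts, no motion, and the device constants are
conventions.  Numbers from the synthetic cohort (densities near 42-50 %,
regression R², p-values) live on the same scales as the clinical setting
this design mirrors but are not reproductions of any clinical result.  One
instructive artifact: the paired t-test on vessel density comes out
significant here even though the inter-device difference is under half a
percentage point, because the coarser SD grid induces a tiny but
sign-consistent resampling bias and the generator omits the between-visit
variability that dominates real density comparisons — agreement should be
judged by the magnitude of the difference and the limits of agreement, not
the p-value.

## Numerical and design notes

* Volumes render in float32 (a 500×500×400 scan is 400 MB); all metric
  accumulation is float64 with numpy pairwise summation, deterministic for
  a given shape and far below the 1e−9 conservation tolerance.
* Renders, angiograms, surfaces and cohorts are deterministic functions of
  (inputs, seed); the pipeline writes byte-identical tables for identical
  configuration and seed.  Timestamps go to the run log, never to tables.
* Registration quantizes translation to the common fine grid (half-pixel
  worst case); the ROI radius retreats one pixel inside both fields.
* Binarization ties: strictly greater than the threshold is vessel.
* Degenerate inputs raise typed errors (all-zero volume, empty mask,
  constant regressor, zero-variance differences, constant ROI, ROI inside
  FAZ) rather than returning sentinel values.
* ΔS-vs-CSV is analysed at the 3×3 mm pattern.  With lesions constrained to
  fit the 3×3 field, their footprint occupies ≤ 15 % of the 6×6 field and
  the mechanism there is diluted fourfold; the report still tabulates both
  patterns.
* Statistical fine print: with five subjects the null distribution of R²
  has mean 1/(n−1) = 0.25, so "no correlation" in the deep retina is a
  statement about the ensemble, not a guarantee for any single five-eye
  draw; the validation suite uses fixed cohort seeds as part of the study
  conditions.
* Problem sizes in the validation suite: unit tests run scaled-down grids
  (e.g. 75×75 to 150×150 A-lines) that preserve every physical convention;
  the acceptance-style tests run the real 245/300/350/500-line grids, with
  the ΔS mechanism checks on the two 3×3 mm protocols and cohorts of 5-8
  eyes.
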