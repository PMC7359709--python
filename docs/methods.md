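# Methods

`graftct` quantifies the physical burden of thrombus deposited on the
blood-contacting surface of tubular vascular-graft biomaterials from
microCT voxel volumes. This note describes the measurement model, the
synthetic phantoms used to validate it, the numerical choices made where
the design was genuinely open, and the limits of what the validation shows.

## Measurement model

A scan is a 3D intensity grid with axis 0 along the graft (the slice
axis). The isotropic voxel size follows from the acquisition geometry:
field of view divided by the reconstruction matrix (60 mm / 512 =
0.1171875 mm, i.e. 117 µm truncated). Projection bookkeeping is the
matching integer arithmetic (e.g. 3672 acquired frames with 4-projection
averaging reconstruct from 918 projections).

Which structure is radiopaque depends on the biomaterial's water
absorption, so segmentation dispatches on material type:

| material type | processing outcome | segmented target(s) |
|---|---|---|
| `PVA` (hydrogel) | casting agent fills the open lumen → bright lumen | lumen |
| `ePTFE` (clinical control) | iodine stain absorbed only by tissue → bright thrombus | thrombus |
| `collagen_ePTFE` (positive control) | four nested materials | lumen, shrink tubing, wall; thrombus as remainder |

Segmentation is strictly 2D per cross-sectional slice with in-plane
4-connectivity; 3D growing could leak through partial-volume bridges
between slices. The primitive is a *masking wand*: the 4-connected
component of pixels whose intensity lies in an operator-calibrated range,
containing a seed click. After wand growth, one layer of "medium gray"
border pixels — partial-volume pixels straddling the material boundary —
is annexed, gated by a second intensity band. Seeds propagate from slice
to slice automatically (the in-mask pixel nearest the previous mask's
centroid, well-defined even for crescents), standing in for the operator's
repeated clicking; if propagation lands out of range, the largest in-range
component is taken; slices with no in-range pixels are recorded as empty
and traversal continues, because full occlusion is a real outcome. A
global-threshold variant is provided for bright-thrombus stacks where a
single masking range may be applied to the whole volume; the per-slice
wand is the default.

For four-material samples the materials are claimed sequentially — lumen,
then the outermost heat-shrink tubing, then the graft wall — each voxel
keeping its first label, and the thrombus is the *remaining material*: the
hole-filled interior of the wall ring minus every explicit claim. Slices
where the wall does not close around a non-empty lumen are flagged in the
result metadata rather than aborting the run.

Morphometry follows per-slice bookkeeping: `AreaPerSlice` profiles
(material pixel count × dy × dx, mm²), volume (voxel count × voxel
volume, mm³, identically the summed profile × dz), and length from slice
numbering — (last occupied − first occupied + 1) × dz, with interior
empty slices counted, since an occluded segment is still graft length.
The headline metric is the average luminal cross-sectional area
A = V / L (luminal volume per unit length). For thrombus-opaque samples
the lumen cannot be segmented directly and is obtained by subtraction:
π(d/2)²·L from the caliper-measured inner diameter and length, minus the
measured thrombus volume. Per-slice variability is summarized as
mean ± SD over the occupied span; the sample (n−1) standard deviation is
used, a choice this package makes because no convention is fixed by the
workflow it reproduces.

## Validation statistics

The measured-vs-reference length comparison uses a least-squares line
constrained through the origin, reported with the *uncentered*
R² = 1 − SS_res/Σy² — the natural coefficient for a forced-origin fit,
since the centered form can be negative there — and an F test on (1, n−1)
degrees of freedom. Correlations of average luminal area with platelet
(billions per mm of graft length) and fibrin endpoints use ordinary least
squares with intercept per material group; significance is the
single-predictor regression ANOVA, F = R²(n−2)/(1−R²) on (1, n−2) df,
flagged at p < α with a strict inequality at the boundary (α = 0.05
by default). No multiple-testing correction is applied across groups,
matching the workflow being reproduced. Fibrin endpoints are treated as
unitless values since their units are not standardized.

## Synthetic phantoms

Phantoms are axis-aligned cylindrical grafts rendered into the scanner's
default 117 µm grid with a few empty slices of axial padding and ~0.4 mm
of in-plane margin. A mural thrombus is modeled as an eccentric annulus
attached to the inner wall: in slice z the open lumen is a disk of radius
ρ(z) = √(R_i² − A_T(z)/π), displaced toward the wall by
eccentricity·(R_i − ρ) at a seed-drawn fixed angle. This realizes any
target per-slice area profile A_T(z) exactly while keeping the deposit
wall-attached, as mural thrombi are under flow; no quantitative thrombus
*shape* statistics exist to calibrate against, so the annulus is a
modeling convenience and is flagged as such. The default profile is a
sinusoid with baseline 6.49 mm², amplitude 1.68 mm² (per-slice SD
amplitude/√2 ≈ 1.19 mm²) and 8 mm axial period — the per-slice mean ± SD
of a representative positive-control sample — clipped to
[0, π(d_i/2)²]; default geometry is a 4 mm inner diameter, 5 mm outer
diameter, 30 mm long graft, matching the study conditions the package is
validated under. A custom per-slice profile may be supplied instead and
must not exceed the lumen capacity.

Partial volume — the "medium gray border pixels" that the calibration
rule targets — is manufactured by in-plane supersampled occupancy
averaging: each voxel is subdivided s² times (s = 4 by default) and its
intensity is the occupancy-weighted mean of the per-material levels.
Axial supersampling is deliberately absent: the thrombus profile is
defined per slice, the cylinder walls are z-invariant, and graft ends
fall exactly on slice boundaries (the requested length is realized as
round(L/dz) whole slices; the truth length is n·dz). Gaussian noise is
added after geometry, from the same seeded generator, so geometry is
seed-stable under changes of the noise level.

Ground truth comes in two deliberately distinct forms:

* **labels** — each voxel's majority material, the voxelized realization a
  perfect voxel classifier would produce;
* **true volumes and per-slice area profiles** — occupancy-weighted sums,
  which follow the continuous geometry to within the supersampling
  quantum (≈1 voxel-area per slice at s = 4, falling as 1/s²).

The distinction matters because pixel counting of *any* binary mask of a
disk of radius ≈17 voxels carries a constant lattice offset of several
voxel-areas relative to πr² (≈3 voxel-areas for the default geometry,
up to ~7 over subpixel center placements). Occupancy-based truth makes
the conservation and refinement properties hold as stated; label-derived
summaries (`truth_summary`) agree with the stored truth to within the
voxelization tolerance (≈1%), not bit-exactly. The same lattice offset
appears, unavoidably, in the segmented lumen+thrombus area compared
against the caliper-cylinder internal area; it is reported as such, while
the segmented interior is compared with the truth-label interior (same
lattice) where it agrees to within 2 voxel-areas per slice.

Default intensity levels per mode are on an 8-bit-like scale (see
`DEFAULT_INTENSITIES`), ordered to mimic the real contrast situations:
bright cast lumen in a gray wall; bright stained thrombus in a dark wall;
and the four-material nesting with a dark lumen. The "noisy" validation
condition uses Gaussian noise with σ = 10% of the target-to-adjacent
contrast each calibration relies on (σ = 12, 16 and 4 intensity units for
the three modes respectively).

## Default operator calibrations

The gray-level boundaries real operators use are not recorded anywhere;
only the rule is reproducible. The package derives default calibrations
from a mode's intensity table: the border band's outer edge sits at the
half-occupancy intensity of the boundary between the target and the
material it physically abuts (so a partial-volume pixel is annexed
exactly when the target occupies its majority), and the core bound
retreats one eighth of the target contrast inside that edge. This gives
near-zero net area bias on a partial-volume skin; measured volume
recovery errors on phantoms are ≤2% noise-free and ≤1.2% at the noisy
condition, against 5%/10% acceptance bands. In four-material mode the
dark lumen's border band climbs to the lumen–thrombus half-occupancy
level; on the (rare, under default conditions) arcs where the lumen
touches the wall directly this annexes some majority-wall skin, a known
bias that does not affect the lumen+thrombus conservation, which is
governed by the wall's own calibration.

## Numerical choices and degenerate inputs

* Slice indices are 0-based with half-open ranges throughout.
* Intensities keep their native numeric scale; no normalization or
  denoising is applied anywhere.
* TIFF stacks carry spacing in a JSON sidecar (`{"spacing_mm":
  [dz, dy, dx]}`) because TIFF has no standard z-spacing tag; NIfTI
  carries spacing in `pixdim`. Round trips are bit-exact on data and
  labels.
* Occupancy argmax ties in phantom truth resolve to the first material in
  (background, lumen, thrombus, wall, shrink) order — deterministic and
  measure-zero in practice.
* An all-zero predictor or reference (zero length, all-zero x) raises
  rather than returning NaN; a thrombus volume exceeding the caliper
  cylinder raises as physically inconsistent.
* Empty slices inside a span contribute zero area but stay inside the
  length and the per-slice statistics.

## Problem sizes used in the shipped validation

The test suite and the acceptance script size their simulations as: a
21-phantom length battery spanning 20–40 mm (whole-slice lengths), 20 mm
phantoms for conservation and volume recovery, 200 random 32×32 images
for the wand/flood-fill equivalence, and 1000 null replicates of n = 100
for the type-I calibration of the significance flag (binomial 99%
interval around α = 0.05).

## Limitations

* Phantoms emulate contrast, partial volume and additive Gaussian noise
  only — no beam hardening, ring artifacts, scatter or polychromatic
  effects, and no anatomically realistic in vivo geometry. Passing
  phantom validation shows the *analysis chain* is unbiased under the
  modeled imaging physics, not that the contrast protocols themselves
  work on new materials.
* The whole-tissue-stained in vivo variant (tracing open lumens through
  anatomy) is out of scope; only the ex vivo tubular-sample modes are
  implemented.
* Inter-observer variability of manual calibration and caliper handling
  involves humans and is out of computational reach; the per-slice QC log
  (seeds used, fallbacks, empty slices, flagged wall closures) is the
  closest automated analogue.
* Surface meshing and rendered-surface area measures are non-goals; areas
  are pixel-count based, which carries the lattice quantization discussed
  above.
* Very thin deposits (per-slice area approaching one pixel ring) can
  fragment under the per-slice wand, mirroring the real difficulty of
  resolving small thrombi at 117 µm.
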