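# Methods

## Problem setting

In MR-guided online adaptive radiotherapy, a patient is imaged at every
treatment session (fraction) and the organs of interest (OoIs) must be
re-contoured on each session image under tight time constraints.
Between sessions the underlying anatomy is largely consistent, with
localized deformation of individual organs (bowel filling, stomach
shape, small shifts of solid organs). `fracaug` models exactly this
regime: it simulates plausible inter-fraction variants of a session
image by deforming each labelled organ independently within bounds,
arranges the resulting multi-session cohorts into organ-conditioned
training cases for a segmentation model, and evaluates contours
geometrically and dosimetrically. The segmentation model itself is
outside the package.

## Coordinate and warping conventions

Volumes are axis-aligned grids; voxel `(i, j, k)` sits at
`origin + index · spacing` (mm) in a fixed right-handed order
(left-right, anterior-posterior, inferior-superior). Displacement
fields `u(x)` are per-voxel 3-vectors in mm defining the transform
`T(x) = x + u(x)` under **backward warping**: the warped output at `x`
samples the input at `T(x)`, linearly for images, nearest-neighbour for
labels (so no organ code is ever invented). Out-of-domain samples take
the nearest-edge value, which avoids injecting background intensity at
the boundary. Fields compose so that one warp by the composed field
equals sequential warps: `compose(u_a, u_b)(x) = u_b(x) + u_a(x + u_b(x))`,
with the accumulated field looked up by linear interpolation. A
composition with the zero field is exact, and the equivalence to
sequential warping is held to within interpolation error (≤ 2 % of the
dynamic range on smooth images; a frozen oracle test).

## Structure-guided deformation

For each organ the simulator draws a random similarity motion with each
component uniform within its bound: translation per axis in
`[−p_disp, p_disp]` mm, isotropic scale in `[1 − p_shrink, 1 + p_exp]`,
and Euler rotation per axis in `[−p_rot, p_rot]` degrees about the organ
centroid. The generator state advances at every draw, so organs receive
distinct draws even under identical bounds. A draw becomes a dense
field through the inverse motion (backward convention):
`u_raw(x) = F⁻¹(x) − x` with `F(x) = c + s·R·(x − c) + t`, weighted by
`w(x) = exp(−d(x)² / (2·σ_decay²))` where `d` is the Euclidean distance
to the organ mask in mm, then Gaussian-smoothed at `σ_smooth`. Inside
the organ the motion is exact (up to smoothing); far away the field
decays to zero, keeping deformations organ-local and smooth.

Organs are visited in ascending label code (configurable, logged): for
organ `k` the already-composed field first warps its mask, the field is
generated from the warped mask, and the composition is updated — so each
organ deforms in the geometry produced by its predecessors. The image
and all labels are warped once by the final total field, which is
returned for QA. The minimum Jacobian determinant of `T` (central
differences, physical units) is the folding diagnostic: values ≤ 0 are
warned about (or rejected in strict mode); plausibility, not
diffeomorphism, is the design goal.

Defaults: `p_disp` 8 mm, `p_exp` = `p_shrink` 0.15, `p_rot` 8°,
`σ_decay` 15 mm, `σ_smooth` 4 mm. These produce visually plausible
abdominal inter-fraction change at the phantom's 2 mm scale; they are
free parameters of the method, set once and exposed in
`DeformParams`. The rotation component stands in for organ "bending";
a true curvilinear bending operator is a known omission.

## MR acquisition-variability augmentations

Three intensity-only augmentations emulate scan-to-scan appearance
change; geometry and labels are never touched, and identity settings
are exact fixed points:

* **Histogram shift** — intensities pass through a monotone
  piecewise-linear curve with `K` evenly spaced control points
  (default 6); interior targets are perturbed within
  `strength × range` (default 0.05) and re-sorted, endpoints pinned, so
  the output range and the intensity rank order are preserved.
* **Intensity scale** — one global factor, uniform in (0.9, 1.1) by
  default.
* **Gibbs ringing** — a centred axis-aligned box in k-space keeps the
  lowest `(1 − α)` fraction of frequencies per axis (α uniform in
  [0, 0.4) by default); α = 0 reproduces the input to FFT round-off,
  and the DC component is always retained.

Order is fixed (shift → scale → ringing), each step gated by its own
draw with probability 1.0 by default; gate draws are consumed
unconditionally so reproducibility does not depend on earlier gates.
The ranges are package defaults — the acquisition-side statistics they
emulate are not calibrated to any particular scanner or sequence.

## Conditioned dataset arrangement

A conditioned case is `D_{mn,o} = [I_m, L_{m,o}, I_n]` with training
target `L_{n,o}`: a prior session image, its binary mask of one organ,
and the current session image, all on the current session's grid (the
prior session is resampled there: linear for the image,
nearest-neighbour for labels). Pair enumeration is within-patient only
and ordered — a patient with `k` sessions contributes `k(k − 1)` pairs
(`all_ordered`), or `k − 1` with the first session as the only source
(`first_to_rest`, the deployment arrangement). Organs absent from a
source label map (e.g. a missing kidney) are skipped with a logged
notice, never emitted as empty conditioning masks. Cross-validation is
leave-one-out at the **patient** level: every fold holds out one
validation patient with all of their sessions, so no patient leaks
across the split. The on-disk layout uses channel-suffix naming
(`<case>_0000/_0001/_0002` + binary target label + descriptor JSON +
manifest CSV) and round-trips losslessly. A post-hoc `ensemble_vote`
utility merges predictions conditioned on several prior sessions by
majority (ties to foreground). Z-score normalisation is computed over
foreground voxels (above the 5th intensity percentile by default) and
is invariant to positive affine intensity changes.

## Contour metrics

* **DSC** `2|A∩B|/(|A|+|B|)`; both masks empty → 1, exactly one empty
  → 0.
* **Surface distances** — surfaces are masks minus their 6-connected
  erosion; directed distances are voxel-centre to voxel-centre in mm via
  Euclidean distance transforms. ASD is the mean and HD95 the 95th
  percentile (linear interpolation between order statistics) of the
  **pooled bidirectional** multiset, hence both are symmetric by
  construction; this convention is stated here because directed and
  averaged variants exist in the literature.
* **DVH / dose statistics** — cumulative volume fraction receiving at
  least each dose level. `D_{V}` (e.g. D0.1cm³, D50 %) sorts mask doses
  descending, places voxel `i` at cumulative volume `(i − ½)·v_voxel`,
  and interpolates linearly; uniform dose returns itself exactly, and a
  brute-force sort oracle pins the definition on random masks. A mask
  smaller than a requested absolute volume is an error.
* **dPD** `|D_method − D_groundtruth| / PD × 100` (absolute by default;
  signed behind a flag), with PD the prescription dose.
* **mDice** — Dice with per-voxel weight `‖∇dose‖` (central
  differences, Gy/mm): `2 Σ_{A∩B} w / (Σ_A w + Σ_B w)`. Under constant
  gradient magnitude it equals DSC to 1e−12 (contract test); zero total
  weight over A∪B falls back to DSC with a notice. This emphasises
  agreement where dose changes fastest, i.e. organs near the target.
* **Report assembly** — one row per ground-truth organ; organs missing
  from the prediction get DSC 0, NaN distances, and a
  `distances_defined=False` flag rather than aborting a cohort run.

## Synthetic phantoms

The phantom is a stylized abdominal template scaled to the grid
(default 64×64×48 at 2 mm isotropic): ellipsoids for liver, kidneys,
spleen, stomach; bent tubes for duodenum (a C-loop hugging the
stomach), small bowel (a winding anterior loop), and large bowel (an
ascending–transverse–descending frame); a posterior midline cylinder
for the spinal canal. Organs are painted in listed code order with
first-come priority, so codes partition the foreground; an organ that
ends up empty or disconnected raises a configuration error naming it.
Intensities are organ-wise means in arbitrary MR-like units plus
additive Gaussian noise (std 5) and an optional low-order multiplicative
bias field (off by default; smooth cosine surface when enabled). Dose
phantoms are flat at `1.15 × PD` inside an 8 mm target sphere with
Gaussian falloff (12 mm scale) outside — smooth, peaked, and monotone
along every ray. Cohorts derive per-patient and per-session child seeds
from one root seed via SHA-256, so everything is bit-reproducible from a
single integer.

What the phantom does **not** emulate: realistic organ shapes and
contact topology, MR pulse-sequence contrast, partial field of view,
cysts and other pathology, sliding interfaces, or breathing. Green
tests therefore certify the correctness of the *operators* (warping,
composition, counting laws, metric definitions) and the plumbing, not
segmentation performance on clinical images.

## Problem sizes and reproducibility

The test suite and the acceptance script run on desk-scale problems
chosen as the smallest grids that still hold all nine template organs:
48×48×32 or 64×64×48 phantoms at 2 mm, a 1 mm 64³ isolated ellipsoid
for sub-voxel recovery oracles, 32³ smooth images for the composition
oracle, and cohorts of 2–7 patients with 2–3 sessions. Sub-voxel
translation/scale recovery is measured on the 1 mm ellipsoid because
nearest-neighbour label warping rounds a spatially constant sub-voxel
shift coherently (up to half a voxel of centroid bias at any
resolution); a mass-weighted centroid on the linearly warped mask
covers the fractional case. All randomness flows from one seed through
named child seeds, and the end-to-end check asserts byte-identical
manifests and metric CSVs across reruns.

## Known limitations

* ϕ is a similarity motion with smooth local support — no curvilinear
  bending, no biomechanics, no guaranteed diffeomorphism (folds are
  diagnosed, not prevented).
* Organ iteration order affects the composed field; it is fixed
  (ascending code) and logged rather than symmetrized.
* Resampling assumes axis-aligned geometries; oblique acquisitions are
  out of scope.
* The DVH voxel model treats voxels as points at their centres; no
  partial-volume dose accumulation.
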