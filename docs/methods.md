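# Methods

## Coordinate conventions

Volumes are `(z, y, x)` arrays: `z` indexes coronal slices posterior →
anterior (reported 1-based as micro-CT *image numbers*; internal indices are
0-based, converted in one place), `y` is the in-plane row proximal → distal
with the origin at the top-left pixel, and `x` the in-plane column. The
canonical frame is a LEFT tibia with `x` increasing medial → lateral;
right-sided stacks are mirrored along `x` on load, which is an involution on
the voxel array. Label volumes use 0 = background, 1 = bone, 2 = articular
cartilage.

## The landmark model

The framework assumes the stack has been brought into a consistent viewer
rotation (the usual micro-CT practice) and formalizes the five slice-wise
bony criteria as measurements on per-slice bone-surface profiles. Each slice
is reduced to h(x), the height of the proximal-most bone voxel per column; a
grey-opening (rolling-minimum) baseline over a 10 mm window is subtracted so
that peak heights are invariant to residual in-plane tilt (the opening of a
linear ramp is the ramp itself, while bumps narrower than the window are
removed — the window must exceed the ~8 mm spine complex). Peaks within 1 mm
of the slice's bone-support edge are discarded: a tilted condylar margin
produces a corner there, not an anatomical prominence. Adjacent peaks closer
than 1.2 mm are merged, since nearest-grid resampling can split one ridge
crest into twin maxima, whereas real prominences (spines 3.6 mm apart, AIA
1.8 mm from each spine) are farther apart. All medio-lateral search bands are
fractions of the *bone extent* of the stack, not of the image width, so
padding and rotation do not move them.

Scanning posterior → anterior ("first image" wins on ties):

* **RP1** — first slice with bone area ≥ 10 voxels (noise floor).
* **RP2** — first slice with *two* spine-scale peaks (prominence ≥ δ =
  0.5 mm) in the central band. The lateral spine arises more posteriorly, so
  the medial spine's emergence is the appearance of the second, more medial
  ridge. This within-slice formulation needs no absolute medial-band
  position and is therefore stable under axial rotation, where ridge x
  positions drift by millimetres.
* **RP3** — first slice where the trough between the two tallest central
  peaks (each ≥ 1 mm, so a freshly emerging ridge cannot carry a saddle)
  becomes shallower than τ = 0.3 mm: the spines fuse in a saddle.
* **RP4** — the two spine ridges are tracked anterior-ward from RP3 (nearest
  peak within 1 mm per slice); RP4 is the first slice where a peak strictly
  between the ridges exceeds both spine heights *of the same slice* by τ.
  Comparing within one slice cancels the uniform crest attenuation that
  resampling causes; the saddle-scale margin keeps single-voxel jitter from
  triggering. RP4 is the least sharp criterion in practice, so all
  thresholds are exposed in `DetectionConfig`.
* **RP5** — last slice where the lateral plateau's *articular footprint*
  persists. On label volumes this is the count of cartilage-bearing columns
  lateral of the intercondylar midline (≥ 5 % of its maximum, floor of 3
  columns); the tibial tuberosity carries no cartilage, so the criterion is
  immune to the tuberosity continuing anterior to RP5. Intensity volumes
  fall back to lateral bone columns beyond a configurable x threshold.

Relative positions are `100·(N_i − N_RP1)/(N_RP5 − N_RP1)`; the plateau
length is the slice span times the slice spacing. Re-zeroing at RP1 removes
blank leading slices from all mm conversions.

## Reference lines and subregions

RL1–RL5 are the coronal planes through RP1–RP5 (RL2 is not used for the
regions). RL6/RL7 are straight lines in the axial (z, x) plane through the
halving points between each spine ridgeline and the outer footprint edge —
lateral anchors at RL3 and RL4, medial anchors at RL3 and the point where
RL5 meets the medial footprint edge (the asymmetry of the two definitions is
preserved as stated; no harmonization is attempted) — extended over the whole
stack. RL8/RL9 are the outer footprint margins and RL10/RL11 the spine
ridgelines, linearly inter-/extrapolated across the RP1–RP5 span.

Longitudinal bands use half-open intervals with the boundary slice assigned
anterior-ward: posterior = [RL1, RL3), intermediate = [RL3, RL4), anterior =
[RL4, RL5]. The central/peripheral split is the signed side of RL6 (lateral
plateau) or RL7 (medial); points exactly on the line count as central. Both
conventions are deterministic tie-breaks. Footprints are the
cartilage-bearing surface columns, split medial/lateral at the valley midway
between the two spine ridgelines. Percent-slice arithmetic rounds half to
even (the printed formula carries no rounding semantics).

## The synthetic phantom

The phantom is an analytic height field over a (z, x) column grid, voxelized
into a bone shell with a cartilage cap, at 0.15 mm isotropic voxels (the
relative-position targets are scale-invariant, so desk-scale voxels replace
the 18 µm of real scans). The default stack is ~280 slices of 110 × 200
pixels: 5 blank posterior slices, a 218-slice RP1–RP5 span (32.7 mm), and
anterior slices holding the tuberosity.

Geometry: two condylar footprints are clipped half-ellipses with curved
centerlines (medial posterior tip defines RP1; the lateral footprint ends
abruptly at RP5, where a shallow EDL groove is carved into the surface); a
posterior slope of 6° tilts the base surface; the spines are Gaussian ridges
(σ = 0.8 mm) at x = 13.2/16.8 mm whose amplitude envelopes are piecewise
linear in z; the inter-spine trough depth is imposed directly by a "bridge"
surface so fusion is an explicit design quantity; the AIA is a third ridge
at x = 15 mm; the tuberosity is an elliptical dome anterior to RP5. Columns
between footprints are filled so the bone shell is a single connected
component.

The criterion crossings are *designed at the ground-truth slices*: the
medial-spine prominence passes δ exactly at RP2, the trough passes τ at RP3,
and the AIA passes the spine height + τ at RP4, each with a steep ramp so
that surface quantization (±half a voxel) and the ~0.2–0.3 mm crest
attenuation of resampling cannot move the crossing slice. Published data
give no quantitative spine/AIA heights; the defaults (spines 4 mm, AIA
5.5 mm above the condylar base) are free parameters chosen for that
sharpness and are exposed in `PlateauShapeParams`.

Thickness fields rise linearly across each footprint from 0.2 mm at the
peripheral (submeniscal) margin to 2.2 mm at the central (spine-side)
margin, for both cartilage and plate, reproducing the central-thick (>1 mm)
/ peripheral-thin (<1 mm) pattern; the rendered voxel runs match the
analytic fields within one voxel per column, and the ground truth stores the
analytic values.

Pathology is placed via the ground-truth subregion map (never the detected
one, to keep oracle independence): osteophytes are marginal bone added
outside the control footprint at the peripheral edge of named subregions
(default: one outgrowth spanning the medial intermediate + anterior
peripheral margins, ~13 mm³), and lesions remove (or thin) the cartilage of
an exact count of columns nearest the target subregion's centroid, so the
affected-area fraction is exact to one column (default: 60 % of the medial
intermediate central subregion, plus 37.5 % of the medial anterior central
and lateral intermediate central ones — the reported post-OA pattern).

What the phantom does **not** emulate: CT intensities and noise, trabecular
microarchitecture, the growth plate, beam-hardening/ring artefacts, natural
shape variability (a single mean shape is generated; `rp_rel`, lengths and
all feature parameters are adjustable but there is no statistical shape
model), and menisci. Passing tests therefore show that the *criteria and
geometry pipeline* recover designed features through voxelization, rotation
and resampling — not that detection is robust to scanner noise or biological
variation.

## Rotation and registration

Rotations are single-plane resamplings about the bone centroid with the
output grid padded so no bone voxel is cropped. Planes follow the viewer
convention: axial = (x, z), sagittal = (y, z), coronal = (x, y); positive
angles rotate the first axis toward the second. Coronal rotation happens
within the slicing plane and leaves image numbers unchanged — the detector
reproduces this exactly on the phantom. Label volumes are resampled by
linearly interpolating per-label indicator images and taking the argmax
(majority-style): label-safe, but far less staircase-prone than plain
nearest-neighbour sampling.

Rigid fits use the closed-form SVD (orthogonal Procrustes) solution with a
reflection guard (det forced to +1); affine fits solve the 12-parameter
least-squares system; both match landmarks by name, validate
collinearity/coplanarity, and report per-landmark residuals and the RMS
fiducial registration error (FRE). The SSD refinement optimizes the six
rigid parameters (Nelder–Mead, coarse-to-fine pyramid, 1e-3 tolerance) on a
binary foreground mask — raw labels would weight cartilage 4× — and never
returns a transform with a higher full-resolution SSD than its
initialization. For registering a rotated stack back to a reference, the
recommended workflow is landmark initialization followed by SSD refinement:
slice-criterion landmarks localize the anterior lateral edge less
consistently on tilted stacks, and the intensity term removes that residual.
FRE, Dice and surface distance are quantitative surrogates added by this
package; the original adequacy judgment for such registrations was visual.

## Morphometry

Thickness is measured along the image column (y) direction per surface
column — a deliberate simplification of surface-normal thickness that
matches per-slice measurement practice on coronal sections: cartilage = the
contiguous cartilage run at the proximal surface, plate = the contiguous
bone run immediately beneath (or beneath the bare bone surface). Sampling
presets place 3 equidistant slices per subregion with the per-subregion
point budgets spread over them; `points96` uses 8 points per subregion
(2 × 48), `points98` redistributes to 52 medial / 46 lateral. Both totals
appear in the source literature for this scheme and the exact per-slice
placement is not recoverable, hence named presets rather than one canon.

Osteophytes are 26-connected components of bone in columns outside the
control bone footprint, filtered at 1 mm³ (configurable), and assigned to
the subregions of the nearest footprint columns within 5 mm. Lesion
fractions are affected columns over subregion columns, binned half-open into
0–25 / 25–50 / 50–75 / 75–100 % with 100 % in the top bin (so exactly 50 %
falls in "50–75%").

## Statistics

Observer errors are pairwise |image-number differences| × slice spacing, in
mm and in percent of each specimen's RP1–RP5 length (mean ± SEM), accepted
when every pairwise mean is below 5 % of length. The ICC is the
single-measure two-way absolute-agreement form

ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

from the two-way mean squares of the n × k table, with the McGraw–Wong
F-based 95 % CI (Satterthwaite degrees of freedom); a zero-variance table is
defined as ICC = 1 with a degenerate CI and a warning. Alternative two-way
mixed/consistency variants are deliberately not offered. The one-way
repeated-measures ANOVA reports F = MS_conditions/MS_error with df (k−1,
(n−1)(k−1)); `nonparametric="auto"` switches to the Friedman test when a
Shapiro normality pre-check of the residuals fails. Both statistics are
verified in the test suite against brute-force sum-of-squares oracles and,
for the ICC, against an independent implementation.

## Problem sizes and determinism

The default phantom (280 × 110 × 200 voxels) generates in ~1 s; the full
test suite, including six ±10° rotations and a registration round trip,
runs in under two minutes on one CPU. The generator is deterministic given
its seed; randomness only enters through optional surface noise
(`surface_noise_mm`, default 0).

## Known limitations

* The detector is validated on clean label phantoms; grayscale stacks need a
  bone threshold and untested noise robustness.
* RP5 on intensity volumes falls back to a bone-column criterion that can be
  confounded by a laterally-placed tuberosity under large axial rotations.
* Thickness along image columns underestimates true normal thickness on
  steeply sloped surfaces.
* Landmark-only registration carries the slice-criterion localization bias
  described above; use the SSD refinement when sub-slice accuracy matters.
* RL6/RL7 anchor asymmetry is reproduced as defined, so the medial
  central/peripheral split converges toward the spine near RP5.
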