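# Methods

`angioseg` is a desk-scale re-implementation of an automatic postprocessing
pipeline for contrast-enhanced head-and-neck CT angiography: cascaded 3D
residual U-Nets segment and subtract bone, a region-conditioned network
extracts the arterial tree, and a connectivity-repair stage closes spurious
gaps in the segmented vessels. Because clinical CTA cohorts of this kind are
not publicly available, the package ships a synthetic phantom generator that
reproduces the statistical structure the pipeline relies on, and every
quantitative claim in this repository is measured on those phantoms.

## The segmentation cascade

**Inputs.** A 3D scalar volume with HU-like intensities in `(z, y, x)` axis
order, `z` the scan axis (feet→head). Voxel spacing is carried in mm;
`normalize_resolution` resamples to a configurable isotropic target (default
0.5 mm; linear interpolation for images, nearest for labels). Large volumes
are decomposed into cubic patches (256³ at clinical scale, 64³ at desk
scale) and probabilities are stitched back with mean (or max) combination
over overlaps.

**Bone stage.** Two cascaded networks: the first maps the intensity volume
to a bone probability; the second ("edge refiner") receives the volume plus
that probability as a second input channel and re-predicts the bone mask.
The thresholded refined mask is subtracted from the volume — bone voxels are
replaced with the configured background fill (default 40) — so the bright
cranium can no longer adhere to intracranial vessels whose intensity is
similar. The downstream vessel and repair networks train on volumes
subtracted with the *predicted* bone mask, so residual bone (a false
negative of the bone stage) is part of their training distribution rather
than a surprise at deployment. In the final result the bone and vessel
masks are reconciled in the vessels' favour: a voxel claimed by both is
reported as vessel, keeping the two masks disjoint without carving thin
vessels out of the tree.

**Region split.** The volume is partitioned along `z` into three bands —
aorta, carotid, intracranial — by two cut fractions (default 1/3, 2/3; cut
index `floor(Z·f)`, last band takes the remainder). The split encodes the
anatomical prior that the three arterial territories differ by an order of
magnitude in calibre, which a single set of convolutional features handles
poorly. One vessel network serves all three bands: the input carries three
one-hot region channels and the output is a single per-voxel vessel
probability; the artery *class* of a predicted voxel is its anatomical
band, which is exactly the classification the split encodes. (A sigmoid
head per artery class was evaluated and rejected: for the thinnest class,
pure-Dice training has a sticky all-positive equilibrium — the push-up
force on a few hundred true voxels balances the carve-down force spread
over the crop — that traps a fraction of random seeds. The shared vessel
head shows no such failure. The network constructor itself remains fully
multi-class: one sigmoid channel per class, ties between heads resolved by
highest probability then lowest class id.) The no-region-split ablation
zeroes the conditioning channels; classes are still banded.

**Connectivity repair.** The repair network receives the image and the
current binary vessel mask as two channels and predicts the voxels missing
from the mask. Additions are constrained to be (a) inside a corridor
obtained by dilating the skeleton endpoints of the input mask (default ball
radius 5 voxels) and (b) 26-connected to the input mask. Consequently the
repaired mask is always a superset of its input and its connected-component
count can only decrease — the stage can merge fragments but never create
new ones. Training pairs are manufactured by severing ground-truth vessels
(see phantoms) and supervising on the removed voxels.

**Cleanup.** A connected-component filter removes per-class components
smaller than a configured size (default 27 voxels at clinical scale, 8 at
desk scale), the same operation used to de-noise annotations before
training. It is idempotent and only ever moves voxels to background.

## Network architecture

The ResU-Net constructor serves all four networks. For `L` levels (default
4) the encoder applies one 3×3×3 stem convolution and `L` kernel-2 stride-2
downsampling convolutions; the decoder applies `L` kernel-2 stride-2
transposed convolutions, each followed by a skip concatenation and a 3×3×3
merge convolution. Eight bottleneck-residual blocks — 1×1×1 contraction to
half the channels, 3×3×3, 1×1×1 expansion, identity shortcut added after
the stack — are distributed two per decoder level. Every convolution is
followed by LeakyReLU with slope 0.1; the head is a 1×1×1 convolution with
one sigmoid channel per class. Channel width doubles per level from a base
of 8 (desk scale; 32+ at clinical scale). A zero-weight bottleneck block is
exactly the identity, which the tests exploit.

Design points where the published description is silent and this package
had to choose:

- **Sampling units**: kernel-2 stride-2 (transposed) convolutions. They
  halve/double each axis exactly, and the stride-2 structure makes the
  backward pass a pure reshape+matmul in the numpy backend.
- **Block placement**: the eight bottleneck blocks sit on the decoder side,
  two per resolution level (configurable via `n_blocks`/`levels`).
- **Normalization layers**: none (matching the described architecture); the
  input is scaled by a fixed intensity constant (default 1/300) instead.
- **Head bias**: the bone and vessel nets initialize their output bias to
  −2 so untrained probabilities start near 0.12 rather than 0.5 — with a
  soft-Dice objective and sparse foregrounds the symmetric start point
  wastes the early schedule suppressing background, and the vessel heads
  can drift toward all-positive before the foreground signal takes hold.
  The repair net instead starts from a neutral bias (0): its target (the
  few hundred voxels of a severed gap) is so sparse that a −2 start sits on
  the edge of a dice-gradient dead zone — occasional runs sink the whole
  output into sigmoid saturation at zero and never recover. Both settings
  are per-stage estimator parameters.
- **Bone edge refiner**: no architectural details are published beyond its
  purpose; it is instantiated as the same constructor with two input
  channels.

The whole stack (layers, backward passes, SGD) is implemented directly on
numpy in channels-last layout; there is no deep-learning framework
dependency. Forward and backward passes are deterministic.

## Training

Loss is soft Dice, `1 − 2Σ(w·p·y) / (Σ(w·p) + Σ(w·y))` with smoothing
ε = 1e-6 in numerator and denominator, averaged over class heads with equal
weights. The optional per-voxel weight map `w` implements the
vessel-interruption remedy: voxels within half the branch radius of a
centerline get weight `factor` (default 2), everything else 1, so missing
the artery core costs more than missing its rim.

The optimizer is plain SGD: momentum 0.9, weight decay 1e-4, learning rate
`0.01 × 0.99995^step` (one step = one batch update). Clinical-scale
training runs 200,000 steps on 256³ patches (kept in
`configs/reference.yaml`, not executed by the tests); the desk-scale
defaults are 32³ crops, batch 1, and 700 / 400 / 500 / 600 steps for the
bone / refiner / vessel / repair networks — sized so the full cascade
trains in minutes on one CPU. The bone net in particular needs the longer
schedule to stop mistaking the thick bright aorta trunk for vertebral bone
(a shape-versus-intensity confusion the phantom deliberately poses); at
short schedules its false positives land exactly on vessels, and the
subtraction then erases them for every later stage.
Crops are foreground-biased: with probability 0.7 a crop is centred on a
voxel of a uniformly chosen present class, which balances the thin
intracranial class against the voxel-rich aorta. Training is fully
deterministic given the seed; non-finite loss aborts with diagnostics.

Training-set expansion follows the 5N augmentation protocol: horizontal
(x-axis) flips, in-plane rotations up to 25°, in-plane shifts up to 20
voxels (image linear / label nearest interpolation), image-only rectangular
occlusion filled with a single random value (emulating metal artifacts),
and additive Gaussian noise. The originals are included once; whether the
published 5N included the originals is not stated, so including them is a
package choice.

## Evaluation metrics

- **DSC** `2|Y∩Ŷ|/(|Y|+|Ŷ|)`; the empty-vs-empty case is defined as 1.0
  (configurable).
- **Recall** `|Ŷ∩Y|/|Y|`; undefined (raises) for empty ground truth.
- **V-score** `Σ weighted(Ŷ∩Y) / Σ weighted(Y)`: a weighted recall whose
  weights decrease from proximal to distal along the tree, so it penalizes
  continuity loss near the vessel origin. The published description fixes
  only the proximal>distal ordering; this package uses
  `w = exp(−decay · g)` with `g` the geodesic (along-centerline) distance
  from the aortic root, decay 0.05/voxel by default. With decay 0 (uniform
  weights) the V-score equals recall exactly. The score as defined lies in
  [0, 1] with 1 perfect; a `negate` flag reports the sign-flipped value for
  parity with conventions that print it negated.
- **Case accuracy**: the fraction of cases whose DSC (and optionally
  V-score) clear configurable thresholds — the published case-level
  "accuracy" has no printed per-case rule, so the rule here is explicit
  and configurable.
- Probability fields are binarized at `p ≥ t`, default t = 0.5 (the
  threshold is introduced but never valued in the source description).

## Synthetic phantoms

`generate_phantom` builds, deterministically per seed, a 64³ (default)
volume containing:

- a single connected arterial tree spanning three calibre regimes along z:
  one aorta-like trunk (radius 4–5.5 voxels) below the first cut, two
  carotid branches (2–2.8) in the middle band, and a binary intracranial
  tree (1–1.6, depth 2) above the second cut. Centerlines are polylines
  with jitter, dilated to tubes via a Euclidean distance transform; vessel
  class labels are assigned by z-band, which makes the region split exact
  by construction;
- bone: a skull-like spherical shell capping the intracranial band, placed
  within a configurable clearance (default 2 voxels) of the uppermost
  vessels to reproduce the bone–vessel adhesion hazard, plus vertebra-like
  blobs behind the carotids;
- intensities: background 40, vessel 250, bone 300 (bone ≥ vessel by
  construction — the adhesion failure mode requires it), plus Gaussian
  noise with σ = 15.

`inject_ruptures` severs chosen branches at interior centerline points by
deleting vessel voxels inside a ball of radius `branch radius +
gap_length/2` (gap length default 3 voxels), records the removed voxels,
and reports whether each gap actually raised the 26-connected component
count. `vessel_weight_map` converts the centerlines into the V-score weight
field described above. All component analyses package-wide use
26-connectivity.

**What the phantoms do not model**: CT physics (beam hardening, metal and
motion artifacts), contrast-phase timing (vein misidentification is out of
scope), anatomical variation of real vasculature, and the intensity overlap
of pathology. Passing the desk-scale experiments therefore demonstrates
that the pipeline's machinery — cascading, subtraction, conditioning,
repair, metrics — is implemented correctly and can be trained, not that the
trained weights would transfer to clinical scans.

## Reproducibility and problem sizes

Every random choice flows from explicit seeds (`numpy.random.default_rng`);
a single CLI seed fans out to per-stage seeds via a CRC-based derivation.
The study exercised by the tests and by `scripts/acceptance.py` uses 30
phantoms at 64³ (24 training, 6 held out) for segmentation quality, and 10
further phantoms with 3 injected ruptures each for repair recovery; these
sizes are the package's desk-scale study conditions. CLI runs write a JSON
manifest (config snapshot, seeds, version, timings, output checksums)
sufficient to rerun bit-identically.

## Known limitations

- The learned region split is replaced by configured cut fractions; an
  interface hook exists but no learned-plane regressor is shipped.
- The repair corridor confines additions near skeleton endpoints; a
  rupture whose fragments are farther apart than twice the corridor radius
  cannot be bridged.
- The numpy backend is single-threaded compute; clinical-scale (256³,
  200k-step) training is configured but not practical in it.
- Multi-class outputs use independent sigmoid heads; probabilities across
  classes need not sum to one.
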