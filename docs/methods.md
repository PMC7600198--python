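# Methods

## The segmentation model

The pipeline treats SDH segmentation as per-superpixel binary
classification followed by 3D morphological repair. Its assumptions are
those of the underlying clinical problem: subdural blood forms connected
crescents directly apposed to the inner skull table, no deeper than
3.2 cm from it; blood is texturally homogeneous relative to brain
parenchyma; and its density relative to brain encodes chronicity (acute
hyperdense, subacute isodense, chronic hypodense, mixed layered).
Isodense collections are therefore separable only by texture and
location, never by intensity alone — this drives most design choices
below.

Axes are `(row, column, slice)` with axial slices last; voxel indices are
0-based, physical positions voxel-center based, and every distance,
filter scale, or smoothing kernel that has physical meaning is expressed
in mm and converted per-axis by the voxel spacing. This matters because
archived head CT is strongly anisotropic (sub-millimeter in-plane,
typically 5 mm between slices): an index-space distance would be wrong by
an order of magnitude along the slice axis.

## Pre-processing

Bone is thresholded at 300 HU (configurable; any value separating bone
from both brain and acute blood behaves identically) and the largest
3D-connected component kept, so per-slice fracture gaps survive. Per
slice, a closed skull ring is flood-filled; a ring judged open (its
filled interior collapses relative to the ring's bounding box) is closed
by a morphological geodesic active contour — a curvature-regularized
level set — grown from the slice interior with an iteration cap of 120
and a convergence window of 2 px change per 10 iterations, falling back
to plain morphological closing when the cap is hit. The ROI band is the
set of intracranial voxels whose anisotropic Euclidean distance to the
inner skull surface is ≤ 32 mm.

### Mirror padding

Texture windows near the skull must not see bone, so the skull is removed
and intracranial intensities are reflected outward across the irregular
boundary: per iteration k = 1..12, the outer mask dilates and the inner
mask erodes by one 8-connected step, and each newly grown pixel copies
its nearest pixel (Euclidean; ties broken row-major, lowest index first)
on the current inner mask. On a straight boundary this reproduces
classical mirror ("reflect") padding exactly; pixels inside the
intracranial mask are never altered. Beyond the padded ring, the slice is
extended by nearest-valid-value fill so the largest filter kernels see no
artificial step; this extension lies outside every analysis window and
only stabilizes convolution tails.

## Features

51 hand-crafted columns per superpixel: 9 histogram statistics from the
25 × 25 px centroid window (min, max, mean, sd; superpixel mean;
skewness, excess kurtosis and entropy of a 32-bin histogram over the
0–100 HU brain window; smoothness R = 1 − 1/(1+σ²) on [0, 1]-rescaled
intensities, with skewness/kurtosis of a flat patch defined as 0); 32
Gabor magnitudes (8 orientations × wavelengths {2, 4, 8, 16} px/cycle,
envelope σ = 0.56·λ ≈ one octave); 5 LoG scales (σ ∈ {1, 2, 4, 8, 16}
px); spherical location (r, θ, φ, r′); and age. Filter responses are
pooled as the mean over the superpixel's own pixels (magnitude for
Gabor, signed for LoG).

Two numerical details depart from the naive implementation. Sampled
Gabor/LoG kernels do not sum exactly to zero, leaking an
orientation-dependent DC response that would make "texture" features
depend on absolute intensity; bank kernels are therefore DC-corrected by
subtracting a Gaussian-envelope-proportional component, which also makes
the symmetric LoG annihilate affine images exactly. Convolutions use
edge-replicated boundaries for the same reason.

The location frame fixes its origin at the skull's center of mass on the
lowest axial slice with at least 200 intracranial pixels; the midline is
the in-plane principal axis of the intracranial mask on that slice,
oriented anterior, so the azimuth is robust to head tilt and mirrored
points get equal-magnitude, opposite-sign θ.

### Deep features (optional, off by default)

A compact encoder–decoder network (3 levels, base 16 channels, last
decoder layer widened to 64 channels as the feature tap, 1 × 1 sigmoid
output) implemented directly in NumPy (im2col convolutions, manual
backpropagation, Adam, cross-entropy + soft-Dice loss) is trained per
fold on that fold's training scans only; per-superpixel features are the
64 tap activations mean-pooled over the superpixel. A fold-identity check
makes it impossible to extract features for a scan from a model whose
training saw it. The architecture and budget (4 epochs, 32 px patches)
are sized for CPU execution; they exercise the integration contract, not
a claim of matching a full-scale network.

## Classification

Random forest, 200 trees, √p features per split, unlimited depth, fixed
seed. Folds split by scan — never by superpixel — and stratify on
(lesion type, volume stratum at cut points 25/50/100/200 cc), dealing
round-robin with a rotating offset after a seeded shuffle. Training
rebalances by keeping every positive superpixel and drawing an equal
number of negatives without replacement. Probabilities map back to
voxels as superpixel-constant fields; the initial mask thresholds at
0.5, the natural operating point of a balanced forest.

## Post-processing

Order: 2D component filtering → hole/gap filling against the skull → 3D
continuity → 3D Gaussian smoothing. Defaults are stated for the
generator's 0.75 mm in-plane, 5 mm slice grid and are configurable.

- **2D clean**: components below 128 px (≈ two superpixels) are removed.
  In a superpixel-classified mask the smallest possible detection is one
  superpixel (~64 px), so a pixel-scale area floor would never fire; the
  operative notion of "sparse" is an isolated single-superpixel
  misclassification.
- **Fill against skull** (radius 2 px ≈ 1.5 mm): closing of mask ∪ skull
  bridges sub-radius gaps along the inner table; holes enclosed after
  skull removal are filled only up to 200 px — two detections plus the
  skull ring can enclose a large pocket of healthy brain, which must stay
  open — and only repairs attached to an original detection survive.
- **3D continuity**: 26-connected components spanning fewer than 2 slices
  are dropped, with components on adjacent slices merged when their
  footprints lie within 4 mm in-plane. At 5 mm slice spacing a crescent
  following the curved inner table shifts in-plane by several voxels
  between slices; strict voxel connectivity misreads that drift as a
  break and would delete correctly detected end caps.
- **Smoothing** (σ = 1 mm, physical): re-binarization is
  volume-preserving — the threshold is the blurred field's quantile (taken
  within the ROI band) that keeps the pre-smoothing voxel count. A fixed
  0.5 level is unbiased only for straight boundaries; for a crescent a
  few voxels thick it is strictly erosive (mean-curvature shrinkage), and
  blur mass leaking into the skull would otherwise count against the
  mask.

## Severity and evaluation

Volume is voxel count × voxel volume in cc; the dichotomy is < 25 cc
(non-hematoma/mild) vs ≥ 25 cc (moderate/severe). Dice, recall and
precision are undefined (reported absent) for lesion-free references;
specificity takes its complement within the ROI band, since voxels the
classifier never saw are not meaningful negatives. Volume agreement
reports the least-squares slope (with SE), the through-origin slope, and
Bland-Altman bias with 1.96·sd limits. Severity confusion statistics are
percentages to two decimals for the ≥ 25 cc class.

## The phantom generator

The generator emulates the imaging structure the method depends on, at a
reduced grid (224 × 224 × 18 voxels, 0.75 × 0.75 × 5 mm — clinical-like
in-plane scale on a smaller matrix so the fixed 25 px window keeps a
realistic physical footprint):

- **Cranium**: a superellipsoid shell (z-exponent 4) 6 mm thick at
  1000 HU. A plain ellipsoid was rejected because its strong wall
  curvature in z makes crescents jump in-plane between 5 mm slices far
  more than a real, near-vertical parasagittal skull wall does.
- **Interior**: brain at 35 HU carrying a smooth correlated texture field
  (6 HU sd, ~4.5 mm correlation in-plane) plus 4 HU white noise; a
  central CSF cavity; and a 2 mm subarachnoid CSF rim along the inner
  table. The rim is load-bearing: subdural blood displaces it, so
  "isodense tissue directly against bone" is evidence of subacute blood
  only because normal cortex is separated from bone by CSF. Without the
  rim, normal scans are indistinguishable from subacute lesions near the
  skull.
- **Lesions**: the region between the inner-skull surface and a copy of
  it displaced away from the lesion apex, clipped to an angular sector
  whose half-width grows with volume (70°–115°) so severe collections
  spread rather than pooling implausibly deep; the displacement is
  bisected so the realized voxel volume hits the target within 10%.
  Classes: acute 70 HU, subacute 35 HU (isodense by construction),
  chronic 15 HU, mixed = skull-adjacent acute layer over a deeper chronic
  layer. Blood is homogeneous apart from noise.
- **Cohorts**: lesion cases deal round-robin across volume strata
  (defaults 8–25, 25–50, 50–120, 120–220 cc) with the lesion-type cycle
  deliberately out of phase so type and size decorrelate; cases ≥ 50 cc
  present bilaterally with a smaller contralateral lesion of
  complementary chronicity (acute↔chronic, subacute↔mixed), mirroring
  combined presentations in the elderly and giving every
  cross-validation fold thin *and* thick examples of each intensity
  class; sub-25 cc cases skew acute (small mixed lesions are clinically
  implausible — rebleeds occur into already-large chronic collections);
  ages are drawn per chronicity (chronic/mixed elderly, acute younger).
  Everything is a pure function of the seed.

What the phantom does not emulate: gyral/sulcal anatomy, beam hardening
and streak artifacts, partial-volume blur at the skull interface,
non-SDH pathology (hygroma, epidural blood, contusion), and annotation
noise. Consequently the phantom cohort is *easier* than clinical data:
the classifier reaches superpixel AUC ≈ 0.99 and initial Dice ≈ 0.9,
where the clinical regime is markedly noisier. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under controlled
contrast/volume/laterality conditions, not clinical-grade accuracy. One
concrete consequence: with near-ceiling initial masks, the post-processing
chain is approximately neutral on average (stage-wise: continuity
filtering gains, smoothing loses slightly), whereas on noisy clinical
probability maps the same chain is reported to help; the direction of the
before/after comparison on phantoms is within half a Dice point of zero
and lands slightly negative at the default conditions.

## Problem sizes and determinism

The reproduction run (`scripts/acceptance.py`) uses 10 lesion scans + 2
lesion-free controls under 2-fold scan-level cross-validation with
hand-crafted features only — about 2,800 superpixels per scan — chosen as
the smallest cohort in which every fold trains on all four chronicity
classes at more than one thickness. Unit tests use a 96 × 96 × 10 grid.
All randomness (phantom synthesis, fold shuffling, undersampling, forest
seeds, network initialization) derives from a single integer seed;
reruns are bit-reproducible.

## Known limitations

- Sub-25 cc lesions segment far less reliably than larger ones (halo
  false positives and partial detections dominate at that scale); the
  severity call near the 25 cc boundary inherits that uncertainty.
- The level-set closure of open skull rings is exercised on synthetic
  gaps only; cranial-base anatomy is far harder.
- The forest extrapolates poorly to feature regimes absent from its
  training folds (e.g. depths r′ beyond any training lesion); small
  cohorts must cover the intended volume range per fold.
- The deep-feature network is CPU-scale; enabling it on the default
  cohort multiplies runtime severalfold and is off by default.
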