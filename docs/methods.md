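# Methods

`daras` implements the recognition half of an ambient in-home monitoring
system built around a wall-mounted depth sensor: from depth frames
(millimeter distances per pixel) and 19-joint skeleton streams, it labels
every frame with one of six activity categories — walking, reaching
overhead, reaching forward, reaching below the waist, hand manipulation, and
a background class ("none of the above") that also absorbs simultaneous
mixed actions — and segments the labeled frames into action instances.
Because the clinical recordings such systems produce cannot be shared, the
package ships a synthetic session generator that stands in for them; every
stage downstream of the files on disk is identical either way.

## Data model and formats

Frames are 0-based; temporal intervals are half-open `[start, end)`. Depth
frames are stored as single-channel 16-bit PNGs whose pixel value is the
distance in millimeters (no rescaling). The logger's batched write cache is
persisted as a `.dcache` block: an 8-byte magic plus u32 frame count, height
and width; a zlib-compressed concatenation of at most 30 little-endian u16
frames; and a CRC-32 of the compressed payload as the tail. The block format
is a frozen dialect of a mechanism whose published description names only
the batching (30 frames) and the header/tail validation, not the bytes; the
logger's live threading machinery (`consume`/`full` status flags) is not
emulated, only the at-rest format. Skeleton streams are JSON-lines, one
record per body per frame, holding 3D joints in meters, optional 2D pixel
projections, and a floor plane; label tracks and segment lists are TSV.

The 19-joint template follows the Astra-style convention: head, neck, chest,
torso, mid-hip, plus left/right shoulder, elbow, wrist, hand, hip, knee, and
foot. Published descriptions of such sensors give only the joint count, so
the naming is frozen here.

## Synthetic sessions

The generator animates an articulated figure (bones rendered as capsules)
in front of a flat wall 4 m from the camera, viewed side-on at chest height
through a pinhole model, and emits aligned depth, skeleton, and per-frame
truth. Actions are parameterized kinematically:

* **walking** — the root translates laterally (±0.7 m, out and back) with
  antiphase leg swing;
* **reaching overhead / forward / below waist** — one arm blends from rest
  toward a target (wrist 0.55 m above the shoulder, 0.55 m forward, or
  0.95 m down) along a raise–hold–lower profile with cosine-eased ramps, so
  the wrist trajectory is unimodal and the clip starts and ends at rest;
* **hand manipulation** — the forearm holds at counter height with a small
  (~0.1 m) rhythmic wrist oscillation;
* **background** — idle standing with millimeter-scale sway.

Every clip starts and ends at the rest pose, which makes concatenated
scripts hand off smoothly. Noise defaults are 5 mm depth noise, 5 mm joint
noise, and 2% per-joint dropout (dropouts are NaNs, linearly interpolated
before the skeleton network). Default frame rate is 8 fps, the rate the
logger achieves in deployment; 30 fps is configurable. Amplitudes and speeds
are the package's own choices of ordinary kitchen-activity motion — they are
not estimates for any clinical cohort, and nothing about impaired movement
(reduced range, compensation, tremor) is modeled. Passing tests on this
generator demonstrate that the pipeline's machinery is correct and that the
detectors can learn genuinely separable spatiotemporal classes; they say
nothing about accuracy on real in-home recordings. The renderer is likewise
deliberately minimal: no objects, clothing, self-occlusion handling, or
sensor artifacts beyond Gaussian noise.

A second idle body can be injected over a frame span to exercise the
multi-person filter.

## Annotation rules

Ground-truth tracks are cleaned with two rules: non-background runs shorter
than 5 frames are relabeled background (relabeled rather than excised so the
depth, skeleton, and label streams stay frame-aligned; excision happens only
at clip export), and background runs longer than 150 frames are truncated to
their first 50 frames, with the dropped frames leaving the dataset view via
a returned index map. A run of exactly 150 frames is untouched (strict
inequality). Short-run relabeling is applied first, so a removed fragment can
merge two background runs which are then truncated as one. Whether the
5-frame rule should also delete short *background* runs is genuinely
ambiguous; here it applies to action runs only, with a switch
(`apply_min_to_background`) for the other reading. Frames where two or more
bodies coexist are removed outright from all three streams. Class balancing
augments rare action classes (temporal resampling ±20%, horizontal mirror
with left/right joint swap, additive noise) up to a ≤2:1 max/min spread and
down-samples background to at most the largest action-class count; the 2:1
target is a declared default, not a published value.

## HON4D descriptor

For each interior pixel of each consecutive frame pair, a 4D normal
`(dz/dx, dz/dy, dz/dt, −1)` is formed from central spatial differences and a
forward temporal difference, then unit-normalized; the constant −1 keeps the
vector nonzero on flat regions. Border pixels are skipped rather than
clamped, so a K-frame H×W clip yields (K−1)(H−2)(W−2) normals. The 120
vertices of the regular 600-cell (8 permutations of (±1,0,0,0), 16 of
(±½)⁴, 96 even permutations of (±φ, ±1, ±1/φ, 0)/2) serve as projectors;
bin k accumulates `max(0, p_k·n)`. The clip volume is split into a 4×4×3
(width × height × time) cell grid — read as cell *counts*, with ⌈dim/cells⌉
pixel extents — per-cell histograms are L2-normalized, concatenated (5760
values), and L2-normalized again. "Combined and normalized" admits a
sum-pooling reading too, so `pool="sum"` collapses the grid to 120 bins; the
concatenation is the default. Only the descriptor half is implemented — no
discriminative projector refinement. Pre-segmented clips are classified with
a linear max-margin one-vs-rest SVM (scikit-learn `LinearSVC`, fixed seed).

## Networks

All three networks run on a compact numpy layer library written for this
package (`daras.nn`: 3D/1D convolutions, ceil-mode max pooling,
zero-stuffing temporal upsampling, ReLU, fully connected layers, SGD with
momentum, weight decay, step decay, and optional gradient-norm clipping).
Float32 arithmetic and explicit forward/backward passes keep desk-scale
training fast on one CPU and bit-reproducible given a seed.

**CDC (per-frame scorer).** Five conv/pool stages reduce a 112×112×L
single-channel window to a 4×4 map at L/8 temporal resolution (pooling is
ceil-mode, so 112→56→28→14→7→4); three de-convolutional stages collapse
space to 1×1 and upsample time through L/4 and L/2 back to L, ending in a
per-frame (K+1)-way softmax, i.e. a (K+1, L, 1, 1) output per window. The
temporal upsampling is realized as zero-stuffing followed by a kernel-3
convolution (equivalent to a stride-2 transposed convolution); internal
kernel sizes are 3 everywhere, a frozen choice since only the stage
resolutions are published. Untrimmed video is cut into non-overlapping
16-frame windows, the last padded by repeating the final frame (padding
dropped after prediction). Depth enters the network as `mm/8000 − 0.5`: a
fixed full scale so the unit is preserved, centered because the uncentered
variant leaves a DC component that measurably stalls SGD on these small
ReLU networks. Channel widths are scalable; geometry contracts (×8 temporal,
112→4 spatial) hold at any width.

**R-C3D-style detector.** Three conv/pool stages (temporal stride 8) plus a
spatial global max produce a temporal feature map over the whole sequence.
A proposal head scores ten anchor scales {2,4,5,6,8,9,10,12,14,16} per
feature position (anchor center of position j is (j+0.5)·stride) and
regresses offsets t_x = (x−x_a)/w_a, t_w = log(w/w_a). Surviving proposals
(score ≥ 0.05, greedy NMS at IoU 0.7) are RoI-pooled to a fixed temporal
length (4 bins, max per bin) and classified/refined by two fully connected
stages with per-class offsets; final detections pass a 0.30 class-score
floor and per-class NMS at 0.4. NMS ties break by earlier start then shorter
length, so output is deterministic. A per-frame track is painted from the
detections (higher score wins overlaps) because evaluation and fusion are
per-frame.

**RHCN (skeleton detector).** Joint positions S (root-centered at the
mid-hip) and their temporal differences M_t = S_{t+1} − S_t (final frame
zero-padded; repeat-last available) pass through per-stream point-level
convolutions with kernel extent 1 along the joint axis, a transform stage
that swaps the joint and feature axes so subsequent convolutions mix all
joints (co-occurrence learning), two pooled co-occurrence stages (temporal
stride 4), and a fusion convolution over the concatenated streams. The same
proposal/classification subnets follow, with long anchor scales
{50,100,200,400}. Because skeleton streams are the noisier modality, only
walking detections are kept by default (configurable set).

**Training.** Both detector subnets optimize mean softmax cross-entropy plus
a smooth-L1 offset regression active only on positive anchors (kink at 1.0,
trade-off λ = 1). Anchors are positive at IoU ≥ 0.7 against their best
ground truth, negative below 0.3, ignored between; these thresholds and the
NMS thresholds follow the anchor-detection lineage the architecture comes
from and are all configurable. Two hyperparameter profiles exist. The
`paper` profile preserves the published settings verbatim — CDC: SGD
momentum 0.9, weight decay 0.005, lr 0.001 decayed ×0.1 every 5000
iterations; detectors: lr 1×10⁻¹⁴, weight decay 0.0005, decay step 7, 10
epochs. A learning rate of 10⁻¹⁴ cannot move float32 weights, so this
profile is in effect a frozen-feature regime; it is kept as printed rather
than silently corrected. The `desk` profile actually learns at test scale:
CDC lr 0.01 (clip-norm 5, decay ×0.5 every 900 iterations, 16 epochs, batch
8); detectors lr 0.005, 10 epochs, positive threshold relaxed to 0.5 with
best-anchor forcing, since desk-scale actions (16–28 frames) rarely reach
0.7 IoU against the fixed scale set. Detector heads start with their final
layers scaled by 0.1 so early logits are near-uniform. Batch-of-one SGD on
tiny models occasionally collapses to the background prior; the collapse is
visible in the final training loss, so the ensemble trainer deterministically
retrains from a shifted init seed when the loss ends above a plateau
threshold (0.9 for the CDC, 1.2 for detectors, at most two restarts).

## Fusion and metrics

Per frame, the three detectors each cast one vote; two agreeing votes win,
otherwise the frame is background. Fused runs shorter than 5 frames are
suppressed to background — the same minimum-duration convention the
annotation rules impose on ground truth. Per-frame precision is micro
accuracy over all frames (background included; an actions-only variant and
macro per-class precision are also reported since the estimator was never
published). Per-action precision is the fraction of predicted non-background
segments matched one-to-one (greedy by score) to a same-label ground-truth
segment at temporal IoU ≥ 0.5, the community-default threshold, exposed as a
flag. Confusion matrices are row- (ground-truth-) normalized.

## Desk-scale benchmark

The end-to-end benchmark trains the ensemble on 200 synthetic single-action
sessions (one action instance of 16–28 frames framed by 8–16 background
frames on each side, 28×28 depth, default noise) and evaluates the fused
output on 50 held-out sessions, pooling frames and segments across sessions.
Tiny widths are used throughout (CDC 4–8 channels, detector backbones 4–32).
These sizes are the package's choice of a benchmark that a laptop CPU
finishes in minutes while still exercising every stage; the published
system trained far larger models on months of in-home recordings, and the
numbers from this benchmark are not comparable to any clinical result.

## Known limitations

* The synthetic generator produces one stereotyped trajectory family per
  class; real intra-class variation (handedness, speed, style, pathology) is
  absent, so desk-scale accuracy overstates what identical models would do
  on real data.
* The RHCN anchor scales {50,100,200,400} target multi-second walking bouts;
  on short synthetic sessions detection relies on boundary regression
  shrinking the shortest anchor, which works but is stretched outside its
  design regime.
* `roi_out_len`, score floors, and NMS thresholds are sensible defaults, not
  reconstructions; none were published.
* The cache format, skeleton-stream schema, and joint naming are frozen
  dialects; they are self-consistent round-trip formats, not byte-compatible
  with any vendor SDK.
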