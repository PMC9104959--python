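# Methods

This note records the scientific and numerical choices behind `lighteyes`:
what the model computes, where the published description leaves the design
open and what this implementation chose, what the synthetic fixtures do and
do not establish, and the problem sizes the test suite runs at.

## Network

The encoder is a stack of `nl` (default 24) same-padded 3×3 stride-1
convolutions, each followed by ReLU. Zero padding of (k−1)/2 on every conv
is what preserves resolution end to end; the padding scheme is forced by
the requirement that all encoder maps have the input's spatial size. Width
is `nc` (default 16) for layers 1–`nl`/2, then a width-reduction conv maps
to `narrow_width` (default 8) for the remaining layers. For non-default
depths the same schedule generalises: wide block = layers 1..`nl`//2,
reduction at `nl`//2+1, mid-branch tap at layer min(`nl`//2+3, `nl`) —
which reproduces the classic conv1–12 / conv13 / conv15 layout at `nl`=24.

Decoder choices that the architecture description leaves open, and how they
were fixed here:

* **Pooling** — the pooled branch uses 2×2 **max** pooling, stride 2
  (configurable to average). Max is the common default in segmentation
  encoders of this family.
* **Half-resolution head** — the pooled branch's 1-channel head operates at
  half resolution and is *then* upsampled ×2; the per-layer accounting of
  the architecture is only self-consistent with this ordering, so it is
  used even though a prose reading could place the head after upsampling.
* **Auxiliary supervision at full resolution** — the pooled branch's head
  is supervised *after* upsampling, against the full-resolution ground
  truth. This avoids inventing a ground-truth downsampling rule.
* **Upsampling** — bilinear, align-corners-off convention (output sample i
  reads source coordinate (i+0.5)/2 − 0.5). Nearest-neighbour is available
  via config.
* **Heads carry logits** — ReLU follows every conv except the four
  1-channel heads, which must keep signed logits for the losses and the
  fusion conv.
* **Fusion input** — the fusion conv consumes the three branch **logits**
  (pre-sigmoid), making it a genuine learned fusion; a post-sigmoid variant
  is a config switch (`fusion_input: probabilities`).
* **Input normalisation** — images are scaled to [0,1] (divide by 255 when
  8-bit); no mean subtraction.

Forward passes require even height and width so the pool/upsample pair
restores size exactly; the inference path reflect-pads odd inputs and crops
the output back. Per-layer "ops" counts are not reported in the summary:
no reconstruction of the original op-counting convention matched the
printed numbers, so the summary confines itself to filters, parameters and
receptive fields, which are exact.

### Receptive fields

Computed by the standard recursion rf ← rf + (k−1)·jump, jump ← jump·stride
along the unique path from the input (upsampling counts as k=2, stride ½).
For the default network: encoder tap 49×49, mid-branch head 33×33, final
head 51×51, pooled-branch head 66×66. The test suite validates the
recursion against a forward-perturbation support oracle on a
constant-positive-weight network, where reachability is exact in floating
point (unreachable units are convolutions of exact zeros).

## Loss

The random-drop loss is implemented exactly as the sum form

L = −β Σ_fg log p_j − (1−β) Σ_bg 1(p_j) log(1−p_j),  β = N_n/(N_n+N_p),

with these choices where the definition is silent:

* **β uses the retained background count** N_n (the literal definition),
  recomputed from each draw, not the pre-drop background count.
* **Reduction** is the sum, as written; a mean option exists but is off by
  default.
* **Per-head independence** — the three auxiliary losses and the fusion
  loss each draw their own drop indicators and compute their own β; heads
  are summed with equal weight 1.
* **Clamping** — probabilities are clamped to [1e−7, 1−1e−7] before the
  logs. 1e−7 keeps |log| ≤ ~16 while being far below any probability the
  sigmoid produces from O(10) logits.
* Degenerate maps: all-foreground gives β=0 and hence L=0 (the weighting
  annihilates the loss); no foreground *and* no retained background is an
  error rather than 0/0.

Gradients are returned with respect to the probability map (∂L/∂p); the
training step chains through the sigmoid analytically. The full network
gradient is checked against central finite differences to ≤1e−6 relative
error in the tests.

## Metrics

Confusion counts are tallied pixel-by-pixel, restricted to the FOV mask
when one is supplied. Conventions chosen where unstated:

* **Threshold grid** for the equilibrium point: 256 evenly spaced values in
  [0,1], augmented with every distinct probability when the pooled map has
  ≤10⁴ pixels (then the sweep is exhaustive). Binarization is p ≥ t.
* **Ties** in |Pr − Re| break toward the lower threshold (higher recall).
* **Dataset-level pooling** — test images are concatenated and a single
  global equilibrium threshold is chosen, rather than per-image
  thresholds; a single operating point is the natural reading of
  equilibrium binarization.
* **FOV policy** — vessel evaluation conventionally counts only in-FOV
  pixels (`use_fov=True`); lesion evaluation counts the whole image.
* Zero denominators yield NaN with a warning, never a silent 0.

ROC-AUC is delegated to scikit-learn and cross-checked in the tests against
the O(n²) Mann–Whitney pairwise statistic.

## Training regime

Defaults mirror the regime the architecture was designed for: ADAM at
constant learning rate 1e−3, batch size fixed at 1, xavier-uniform
initialisation, iterations over the augmented training list in seeded
shuffled order. Unstated details fixed here: ADAM moments (0.9, 0.999,
1e−8) — recorded in every run record; no weight decay; no learning-rate
schedule; no test-time pre/post-processing. A non-finite loss aborts with
the per-head β, N_n, N_p at failure.

The ×6 augmentation set is {identity, horizontal flip, vertical flip,
rotations 90°/180°/270°} — right angles so masks need no interpolation;
this reproduces the 54→324 and 20→120 training-set expansions. (A printed
10→80 expansion for one vessel dataset implies ×8 and is inconsistent with
×6; the factor is a config knob, default 6, and the discrepancy is simply
documented.) Rotating non-square images transposes H and W, which a fully
convolutional model at batch size 1 accepts. Lesion-scale images are
resized to 712×1072 (H×W) — bilinear for images, nearest for masks.

## Synthetic fixtures

The generator emulates only the statistics the pipeline is sensitive to:

* **lesion** task: sparse bright blobs (radius 1–4 px) on a vignetted
  reddish background with Gaussian noise (sd 8 of 255), at a target
  foreground fraction defaulting to 0.001 — the microaneurysm imbalance
  regime. Blob radii are capped adaptively so the delivered fraction stays
  within a factor 2 of the request.
* **vessel** task: branching random walks, widths 1–4 px (width-1 masks
  are skeletonized so they are exactly one pixel wide), default fraction
  0.08. These are random walks with curvature, not physiological trees.

Foreground contrast (≈70/255) and noise were chosen once so that a plain
intensity threshold reaches ROC-AUC > 0.8 — i.e. the task is verifiably
winnable — and that ~200 training iterations at 64×64 suffice for the
end-to-end smoke test. Passing on these fixtures demonstrates that the
architecture, loss, optimiser and evaluation machinery are wired correctly
and can fit a separable thin-structure/small-blob task; it does **not**
demonstrate segmentation accuracy on real fundus photographs, which have
texture, illumination variation, camera effects and anatomy the generator
deliberately omits. Generation stalls (100 consecutive placements adding no
foreground) raise an error rather than silently under-delivering the
requested fraction.

## Problem sizes in the test suite

Unit tests run the full-size default network only for cheap accounting and
single forward passes; gradient checks use a reduced network (nc=4, nl=4–6)
where finite differences are fast; the training smoke test uses the
published optimizer settings (ADAM 1e−3, batch 1) at 200 iterations on four
64×64 synthetic lesion images with two held-out images — small enough to
run in about a minute on one CPU core while still exercising every head,
the drop loss, checkpointing and dataset-level evaluation.

## Known limitations

* The numpy backend is single-image and CPU-only; it is intended for
  correctness, small-scale experiments and testing, not for the tens of
  thousands of iterations full-resolution benchmark training requires.
* No pretrained weights are shipped or importable from other frameworks.
* The equilibrium threshold is computed over a finite grid; for maps with
  >10⁴ pixels the minimizer is grid-resolution accurate (1/255 spacing).
* The fixture generator is not a retinal image simulator of record; no
  optics, no camera noise model, no inter-image variability.
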