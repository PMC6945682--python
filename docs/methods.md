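# Methods

## Problem and model

A rectified stereo laparoscope sees corresponding points on the same image
row, separated by a disparity `d ≥ 0` that is inversely proportional to
depth (`D = f·B/d`, focal length `f` in px, baseline `B` in mm). The
package-wide sign convention is that the right-view column matching left
column `x` is `x − d`; one constant (`losses.WARP_SIGN`) carries this
convention so no sign logic is scattered.

Supervision comes from classical stereo rather than ground truth. The
classical matcher is AD-CENSUS: per pixel and candidate disparity, a census
Hamming cost (9×7 window by default, edge-replicated borders, bit = 1 iff
neighbour strictly darker than centre) and an absolute-difference cost are
combined as `ρ(c_census, λ_census) + ρ(c_AD, λ_AD)` with
`ρ(c, λ) = 1 − exp(−c/λ)`, giving costs in [0, 2]. Defaults `λ_census = 30`
(bit counts) and `λ_AD = 10` (8-bit intensity scale; divided by 255
internally since images travel in [0, 1]) follow the published constants of
the cost combination. Aggregation is fixed-window box filtering (7×7),
chosen over cross-based regions with scanline optimisation because it
preserves plain cost-volume semantics — which the confidence measures
sample — and admits an exact brute-force oracle; cross-based aggregation is
an extension point, not a default. Out-of-view cells carry an infinite
sentinel: they are excluded from aggregation means and never win
winner-take-all; a pixel with no finite cost at all becomes invalid (0).
Winner-take-all breaks ties toward smaller disparity (determinism) and
optionally refines by the parabola through the winner and both neighbours,
clamped to ±0.5 px.

## Confidence distillation

Each measure acts as a veto and the retained set is the conjunction — a
pixel survives only if every enabled measure accepts it. Distillation never
edits a value; it only zeroes pixels.

| measure | rule | default threshold |
|---|---|---|
| LRC | `\|d_l(x) − d_r(x − d_l(x))\| ≤ ε` (rounded sample; off-image fails) | ε = 1 px |
| UC | among row pixels claiming one target column, only the cheapest winning cost survives | — |
| DB | Chebyshev distance to the border ≥ margin | margin = d_max |
| APKR | windowed mean of `c₂/c₁ ≥ thr` | 1.5 |
| WM | `(c₂ − c₁)/Σc ≥ thr` | 0.02 |
| median | `\|d − median₅ₓ₅(valid)\| ≤ τ` (evaluation profile only) | τ = 2 px |

`c₂` is the smallest cost at disparities non-adjacent to the winner
(`|Δd| > 1`) — a deterministic surrogate for the second local minimum that
behaves on coarse 10–20-bin cost curves; `c₁` is floored at 1e−6. Median
windows with fewer than 3 valid pixels pass by default so sparse regions
are not mass-rejected (DB already guards borders). Two profiles exist:
`training` = {LRC, UC, DB, APKR, WM} for building training labels, and
`rigid` = training + median for building proxy ground truth at evaluation
time; the defaults make `rigid` strictly tighter. No published threshold
values exist for this distillation, so all of the above are package
choices, exposed in the config.

## Losses

All four terms are computed at four scales (1/8 … 1/1 of input resolution)
and summed with weights (α, β, γ, φ) = (1.0, 1.0, 0.1, 0.5), the published
operating point. Images are block-mean downsampled per scale; proxy labels
are decimated nearest-neighbour on their support with values divided by the
scale factor (disparity is resolution-dependent; decimation keeps sparsity
semantics). Every term averages only over principled-mask-valid pixels —
the mask is computed analytically as "sampling coordinate inside
[0, W−1]" — and the photometric term additionally erodes the mask by the
SSIM window radius so a pixel contributes only if its whole comparison
window is valid; an exact reconstruction then scores exactly zero.

* `L_r`: `α_ssim (1 − SSIM)/2 + (1 − α_ssim) L1` per view, α_ssim = 0.85,
  SSIM with 3×3 mean pooling and C1 = 0.01², C2 = 0.03².
* `L_rc`: mutual L1 between each view's disparity and the other view's
  disparity bilinearly sampled at the matching column, both directions.
* `L_p`: over the proxy support, `|d_l − d̃|` plus `|d_r(sampled at
  x − d_l) − d̃|`, normalised by N_p; samples leaving the image drop the
  second term; an empty support defines `L_p = 0` with a warning. The
  matching coordinate uses the package sign convention (sample at `x − d`),
  treating the generic warped-index notation of the loss definition
  accordingly — with non-negative disparities the opposite sign would
  sample away from the correspondence.
* `L_s`: `λ Σ (D_i − D_j)² exp(−t (f_i − f_j)²)` over horizontal and
  vertical neighbour pairs, normalised by the pair count so φ is
  resolution-independent; λ = 1 (φ already weights the term), t = 10 —
  both unpublished, chosen so that a one-intensity-unit feature edge
  damps the penalty to e^(−10). `D` is the predicted *disparity* at that
  scale, not metric depth: the loss then needs no camera model, and
  disparity and depth smoothness agree up to first order on smooth
  surfaces. `f` is the channel-mean of the same-scale decoder feature
  map, min-max normalised per image — the nearest spatially aligned
  activation tensor.

Gradients: every loss is built on the in-package reverse-mode autodiff
engine, so `∂L/∂d` (and `∂L/∂f`) are analytic; the test suite verifies
them against central finite differences at 1e−4 relative tolerance.
Non-smooth points (L1 at zero, bilinear knots at integer coordinates) have
measure zero for the random inputs used.

## Network and training

Both branches share one parameter set; the right branch sees the
horizontally flipped right image and its outputs are flipped back, so a
single network learns a single disparity chirality. Convolutions use
edge-replicated padding — a constant image then stays constant through
every layer, which makes the two branches agree exactly on symmetric
inputs (and suits images better than zero borders). Disparity heads are
3×3 convolutions with sigmoid output scaled by
`max_disparity_fraction × W(scale)` (default fraction 0.3). Head weights
are initialised at 0.1× the He scale: the network starts near mid-range
disparity, away from sigmoid saturation — with full-scale head
initialisation the large initial consistency loss drives the heads into
saturation within a few Adam steps, after which the gradient vanishes —
while keeping enough spatial variation to break symmetry.

Backbones: `tiny` (four stride-2 ELU conv blocks, 16/32/64/64 channels,
~1.3e5 parameters, /16 bottleneck) is the tested default; `resnet50`
(bottleneck stages [3, 4, 6, 3], /32, five-stage decoder, a stride-2
convolution in place of the stem max-pool) is available for full-scale use
but is not exercised beyond construction in the test suite. The decoder
upsamples nearest-neighbour ×2 per stage with encoder skip connections and
exposes its last four feature maps for `L_s`.

The optimiser is Adam (default moments), matching the encoder–decoder
baseline this design follows; the published schedule gives batch 8,
50 epochs, initial lr 1e−4 "varied based on training steps", realised here
as epoch-indexed factors (×0.5 at 30, ×0.25 at 40) in the defaults.
Divergence to NaN aborts with a diagnostic; per-step histories log every
term and a checkpoint is written per epoch when a directory is configured.
At test time `d_r` (finest scale) is warped into the left view along
`d_l` and the fusion is the mean of the two where the principled mask is
valid, `d_l` elsewhere — the fusion operator is unspecified in the source
design, mean-after-warp is this package's documented choice.

## Synthetic scenes

The generator renders what the method needs and nothing more: a smooth
non-negative disparity surface (Gaussian-filtered noise, correlation length
= `smoothness` × short side, clipped to [d_min, d_max]; the smoothing → ∞
limit is the constant mid-range field), a multi-octave noise texture with
enough 7×7 contrast for census matching to be well-posed, and a right view
rendered by inverting the forward map `x ↦ x − d(x)` per row with bilinear
sampling. A left pixel is occluded iff a larger-disparity pixel lands on
the same rounded right column; occluded and out-of-view pixels are zeroed
in the validity mask. Additive Gaussian noise is optional and seeded. The
default study conditions are noiseless 128×128 scenes with d ∈ [2, 12] px
(64×64 for network training runs) and a camera (f = 150 px, B = 4 mm)
giving 50–300 mm working depth, typical of a laparoscope.

What the generator deliberately lacks: specular highlights, smoke, blood,
non-Lambertian tissue — and any statistical coupling between texture and
depth. That last omission matters for interpreting results: texture and
disparity are independent random fields, so the images carry no monocular
depth cue, and the network can reduce error below the proxy-label level
only by memorising scenes. Passing tests therefore demonstrate that the
distillation pipeline, the losses and their gradients, and the
optimisation dynamics are correct — not that the network would learn
transferable monocular cues on real tissue.

## Scaled-down study conditions

Desk-scale runs use the tiny backbone on 8 synthetic 64×64 pairs for 300
Adam steps at lr 1e−3 (full batch). The lr is higher than the full-scale
default because 300 steps from a fresh initialisation at 1e−4 barely move
the network; 1e−3 makes the short run a meaningful overfit check. Under
these conditions the total loss falls by more than half and the fused
prediction lands within 2 px (median) of ground truth. Longer runs (1500
steps) plateau at the same point: with no appearance–depth coupling in the
data (above) the smooth-field optimum is the attainable target, and the
residual error reflects the disparity field's spatial variance, not an
optimisation failure.

## Evaluation protocol

Predictions triangulate to depth (`D = f·B/d`, invalid where `d ≤ 0`) and
to point clouds `X = (u − c_x) D / f_x`, `Y = (v − c_y) D / f_y`, `Z = D`
(ASCII PLY output). MAE and RMSE are computed per frame over the non-zero
ground-truth pixels; frames with fewer than 10,000 valid points are
excluded (strictly-less rule: a frame at exactly 10,000 is kept), and a
disparity threshold `τ_bg` removes far background before scoring.
Aggregates are mean ± population standard deviation (a sample-std switch
exists). Where no true ground truth exists, the `rigid` distillation
profile builds proxy ground truth and the same machinery applies —
a wiring of existing operations, no new math.

## Numerical choices and degenerate inputs

Cost sentinels are `inf`, excluded from every mean and argmin; box-filter
round-off is clamped at zero. WTA sub-pixel refinement is skipped at range
ends, next to sentinels, and on flat curves (denominator ≤ 1e−12). The
warp clamps sampling coordinates and zeroes the disparity gradient outside
(0, W−1). Empty masks and empty proxy supports define their losses as 0
with warnings rather than NaNs. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; equal seeds give byte-identical
scenes, initialisations and training histories.

## Known limitations

* Box aggregation and the absence of scanline optimisation make the
  classical matcher weaker than full AD-CENSUS on real low-texture tissue;
  on the smooth, well-textured synthetic scenes it is sub-pixel accurate.
* The numpy autodiff engine is single-threaded; full-scale ResNet-50
  training is out of its intended range (construction and inference work).
* The synthetic benchmark cannot measure monocular generalisation (see
  above); clinical validation requires real rectified laparoscopic data.
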