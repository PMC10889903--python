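# Methods

`illusionprobe` asks a narrow, answerable question about a convolutional
network: after learning to discriminate genuinely tilted bar gratings from
near-horizontal ones, does the network treat a tilt *illusion* — an image
whose bars are physically horizontal but appear tilted to human observers —
like a real tilt?  This note records the models, parameters and numerical
choices behind each stage, and what the synthetic components do and do not
emulate.

## Stimuli

Each stimulus is a 560 × 160 px RGB raster: four horizontal coloured bars
(14 px thick, evenly spaced) over a background of 10 px vertical stripes
alternating black and dark blue `(0, 0, 96)`.  Along each bar, diamonds
(squares rotated 45°, side 5–10 px) straddle the bar's long edges at a 20 px
pitch, alternating black and white; the alternation phase flips between the
top and bottom edge.  This is the Café-Wall family of figures: the offset
light/dark elements induce an apparent slope in a physically straight
contour.  Two *positional settings* are rendered — setting II swaps the
black/white alternation phase of setting I — which reverses the direction of
the apparent tilt.

The default grid crosses 12 fully saturated hues (the RGB colour ring at 30°
steps) with 6 diamond widths and both settings: 144 stimuli.

Rendering is done with PIL polygon fills at 4× supersampling followed by a
box-filter downsample, which anti-aliases sub-pixel geometry; everything is
deterministic, so renders are bit-reproducible and a zero-angle "tilted"
render is bit-identical to the illusion render.  Tilts rotate each bar (and
its diamonds) about the bar's own centre, clockwise-positive in raster
coordinates.  A test validates geometric accuracy against an image-moment
principal-axis oracle to within 0.2°, well below the 0.1° level width at
which angles are later binned (the moment estimator itself carries a few
hundredths of a degree of discretisation error; the renderer's requested
angles are exact in the polygon coordinates).

Degenerate geometry is rejected rather than clipped: a diamond whose
half-diagonal exceeds the bar thickness raises an error.

## Perceived tilt, strength levels and classes

In the adjustment task being modelled, an observer rotates four comparison
bars until they match the perceived tilt of the four stimulus bars.
*Illusion strength* is the mean of the absolute values of those four signed
angles, in degrees.  Strengths are binned into eight 0.1° levels covering
(0, 0.8]; level k is the half-open bin ((k−1)·0.1, k·0.1].  Levels 1–4
(strength ≤ 0.4°) form the **No-illusion class C1**, levels 5–8 the
**With-illusion class C2**.  Exactly 0.4° is C1.  Binning uses a 10⁻⁹ °
edge tolerance so that a float that prints as a bin edge lands in the lower
bin; strengths above 0.8° clamp to level 8.

### The synthetic response model

No per-observer angle data are bundled; a generative stand-in produces them
with the structure such experiments report:

- a base strength per (hue, diamond width), in degrees.  Five "quiet" hues
  (green, spring green, cyan, yellow-green, yellow) stay below the 0.4°
  class threshold at every width; the other seven exceed it at widths
  5–8 px — strongest for the smallest diamonds — and drop below it at
  9–10 px.  Magnitudes are graded across hues so the grid populates all
  eight levels; all bases lie in [0, 0.8]°.
- sign: positive (clockwise) for setting I, negative for setting II.
- observer noise: independent Gaussian noise, sd 0.1° per bar, per
  participant; 23 participants by default.

Aggregation averages strength across participants per stimulus, then bins.
Real angle tables can be substituted through the same CSV interface
(`stimulus_id, participant_id, angle1..angle4`), and every scoring function
is agnostic to the data's origin.

What the generator does *not* emulate: inter-observer strength correlations,
response drift or learning across trials, anchoring in the adjustment
procedure, and any dependence of noise on strength.  Tests that pass on this
model certify the scoring/classing machinery and the pipeline around it, not
human psychophysics.

A statistical subtlety the tests respect: the strength estimator is a mean
of |angle|, so under noise its expectation is the folded-normal mean
E|b + N(0, σ²)|, which exceeds the base b when b is small.  Noiseless
recovery is exact; noisy recovery is checked for convergence to the
folded-normal expectation, not to b.

## Datasets

All datasets are *manifests* — CSV tables carrying the full generating
parameters of every image — so pixels are re-rendered on demand and any
split can be reproduced from (config, seed) alone.

- **Training pool**: per strength level k, `per_level` images whose four
  bars are genuinely co-tilted by a magnitude drawn uniformly from level k's
  half-open bin, signed by the stimulus's positional setting.  Hue, width
  and setting are drawn independently of the level so tilt is the only
  label-correlated signal.  The production size is `per_level = 3000`
  (24,000 images, 12,000 per class); desk runs use 300 and tests smaller
  sizes still, with the stratification invariants checked at several scales.
- **Train/validation split**: stratified by level at 3:1.
- **Independent tilted test set**: same construction from a disjoint named
  seed stream; 1,200 images by default, level-balanced by round-robin.
- **Illusion test set**: the 144 grid stimuli rendered with horizontal bars,
  labelled by perceived strength class.

Seed fan-out uses `numpy.random.SeedSequence` keyed by (seed, stream-name
CRC), so streams are independent, reproducible, and all derived seeds stay
below 2³¹.

## Classifier and training

The built-in architecture (`desknet`) is sized for single-CPU training on
2×-downscaled renders (80 × 280):

    conv 5×5/2 (3→16) · ReLU · maxpool 2
    conv 3×3 (16→24) · ReLU · maxpool 2
    conv 3×3 (24→32) · ReLU · maxpool 2
    conv 3×3 (32→32) · ReLU
    flatten · dropout 0.2 · fc 64 · ReLU · fc 2

The four post-ReLU block outputs are registered tap points for feature
extraction and class-activation maps.

A deliberate design choice: the head **flattens** the coarse final feature
map rather than global-average-pooling it.  A sub-degree bar tilt manifests
as a small vertical drift of the bar from the left edge of the image to the
right; global average pooling is translation-invariant within the map and
destroys exactly that cue (pilot models with a pooled head did not learn the
task).  The flattened head keeps the horizontal layout at 5 × 17 resolution,
which is coarse enough to stay small (≈180 k weights into the dense layer)
but positional enough to carry the drift.

Training: Adam (β₁ = 0.9, β₂ = 0.999) with decoupled weight decay 10⁻⁴
applied to matrices only; softmax cross-entropy computed in float64;
initial learning rate 10⁻³ multiplied by 0.9 every 5 epochs; batch size 32;
inputs normalised to x/255 − 0.5; 10 epochs by default.  All parameters sit
on one `HyperParams` object and are CLI-exposed.

The numerical core is a small NumPy implementation (convolution as one
channel-mixing GEMM per kernel tap over strided views, channels-last
layout); its forward passes are verified against `scipy.signal.correlate`
and all gradients against central finite differences.

## Significance: permutation test

The competence claim ("the network classifies real tilts above chance") is
tested by retraining: permutation i shuffles the training and validation
labels (seed `base + i + 1`), retrains a freshly initialised model under the
identical policy, and records its accuracy on the *true-label* test set.
The observed accuracy is significant when it exceeds the nearest-rank 95th
percentile of the null accuracies (rank ⌈0.95 n⌉ of the ascending sort).
Because each permutation is a full retraining, the default budget guards
against accidentally requesting thousands; full-scale runs pass an explicit
override.

## Grad-CAM

For class score y^c (the pre-softmax logit) and tapped activations A^k, the
weight of feature map k is the spatial mean of ∂y^c/∂A^k, and the
localisation map is ReLU(Σ_k α_k A^k) at the tap's resolution.  The
implementation is checked against naive definitional loops to 10⁻⁹.
For display the map is min–max normalised, bilinearly upsampled and
alpha-blended (α = 0.45, jet colormap) over the stimulus; a zero-range map
(common when ReLU rectifies everything away) is flagged `degenerate` and
rendered as a uniform wash rather than dividing by zero.

## Cross-set RDMs and the depth profile

For each strength level, the grid stimulus whose perceived strength lies
nearest the bin centre ((k−½)·0.1°) is the level's exemplar.  Each exemplar
is rendered twice: physically tilted at its signed perceived strength on all
four bars ("perceived-tilt render") and as the horizontal illusion image.
At a given tap, r[i, j] is the distance between the features of
perceived-tilt level i and illusion level j; the normalised matrix
R = r / mean(r) has unit mean by construction, making depths comparable.
An all-zero r (identical feature sets) normalises to all ones.  Two distance
modes are provided — summed squared difference (`sq_sum`) and its square
root (`euclidean`, the default) — and since the unit-mean normalisation is
not invariant to that choice, the mode is recorded in every output.

The depth profile renders *every* grid stimulus both ways, classifies the
illusion render, and averages pair distances per layer within strata crossing
classifier correctness with the true class; empty strata are simply absent.

`diagonal_contrast` (mean off-diagonal − mean diagonal of R) summarises a
matrix: positive values mean matched levels are more similar than mismatched
ones.

## Framework score

The scalar synthesis `S_DNN` combines one Grad-CAM summary — the mean
absolute difference of the min–max-normalised C1 and C2 maps, a measure of
class-discriminative spatial evidence — with one RDM summary — the diagonal
contrast of the earliest-depth matrix, where tilt-like coding of the
illusion is most plausible — as a weighted sum, default weights (0.5, 0.5).
The components are always reported alongside the scalar so the synthesis is
auditable.

## Problem sizes

Chosen as the package's own desk configuration: training at
`per_level = 300` (2,400 pool images) for 10 epochs at 2× downscale with a
1,200-image independent test set; the permutation null at reduced size
(the test suite uses 20 single-epoch permutations on a small pool); RDMs and
Grad-CAM on the fixed 144-stimulus grid.  The full-scale invariants
(24,000-image pool arithmetic) are verified at the manifest level without
rendering.

## Known limitations

- The response model is a stand-in; conclusions about *human* perception
  require substituting real angle tables via the CSV interface.
- Only one architecture ships.  The registry accepts additional builders,
  but no pretrained backbones are bundled, and `pretrained=True` is
  rejected rather than silently ignored.
- The illusion test set labels derive from perceived (synthetic) strength;
  a network that classifies every illusion image as "not tilted" is being
  scored against those labels, which is the point of the probe, but means
  illusion-set accuracy is not a competence measure.
- Grad-CAM at the deepest tap has 5 × 17 resolution; fine spatial claims
  should use the shallower taps.
- The strength estimator's folded-normal bias (above) means noisy synthetic
  panels systematically over-estimate small base strengths; this is a
  property of mean-|angle| scoring itself, not of the implementation.
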