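# Methods

`emgknee` estimates the continuous knee-joint angle from four channels of
surface EMG (sEMG) recorded over two knee extensors (rectus femoris RF,
vastus medialis VM) and two flexors (biceps femoris BF, semitendinosus SE).
The pipeline is: windowed RMS feature extraction, unsupervised feature
reconstruction by a deep belief network (DBN) whose four hidden-layer
widths are chosen per subject by particle swarm optimization (PSO), and a
small backpropagation network (BPNN) regression head. This note records
the model, the numerical choices, and what the bundled synthetic-data
generator does and does not emulate.

## Signal model and preprocessing

Raw sEMG is sampled at 1928 Hz, the knee angle (from motion-capture
markers) at 100 Hz. The useful sEMG band is 10–400 Hz; mains interference
sits at 50 Hz. Preprocessing applies a 4th-order Butterworth bandpass
(10–400 Hz) and a 2nd-order IIR notch (50 Hz, 2 Hz bandwidth), both
forward–backward so filtering is zero-phase, then full-wave rectifies and
segments the signal into 180 ms windows sharing 80 ms with their
neighbours (stride 100 ms). Window and stride lengths in samples are
`round(seconds × fs)` — 347 and 193 at 1928 Hz — because 192.8 samples is
not an integer and some rounding convention must be fixed.

Each window yields one RMS value per channel. Features are min–max
normalized per channel, with the bounds fitted on the training split only;
test features can exceed [0, 1] and are clipped before entering the
(sigmoid-visible) DBN. Each window's label is the mean of the 10 angle
samples (100 ms) centred on the window centre: the 100 ms label window and
the 180 ms analysis window live on different time bases, and centring is
the alignment that biases the label least.

The knee angle itself is defined from three sagittal markers — A on the
thigh, B at the knee rotation centre, C on the shank — as
`180° − arccos(l1·l2 / |l1||l2|)` with `l1 = A−B`, `l2 = C−B`, i.e. the
angle between the extended thigh line and the shank; the cosine is clamped
to [−1, 1] before `arccos` and the output confined to [0°, 180°].

## Restricted Boltzmann machines and the DBN

An RBM with visible vector `v` (length m), hidden vector `h` (length n),
weights `W`, visible bias `b` and hidden bias `c` has energy
`E(v,h) = −vᵀWh − bᵀv − cᵀh` and `P(v,h) ∝ exp(−E)`. The bipartite
structure factorizes the conditionals into `σ(Wᵀv + c)` and `σ(Wh + b)`.
Training approximates the likelihood gradient by contrastive divergence
(CD-1): positive statistics from the data, negative statistics after one
Gibbs step. Normalized real-valued features in [0, 1] are fed to the
Bernoulli units as probabilities; hidden states are sampled binary during
CD while visible reconstructions stay probability-valued — the standard
treatment for normalized continuous inputs. Learning rate 0.01, 200
epochs, minibatches of 32; CD-k with k = 1.

The DBN stacks four RBMs trained greedily, each on the hidden
probabilities of the frozen layer below, then unrolls encoder plus
transposed decoder into a deep autoencoder fine-tuned on the mean squared
reconstruction error. The top layer's activations are the reconstructed
feature vector passed to the regression head; its width (the last
architecture entry) sets the head's input size.

Two numerical choices here departed from the obvious defaults after the
obvious defaults failed:

* **Weight initialization.** Near-zero Gaussian init (std 0.01) collapses
  the stack: with only 4 visible units, every deeper layer's output is
  essentially `σ(c)` — constant across samples (per-layer output spread
  shrinks below 1e-5 by layer 3) — so the code carries no information and
  no head can regress on it. RBMs are therefore initialized with
  fan-scaled uniform weights, `U(±4√(6/(m+n)))` (the sigmoid variant of
  Glorot scaling), which keeps sample-to-sample spread through the stack.
* **Fine-tuning optimizer.** Fixed-rate gradient descent either crawls or
  diverges depending on architecture. Fine-tuning runs full-batch descent
  with multiplicative learning-rate adaptation: a step that reduces the
  loss is accepted and the rate grows 5%; a worsening step is rejected and
  the rate shrinks 30%. This is deterministic, needs no tuning per
  architecture, and handles the vanishing-gradient plateaus that long CD
  training creates by saturating hidden units. Default 500 iterations from
  an initial rate of 0.1.

## PSO architecture search

The four hidden-layer widths are searched over the integer box [1, 50]⁴
with 20 particles and 10 iterations; learning factors c1 = 0.9, c2 = 0.5;
inertia decreasing linearly from 0.9 to 0.5; per-term, per-component
uniform random factors. Positions stay integral by round-then-clamp after
each continuous update; velocities are clamped to half the box width.

Fitness of a candidate architecture is the validation RMSE (degrees) of a
reduced-budget pipeline — 50 CD epochs with minibatch 64, 40 fine-tune
iterations, 200 head iterations — trained on an internal chronological
80/20 split of the training windows. Fitness is deterministic per
position, so revisited positions are served from a cache, and the search
can write a per-iteration log (iteration, best position, best fitness) as
delimited text.

A reduced-budget fitness ranks architectures with noise, and the best
ranked candidate occasionally retrains poorly at full budget (winner's
curse). The final stage therefore retrains the swarm's top two candidate
architectures at full budget (two independently seeded restarts each) and
deploys the run with the lowest internal-validation RMSE. Only
training-split data is ever used for these choices.

## Regression head and the three variants

The head is `θ̂ = W_out · tansig(W_in y + b_in) + b_out` with 12 hidden
units, `tansig(x) = 2/(1+e^(−2x)) − 1` (= tanh), and a linear output.
Training is full-batch gradient descent on the MSE with the same
multiplicative rate adaptation as the fine-tuner (initial rate 0.01, at
most 1000 iterations). Both inputs and labels are standardized internally
— DBN codes can occupy narrow, saturated subintervals of (0, 1) that
would starve a fixed-scale weight initialization — and both affine maps
are folded back into the stored weights, so the trained parameters map
raw features directly to degrees.

Three variants implement the comparison protocol:

* `pso_dbn_bp` — searched architecture, full DBN, BPNN head;
* `dbn_bp_fixed` — fixed 18-12-6-3 architecture (3-input head), no search;
* `bpnn_plain` — the head alone on the 4 normalized RMS features.

Each subject's recording is split 70/30 chronologically (shuffling would
leak overlapping windows across the split). `calibrate` is the per-subject
self-updating mechanism: it re-runs the architecture search and retrains
every stage on a new subject's training windows from scratch, returning a
new model and leaving the original untouched.

## Metrics

RMSE in degrees, Pearson correlation (CC), and `R² = 1 − SS_res/SS_tot`
with the total sum of squares around the mean of the *actual* series.
CC and R² raise on constant inputs rather than returning a filler value.
Comparisons train each variant repeatedly with distinct seeds (15 by
default; experiments in the test suite use 5) and report mean ± standard
deviation on the held-out split.

## Synthetic subjects

No public recordings accompany the protocol this package targets, so the
generator produces subjects with the statistical structure the pipeline
assumes:

* **Motion**: raised-cosine cycles spanning [0°, 90°] by default, 20
  cycles of 4 s (an 80 s trial); the squat mode adds a brief hold at the
  deepest position. The sampled series is rescaled so the configured
  bounds are attained exactly.
* **Activation**: an extension-demand signal, 0.9 × normalized angle +
  0.1 × normalized angular velocity, rescaled to [0, 1]. Extensor
  envelopes follow it, flexor envelopes its complement, each scaled by a
  per-muscle gain; all four are advanced by the electromechanical lead
  (default 50 ms — muscle activity precedes motion by ~30–150 ms). The
  velocity share is deliberately small: a large share folds the rising and
  falling phases of the cycle onto one demand value and makes the angle
  unidentifiable from a memoryless feature window (the conditional floor
  rises from ~6.5° to ~18° at a 35% share), which would contradict the
  accuracy this class of pipeline is known to reach.
* **EMG**: per channel, the envelope (linearly interpolated to 1928 Hz)
  multiplies a unit-RMS Gaussian carrier band-limited to 10–400 Hz; a
  50 Hz sinusoid at 0.2 × signal RMS and white noise at 10 dB SNR are
  added. Everything is reproducible from the config seed.
* **Markers**: B at the origin, A fixed along the thigh axis, C rotated
  about B in the sagittal plane so the marker-derived angle reproduces the
  generated trajectory to < 1e-6 degrees.

What the generator does **not** emulate: motor-unit action potentials and
their recruitment statistics, muscle fatigue (median-frequency drift),
electrode shift or detachment, co-contraction beyond the strict
antagonist complement, and day-to-day nonstationarity. Passing tests on
synthetic subjects therefore demonstrate that the implementation is
faithful and the pipeline recovers the angle under the assumed signal
model — not that it reaches any particular accuracy on real recordings.
One structural consequence: the four synthetic channels are redundant
transforms of one demand signal, so the plain BPNN baseline is nearly
optimal here and the searched pipeline's margin over it is small, whereas
published comparisons on real subjects show a larger gap.

## Degenerate inputs and edge rules

Zero-amplitude motion (angle_min = angle_max) produces constant envelopes
at demand 0.5. A zero-variance feature channel normalizes to 0 (the
min–max span is replaced by 1). RMS of an empty window, correlation of a
constant series, and R² of a constant actual series raise `ValueError`.
Marker frames with a zero-length limb vector are rejected with the frame
index. The exhaustive RBM oracle refuses models with more than 16 total
units.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` train on one 80 s synthetic
subject per condition (798 feature windows; 558 train / 240 test), with 5
repeat seeds in the suite and 3 in the acceptance script. These sizes
match the protocol's single-subject trial length; the repeat counts are
the package's choice for stable medians and means.
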