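# Methods

## The model

The network is a deep belief network: a stack of three Restricted
Boltzmann Machines (RBMs) over a 1925-unit visible layer, with hidden
layers of 300, 200 and 100 units (defaults). Each RBM couples its visible
layer `v` and hidden layer `h` through a single symmetric weight matrix
`W` and bias vectors `c` (visible) and `b` (hidden); there are no
within-layer connections. Unit activations are logistic probabilities:

    h_j = sigma(sum_i w_ij v_i + b_j),   v_i = sigma(sum_j w_ij h_j + c_i)

with `sigma(x) = 1/(1+exp(-x))`.

Weights are initialised from Normal(0, 0.1) and biases at 0.

### Learning

Each RBM is trained by one-step contrastive divergence (CD-1) with
per-pattern online updates:

    dw_ij = eps * (v+_i h+_j  -  v-_i h-_j)

where `(v+, h+)` are the data-driven activities and `(v-, h-)` the
one-step reconstruction-driven activities. Biases are trained with the
same rate. The positive-phase hidden probabilities drive the negative
phase as Bernoulli samples; all statistics entering the update use
probabilities (the standard CD-1 recipe; a fully deterministic
`all_probabilities` mode exists for exact small-scale oracles). The stack
is trained greedily: layer 1 on the data, layer 2 on layer 1's
deterministic hidden probabilities (no dropout, no sampling), and so on,
each layer receiving the full epoch budget.

Dropout is per-epoch: each hidden unit is excluded from computation and
learning for an entire epoch with probability p = 0.5. A fresh mask is
drawn per epoch; pattern order is shuffled per epoch.

Defaults (the baseline study condition): 500 epochs per layer, 5000
training patterns per epoch, learning rate eps = 0.002 per pattern,
dropout p = 0.5. Without dropout the learning rate drops to 0.0002.

### Test-time computation

Reconstruction is a deterministic mean-field pass: probabilities up
through layers 1..k, then down through k..1, no sampling, no dropout.
Two dropout-compensation modes exist: `none` (activations used as
computed) and `retention` (every hidden activation scaled by the
retention probability 0.5). The default is `none`: in scaled-down
calibration the unscaled pass reproduced the qualitative region-mean
pattern markedly better at every depth (retention scaling starves the up
pass, whose inter-layer inputs were never dropout-scaled during greedy
training), and the saturation the down pass might suffer from the doubled
active population did not materialise at the scales measured.

Class-restricted reconstruction (the population-ablation analyses) zeroes
the activations of excluded hidden neurons in every layer on both the up
and down passes; ablation acts on activations, not weights.

## The task

The visible layer concatenates five channels: a 25x25 red map, a 25x25
green map, two 25-unit context blocks (mutually exclusive, all-ones /
all-zeros), and a 25x25 action map. Stimuli are 5x5 blocks of ones at one
of 441 positions; the action is a 5x5 block at the location of the
stimulus whose colour matches the context (red in context A, green in
B). "Non-overlap" of the two stimuli is spatial: the two 5x5 footprints
share no grid cell, enforced by rejection sampling, uniform over
admissible pairs. Channel order (red, green, context A, context B,
action) is a fixed convention.

The training set holds 5000 patterns: half single-stimulus (the stimulus
colour always paired with its matching context), half double-stimulus,
contexts balanced within each half. Test sets hold 1000 double-stimulus
patterns, 500 per context, either with the action channel provided
("complete") or externally zeroed ("no_action"). Test draws are fresh and
independent of the training positions.

## Analyses

* **Region means** — per double-stimulus pattern the 1925 units are
  partitioned into seven regions (relevant / irrelevant stimulus square,
  correct / incorrect action square, correct / incorrect context block,
  remainder); the reported statistic is the mean reconstruction over each
  region, averaged over the test set and replications. "Remaining" is
  defined as the complement of the six named regions.
* **Replication statistics** — each condition trains 10 networks (2 at
  the reduced desk scale) differing only in seed; comparisons between
  regions or conditions use two-tailed t-tests over replications, paired
  whenever the same trained networks underlie both samples. No
  multiple-testing correction is applied, matching the reporting style
  this package mirrors.
* **Layer ablation** — reconstruction with only the first k layers
  operating, k = 1..3.
* **Iterative generation** — the network runs on its own reconstruction
  for up to five steps.
* **Instructed delay** — eight processing steps; one item (both stimuli,
  or the context cue) is presented for steps 1-2, blank 3-4, the other
  item 5-6, blank 7-8; the action channel is never provided. From step 2
  on the input is 0.9*external + 0.1*previous-reconstruction, applied
  uniformly to all 1925 channels, so self-generated traces persist
  through blanks with weight 0.1. Unpresented channels are externally 0
  (the context blocks carry no 1/0 code during stimulus-only steps).
* **Receptive fields** — layer-1 RFs are raw weight columns; deeper
  effective RFs threshold each lower weight matrix at |w| >= 0.5 and
  multiply the thresholded matrices (threshold-then-combine; the
  alternative order is available behind a flag). Raw weights are used
  (no dropout scaling), consistent with the `none` test-scale default.
  A neuron is context-dependent when |mean(ctxA weights) -
  mean(ctxB weights)| >= 0.3, the sign giving the preferred context;
  action-stimulus RF similarity uses Pearson correlation (zero-variance
  maps report r = 0 with a degenerate flag).

## Control conditions

Eight controls vary one factor each: double-stimulus-only training; 250
or 1000 epochs; no dropout (eps = 0.0002); stimuli restricted to the
top-left/bottom-right corners (training and testing); a modular
architecture whose layer-1/2 connectivity is block-diagonal over the
stimulus/context/action channels (blocks 150/50/100 then 100/25/75,
layer 3 fully connected); and half (150,100,50) or double (600,400,200)
hidden-layer sizes.

## Problem sizes used by the default test battery

Full-scale training (500 epochs x 5000 patterns x 3 layers x 10
replications) is a multi-hour CPU job. The package's default tests and
the acceptance script therefore run a reduced desk-scale study — 100
epochs per layer, 1000 training patterns, hidden sizes (150, 100, 50),
2 replications — which preserves every pipeline stage while training in
about a minute per replication. `StudyConfig.scaled` and the CLI
`--scale` flag expose the same uniform shrinking for arbitrary factors.

What the desk scale does and does not show: the direction of the
selective-attention effect (relevant > irrelevant) and the two-locations
null replicate robustly at this scale, but the *magnitudes* do not. With
100k pattern presentations per layer (versus 2.5M at full scale) each
RBM's autoencoding fidelity is limited (per-epoch dropout caps it
further), and reconstruction error compounds across the three-layer
down pass, so absolute region means at depth 3 are far below the
full-scale values and deep-stack effects (the growth of the attention
gap with depth, the instructed-delay divergence after the cue) are
attenuated below their full-scale signatures. Full-scale runs are a
CLI command away (`selattn run-study --config studies/baseline.yaml`);
magnitudes grow steadily with the training budget and can be tracked
with intermediate `--scale` factors.

## Numerical choices

* Activations are never clipped in the forward pass; clipping to
  [1e-7, 1-1e-7] is applied only inside log-based diagnostics.
* Online rank-1 weight updates use BLAS `dger` on a Fortran-ordered
  matrix; with a connectivity mask the masked-delta path keeps excluded
  entries exactly 0 through training.
* Minibatched CD (summed statistics per batch) exists as an optimisation
  knob; every study configuration uses online updates (minibatch 1).
* Degenerate inputs: an untrained network reconstructs ~0.5 everywhere
  (logistic of near-zero input) and is handled by all analyses; region
  metrics reject single-stimulus specs, whose "irrelevant" region is
  undefined.

## Known limitations

* Mean-field reconstruction is a deterministic stand-in for averaging
  stochastic passes; with heavily saturated units the two can differ.
* Whether the original procedure applied its 500-epoch budget per layer
  or across the stack is not derivable from the text; this package trains
  each layer for the full budget (configurable).
* The synthetic task is binary and noiseless; conclusions about graded or
  noisy stimuli are out of scope.
* The instructed-delay mixing rule is applied uniformly to all channels;
  if the original work mixed only stimulus channels the blank-period
  dynamics could differ in detail.
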