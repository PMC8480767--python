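# Methods

## Task model

A session is a continuous stream of presentation cycles on a 250 ms grid:
one image frame followed by two gray frames (an omission replaces the image
frame with gray, extending the effective inter-stimulus interval to 2.0 s).
The number of consecutive presentations of the current image before a
change or sham change is truncated-geometric: after the 4th repeat each
further presentation ends the run with per-presentation hazard 0.3, forced
at 11. Only the bounds (4 and 11) of this distribution are fixed by the
task description; the hazard is a package default chosen to give the
characteristic right-skewed repeat distribution on [4, 11]. The terminating
presentation is a change to one of the other 7 images (uniformly) with
probability `p_go` (default 0.5, so all 64 transition cells, including the
diagonal, accumulate trials) or a sham change. Omissions (default 5 % where
enabled) are drawn among presentations that are not themselves a
change/sham and are not immediately followed by one; consecutive double
omissions can occur and are excluded from the omission analyses. The
`repeat_index` carried on each frame counts consecutive scheduled
presentations of the current image (1 on a change presentation, continuing
through sham changes and omissions).

Gray and omitted frames deliver exactly zero input to the models — the
encoder response to the mean-luminance screen is defined as 0. The
`encoder.gray_response` helper exists to check this convention against an
image-computable encoder.

## Synthetic embeddings

The default input stand-in for a pretrained convolutional encoder is an
8 × 64 non-negative matrix: each input unit responds to k ∈ {1..4} images
(mixture weights 0.4/0.3/0.2/0.1, so E[k] = 2 and ~75 % of entries are
zero) with graded amplitudes uniform in [1, 5]. Rows are rescaled so each
image's total drive equals the across-image mean times a lognormal saliency
factor exp(N(0, 0.25²)) — the saliency heterogeneity that seeds the
behavioral asymmetry. The amplitude scale was chosen so that repeated
stimulation depresses the presentation-time synaptic efficacy to ≈ 0.5
(mean driven rate ≈ 3 with U = 0.5, τₓ = 1.5 s, Δt = 0.25 s), the regime in
which depression dominates and carries a usable memory trace; with much
weaker drive the depression contrast disappears into the response noise and
the feedforward model cannot learn the task at all.

## Depression dynamics

The resource equation is linear in x, so the backward-Euler step has the
closed form x′ = (x + Δt/τₓ)/(1 + Δt/τₓ + U·Δt·r). It is unconditionally
stable, keeps x in (0, 1] for any non-negative rate, and its fixed point
coincides with the continuous steady state x* = (1/τₓ)/(1/τₓ + U·r).
Because the scheme is first order, its transient matches a fine-grained
integration to 2 % only at modest drive (U·Δt·r ≲ 0.1); correctness at
strong drive is asserted through the implicit defining relation, which the
closed form satisfies exactly. Noise is applied to the input *before*
depression gating (the noise models encoder variability, which drives
release), and the updated resources gate the same frame's drive. All
synapses from one presynaptic unit share one resource variable.

## Models and noise

All three models are 64–16–1 rectified networks with one hidden bias and an
output bias (matching the reference parameter counts); STPRNN adds a second,
non-adapting input block and recurrence. Multiplicative Gaussian noise
(sd 0.5) perturbs input features and hidden activities as
max(0, a·(1 + ε)) — the zero-mean Gaussian is read as a perturbation of the
gain, which preserves zeros and non-negativity. The same sd is used for
both layers (no separate hidden-noise parameter is given). The noised hidden
activity is what recurrence propagates and the output reads. Hidden and
synaptic state are initialized to zeros / fully recovered at session start
and are not reset between trials (the task is continuous). Weights are
initialized uniform in ±1/√fan_in.

## Training

One epoch = one freshly generated session of 100 trials (the epoch size is
a package convention; nothing downstream depends on it beyond compute). The
loss is binary cross entropy over image frames only (inter-stimulus frames
are masked out), with label-1 (change) terms weighted 5×, averaged over
masked-in frames, plus 0.001 × mean squared hidden activity over all frames.
Gradients flow through the full unrolled session (truncated at session
boundaries) and through the rectifiers and noise gains, but not into the
depression trajectory, which is input-determined and independent of the
trainable weights. Adam uses lr 1e-3, betas (0.9, 0.999). After each epoch,
responses are Bernoulli-sampled from the output sigmoid at change and sham
presentations; hit and false-alarm rates give a d′ (quantile difference
with rates clipped to [1/2n, 1 − 1/2n]), and training stops once d′ ≥ 1.5
for 5 consecutive epochs (cap 5000). Early-stop evaluation is done on the
training epoch's own session; no held-out set is used. Training sessions
never contain omissions; the evaluation driver, not the config, re-enables
them. Everything is deterministic given the seed, which expands via
`SeedSequence` into independent init / session / noise / evaluation streams.

## Evaluation battery

Each trained model is evaluated on fresh sessions: 2 000 trials without
omissions for the response matrix, Q, input-unit CMI, decoding and
geometry; 1 000 trials with 5 % omissions for the omission table. These
session sizes are package choices balancing estimator noise in the 64
matrix cells (≈ 18 go trials per off-diagonal cell) against runtime.
Per-presentation unit responses are the activity at the presentation frame,
noise on; for depressing models the input-layer response is the
post-depression (gated) activity. "Pre-change" means the presentation
immediately before a change; sham-change presentations are not pre-change.
Units with a negative mean response on either class are excluded from CMI
(cannot happen for rectified model units; relevant for external dF/F data).
Decoders are linear SVMs (C = 1) with stratified 3-fold cross-validation;
the change decoder trains on change vs pre-change presentations (balanced
by construction) and is tested on go and catch trials for the Jaccard
comparison with sampled behavior. PCA retains components to 95 % variance;
distances are measured from the mean across all image presentations, pooled
over images at each repeat index, per session (never pooled across runs).

The omission table scores five categories (go, catch, all non-omitted
presentations, omitted, post-omitted); a response during an omission forces
that trial's post-omitted score to zero, mirroring the experimental
trial-abort logic. Hidden-activity probes during omissions are reported as
*evoked* activity — hidden minus the gray-screen baseline relu(b_h) — since
a trained network's constant baseline is not a stimulus response (and is
what a dF/F measurement would subtract). For the feedforward depressing
model the evoked activity during omissions is exactly zero; for the
recurrent model it is positive and stimulus-dependent.

## Synthetic adapting population

For validating the estimators, a population of units with known ground
truth is generated: each neuron has a tuning curve over images (same
breadth mixture as the embeddings) and is driven through its own depressing
synapse; the response on presentation p of image i is
tuning(i)·x(t_p)·(1 + ε), ε ~ N(0, noise_sd). The ground-truth change
modulation is the tuning-weighted resource contrast
(x̄_c − x̄_p)/(x̄_c + x̄_p), where x̄ are tuning-weighted means of the
noise-free resource at change / pre-change presentations — the quantity the
CMI estimator converges to as trials accumulate, and exactly zero when
depression is disabled. Recovery tests (200 neurons, noise sd 0.2, 400
trials) bound the estimator's mean absolute error below 0.05.

What the generator does *not* emulate: calcium-indicator dynamics and
windowed dF/F extraction, correlated trial-to-trial variability, facilitating
or mixed synapses, non-uniform transition statistics, and reward/timeout
trial logic. Passing the recovery suite therefore shows the estimators are
correct on an idealized adapting population, not that real recordings meet
their assumptions.

## Numerical and design notes

- The implicit depression update is solved in closed form, never iterated.
- d′ clipping uses 1/(2n) of the relevant trial count; any monotone clip
  would do, but this one is fixed and documented.
- Response-matrix cells with no trials are reported as missing (NaN), never
  as zero; Q requires all off-diagonal cells populated and raises (or, in
  the pipeline driver, records NaN) otherwise. Q is invariant under image
  relabeling, so the display ordering of the matrix is cosmetic.
- The Jaccard null permutes the decoder predictions 1000 times (200 in the
  bulk pipeline driver for speed) and reports the null mean and 95 % band.
- The CIFAR-10 encoder path is faithful but optional; it trains a 63,658-
  parameter CNN in NumPy (im2col convolutions) and is exercised in tests on
  small synthetic image sets only, since the dataset is external.
- Dimensionality-reduction variants beyond PCA (LDA, isomap) are out of
  scope; `repeat_distance` operates on any `PresentationResponses`, so a
  different reducer can be applied upstream.

## Known limitations

- The omitted-presentation response probability of the trained feedforward
  depressing model is ≈ 0 under the zero-input convention for gray/omitted
  frames: its zero-input logit falls well below the response threshold after
  training. Reported experimental-model values for this quantity are higher,
  consistent with an encoder whose gray-screen response is not exactly zero;
  the package pins the convention to zero input and reports what follows
  from it. The qualitative dissociation (recurrent models respond to the
  omission, depressing models to the post-omission image) is unaffected.
- Backpropagation does not flow through the depression trajectory; for
  input-layer depression the trajectory is weight-independent, so this is
  exact, but it would be an approximation for depressing *recurrent*
  synapses, which are not implemented.
- Only depression is modeled (no facilitation, no spiking, per-unit rather
  than per-synapse resources).
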