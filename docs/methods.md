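# Methods

This note records the modelling choices, their rationale, and the
limits of what the synthetic experiments can show.

## Acoustic front end

Audio is decoded from WAV (integer PCM rescaled to [-1, 1]),
average-downmixed to mono, and polyphase-resampled to 22,050 Hz. MFCCs
use a 2048-sample Hann window, hop 512, centered frames (a clip of n
samples yields 1 + ⌊n/512⌋ frames), a 128-band triangular mel
filterbank on the HTK mel scale up to Nyquist, dB compression, and an
orthonormal DCT-II along the mel axis keeping the first 52
coefficients. These STFT conventions are stated because the frame-count
oracle in the tests depends on them; nothing downstream is sensitive to
the mel variant.

Length normalization pads shorter feature matrices with zero columns on
the right and keeps the first 926 columns of longer ones (the clip
onset is retained; truncation happens after MFCC extraction). The
canonical pipeline applies no per-feature standardization. The trainer
offers an optional z-score whose per-coefficient statistics are fitted
on its training split only; the desk-scale configuration enables it
because raw dB-scale magnitudes (first coefficient in the hundreds)
stall small-budget optimization. Label codec order is the lexicographic
sort of the eight class names, making the index map deterministic.

## Synthetic auscultation fixtures

The generator emulates the two adventitious signatures the
architecture exploits — wheezes (narrowband tones with ~1%
phase-modulated vibrato, gated to a window of the breath cycle) and
crackles (damped-sinusoid transients) — on breath-modulated Gaussian
noise with a 3-s respiratory cycle (20 breaths/min). Per-class recipes
are fixed: distinct wheeze bands for asthma/COPD/URTI/bronchiolitis,
distinct crackle rates and click bands for pneumonia vs LRTI, and one
deliberately order-coded pair: bronchiectasis and bronchiolitis carry
*identical* wheeze and crackle content and differ only in where those
events sit within the breath cycle (early-phase wheeze with late
crackles, or the reverse). Event timing relative to the respiratory
cycle is a genuine auscultatory cue, and it is exactly the kind of
information a time-averaged spectral representation destroys: a
classifier that global-average-pools convolutional features is at
chance on the pair, while a recurrent model is not. Crackle times wrap
modulo the clip length so that edge pile-up cannot leak timing into
amplitude statistics.

Default per-class clip counts reproduce the reference corpus's
imbalance (COPD 793 … asthma 1; 920 clips of 10 s). Clips are assigned
round-robin to a configurable number of virtual patients per class; a
patient never spans two classes. Subjects carry no acoustic signature
of their own, so subject-held-out evaluation here measures
clip-level generalization — one of several reasons fixture results say
nothing about real auscultation performance (no device or site
variability, no airflow physics, no pediatric/adult differences, no
inter-patient variation).

## Augmentation pipeline

Balancing targets are drawn uniformly from [720, 760] per class and
run (classes already above 760 are untouched), reproducing the
"every class ≥ 720" regime without inventing an exact target. Classes
that cannot reach the target in one 25× pass are routed through the
25× up-sampling stage first and the op mix then iterates until the
target is met. Candidates are a 60/40 mix of classical transforms and
the generative surrogate; the surrogate is a seeded convex time-domain
mixture (weight U(0.3, 0.7)) of two same-class clips followed by a
random classical op — a deterministic stand-in occupying the generative
quota, on the view that the operative contract is the fidelity gate,
not the generator.

The gate: r = peak over time lags of the normalized cross-correlation
of mean-centered 64-band log-mel spectrograms, accept iff r > 0.85.
Gain changes pass at r = 1 exactly (a dB offset vanishes under
centering); pitch shifts within ±2 semitones mostly pass; aggressive
time stretches are frequently rejected (observed overall acceptance
≈ 0.5), which is the intended behavior of a fidelity gate rather than a
defect — rejected candidates are regenerated with fresh parameters up
to a retry budget of 25 attempts per needed sample. Pitch shifting is
a phase-vocoder time stretch followed by polyphase resampling; noise
injection hits the requested SNR to within 0.1 dB and offers white and
pink spectra (device-specific noise profiles are config-pluggable
rather than baked in).

Every augmented clip inherits its source clip's subject id. That single
invariant, plus an audit that refuses any training clip carrying a
held-out subject's id, is what makes leakage structurally impossible in
the evaluation protocols; violation raises an error, never a warning.

## Diagnoser

The layer sequence and hyperparameters follow the canonical
configuration (two 1-D convolutions of 64×5 and 128×3 with ReLU, batch
normalization after each convolution, max-pool 2, LSTM(128) returning
sequences, two-stage attention scoring through 64 tanh units to one
score per step, LSTM(64) returning its final state, dropout 0.5,
Dense(128), softmax over 8). Two batch-norm layers are used — one per
convolution — matching the 384 non-trainable parameters that implies.
A second ReLU dense layer can be enabled by flag but is off by
default. The attention layer hands the downstream LSTM the weighted
sequence scaled by the step count, {T·αₜhₜ}: the scale keeps the
sequence's magnitude independent of T (without it the 1/T shrinkage
freezes training), makes uniform attention reproduce the input sequence
exactly, and leaves the context-vector reading intact as the time
average. The mean-pool ablation (`no_attention`) is literally the
uniform-α special case; `cnn_only` removes both LSTMs and
global-average-pools the convolutional features.

The network is pure numpy with hand-written backpropagation (float64
throughout). Correctness rests on two test pillars: forward passes
match independent loop-level transcriptions to 1e-6, and every
backward pass matches central finite differences. LSTM input kernels
use Glorot scaling and recurrent kernels per-gate orthogonal
initialization with forget-gate bias 1; Adam supports global
gradient-norm clipping and an optional cosine learning-rate decay.
Early stopping monitors validation loss with patience 10 and restores
the best epoch's weights (batch-norm running statistics included).

The desk-scale configuration (`DiagnoserConfig.reduced()`) keeps the
topology and halves widths (32/64 conv filters, 64-32-32-64 recurrent
and dense units), with T=128 frames, ≤15 epochs, batch 8, learning rate
7·10⁻³ cosine-decayed to zero, clip norm 2, dropout 0.1 and the
training-split input z-score. These optimization settings were chosen
so that from-scratch backpropagation-through-time converges within the
small epoch budget; the canonical configuration keeps its stated
defaults verbatim. Under the desk protocol (40 clips/class, 5 virtual
patients/class, one patient per class held out, seeds 0–4) the full
model averages ≈0.94 held-out accuracy and the CNN-only ablation is
capped by the order-coded pair near 0.88–0.89, confirming that the
recurrent stack carries the temporal information the pooled variant
cannot represent. The mean-pool ablation performs comparably to full
attention at this scale: the fixture's order cue is recoverable by the
LSTMs with uniform weighting, so the desk experiments separate
recurrent-vs-pooled, not attention-vs-mean-pool. Magnitudes on real
audio are out of reach here by design.

Two documented ablation variants — a joint diagnosis+prescription head
and a transformer encoder — are registered but intentionally
unimplemented: no paired audio–prescription data exists in this
artifact, and the transformer is not part of the canonical model. At
full-model level a constant input yields uniform attention only up to
the recurrent warm-up transient and convolution boundary (the property
is exact at the attention layer, and the steady-state interior is flat
to < 5%).

## Biomarker channel and fusion

The disease→marker map ships as an editable YAML knowledge file: 20
distinct markers, three per non-healthy disease (IL-6 shared by
pneumonia and COPD), healthy mapping to baseline only. Association
weights are uniformly 0.8 with baseline 0.1 — the literature gives
directions, not magnitudes — and are config-overridable. A sample's
vector is baseline + posteriorᵀW + N(0, σ²) clipped to [0, 1], with
σ = 0.05 by default.

At inference the driving posterior is the *audio model's prediction*,
never the true label: label-driven vectors at evaluation time would
leak the answer into the molecular channel. A `from_labels` mode exists
for controlled experiments. The consequence is honest but humbling: a
posterior-driven vector adds no information beyond the audio model, so
on the fixtures fusion can only match audio-only performance (the test
asserts the ≥ direction). Genuine gains require measured molecular
data, or the label-driven mode as an upper-bound simulation. Fusion
itself retrains a multinomial logistic head on [latent ‖ vector]; the
audio-only comparator head is trained identically on the latent alone,
so the comparison isolates the molecular block.

## Prescribing cohort and recommender

Demographics: age uniform on [1, 95]; minors never smoke; weight
age-dependent for children. Diagnoses follow a respiratory-burden-
weighted prevalence (COPD .30, asthma .20, URTI .15, pneumonia .12,
healthy .10, bronchiolitis .06, bronchiectasis .04, LRTI .03), chosen
so every formulary drug has non-zero support at n = 2000 and
config-overridable. The comorbidity share is quota-sampled — exactly
round(0.15·n) records impaired — making the printed 15% an exact
contract rather than a Bernoulli expectation. eGFR is U(15, 59) for
renal-impaired records and N(95, 15) truncated at 60 otherwise, so the
flag and the threshold agree by construction. Eight percent of patients
aged ≥ 40 carry a background anticoagulant, giving the 25-pair
interaction screen (5 anticoagulants × 5 interacting drugs, three of
them in the formulary) real work.

The formulary maps (diagnosis, age band, smoking modifier) to
drug/dosage/frequency with a per-rule alternate used when the primary
is contraindicated or interacts; its codomain is closed over the
10-drug, 14-dosage, 10-frequency vocabularies and every class is
reachable. Renal adjustment applies to renally-cleared antibiotics
with plain-mg doses: dose × min(1, eGFR/60), snapped to the largest
point-valued mg class not exceeding the result (the nearest-lower
rule), which guarantees an impaired patient never receives the
unadjusted class. Range-valued classes ("400-600 mg", weight-based
pediatric doses) are treated as opaque labels and excluded as snap
targets.

Oversampling runs strictly inside the training partition (after the
80/20 split) to avoid leakage: (diagnosis, drug) pairs below 5%
prevalence are synthesized up to the 5% count by interpolating numeric
features between same-pair rows and copying categorical features and
targets from the nearer parent; singleton pairs are duplicated with ±2
years of age jitter; impairment flags are recomputed from the
interpolated eGFR. Because labels are deterministic given features,
held-out accuracy approaches 1 by design — the ≈99% figures certify
that the ensemble recovers the generating rules, nothing more. A
label-noise switch (default 0) exists to emulate disagreement.

## Evaluation protocols and metrics

LOSO retrains from scratch per fold with the held-out subject excluded
from training *and* augmentation; k-fold uses stratified, subject-
grouped folds. Both audit subject-disjointness (including augmented
derivatives) and abort on violation. The SNR sweep corrupts clean test
clips at each grid point (default 5/10/15/20 dB) with fresh seeds,
re-extracts features and re-classifies. Proportion intervals use the
Wilson score (well-behaved near 100%, where these models live); kappa
intervals use the percentile bootstrap; per-class AUC is one-vs-rest
with macro averaging. Degenerate kappa (chance agreement 1) is reported
as NaN rather than a number.

## Attribution

Global attribution for the recommender defaults to permutation
importance — assumption-light and library-independent. Local additive
explanations use exact Shapley values by coalition enumeration, which
is tractable at the cohort's feature count and additivity-exact (the
attributions sum to f(x) − E[f(background)]); the two methods agree on
the dominant driver in the tests. The formulary conditions on
diagnosis, age band, smoking and renal function, so sex and weight act
as built-in null features that must rank near zero.

## Known limitations

* Fixture acoustics are statistical stand-ins, not physiology; all
  fixture-level accuracies certify the pipeline and architecture, not
  clinical performance.
* Posterior-driven biomarker simulation cannot demonstrate a fusion
  gain, only non-degradation; gains require real molecular inputs.
* The prescription experiment's ceiling is built in; clinical validity
  would require EMR-derived data and regulatory-grade validation.
* The numpy network trains desk-scale configurations comfortably but is
  not a platform for full-scale (T=926, 100-epoch) training runs.
* Only WAV input is supported for audio I/O.
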