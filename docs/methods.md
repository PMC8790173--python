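# Methods

This note documents the models, algorithms and design choices behind
`stimdecode`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic studies do and do not establish.

## Study design being emulated

The pipeline targets a within-subject, three-session design: each subject
receives 10-Hz tACS over the left motor cortex (`lMC`, ring electrodes
around FC3 and CP3), over the right cerebellum (`rCB`), and `sham`, in
separate sessions.  EEG (64 channels, extended 10–20, 512 Hz, online
reference CPz) is recorded before (PRE) and after (POST) stimulation during
a visuomotor task (~80 stimulus-locked epochs per phase) and during
eyes-open/eyes-closed rest (200-s runs cut into 4-s epochs; the rest
duration is a free generator parameter because pooling conventions differ —
the default 680 s yields the nominal ~170 epochs per phase).

## Preprocessing

Fixed order: band-pass → mastoid re-reference → (artifact-removal hook) →
epoching → ±70 µV rejection → common average.  All operations return new
containers.

* **Filtering.** Zero-phase windowed-FIR band-pass (1–49 Hz) with 1-Hz
  transition bands (MNE's `filter_data`).  The narrow upper transition is
  required by the filter's contract here — a 1–49 Hz band must attenuate
  50-Hz line noise by ≥ 90% — which no low-order IIR band-pass can satisfy
  with a cutoff that close; stopband attenuation of the FIR design is
  > 50 dB.  Zero phase protects the later phase-locking analysis.
* **Re-referencing.** Mastoid average first ((M1+M2)/2 subtracted, which
  re-instates the online-reference channel CPz as a data channel; mastoids
  are then dropped, leaving 62 scalp features at full montage density);
  common average is applied last, after rejection, over the retained scalp
  channels.
* **Rejection.** An epoch is rejected iff any channel sample exceeds
  (−70, +70) µV on the filtered data.  Eye-blink removal is represented by
  a pluggable hook and is otherwise a logged no-op: the synthetic data
  carry no blinks, and independent component analysis is out of scope.

## Spectral features

Complex Morlet wavelets, 7 cycles, σ_t = n_cycles/(2πf), frequencies 1–49 Hz
at 1-Hz steps, realized as FFT-domain multiplication with the wavelet's
Gaussian frequency response over the full epoch and then cropped to the
analysis window (the epoch's padding absorbs edge effects; a frequency whose
7-cycle support exceeds the epoch raises an error naming it).  The gain
convention is analytic-signal-like (gain 2 at the centre frequency), so a
unit-amplitude sinusoid yields power ≈ 1 regardless of frequency.  Power is
sampled on a 10-ms grid over a 400-ms window — from stimulus onset for task
epochs; for rest epochs, which have no stimulus, the window starts one
wavelet half-support into the epoch — and averaged in groups of five bins
into 8 time-segments, the classifier's feature vector.  No baseline
normalization is applied anywhere: the POST−PRE difference is the
normalization.  Band averages (θ 4–8, α 9–13, β 14–30, γ 31–49 Hz) are
unweighted means over integer frequencies; an 8–13 Hz alpha variant exists
as `ALPHA_WIDE` since both conventions circulate.

## Difference samples and the classifier

Epoch order is permuted independently within PRE and within POST ("shuffled
along the time axis"; no other dimension is shuffled), pairs are formed
positionally, and the first min(n_PRE, n_POST) pairs are kept — the pairing
rule for unequal counts is a package choice, and it makes the used surplus
epochs a random subset.  Each subject's three sessions pool into one
three-class problem; the fold assignment (stratified 10-fold, seeded) is
fixed per subject across channels and frequencies so scores are comparable.

The classifier is a shrinkage-regularized multiclass LDA.  Within-class
scatter is shrunk towards the scaled identity, (1−λ)S_W + λ(tr S_W/d)I,
with λ estimated analytically (Ledoit–Wolf) from the within-class-centred
training residuals of each fold only — no leakage across folds.  The data
are projected onto the top two generalized eigenvectors of (S_W, S_B) (the
discriminative subspace has n_classes − 1 = 2 dimensions); because those
eigenvectors whiten S_W (VᵀS̃V = I), the shared model covariance in the
subspace is the identity over its degrees of freedom, and the Gaussian
discriminant score reduces to a priors-adjusted nearest-centroid rule
there; at λ = 1 it is exactly nearest-centroid.  Ties break towards the
lowest class index.  Per-class tp/fp/fn accumulate over folds;
F1 = 2PR/(P+R) per class with F1 = 0 when P+R = 0; the aggregate is the
unweighted macro average over the three classes, whose chance level for
balanced classes is ≈ 1/3 (reported as "≈ 34%" when rounded to percent).
A vectorized path fits all channel × frequency problems of one subject
simultaneously; its equality with the reference single-problem
implementation is asserted in the tests.

With only `lMC` carrying a scalp-visible effect, `rCB` and `sham` are
indistinguishable by construction, so even a perfect detector saturates
near macro F1 ≈ 2/3, not 1; the per-class `lMC` F1 approaches 1 in the
strong-effect, low-noise regime.

## Group statistics

* **Cluster test.** Per channel, a dependent-samples one-way F
  (repeated-measures, subject as blocking factor; equality with a standard
  RM-ANOVA implementation is tested) across the three within-subject class
  scores; channels above the F(k−1,(k−1)(n−1)) 95th percentile (the
  threshold is configurable; no canonical value exists) are clustered
  through the montage neighbour graph; cluster mass (ΣF) is compared to the
  maximum-mass null from within-subject label permutations;
  p = (1+#{null ≥ obs})/(1+n_rand), never exactly 0.  Default 1000
  randomizations.
* **ROI tests.** Kruskal–Wallis (midranks, tie-corrected) per ROI with
  Benjamini–Hochberg FDR across the ROI family; Wilcoxon signed-rank
  post-hocs (normal approximation, zeros dropped) with FDR over the pair
  family; one-sided signed-rank tests against the 1/3 chance constant.
* **Correlations.** Product-moment by default (rank correlation available),
  Fisher-Z comparison Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)).
* **Power contrast.** The traditional analysis — trial-averaged POST−PRE
  band power per channel — reuses the identical cluster machinery, so the
  decoding and averaging pipelines differ only in the quantity tested.

## Source reconstruction

A three-layer spherical conductor (MNE's analytic sphere model, centre and
radius fitted by least squares to the 62 standard electrode positions)
replaces a template-MRI BEM; electrodes are projected onto the sphere
surface.  Leadfields are computed on a volumetric lattice (default 12-mm
spacing, radial shell 0.25–0.85 × head radius, points far below the equator
excluded — the model brain occupies the upper sphere).  Five left
sensorimotor ROIs (M1, S1, PMC, SPL, IPL) are angular sectors anchored at
the scalp directions of C3, CP3, FC3, P3 and CP5 — a geometric stand-in for
atlas parcellation that preserves the ROI-averaging logic.

The LCMV filter w = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ uses the sensor covariance of
band-passed data pooled across PRE and POST of one session (condition-wise,
not pooled across conditions), with diagonal loading of 5% of the mean
eigenvalue (the regularization has no canonical value; it is configurable).
Source orientation is the direction of maximum output power (the smallest
eigenvector of LᵀC⁻¹L), after which the scalar filter is recomputed;
unit gain wᵀL = 1 holds to machine precision.  Output power maps are
noise-gain normalized (divided by ‖w‖², the neural activity index) because
the raw unit-gain map is depth-biased — weak-leadfield points amplify
noise; with white-noise input the raw map is proportional to the noise-gain
map, which the tests assert.  In a conducting sphere no source is
electrically silent at the scalp, so the "cerebellar" source — outside the
montage's coverage in the emulated study — is realized as a latent source
whose scalp gain is set to zero by construction rather than by geometry.
Band-limited source power uses the Hilbert envelope; the analytic signal is
computed in sensor space and projected through the filters afterwards
(both operations are linear, so this is exact and much cheaper).  Source
decoding mirrors the sensor pipeline per grid point with 8 envelope-power
time-segments as features; point F1 is averaged within ROIs before testing.

## Phase coupling

PLV between θ and α is computed literally as printed in the field's
convention: per time point, the modulus of the trial-averaged unit phasor
of φ_θ(t) − φ_α(t); the reported scalar averages that over the analysis
window (the time reduction is left implicit in the defining equation; this
package makes it the per-timepoint-then-average choice).  A 1:1 phase
difference between oscillators of different centre frequency drifts within
a trial unless the two bands share a generator, so the discriminating
quantity is across-trial consistency; an n:m mode (e.g. 2:1 for θ:α) is
available but not the default, since the defining equation names none.
For phase-locked trials PLV = 1 (exactly, for identical phase
trajectories; to ~10⁻³ for distinct trials, limited by Hilbert edge
effects), for N = 1 it is 1 regardless of the data, and for independent
phases its expectation is the Rayleigh mean √π/(2√N).

## The synthetic-data generator

Signals are sums of leadfield-projected oscillatory sources plus 1/f
background (log-log PSD slope −1 over 2–40 Hz) plus white sensor noise,
recorded against CPz, deterministic given (seed, config) and generated
lazily per recording so full-scale studies need not be held in memory.
Sources are amplitude-modulated sinusoids with random phase per epoch and
±1 Hz frequency jitter; the planted aftereffect is one dipole under each
stimulation electrode (FC3, CP3) whose POST power changes by the effect
size in `lMC` only.  Occipital alpha and frontal-midline theta bystander
sources are present in all conditions.  Optional theta–alpha phase locking
shares the per-epoch phase between a motor theta source and the motor alpha
source in configurable (protocol, phase) cells.

Default amplitudes were frozen after a pre-build Monte-Carlo calibration at
the emulated study's scale (24 subjects, 80 task epochs): motor-alpha peak
scalp amplitude 3.6 µV against 4 µV of 1/f noise and 1 µV sensor noise,
per-epoch log-normal amplitude σ = 0.1.  At that operating point the
planted 30% power decrease yields subject-level alpha-band F1 of ~0.39 at
the stimulation site against 0.33 elsewhere — the focal, modest elevation
regime the method is designed for — and the group cluster test recovers a
left-central cluster containing FC3 or CP3 in ≥ 80% of study seeds.

Between-subject heterogeneity has three components:

* a **whole-recording gain** (log-normal, σ = 0.6, truncated to
  [0.4, 2.5]): head geometry, skull conductivity and electrode impedance
  scale signal and noise together, so raw power varies several-fold across
  subjects while per-subject discriminability is unaffected; the
  truncation reflects that a recording whose amplitude saturated the
  artifact threshold throughout would be re-prepped or excluded, not
  analysed;
* an **oscillation-specific amplitude factor** (log-normal, σ = 0.2);
* a **responder factor** (normal, mean 1, σ = 0.75) multiplying the planted
  power change: tACS aftereffects vary strongly in magnitude — and
  occasionally in direction — across individuals, which is a central
  empirical motivation for decoding-based analyses.  The planted effect
  size is the mean across the population.

What the generator does **not** emulate: eye blinks and muscle artifacts
(the rejection stage is exercised with injected high-amplitude transients
instead), session-to-session nonstationarity of oscillatory power (PRE and
POST differ only by sampling noise and the planted effect, a condition the
null-calibration guarantees require), realistic head-model asymmetries, and
behaviour.  Passing tests therefore establish the pipeline's statistical
calibration and its sensitivity to focal band-limited power changes of
known provenance — not performance on artifact-laden, nonstationary human
recordings.

A consequence worth stating plainly: in this stationary synthetic world
with many trials per session, the per-subject POST−PRE power change is
estimated precisely, and whenever its *direction* is consistent across most
subjects the trial-averaged contrast is a near-optimal test — at small
planted effects it can outperform the decoding pipeline.  The decoding
pipeline's advantage appears where aftereffects are direction-inconsistent
or the data nonstationary, i.e. in the very regimes the clean generator
deliberately excludes.  The sensitivity-ordering check in the acceptance
suite measures this honestly rather than asserting the expected ordering
into existence.

## Numerical and reproducibility choices

Seeds for simulation, epoch shuffling, CV folds and permutation tests are
separate and all recorded in the pipeline manifest; identical seed and
configuration reproduce recordings bit-for-bit.  The Morlet transform runs
in single precision (features feed rank- and count-based statistics; the
quantization floor of the EDF format itself is 0.1 µV).  Scaled-down test
studies use 8–16 channels at 128 Hz; reduced montages scale the
neighbour-graph threshold up from 0.4 × head radius until the scalp graph
is connected, since sparse montages have proportionally larger
inter-electrode spacing.  EDF export uses 16-bit samples at 0.1 µV
resolution with a JSON sidecar for events, seeds and ground truth.
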