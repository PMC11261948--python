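# Methods

## Problem and model

Interictal high-frequency oscillations (HFOs, brief 80–300 Hz bursts in
intracranial EEG) are candidate biomarkers of the epileptogenic zone, but
they arise from both pathological and physiological generators and no
signal-processing rule reliably separates the two. This package implements
a self-supervised route to that separation: every detected event is
rendered as a normalized Morlet time–frequency image, a beta-VAE learns an
8-dimensional morphology code without labels, and a two-stage Gaussian
mixture on the codes discovers an artifact class (mArtifact) and a
putative-pathological class (mpHFO) whose only contact with clinical data
is a single labeling bit: among seizure-free resected subjects, the
cluster with the higher fraction of events on resected channels is deemed
pathological.

The intended chain is

    EDF → montage/resample/notch → STE+MNI detection (80–300 Hz) → merge
        → ±285 ms, 10–290 Hz Morlet image (64×64, min–max to [0,1])
        → beta-VAE encoder (8-D latent)
        → stage 1 GMM (k=2, latents + reconstruction-error feature) → mArtifact
        → stage 2 GMM (k=2, latents) + clinical labeling bit → mpHFO / non-mpHFO

with downstream analyses (cone template, latent traversal, sub-HFO
stretching, resection-ratio outcome models) reading off what the model
learned.

## Preprocessing

Grid/strip channels receive a common average reference computed over the
non-bad grid/strip channels; the exact "customized" reference recipe used
clinically is not fully specified anywhere, so the plain non-bad-channel
mean is used. Depth (SEEG) contacts are paired into adjacent-contact
bipolar derivations per shaft (alphabetic prefix + contact number; a
single-contact shaft yields no pair and is dropped with a warning).
Signals are resampled to 1,000 Hz by polyphase anti-aliased filtering
(exactly rational for the common 2,000→1,000 case) and the 60 Hz line
frequency and all harmonics below Nyquist are removed with zero-phase
(forward–backward) Butterworth band-rejects of 2 Hz stopband, so event
morphology suffers no phase distortion. Attenuation at the harmonics
exceeds 40 dB by a wide margin; passband ripple away from the stopbands is
below 1 dB.

## Detection

Two classical detectors run per channel in the 80–300 Hz band and their
events are merged by interval union (any shared sample merges; the merge is
idempotent and order-invariant).

- **STE**: 3 ms moving RMS of the band-passed trace; events where RMS
  exceeds the epoch mean + 5 SD for ≥ 6 ms, with ≥ 6 rectified peaks above
  mean + 3 SD; events closer than 10 ms are joined. Epochs are 600 s; a
  shorter trace falls back to a single epoch with a warning.
- **MNI-style baseline detector**: 125 ms windows whose normalized
  spectral entropy exceeds 0.9 are treated as oscillation-free baseline
  (spectral flatness is the computable proxy for the published
  wavelet-entropy criterion). Band energy (10 ms moving average of the
  squared signal) from baseline is fitted with a gamma distribution and
  the detection threshold is its 99.9999th percentile; events must last
  ≥ 10 ms. With under 5 s of baseline the whole trace is used
  (continuous-mode fallback, logged).

Both thresholds are data-relative, so detection is invariant to global
amplitude scaling. A transparent amplitude rule replaces the released
deep-learning spike classifier: an event is tagged "spk" iff the 10–80 Hz
band within ±100 ms of its center exceeds 4 SD of that band over the whole
channel.

## Feature images

Each event is represented by the magnitude of its Morlet transform
(7 cycles at all frequencies; the segment is extracted wide enough that
the longest wavelet never sees the crop boundary), on a 1 Hz grid from 10
to 289 Hz over ±285 ms, bilinearly resized to 64×64 and min–max normalized
per image. Normalization is per image (not per dataset): amplitude is
deliberately discarded so that only morphology is modeled, and tone
localization is exact to ±1 row across the band. A constant-zero window
produces a defined all-zero image with a flag, never NaN.

## beta-VAE

Because no deep-learning framework is part of this package's dependency
set, the VAE is a residual fully-connected encoder/decoder pair written
directly over numpy with a small reverse-mode autodiff core
(`hfomorph._autograd`): input projection 4096→width, a stack of residual
blocks, linear heads for the posterior mean and (soft-clamped)
log-variance; the decoder mirrors this with a sigmoid output. The loss is

    loss = recon + beta · KL,   KL = −½ Σ_d (1 + log σ²_d − μ_d² − σ²_d)

per sample, batch-averaged, with beta = 0.1. Reconstruction error is
summed per sample (the standard beta-VAE scaling — with per-pixel means
the KL term dominates and the posterior collapses). Two criteria are
provided: plain MSE and a perceptual distance under a fixed feature
extractor (4×4 average pooling plus a seed-fixed random nonlinear
projection; the weights are deterministic and ship with the code, keeping
runs hermetic).

Training uses Adam, per-subject stratified sampling capped per epoch,
time-axis flip augmentation with probability 0.5, a subject-wise
validation split (10 subjects per site when available, else 20% of
subjects), and returns the checkpoint with the lowest validation loss.

Defaults follow the full-scale configuration (8-D latent, beta 0.1,
80 epochs, batch 512, lr 3e-4, cap 2,500/subject/epoch, perceptual
criterion; a 16-D latent is available via config but untested). The tested
desk-scale variant `VaeConfig.small()` — width 128, one residual block,
120 epochs, batch 32, lr 3e-3, MSE criterion — exists because the small
model takes orders of magnitude fewer optimizer steps: the learning rate
is raised accordingly, the MSE criterion is better conditioned at this
scale (the perceptual criterion's validation curve was unstable enough to
select near-initial checkpoints), and shorter schedules left the model
visibly undertrained (class structure absent from the latents). The
printed learning rate of the original large-scale setup is truncated in
the source text; 3e-4 is the standard Adam setting consistent with it.

## Two-stage clustering

Stage 1 fits a k=2 full-covariance GMM (k-means init, 5 restarts, 1e-6
covariance floor, fixed seed) on the latent codes augmented with one
standardized log-reconstruction-error column scaled by `err_weight`
(default 3). The augmentation is deliberate: artifacts are identified by
latent codes *and* reconstruction loss, and with latents alone the
dominant variance axis at small scale is sub-HFO power, which groups
spike-bearing pathological events with artifacts. Weighting the error
feature makes reconstruction quality the partition axis, which is exactly
the artifact semantics. The cluster with the higher mean reconstruction
error is mArtifact (exact ties break to the lower index with a warning).

Stage 2 fits a second k=2 GMM on the non-artifact latents (cap
2,000/subject; stage 1 caps at 10,000/subject). The labeling rule then
computes, per cluster, the fraction of its events lying on resected
channels, restricted to seizure-free resected subjects; the
higher-fraction cluster is mpHFO. No qualifying subject, a cluster with no
qualifying events, or an exact tie raises a labeling error rather than
guessing.

Inference encodes an image, computes its reconstruction error, and routes
the augmented code through stage 1 (artifact → label mArtifact,
P(mpHFO) = 0) and otherwise stage 2, where P(mpHFO) is the posterior of
the pathological component conditioned on non-artifact. The label map is
invariant to permuting GMM component indices.

## Interpretability

- **Cone template**: per subject, per pixel, a two-sided Welch t-test of
  mpHFO vs non-mpHFO images; a pixel enters the consensus mask iff it is
  significantly *higher* in mpHFO (p < 0.05) in more than half of the
  usable subjects. No multiplicity correction — the cross-subject
  consensus is the robustness device; alpha is configurable.
- **Pathological dimension**: per-dimension Cohen's d between mpHFO and
  non-mpHFO codes, oriented positive = mpHFO-higher; the argmax of |d| is
  the pathological dimension, flagged unstable when max |d| < 0.2.
- **Latent traversal**: one dimension is swept over empirical percentiles
  (default 5–95); decoded images are scored for power above 30 Hz inside
  the template, beta-band (10–30 Hz) power, and P(mpHFO). Decoded images
  are min–max re-normalized before re-encoding — every image entering the
  inference pipeline satisfies that contract, and raw decoder output has a
  reconstruction error far outside the stage-1 feature's fitted range.
- **Sub-HFO stretching**: a zero-phase order-12 Butterworth low-pass at
  80 Hz splits the segment (high = original − low, exactly complementary);
  the low component is resampled by the stretch factor and center-cropped;
  output = stretched-low + original-high. Factor 1 is the identity; the
  high band is conserved to < 0.1% relative RMS away from filter edge
  transients. The resampling route was chosen over a phase vocoder for
  determinism and simplicity.

## Outcome analyses

Subject-level resection ratios are computed on merged (disjoint) events so
STE/MNI duplicates of one burst count once; subjects with zero events of a
class are excluded from that model with a logged count. Event rates are
count/channel/min with SOZ vs non-SOZ Welch t-tests per label.
Covariate-separability tests train a multinomial logistic classifier on
the latents across repeated CV folds with the true labels and with
permuted labels, and compare the two accuracy collections by Welch t-test.
Outcome models are unpenalized (C = 1e6) logistic regressions — AUC is
meant to reflect the feature, not regularization — scored on pooled test
folds of a site-stratified subject-wise 5-fold split, plus a 500-tree
random forest reporting per-fold accuracy/F1 as mean ± SEM. t-SNE
projection is visualization-only and asserted only for shape.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

- **Background**: 1/f (alpha = 1) noise at 10 µV RMS per channel.
- **Physiological events**: Hann-windowed ripple bursts, 85–150 Hz,
  40–100 ms, peak 5–10× background RMS (detectability by construction).
- **Pathological events**: the same ripple plus a biphasic spike transient
  (8–15× RMS, dominant energy 10–80 Hz) and a gamma burst (30–80 Hz,
  3–6× RMS) — the co-occurring sub-HFO signature.
- **Artifacts**: deliberately heterogeneous broadband transients — random
  trains of 1–4 ms impulses, steps, ringing at arbitrary frequencies, and
  slow drift, at 10–20× RMS. The heterogeneity is essential: the stage-1
  premise is that artifacts reconstruct poorly, which requires their
  morphology distribution to be broad.
- **Structure**: per-channel event centers ≥ 200 ms apart (so ±285 ms
  windows of distinct events never share a center); default mix
  0.40/0.35/0.25 pathological/physiological/artifact at 2 events/min;
  SOZ fraction 0.25, resections covering the SOZ at fraction 0.5; 70% of
  subjects seizure-free; pathological events placed on resected channels
  of seizure-free subjects with odds multiplied by the enrichment factor
  (default 5; infinity forces all of them there; 1 gives uniform
  placement).

What the generator does *not* emulate: propagation across channels, fast
ripples (> 300 Hz), sleep-stage structure, realistic inter-subject
morphology variability, or annotation noise in SOZ/resection labels.
Passing tests therefore demonstrate that the pipeline's machinery recovers
the intended structure when its premises hold, not that the premises hold
in clinical recordings.

## Problem sizes and numerical choices

The test suite and acceptance script run a five-subject cohort (6 channels
× 120 s at 1 kHz, 4 events/min) end to end with the small VAE; the
two-stage clustering and labeling-rule checks use 20 cohorts of metadata
scale, and null calibrations use 10 seeds each. These sizes were chosen so
that class structure is statistically resolvable (a few hundred events,
roughly balanced classes) while a full run stays in the tens of seconds.
Key tolerances: notch depth ≥ 40 dB; tone localization ± 1 row; analytic
KL to 1e-9; GMM-vs-naive-EM agreement ARI = 1 on separated blobs; stretch
identity and high-band conservation < 1e-3 relative RMS measured away from
filter edge transients (IIR edge ringing is excluded by construction, not
tolerance-widened). Filtering edge cases: single-contact shafts drop with
a warning; empty selections, single-class inputs, unlabeled classifiers
and undefined ratios raise typed errors rather than returning silent
defaults.

## Known limitations

- The stage-1 clustering space (latents + weighted error feature) is a
  documented departure from clustering on latents alone; with weight 0 the
  original behavior returns, but at desk scale it mislabels spike-bearing
  events as artifacts.
- The MNI detector is a faithful re-implementation of the published
  *scheme* (baseline by background-likeness, gamma-percentile threshold),
  not a port: the original wavelet-entropy baseline criterion is replaced
  by spectral entropy and minor constants differ.
- The perceptual criterion is available but the desk-scale default is
  MSE; at full scale the perceptual criterion with a stronger feature
  extractor is expected to behave differently.
- Outcome models at five subjects are exercised through synthetic
  subject-feature tables (hundreds of subjects), not through the
  five-subject pipeline output, which is too small for meaningful AUC.
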