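# Methods

`lpsnet` implements a source-space, frequency-domain network analysis
for event-related EEG: lagged phase synchronization (LPS) between
cortical region-of-interest (ROI) time series in a narrow band,
baseline-normalized connectivity indices, dendrogram-based sub-network
identification, weighted clustering coefficients, permutation inference
with max-statistic family-wise correction, and a response-time
correlation analysis.  Because studies of this kind rarely deposit raw
EEG, the package pairs the analysis chain with a ground-truthed
synthetic-study generator, so every stage can be validated against
known planted structure.

## The connectivity estimator

Per trial, each ROI's 2-s epoch is Fourier transformed (0.5 Hz
resolution at 250 Hz); the coefficients at the bins inside the analysis
band (default upper alpha, 10–12 Hz) are normalized to unit modulus
(phase-only).  Cross products are averaged over trials, then over band
bins, giving a pairwise phase coherency ρ.  The lagged phase
synchronization is

    LPS = Im(ρ)² / (1 − Re(ρ)²),

in [0, 1].  The real (instantaneous) part of the coupling is projected
out, so any strictly zero-lag mixture — volume conduction on the scalp,
or crosstalk of a linear inverse — produces no LPS at all; the
degenerate case Re(ρ)² = 1 (identical signals) is mapped to 0.  An
amplitude-weighted coherency variant is available behind a flag
(`phase_only=False`).

Two indices summarize an event-related study: the absolute SDP-window
connectivity (c2), and the event-related index c1, the percent change
of SDP connectivity relative to the last 2 s of the pre-stimulus
baseline.  At the element level c1 = (event − baseline)/max(baseline,
ε) with ε = 1e−6 (a `ratio` variant exists).  For *group-level*
statistics, c1 is the percent change of the *summed* group
connectivity, not the sum of elementwise ratios: individual baseline
entries of weakly coupled pairs sit at the estimator's noise floor, and
elementwise ratios there are arbitrarily heavy-tailed, whereas sums
over hundreds of pairs are stable.

## Source model and inverse

Channel epochs are mapped to one scalar time series per ROI centroid
with a standardized minimum-norm operator: W = Kᵀ(KKᵀ + λH)⁺, H the
average-reference centering matrix, standardized per source by
√((WK)_jj).  Standardization gives the zero-localization-error
property: for noiseless single-source data the standardized power peaks
exactly at the true source (Cauchy–Schwarz on the resolution Gram
matrix), verified exhaustively for all 84 sources.  λ defaults to
1e−4·trace(KKᵀ)/n_channels; sources are scalar (fixed orientation) —
the analysis consumes one time series per centroid, so vector dipoles
would only add un-exercised machinery.

The forward model is a deliberately simple spherical head: electrodes
on a Fibonacci layout covering the upper unit hemisphere, sources at
seeded random positions on the upper sphere (cortex sits under the
cap), Gaussian-topography columns (spread 0.25) centered to zero mean
across channels.  Sources are grouped into four compact, well-separated
spatial clusters of consecutive column indices, mirroring the fact that
functional sub-networks are distinct anatomical systems; without
spatial coherence between index blocks and positions, inverse crosstalk
mixes the groups and no pipeline-level recovery is possible for *any*
method.  The inverse accepts any externally supplied leadfield.

## Synthetic study generator

The generator emulates a 16-subject study with four conditions (two
tasks × instructed lying / instructed truth-telling), 25 trials per
condition, and per trial a 2-s baseline and a 2-s stimulus-delivery
(SDP) window, at 64 channels / 250 Hz.

* **Latent coupling model.**  Each of four ROI groups owns a latent
  band-limited process, synthesized directly in the frequency domain
  (nonzero coefficients only inside the band).  Node i of group g
  reproduces its group latent at a node-specific lag τ_i ~ U[8, 40] ms,
  applied as an exact e^(−2πifτ) phase factor, over a 1/f background.
  Lags are strictly positive so the coupling is visible to a
  lagged-phase measure; the closed-form cross-spectrum this synthesis
  affords is the oracle for all estimator-consistency tests.  For
  jointly Gaussian spectra with coherency γ, the expected phase-only
  cross term is (π/4)·γ·₂F₁(½, ½; 2; |γ|²), which maps the model's
  coherency to the estimator's asymptote.
* **Directed between-group coupling.**  The lower-indexed group drives
  the higher-indexed one through a single lag fixed at a quarter cycle
  of the band center.  A *symmetric* bidirectional mixture with a shared
  lag contributes 2B·cos(ωτ) to the cross-spectrum — purely real, hence
  invisible to LPS and sign-unstable across lag draws — so the directed
  form is the only one whose planted coupling the estimator can see
  reliably.  Receiver latents are normalized to unit power so that
  raising a between-group gain does not inflate the receiver group's
  internal coherence as a side effect.
* **Planted contrast.**  In conditions tagged "IL" the SDP-window
  coupling between groups 0 and 2 is multiplied by 2.5 (baseline
  windows unmodulated).  Groups 0 and 2 occupy diametrically opposite
  cortical patches, so the contrast is not confounded with crosstalk
  between spatially adjacent groups.
* **SNR.**  Per node, the in-band 1/f-background power is fixed at
  −10 dB relative to the band-limited signal (configurable); the noise
  floor is normalized at reference amplitudes so that amplitude
  modulations change the effective SNR (and hence measurable coupling)
  rather than being invisible.
* **Behavioral link.**  One target ROI (44R in the default labelling)
  is a hub carrying every group's latent (own group dominant at weight
  0.75).  A per-subject engagement trait (SD 0.35) scales the hub's SDP
  signal supralinearly (cubed) against its fixed noise floor (0 dB
  reference), and response times are intercept + slope·(engagement−1)
  plus noise (SD 0.05 s).  The chain RT ← engagement → measured
  event-related clustering coefficient realizes a correlation of ≈0.8
  between RT and the target's coefficient at 25 trials.  The supralinear
  mapping and the low RT noise are calibration: the max-|ρ| threshold
  over 84 variables at n = 16 is ≈0.72–0.75, so a weaker planted link
  is not recoverable at the stated rates by any method.
* **Artifacts.**  Blinks are 250–400 ms raised-cosine transients with a
  frontal topography; muscle bursts are Hanning-windowed white noise
  with localized random topographies; dedicated EOG/EMG reference
  channels carry the waveforms plus 1% noise.  With both rates zero the
  EEG passes through bit-identical.

What the generator does **not** emulate: realistic head geometry and
conductivity, non-stationary oscillatory dynamics (bursting alpha),
1/f-slope variation, line noise, electrode drift or bridging, or
condition-dependent ERP transients.  Passing tests demonstrate that the
chain recovers the statistical structure it assumes — lagged narrowband
group coupling under instantaneous mixing — not that it is robust to
every failure mode of real recordings.

## Cleaning chain

Band-pass 1–30 Hz (4th-order Butterworth, forward–backward, so no phase
distortion reaches the lag-sensitive estimator), common-average
reference, ocular artifact removal by second-order blind identification
(SOBI: whitening, then joint diagonalization of lagged covariances,
lags 1–50 samples, by Jacobi-style Givens sweeps), and muscle artifact
removal by BSS-CCA (canonical correlation between the data and its
one-sample-delayed copy; components below a lag-1 autocorrelation of
0.85 are discarded).  Muscle removal runs on the broadband data
*before* the 1–30 Hz filter: band-limiting first raises EMG components'
lag-1 autocorrelation (a flat 1–30 Hz spectrum at 250 Hz already
autocorrelates at ≈0.90) above the brain/muscle separation threshold.
SOBI components correlating with the EOG reference at |r| ≥ 0.7 are
zeroed; if none reaches threshold the data pass through unchanged
(optionally the single most-correlated component is removed).  On
single 2-s trials a full-rank 64-channel decomposition is
over-parameterized and smears blinks across components, so SOBI
restricts itself to the strongest 20 principal components by default.
Both BSS steps run per trial or on the trial concatenation
(`artifact_removal="per_trial" | "whole"`); the whole-recording mode is
statistically much stronger and is the pipeline default.

The response-time channel is processed causally (forward-only 1–25 Hz
filter, rectification, trailing 50 ms moving average): a zero-phase
envelope would smear burst energy backwards and bias onset detection
early.  Onset is the first sustained excursion above baseline mean +
k·SD (k = 3, ≥100 ms), an invented but documented criterion; the
response time is measured from stimulus *offset* to that onset.

## Statistics

Paired comparisons across many variables use the tmax permutation
scheme: whole-subject sign flips of the difference vectors (preserving
cross-variable correlation), with the corrected p-value of each
variable read off the null distribution of the maximum |t|.  Exhaustive
enumeration replaces Monte-Carlo sampling whenever 2ⁿ (or n! for the
correlation test) fits under 2²⁰; Monte-Carlo p-values carry +1
smoothing and are never exactly zero.  Correlation tests are Spearman
(mid-ranks) with the max-|ρ| correction under joint permutation of the
predictor.  Intra-group (4 variables) and inter-group-pair (6
variables) indices are corrected as two separate families; per-ROI
clustering-coefficient contrasts are corrected across all 84 ROIs.

## Network metrics

Node distances for the dendrogram are 1 − r between connectivity
profiles (rows, excluding the pair's own columns) by default, or
1 − connectivity; both recover the planted partition on clean block
structure.  Merging is unweighted average linkage (UPGMA, via scipy),
and the partition is a deterministic K-cluster cut (K = 4 default) —
the reproducible stand-in for selection "by visual inspection", with
the dendrogram logged so a user can override membership.  Dendrograms
are computed on absolute (un-normalized) SDP matrices; the consensus
partition pools the group-mean matrices of every condition and window.
The weighted clustering coefficient is the fully weighted
geometric-mean triangle form, C_i = Σ_{j≠h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
(k_i(k_i−1)) with ŵ = w/max(w), invariant to global rescaling and
checked against brute-force triangle enumeration and networkx.

## Numerical and design choices

* Phase-only coefficients with zero modulus (exactly zero signal) are
  treated as zero contributions; coherency magnitudes above 1 + 1e−9
  raise an integrity error.
* Baseline division floors at ε = 1e−6 and flags floored entries.
* UPGMA ties follow scipy's deterministic nearest-pair order.
* Every random draw is addressed by a `SeedSequence` spawn key derived
  from (seed, subject, condition, window), so identical configurations
  are bit-identical regardless of execution order, and streaming
  per-subject generation equals bulk generation.
* Per-cell channel noise/artifact seeds derive from a SHA-256 of the
  configuration hash and cell coordinates (process-independent).

## Problem sizes used in validation

Estimator-consistency checks run at 400 trials (tolerance ±0.1 against
the closed form); partition recovery uses 6-subject group means;
family-wise error uses 1000 replicates of 84 correlated variables at 16
subjects; the pipeline-level contrast recovery runs 50 independent
16-subject studies (artifact injection off in those runs — per-trial
blind source separation costs dominate otherwise and the artifact chain
is validated separately); the behavioral-link recovery runs 60 studies
plus 180 null-response-time replicates.  The acceptance script uses the
same machinery at 30/40 replicates.

## Known limitations

* The toy spherical forward model is not a head model; localization
  claims concern the operator algebra, not anatomy.
* With 25 trials × 5 band bins, any per-subject coupling functional
  carries ≥10% relative noise; group-level indices inherit this, which
  is why elementwise percent-change matrices are reported but
  group statistics use percent change of sums.
* The dendrogram cut assumes the group count K is known (K = 4); no
  model-selection criterion is provided.
* Event-related clustering coefficients divide by baseline
  coefficients; ROIs with near-zero baseline clustering would be
  unstable (not exercised by the default generator, whose baseline
  networks are dense).
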