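# Methods

`voicesym` implements a two-stage analysis of depressive symptom structure:
(1) unsupervised grouping of patients by their HAM-D-17 symptom profiles,
and (2) supervised separation of those groups from acoustic features of
fixed-phrase speech recordings. Because clinical recordings of this kind
cannot be redistributed, the package ships a generative model of both data
modalities; every published number the package reports is recomputed from
synthetic cohorts or from printed study tables.

## 1. Symptom clustering

**Input.** Per-subject integer scores on the 17 HAM-D items. Items 4, 5, 6,
12, 13, 14, 16 and 17 are scored 0–2, the rest 0–4; the severity total is
the plain sum.

**Distance.** The dissimilarity between two subjects is the correlation
distance `d(a, b) = 1 − r(a, b)` with `r` the Pearson correlation of their
17-item profiles. This compares the *shape* of the symptom profile and is
insensitive to overall severity. A zero-variance profile has no defined
correlation; such pairs are assigned `d = 1` (treated as uncorrelated) so
the procedure is total. `1/r` was rejected as a distance: it is undefined
at `r = 0`, negative for `r < 0`, and not monotone in dissimilarity.

**Three-tier procedure.**
1. Subjects with total 0 are excluded (no symptoms to group).
2. Subjects with total ≥ 4 are split into k = 2 clusters by K-means under
   correlation distance: assignment to the nearest centroid by `d`, centroid
   update as the arithmetic mean of member profiles. Initial centroids are
   two distinct random subject profiles; the best of 20 restarts by total
   within-cluster distance is kept; convergence is declared on an unchanged
   assignment or after 100 iterations. An emptied cluster is re-seeded with
   the point farthest from the surviving centroid.
3. Subjects with totals 1–3 are allocated to the nearer centroid
   (ties → group 1).

Labels are canonicalized so that **group 1** is the cluster with the higher
centroid score on item 7 (work and activities) — the *inactivity* group —
making group identity invariant to the clustering seed.

**Item tests.** Group differences per item, plus the total, are tested with
the two-sided Wilcoxon rank-sum test in its normal approximation with tie
and continuity corrections (`scipy.stats.mannwhitneyu`); exact enumeration
is defeated by the heavy ties of small-integer scores at realistic n. With
18 tests the Bonferroni-corrected family levels are 0.05/18 ≈ 2.8 × 10⁻³,
0.01/18 ≈ 5.5 × 10⁻⁴ and 0.005/18 ≈ 2.8 × 10⁻⁴; the report stores for each
test how many of these levels it clears. If every score in a comparison is
identical the test is reported as p = 1 (no evidence) rather than
undefined.

## 2. Acoustic features

All recordings are mono PCM at 11.025 kHz by default. Analysis frames are
25 ms Hamming windows with a 10 ms hop except where noted. Unvoiced or
invalid frames carry NaN and stay missing through aggregation; the tree
learner consumes missing values natively (median imputation is available as
a fallback for other learners).

* **F0 / HNR** (40 ms frames): the normalized autocorrelation is divided by
  the window autocorrelation (Boersma's correction) so a perfectly periodic
  frame scores r ≈ 1 despite the taper. The pitch lag is picked on a
  low-passed copy of the signal (cutoff `max(3·fmax, 1200)` Hz) because
  cycle-to-cycle jitter decorrelates high-frequency formant ringing at the
  one-period lag; candidate peaks carry a per-octave lag cost of 0.25 since
  under i.i.d. jitter the two-period acf peak is systematically sharper
  than the one-period peak (summed intervals average the jitter out).
  Search band 60–400 Hz; a frame is voiced when the full-band corrected r
  at the chosen lag exceeds 0.45. HNR = 10·log₁₀(r/(1−r)) dB, clipped at
  40 dB.
* **Jitter / shimmer**: anchor peaks (one per cycle) from a low-passed
  copy (1.5 × median F0); each period is then refined by waveform matching
  on the raw signal — the lag maximizing the normalized cross-correlation
  of consecutive cycle windows, with parabolic sub-sample interpolation.
  Local jitter (shimmer) is the mean absolute consecutive period
  (amplitude) difference over the mean.
* **Spectral** (per frame): linear power summed over half-open FFT bands
  [0, 500), [500, 1000), [1000, 4000) Hz, so the bands partition 0–4 kHz
  without double counting; power-weighted spectral centroid; spectral flux
  as the Euclidean distance between consecutive unit-power magnitude
  spectra (first frame 0); energy RMS on rectangular frames.
* **Formants**: linear prediction of order `2 + rate/1000` (≈ 13 at
  11.025 kHz) on pre-emphasized (0.97) voiced frames, autocorrelation
  method via Levinson–Durbin; polynomial roots with bandwidth ≤ 400 Hz and
  frequency ≥ 90 Hz, first five in increasing order.
* **MFCC**: 26 triangular mel filters spanning 0 Hz–Nyquist on the frame
  power spectrum, log with floor 1e-10, orthonormal DCT-II, coefficients
  1–12 (the energy coefficient 0 is excluded, which makes the returned
  coefficients exactly invariant to global amplitude scaling).
* **Glottal flow (IAIF)**: per 64 ms voiced frame (32 ms hop), two
  iterations of iterative adaptive inverse filtering — order-1 glottal
  pre-model, vocal-tract LPC, inverse filtering, order-4 glottal re-model,
  final tract LPC — with leaky integration (pole 0.99) to the flow;
  per-frame flow-derivative segments are overlap-added with Hann weights.
  Glottal closure instants are negative peaks of the flow derivative.
* **NAQ / QOQ** per detected cycle: NAQ = peak-to-peak flow / (|most
  negative flow derivative| × cycle duration); QOQ = fraction of the cycle
  during which flow exceeds the cycle minimum plus half the peak-to-peak
  amplitude. First differences live at sample midpoints, so node-centered
  derivatives are reconstructed by half-sample extrapolation — without
  this the sharp negative peak at glottal closure is underestimated by
  several percent. Degenerate cycles are skipped and counted.

**Feature vector.** The registry enumerates (feature, statistic, phrase)
triples in fixed order: 27 frame/cycle-wise features × {mean, std} plus
jitter and shimmer as single per-recording values, for each of the 21
phrases — 1176 predictors per subject. (The study reports 1032 independent
variables; its exact composition — MFCC count, which features carry a
standard deviation — is not published, so the registry is self-consistent
rather than matched to that count.)

## 3. Classification

Stratified five-fold cross-validation of group prediction with a
gradient-boosted decision-tree ensemble (LightGBM), positive class =
group 1. Small-data guardrails: 80 trees, learning rate 0.1, ≤ 7 leaves,
depth ≤ 3, ≥ 5 samples per leaf, 70% feature subsampling, L2 = 1, all
overridable via config. Per fold, the decision cutoff on the predicted
probability is the threshold maximizing the Youden index J = sensitivity +
specificity − 1 over the midpoints of sorted unique *training-split*
scores plus sentinels, ties broken toward the lowest threshold. Choosing
the cutoff on the training split avoids leaking test labels; a config
switch (`cutoff_on="test"`) exposes the alternative reading. Test-split
predictions are thresholded into a fold confusion matrix; the five fold
matrices are summed cell-wise and sensitivity, specificity and accuracy
are computed from the pooled counts. Note that pooled metrics can differ
from averaged per-fold metrics by rounding — from the pooled study table
(31, 6, 10, 30) the exact values are sensitivity 83.8%, specificity 75.0%,
accuracy 79.2%.

The feature report lists every (feature, statistic, phrase) triple with
nonzero split gain in any fold, ranked by total gain.

## 4. Synthetic data generator

**HAM-D cohorts.** A one-factor Gaussian latent model: a shared
standard-normal factor per subject loads on items 1 and 7 so their
*observed* correlation matches a target (default 0.7), and weakly
(loading² = 0.3) on the other items; rounding to integers adds variance
1/12 (Sheppard's correction), so the latent coupling is inflated by the
inverse attenuation factor before discretization. Item scores are rounded
and clipped to their ranges. Group profiles default to the clinical
contrast: group 1 elevated on guilt (2), work and activities (7) and loss
of appetite (12); group 2 on insomnia early (4); elevation defaults to
1.5 latent SDs. Base means and SDs (0.8/0.7 for 0–4 items, 0.4/0.35 for
0–2 items) keep elevated means clear of the clipping boundaries, which
would otherwise silently shrink the realized separation.

**Voices.** Rosenberg "type C" pulse trains: within a cycle of period T
and open quotient OQ the flow rises as `3u² − 2u³` over `Tp = ⅔·OQ·T` and
falls as `1 − v²` over `Tn = ⅓·OQ·T`, giving the closed forms
NAQ = OQ/6 and QOQ ≈ 0.569·OQ used as oracles. Pulses are evaluated in
continuous time (fractional cycle starts and periods) so sampling adds no
artificial period quantization. Jitter perturbs the cycle *spacing* while
the pulse shape keeps the unperturbed duration — glottal closure events
then carry exactly the designed cycle-to-cycle jitter; Gaussian period and
amplitude perturbations are scaled by √π/2 so the *expected local
jitter/shimmer* equals the requested percentage. Aspiration noise is white
Gaussian passed through the same vocal tract and scaled on the radiated
output to the requested periodic-to-noise power ratio. The tract is a
cascade of unit-DC-gain two-pole resonators (one per formant), radiation a
first difference, and the result is peak-normalized below clipping.

**Linked cohorts.** Each subject's latent group drives both the HAM-D
profile and the voice: at `acoustic_effect = 1` the inactivity group
speaks ~14 Hz lower, breathier (open quotient +0.12, aspiration SNR
−6 dB), and less stably (jitter +1 pp, shimmer +2.4 pp) than the insomnia
group, with a ±1.5% formant-scale shift — shifts of roughly one
between-subject SD, i.e. clinically overlapping rather than separable by
any single feature. Phrases cycle through four vowel-like tract templates
with per-phrase prosodic variation. `acoustic_effect = 0` makes the groups
acoustically identical while the HAM-D contrast remains.

**What the generator does not emulate.** Real phrase recordings are
running speech with consonants, pauses and articulation dynamics, room
acoustics and recorder coloration; the generator produces sustained
stationary phonation per phrase. Passing benchmarks therefore demonstrate
that the pipeline recovers group structure from glottal/prosodic/spectral
differences of the kind the clinical literature associates with
depression — not that it would reach the same numbers on real recordings.

## 5. Verification benchmarks and problem sizes

All benchmarks live in `voicesym.benchmarks` and are exercised both by the
test suite and by `scripts/acceptance.py`.

* **Parameter recovery** (10 seeds, noiseless voices, speakers drawn with
  F0 105–150 Hz, OQ 0.5–0.7, formant scale ±5%): F0 within 2%, injected 2%
  jitter within 0.5 pp, formant medians within 10%, NAQ/QOQ within 5% of
  dense numerical evaluation of the closed-form pulse.
* **Oracle equivalence**: the clustering result equals the brute-force
  best 2-partition (all 2^(n−1) splits) on well-separated cohorts of ≤ 10
  clusterable subjects; the Youden cutoff attains the exhaustive-search
  maximum J on random instances.
* **Cluster recovery** (20 seeds, 30 + 30 subjects): mean adjusted Rand
  index ≥ 0.9 against the true groups. This benchmark uses the broad
  6-item contrast (2/7/12 vs the three insomnia items 4/5/6) at 3 latent
  SDs, which realizes 2–3 observed-SD separations per item. The default
  4-item contrast at 1.5 SD is *information-theoretically* below that bar:
  four items at 1.5 SD give a between-group Mahalanobis distance ≈ 3.0,
  i.e. ≈ 7% error for an optimal classifier (ARI ≈ 0.75), before the
  additional losses from per-profile standardization, integer rounding and
  the shared-factor noise that the prescribed item-1/7 correlation places
  on item 7. Correlation K-means behaves as a matched filter on
  standardized profiles and approaches that bound but cannot beat it.
* **End-to-end signal response** (10 seeds per arm, 40 + 40 subjects, 21
  phrases of 0.45 s): median cross-validated accuracy ≥ 75% at
  `acoustic_effect = 1` and within binomial noise of 50% at 0. Recordings
  of 0.45 s (~50 frames, ~55 glottal cycles) are used because all feature
  estimates stabilize well below that duration on stationary synthetic
  phonation; the generator default for realistic use is 2 s.

## 6. Known limitations

* The acoustic group effect sizes are free parameters of the generator —
  the study reports no per-group acoustic measurements to calibrate them.
* IAIF assumes an all-pole tract and works frame-stationarily; on running
  speech (as opposed to sustained synthetic phonation) NAQ/QOQ estimates
  are noisier than the benchmarks suggest.
* The pitch tracker is tuned for the 60–400 Hz band and modal/breathy
  phonation; strong subharmonics (e.g. vocal fry) would be tracked at the
  subharmonic.
* Pooled confusion metrics are reported exactly; per-fold-averaged
  variants can differ at the second digit.
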