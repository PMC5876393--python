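# Methods

`fnirsdecode` implements a complete decoding analysis for a block-design,
two-wavelength fNIRS experiment on affective valence, together with a
synthetic-data generator that stands in for participant recordings. This
note records the model, the defaults and why they were chosen, the
numerical decisions, and — importantly — what the calibration experiments
run during development revealed about the analysis itself.

## The experiment being modelled

Each simulated participant completes two blocks. In the *passive* block
they view affective images; in the *active* block they imagine affective
situations. A block has 20 trials — 5 positive, 5 negative, 10 neutral —
each with a 30-s epoch of interest, preceded by a 2-s fixation (plus a
2-s instruction cue in the active block) and followed by an intensity
rating and a 2–4 s jittered rest. Trial order is randomized with the
constraint that a neutral trial always separates a negative trial from a
positive one. Passive trials present a new image every 5 s (six per
epoch). The rating screen is self-paced in the real experiment; the
generator uses a fixed 4 s, giving a trial pitch of ~38 s (passive) and
~40 s (active).

Signals are recorded by a 32-channel montage (12 sources, 12 detectors;
30 mm separation; 760 and 850 nm) at 5.2083 Hz. Nine source/detector
pairs cover the fronto-temporal band (26 channels) and three pairs the
occiput (6 channels). The packaged layout reproduces these counts and the
two anatomical anchors (channel 5-5 frontopolar, channel 11-11 at Oz);
the exact pairings of such caps are typically documented only
pictorially, so the layout is a faithful-count stand-in, not a coordinate reproduction.

## Forward model

Each trial contributes a 30-s boxcar convolved with the canonical
double-gamma hemodynamic response (gamma shape parameters 6 and 16,
undershoot ratio 1/6), normalized so the plateau of the convolved
response is 1. The per-trial gain is jittered multiplicatively with
coefficient of variation `jitter_cv` (default 0.2), drawn independently
per trial *and channel* (local vascular variability) and shared between a
channel's two chromophores. HbR amplitudes default to −1/3 of HbO
(anticorrelated neurovascular coupling).

Spatial patterns are specified per region and label in µM
(`EffectSpec`). The defaults emulate the qualitative physiology of the
study: affective trials activate lateral/medial orbitofrontal and
ventrolateral prefrontal channels with a deactivation over dmPFC and a
modest occipital component; passive blocks add a visual occipital
response on every trial; active neutral trials are rest and carry no
planted effect. With `workspace_mode` on (default), positive and
negative trials share one spatial pattern — the affective-workspace
structure in which valence classes differ from neutral but not from each
other; with it off, the negative pattern is sign-flipped (a bipolar
code). The passive and active patterns share their prefrontal core but
differ in gains and in the occipital component, so elicitation condition
is itself decodable. Because the defaults share that core, cross-block
transfer *succeeds* in the default study; planting orthogonal patterns
per block reproduces chance-level transfer instead (both situations are
exercised in the tests).

Noise (`NoiseSpec`, all in µM): white sensor noise (sd 0.3) plus
cardiac (1.2 Hz), respiratory (0.3 Hz) and Mayer-wave (0.1 Hz)
oscillations (amplitude 0.15 each). The oscillators are *phase
random walks* with a 15-s coherence time rather than block-long
fixed-phase sinusoids: real physiological rhythms wander, and an
oscillator coherent over 13 minutes makes trials far apart in time
statistically dependent in a way nothing physiological would. A
per-channel linear drift slope is available but defaults to zero — a
deterministic monotone trend survives the band-pass well enough to make
trial *position* decodable and inflates leave-one-trial-out accuracy by
several points even with no planted effect (we measured +7.7 points at a
0.002 µM/s slope sd); it is retained as a knob precisely to study that
confound. Oscillator frequencies at or above Nyquist (fs/2 ≈ 2.6 Hz)
raise an error rather than aliasing silently.

Concentrations project to optical density by the modified Beer-Lambert
law: ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·L·DPF(λ), with
concentrations in mM, ε in mM⁻¹cm⁻¹ from the pinned Prahl-compilation
table (0.5864/1.54852 at 760 nm, 1.0580/0.69132 at 850 nm for HbO/HbR),
pathlength L = 3 cm, and DPF 7.25 (760 nm) / 6.38 (850 nm). The table is
a versioned in-code constant and overridable through `OpticalModel`.

## Preprocessing and features

The order is fixed: band-pass filter → whole-record baseline →
Beer-Lambert inversion → segmentation.

* **Filter.** Linear-phase FIR band-pass, 0.01–0.2 Hz, Hamming-windowed
  sinc, applied forward-backward (zero phase) so features stay aligned
  with event onsets. The default length is 1001 taps: at this sampling
  rate a 501-tap design leaks DC at −15 dB, which would defeat the
  baseline logic; 1001 taps reach −49 dB at DC per pass while still
  satisfying the 3×-taps series-length requirement for the ~790-s
  blocks. Taps are explicitly symmetrized so linear phase holds to the
  last bit.
* **Baseline.** Each (channel, wavelength) series has its whole-record
  mean subtracted. After the band-pass this is nearly a no-op; it is
  kept as an explicit stage of the modelled procedure.
* **Inversion.** Per channel and sample, the 2×2 system above is solved
  for (ΔHbO, ΔHbR) in µM. Forward/inverse round-trips are exact to
  machine precision.
* **Segmentation.** Half-open windows [onset, onset + 30 s) with floor
  conversion to samples: 156 samples per epoch. Passive epochs start at
  image onset (t = 2 s in the trial), active epochs at the end of the
  instruction cue (t = 4 s).

Each epoch is smoothed per channel and chromophore with a 2-s moving
average at 50% overlap (10-sample windows, hop 5, windows fully inside
the epoch, no padding → 30 windows), and the feature is the mean of the
windowed means. One block therefore yields a 20 × 64 trial matrix
(columns: HbO for the 32 channels in montage order, then HbR).

## Decoding

Two-class linear discriminant analysis, written from scratch. Per fold,
features are standardized with the *training* mean and sample (n−1)
standard deviation; zero-variance features get sd 1 and are flagged.
With class means µ_A, µ_B and pooled within-class covariance S (n−2
denominator), the weight vector is w = Σ_γ⁻¹(µ_B − µ_A) with
Σ_γ = (1−γ)S + γ(tr S/p)I. With p = 64 features and at most 19 training
trials S is always singular, so shrinkage is mandatory; γ defaults to
the Ledoit–Wolf analytic estimate computed on the pooled within-class
residuals, and γ = 0 raises an informative error when S is rank
deficient.

**The decision threshold is placed at the projected grand mean of the
training set** (equivalently b = 0 after fold normalization), not midway
between the projected class means. This is a deliberate choice: in
leave-one-out designs with a handful of trials, the midpoint rule is
systematically pushed toward the majority class by small-sample mean
estimation and yields 40–46% balanced accuracy under a pure-noise null —
the classic anti-learning artifact. The grand-mean threshold satisfies
E[w·(n_Aµ_A + n_Bµ_B)/n] = 0 under an exchangeable null and measured
49.3–50.7% in the same simulations. Ties (decision value exactly 0) go
to the first-listed class.

Three cross-validation schemes mirror the experiment: intra-block
leave-one-trial-out (m = 15 folds for valence-vs-neutral, 10 for
positive-vs-negative), inter-block cross-validation (train on one
condition, test on the other, one fold), and inter-block
leave-one-trial-out (decoding passive vs active within one valence).
Balanced accuracy is the mean of the two per-class percentages, which
compensates the 5-vs-10 imbalance. Classifier weights are aggregated
across folds as mean signed and mean absolute values per feature, with
channel-level views per chromophore.

## Group statistics

Per comparison, participant balanced accuracies are tested against the
50% chance level with a two-sided one-sample t-test and Bonferroni
correction (`min(1, p·k)`); the correction count is caller-supplied with
default 12 (the twelve primary valence comparisons), although the
summary table has 15 rows — which count applies is an analysis choice
left to the caller. Weight maps are compared across
procedures by per-channel paired t-tests corrected for the channel
count; intensity ratings by paired t-tests with a six-way correction;
confounders by a 16 × 15 Spearman grid (average-rank ties, 240-way
correction) and 15 independent-samples gender t-tests (15-way
correction). Degenerate inputs (zero-variance samples, all-tied rank
vectors) are flagged rather than propagated as NaN surprises. All tests
are two-sided.

## What the calibration experiments showed

Development included explicit null and recovery calibrations
(reproduced in the test suite and the acceptance script). Three findings
deserve a record because they are properties of the *analysis design*,
not of any implementation:

1. **The band-pass dominates effective SNR.** A 30-s epoch with ~8-s
   gaps is nearly DC at the 0.01-Hz high-pass edge: roughly 70% of the
   planted plateau amplitude is stripped, and what remains carries a
   trial-layout-dependent ripple proportional to the planted signal
   itself. Decoding accuracy therefore saturates near ~85% no matter
   how large the planted amplitude — consistent with the accuracy range
   real studies of this design report.

2. **Leave-one-trial-out is not chance-calibrated for the
   positive-vs-negative pair.** Epoch means of band-passed noise
   survive only in the 0.01–0.033 Hz band, whose dominant periods are
   about twice the ~38-s trial pitch, so *adjacent* trials' features are
   anti-correlated; the HRF undershoot spilling into the next epoch adds
   to this. The scheduling rule (a neutral trial between negative and
   positive trials) allows same-label trials to be adjacent but never
   opposite-label trials, so the anti-correlation selectively couples
   same-label pairs, and leave-one-trial-out of the positive-vs-negative
   comparison falls to ~41–43% under the null and under workspace-mode
   effects alike. Removing the adjacency rule restores ~50–53% (and a
   strict washout rule overshoots to ~56%), confirming the mechanism.
   The valence-vs-neutral comparisons are calibrated at 50% throughout.
   Because the band edges, the trial timing and the scheduling rule are
   all fixed properties of the modelled experiment, this bias is
   irreducible here; it drags the all-comparison null mean to ~48.3%.
   Analysts using this design should treat below-chance
   positive-vs-negative accuracies as an artifact signature of the
   scheduling-filter interaction, not as evidence about the brain.

3. **Cross-block transfer has a structural ceiling.** Even noise-free,
   identical generative patterns transfer at ~80–85% rather than 100%,
   because the layout ripple and record-wise normalization differ
   between blocks while the classifier direction is fit from 15 trials
   in 64 dimensions.

## What the generator does not emulate

Motion artifacts, scalp-coupling variation, short-channel/systemic
superficial contamination, participant-level amplitude heterogeneity
(only trial-level gain jitter is modelled), the empirically observed
dominance of HbR features over HbO (in the synthetic data HbO carries
at least as much signal), and any actual image/imagery content. Passing
tests therefore demonstrate that the *analysis chain* is correct and
calibrated under its own assumptions — not that those assumptions hold
for any particular real recording.

## Problem sizes used in tests and the acceptance script

Null calibration: 100 simulated participants (both blocks, all three
pairwise comparisons). Workspace-pattern recovery: 40 participants at a
high-SNR setting defined once as 1.5× effect scale, gain-jitter CV 0.05
and physiological noise at a third of the default amplitudes. Schedule
structure: 10,000 seeded schedules. Decoder oracle equivalence: 1,000
random small instances against an explicit-solve reference. Chance-test
type-I calibration: 2,000 simulated group datasets of 49 participants.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping a full run in a few minutes on one
core.
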