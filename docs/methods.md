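# Methods

## Overview

The package models early, unsupervised phonetic acquisition: how a patch of
auditory cortex could turn a continuous speech stream into sparse
distributed representations (SDRs) that are more invariant to noise,
reverberation, pitch and speaker changes than the raw spectro-temporal
input. It has four scientific parts:

1. a synthetic spoken-word corpus generator (the study's stimuli),
2. a multiresolution spectro-temporal front-end (the "subcortical" input),
3. the encoder layer — a grid of cortical columns, each a self-organizing
   map with predictive distal dendrites (the model under study),
4. a word-classification harness (linear SVM, paired statistics) that
   quantifies the invariance of the two representations.

## Front-end

Audio is peak-normalized, then analysed every 8 ms with five Hann windows
(8, 16, 32, 64, 128 ms), each ending at the frame time and zero-padded to
a shared 2048-point FFT grid. Each power spectrum passes through a
128-filter triangular mel bank (0 Hz to Nyquist), and each mel row is
convolved along the filter-index axis with a complex kernel: a Mexican-hat
(Ricker) wavelet of width 10, 8, 6, 4 and 2 filter indices per resolution
(truncated at ±4 standard deviations, samples demeaned so the discrete
kernel has exactly zero DC response), plus *i* times its Hilbert
transform. The modulus is normalized per frame (divided by the frame
maximum across all 5 × 128 values), modelling automatic gain control: the
representation carries spectral shape, not level. Per-row normalization is
available as a config option.

Elements whose pre-normalization magnitude falls below a relative epsilon
(1e-5 of the stream maximum) are flagged *undetermined*; fully
undetermined frames mark silence. Because the input is peak-normalized
first, the whole output — including this mask — is invariant to global
input gain. Convolution uses reflect padding on the tonotopic axis;
the head of the signal is zero-padded so the first frame exists at one
frame period.

## Encoder layer

The reference architecture is a 15 × 15 grid of cortical columns, each a
15 × 15-unit SOM. Each column samples 31 afferent positions from the
5 × 128 front-end array (its wraparound receptive field covers the whole
array, so all 640 positions are eligible); all units in a column share the
same afferent list. Each column links laterally to 72 of the 81 columns in
its wraparound 9 × 9 neighbourhood (90%, floor); each unit carries one
dendrite per linked column with 6 potential synapses onto distinct
randomly chosen units of that column. This yields 50,625 units, 1,569,375
proximal synapses and 21,870,000 distal potential synapses (432 per unit).

**Proximal (static) plasticity.** A standard SOM update: the best-matching
unit and its neighbours (Gaussian kernel over unit-grid Manhattan
distance) move toward the input, independently of which units fired.
Proximal weights initialize uniform in [0, 1], matching the input range.
Undetermined input components are imputed uniformly between per-component
min/max margins learned from determined data (a closed [0, 1] prior before
any data); margins are frozen during inference.

**Distal (dynamic) plasticity.** For every currently active unit, each
synapse onto a target active one step earlier gains Δ⁺ (0.01, doubled when
the column fired massively, so unexpected events imprint more strongly);
synapses onto simultaneously active targets lose Δ⁻ (0.005), floored at
zero. Both rates scale with the training schedule. Every 100 update steps,
any dendrite whose weight sum exceeds one is rescaled to sum exactly one —
the homeostatic bound. Distal weights start at zero: potential synapses
exist only as index slots until sequential activity establishes them; a
synapse counts as *established* once its weight exceeds the synaptic
threshold (0.001), and established connectivity stays sparse (typically
above 90% of potential synapses remain below threshold).

**Activation.** Per column and time step: Euclidean distances to the
proximal weight vectors rank the units; the closest 10% (22 of 225) form
the afferently excited cluster — deterministically, or sampled without
replacement with probability ∝ 1/distance when random behaviour is
enabled. A dendrite is active when its summed weight onto previously
active targets exceeds 100 × the synaptic threshold; each unit's support
is its count of active dendrites. Distances are divided elementwise by
support (zero support → +∞), and units are collected from the smallest
updated distance, whole equality class by equality class, until at least
the minimum active count (1% of units, i.e. 2) is reached. If the
collection is the entire excited cluster — no contextual prediction
distinguishes any unit — every excited unit fires: a massive firing event
(MFE). Otherwise the last class is truncated (stable (distance, index)
order, or randomly in stochastic mode, implementing the output shuffle) so
exactly the minimum count fires. Exact ties among finite updated distances
are measure-zero for continuous inputs; truncation only disambiguates
degenerate cases and keeps the activation count bimodal by construction
(exactly 2 or exactly 22 at reference scale). Per-unit dendrite counts are
recomputed each step; a persistent mode that accumulates them across steps
(an adaptation-like reading of the update) is available behind
``persistent_total_responses`` but is off by default.

**Training schedule.** 4 stages × 4 passes over the corpus, plus a final
4-pass stage with parameters fixed. The proximal learning rate (initial
0.9), the neighbourhood radius (initial: half the unit-grid extent) and
the distal rate scale decay exponentially with a time constant of 4 passes
over *global* pass time, with an extra ×0.5 per stage; the decay is
therefore continuous across stage boundaries and the whole profile is
monotonically decreasing. Context (the previous activation) carries across
passes; the corpus ends in silence, so no spurious transition bridges the
wrap. Inference mode freezes all weights and margins, uses a private RNG
seeded from the model seed, and starts from empty context, so repeated
runs are identical and weight checksums are unchanged.

All randomness flows from one master seed through independent named
SeedSequence streams (initialization, run-time draws, inference).

## Synthetic corpora

The generator emulates the statistical structure of the study's stimuli
without an external TTS. Words are built by additive harmonic synthesis: a
harmonic source at the voice's pitch (with declination and mild vibrato)
whose per-harmonic amplitudes are shaped by three Gaussian formant
resonances gliding from a neutral vocal tract into per-syllable vowel
targets drawn from a canonical inventory. Voices differ in base pitch
(100–250 Hz), vocal-tract scale (0.92–1.1) and speaking rate (0.88–1.12).
A vocabulary holds five words of equal syllable count (1–3 syllables,
~0.25 s per syllable before rate scaling).

Corpus ordering follows strict rotation rules: voices take turns in
pseudo-random rounds (no voice speaks twice before all have spoken), each
voice utters two words per turn, and within a voice no word repeats until
all five have been used. Each utterance is followed by exact digital
silence equal in length to the same voice's rendering of the vocabulary's
reference monosyllable (the first word's first syllable — the analogue of
a fixed reference word, which must exist even for multisyllabic
vocabularies). Degradations: Gaussian white noise scaled to an exact RMS
SNR (19.8 / 13.8 dB in the standard conditions); convolution with an
exponentially decaying white-noise impulse response whose energy decays
60 dB at the requested RT-60 (0.61 / 1.78 s); duration-preserving ±20%
pitch shifts via a phase vocoder; and re-rendering with a second voice
set.

What the generator does *not* emulate: consonantal structure, naturalistic
prosody, coarticulation between words, channel effects, or any real
phoneme inventory. Passing tests therefore show that the encoder acquires
the *sequential and spectral* structure of word-like units and that its
code is more robust than the raw front-end on this controlled family of
stimuli — not performance on natural speech.

## Evaluation

Word boundaries come from silence gaps in the front-end stream: maximal
non-silent frame runs, with runs separated by fewer than 10 silent frames
(80 ms) merged, since the inter-word gaps are word-length. For degraded
corpora the generator's ground-truth boundary track is used instead:
additive noise fills the silence gaps, and using true marks isolates
representation robustness from segmentation robustness. Each word is
summarised by summing activity over its frames — the 640 front-end
magnitudes, or per-unit firing counts (stored sparse) for the encoder.
Features are scaled per component to the training data's [0, 1] range (the
identical unclamped map applied to test data; scaling is refit inside each
CV fold so nothing leaks from held-out folds). Classification uses a
linear-kernel SVM with C swept over 2⁻⁵…2¹⁵ under stratified 5-fold CV;
the best C is refit on all training data for variant scoring. Paired
two-tailed t-tests compare the two sources per condition, with a Holm
step-down at a fixed correction factor m = 7 (the number of standard
conditions, applied regardless of how many tests are supplied);
zero-variance differences are degenerate for the t statistic and are
reported as p = 1 (identical pairs) or flagged degenerate-significant
(constant nonzero difference).

## Scaled-down study condition

The fast robustness comparison runs at reduced size, chosen once: a 3 × 3
grid of 6 × 6-unit columns (sparsity 0.97 and excitation 10%, i.e. 1
active unit sparse / 3 massive), a 100-word monosyllabic corpus from a
5-word vocabulary and 10 voices at 8 kHz, a 2 × 2 + 1-pass schedule, and
13.8 dB white noise. At this size one full run (corpus → front-end →
training → clean and noisy inference → SVMs) takes well under a minute,
and ten seeded replicates give a sign-level comparison: classification
from encoder firing counts versus raw front-end features under noise. The
behavioural demonstrations (sequence learning, sparsity invariant,
homeostasis) use similarly small layers with ratios or thresholds adjusted
only where integer constraints force it (a 25-unit column cannot hold 1%
of 225 units).

## Numerical choices and limitations

- floor() semantics for cluster sizes (10% of 225 → 22; 1% → 2), matching
  the reference counts; configs whose floor would give 0 active units are
  rejected.
- Zero distal support maps the updated distance to +∞, so the no-context
  case degenerates to the massive firing event naturally.
- Stable (distance, unit index) ordering breaks ranking ties
  reproducibly; stochastic excited-cluster sampling uses
  Efraimidis–Spirakis reservoir keys so it is vectorizable and exact.
- Distal weights are float64 so the homeostatic bound holds to 1e-9 after
  rescaling.
- The per-pass MFE rate during training decreases to zero on a learnable
  deterministic cycle, but strict pass-over-pass monotonicity can be
  broken transiently (at the sub-percent level) for some initializations
  while the SOM is still reorganizing: excited-cluster membership shifts
  faster than the distal predictions that reference it. The demonstration
  pins the canonical seed.
- Holm–Bonferroni is implemented in-package because the fixed external
  correction factor (m = 7) is part of the procedure; it matches
  statsmodels when m equals the number of tests.
- Apical dendrites, multi-layer stacks, and growing SOMs are out of scope;
  only lateral context is implemented.
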