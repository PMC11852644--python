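# Methods notes

This note records the models, parameter choices, numerical conventions, and
known limitations behind `slstream`, in the spirit of a simulation package's
model documentation.

## Stimulus model

**Syllabaries and words.** A syllabary is 16 unique CV syllables: a 12-item
pool yields four disjoint high-TP triplets; a 4-item pool yields four low-TP
triplets arranged so each syllable occupies each of the three positions
exactly once across words and each word omits exactly one syllable. With the
pool ordered (a, b, c, d) the low design is the fixed pattern
(a,b,c), (b,a,d), (d,c,a), (c,d,b); applied to (do, ti, ge, mi) it
reproduces the published inventory. The mixed condition takes two words of
each class (variant A: the last two of each unmixed set; variant B: the
first two), mirroring the two published mixed lists. Counterbalancing lists
are the identity, the two cyclic position rotations, and the position
reversal — all four preserve the structural design, and across them every
syllable reaches every position it can occupy.

**Sequencing.** Streams repeat each word 60 times in six blocks of ten under
two adjacency constraints, enforced across block joins: no immediate word
repetition and no identical syllables on adjacent tokens. The generator
shuffles each block's word multiset and repairs violations by swapping a
violating token forward to the first legal position, rejecting and
reshuffling when no repair exists (bounded at 10,000 retries per block, then
an error naming the block). A brute-force validator (independent re-scan of
all adjacency, quota, timing, and chirp constraints) must return zero
violations for every generated stream. Timing is exact: syllable onsets sit
on a 350 ms grid (300 ms syllable + 50 ms interval), so a 720-token stream
lasts exactly 252 s (4.2 min). Intervals are half-open [onset, onset+300).

**Chirps.** 10% of syllable tokens (72 of 720) carry a cover-task chirp,
stratified over the 12 word × position cells (6 per cell; any remainder
assigned to random cells), with no two chirps on adjacent tokens. The 0.1 s
450–1450 Hz sawtooth sweep is realized only in the tone-proxy audio
renderer; downstream modules consume the event annotation, which is the
contract.

**Audio.** Original syllable recordings are not distributed; the renderer
synthesizes each syllable as a fixed-fundamental tone (one pitch per label,
derived from a stable string hash) so streams are audible and
timing-faithful. This is a synthesis stand-in by design, not a perceptual
model.

## Stream statistics

**Two TP quantities.** The bigram transition model `empirical_tp` tallies
*all* adjacent syllable pairs; `empirical_within_tp` restricts the numerator
to pairs inside a single word token while keeping the full denominator
(occurrences of the first syllable that have a successor; the stream-final
token is excluded). The distinction matters: in the low-TP stream, four of
the eight within-word pairs are *echoed* at word boundaries (e.g. do→ti
occurs both inside `dotige` and whenever `migedo` is followed by `tidomi`),
so their full-stream bigram TP is ≈0.5 while the within-word TP is exactly
1/3. The design values quoted for the paradigm (1 and 0.33) are within-word
TPs, and that is the statistic the acceptance checks use. The mixed stream's
two low-class words realize a within-word TP of 0.5 (each low syllable
occurs in only two words there); no design value is asserted for them.

**Theoretical models.** Closed forms assume equal word frequencies and a
uniform choice among legal successor words (legal = different word whose
initial syllable differs from the predecessor's final). Under the published
designs every word has the same number of successors (3 in high/mixed → 1/3;
2 in low → 1/2) and the word chain is doubly stochastic, so the stationary
syllable distribution equals the occupancy frequencies used as π.

**Empirical–theoretical agreement.** Within-word TPs agree with the closed
form to 0.02 on any 720-token stream (the randomness only enters through the
final-token denominator). Boundary successor proportions are ~60 multinomial
draws per word, so their sampling error is ≈0.06; tests and report flags use
max(0.02, 3·SE) for those entries. The sequencer does not force successor
counts toward balance — the streams are pseudo-random, as presented to
participants.

**Entropy.** Three variants are always reported, in bits by default, with
optional normalization by log₂(states) or log₂(16):

- `markov_stationary` (default): −Σᵢ πᵢ Σⱼ P(j|i) log₂ P(j|i);
- `markov_row_mean`: unweighted mean of row entropies;
- `joint_shannon`: conditional Shannon entropy of the bigram distribution,
  H(pair) − H(first). The *unconditional* pair entropy would be nonzero even
  for a deterministic chain and would grow with syllabary size, inverting
  the intended complexity ordering; the conditional form is zero iff every
  row is deterministic, as an uncertainty index must be.

For the three theoretical designs the default variant gives ≈1.459 (low),
0.862 (mixed), 0.528 (high) bits. No variant reproduces previously published
entropy *values* for this paradigm (the originating formula is not fully
specified in the literature we follow); the package's contract is the
ordering low > mixed > high, which holds under every variant and
normalization.

## 2-AFC design

Foils are found by seeded backtracking over position-matched pools with
constraints: three distinct syllables; not equal to any word; no adjacent
pair attested within any word; and — except in the unmixed low-TP condition,
where all four syllables are both word-initial and word-final, making it
impossible — no pair that could be realized across a word boundary. The last
rule is what makes every high/mixed foil pair's *empirical* stream TP
exactly 0 on any seed; low-TP foils tolerate boundary-attested pairs (all
< 1/3).

The 16-trial list is the complete word × foil pairing blocked as a cyclic
Latin design (block b pairs word i with foil i+b mod 4), with a circulant
word-first indicator giving 2 word-first trials per block and 2 per word;
trial order within blocks and block order are then seeded shuffles. Timeouts
score as errors (their scoring is not otherwise specified). The cover-task
exclusion rule — chirp-detection rate must *exceed* 90% — is applied at
scoring time.

## Synthetic cohorts

**Responses.** Each trial is an independent Bernoulli draw at the
(condition, task, word-class) accuracy. Defaults are the study conditions:
implicit/explicit accuracies of 0.613/0.715 (unmixed high-TP), 0.559/0.641
(unmixed low-TP), and word-class-specific 0.658/0.750 (high) and
0.587/0.641 (low) in the mixed condition; group sizes 16/16/23; cover-task
hit rate 0.98. Per-participant accuracies are therefore binomial over 16
trials — the generator reproduces the target means by construction but
*understates* between-participant variance relative to human cohorts (no
trait heterogeneity), so simulated SDs are smaller than published ones. A
consequence worth noting: group differences reach significance more easily
at the default parameters than in a human sample, and null calibration is
checked separately under p = 0.5.

**EEG.** One continuous recording per familiarization stream: 64 scalp
channels (10-10 names) plus two mastoids at 512 Hz, 2 s padding at both
ends. Each word token injects three Gaussian-windowed component kernels at
its onset — defaults N100 (−3 µV, 90 ms, σ 15 ms), P200 (+4 µV, 170 ms,
σ 20 ms), N400 (−5 µV, 400 ms, σ 30 ms) — with amplitude offsets per
condition, exposure half (blocks 1–3 vs 4–6), and word class encoding the
study's qualitative contrasts. Gaussian kernels were chosen over recorded
templates because they give an analytic ground truth for recovery tests.
The forward model is a fixed scalar gain per channel: 1.0 over the
frontocentral ROI (F1, Fz, F2, FC1, FCz, FC2, C1, Cz, C2), 0.3 elsewhere on
the scalp, 0 at the mastoids — no realistic topography is attempted. Noise
is 1/f (exponent 1) plus a 30% white floor, default 10 µV RMS per channel,
flattened below 0.1 Hz to keep the variance finite. Artifacts are ±300 µV,
200 ms square pulses on one random scalp channel at a per-epoch rate,
placed 250–450 ms post-onset so each artifact falls inside exactly one
epoch — this is what makes "rejection removes exactly the injected
artifacts" a testable identity. Identical seeds reproduce recordings
bit-identically.

## ERP chain

Order-4 Butterworth band-pass 0.1–30 Hz applied forward–backward (zero net
phase; the order is a package choice), second-order IIR notch at 50 Hz with
Q = 30, re-referencing to the algebraic mastoid average, then decimation
512 → 256 Hz by sample dropping (the 30 Hz low-pass provides the anti-alias
margin). Epochs span −300 to +1200 ms around word onsets (384 samples at
256 Hz), baseline-corrected to the [−300, 0) ms mean; events too close to
the recording edges are skipped. Epochs with any scalp sample beyond
±100 µV are flagged, and a participant is excluded when more than half are.
Independent-component-based ocular correction is *not* implemented: on
synthetic data, artifact-like activity is entirely captured by the
threshold rule, which is a documented deviation from human-data practice.

Peak measurement averages the ROI channels first, then takes the
single-sample extremum inside the component window (N100 60–120 ms and N400
350–450 ms negative; P200 120–220 ms positive); ties resolve to the
earliest sample, and a flat trace reports amplitude 0 at the window start.
All three components are measured for every grouping rather than selecting
per analysis.

Numerical accuracy of the chain, verified in tests: with noise off the
recovered peak is within 0.1 µV and ~1 sample of the injected kernel (the
residual comes from the 256 Hz grid and the high-pass, both ≪ 0.1 µV for
the default kernels); with 10 µV noise and 16 synthetic participants, an
injected −1.5 µV N400 condition offset is recovered in sign and within
0.5 µV.

## Inference

Chance tests are one-tailed (H1: accuracy > 50%) — the convention that
matches published p values for this paradigm — and can be run from raw
accuracies or from (mean, SD, n) summaries. The mixed ANOVA
(between-stream × within-task) is computed by pingouin, fully-within
designs by statsmodels' repeated-measures ANOVA; both are cross-checked in
tests against longhand sums-of-squares oracles to 1e-10. Greenhouse–Geisser
ε comes from the double-centered covariance of the within-factor levels,
clamped to [1/(k−1), 1], and is 1 by construction for 2-level factors and
single-df effects. ηp² = F·df₁/(F·df₁+df₂). Observed power uses the
retrospective convention λ = F·df₁ against the central critical value at
α = 0.05; it is reported descriptively, as a deterministic transform of F,
not as a prospective power analysis. Bonferroni adjustment is min(1, p·m).
Constant-input designs (all values identical) report F = 0 rather than 0/0.
Reported significance labels: p < 0.05 significant, p < 0.08 marginal.

## Problem sizes and determinism

Default end-to-end runs use the full behavioral cohort (16/16/23 × 2 tasks)
and complete 720-token streams; this finishes in seconds without EEG. The
ERP stage is sized by `n_eeg_per_group` and a montage switch — the full
64+2-channel montage or a reduced ROI+mastoids montage that preserves every
measured quantity (all peak measures are ROI means and the off-ROI channels
carry no additional signal, only the same noise model); simulation suites
use the reduced montage and a handful of recordings per group, with one
full-montage run exercised as a smoke test. Every stage draws from a named
seed recorded in the run manifest, and reruns with an identical
configuration write byte-identical outputs.

## Known limitations

- Tone-proxy audio has no coarticulation, prosody, or speaker variability;
  nothing perceptual should be concluded from it.
- The responder model has no trait heterogeneity, learning dynamics, or
  item effects; passing cohort tests shows the analysis chain is correct,
  not that humans behave this way.
- The EEG forward model is a scalar gain profile; topographic analyses and
  source-level questions are out of scope, as is reading vendor EEG formats.
- Boundary successor proportions in generated streams fluctuate with
  ~0.06 SE around their design values; analyses needing exactly balanced
  transition counts would require a different (Eulerian) sequencer.
- The 2-AFC foil constraint set is provably infeasible in its strictest
  form for the low-TP condition; the relaxation (boundary-attested pairs
  allowed there) is inherent to a 4-syllable design, not a solver failure.
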