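# slstream

Stimulus construction, synthetic cohorts, and analysis for auditory
**statistical learning** experiments in the triplet-embedded (Saffran-style)
paradigm — built for studies that manipulate the **transitional-probability
(TP) structure and entropy** of continuous speech streams and measure
learning behaviorally (two-alternative forced choice) and neurally
(word-onset-locked ERPs: N100, P200, N400).

## Who this is for

Researchers designing or re-analyzing segmentation experiments in which
three-syllable nonsense words are concatenated into a pause-free stream and
the only segmentation cue is the statistics of syllable transitions. The
package generates the materials, quantifies their statistical structure,
simulates complete synthetic cohorts (responses + 64-channel EEG) with known
ground truth, and runs the full inferential chain — so every stage of an
analysis can be validated end-to-end before any human data exist.

## The design in brief

A 16-syllable syllabary is split into a pool of 12 building four **high-TP
words** (each syllable occurs in exactly one word at one position, so every
within-word transition has P(next | current) = 1) and a pool of 4 building
four **low-TP words** (each syllable occurs in three words, once per
position, so within-word TPs are 1/3). Streams present the four words of a
condition (unmixed high-TP, unmixed low-TP, or mixed: two of each) 60 times
in six blocks of 10, at 300 ms per syllable plus a 50 ms interval, with no
word or syllable repeated back-to-back and a chirp-detection cover task on
10% of syllables. Under these constraints a word boundary admits 3 equally
likely successors in the high-TP and mixed streams (boundary TP 1/3) and 2
in the low-TP stream (boundary TP 1/2). Stream-level uncertainty is
summarized as Markov-chain entropy
H = −Σᵢ πᵢ Σⱼ P(j|i) log₂ P(j|i), which orders the conditions
low-TP > mixed > high-TP.

The 2-AFC test pairs each word with each of four **foils** — triplets using
the same syllables at the same positions and frequencies but in orders whose
within-word attestation is zero. Inference uses one-tailed one-sample t
tests against the 50% chance level, mixed repeated-measures ANOVA with
Greenhouse–Geisser correction, Bonferroni post hocs, partial eta squared
(ηp² = F·df₁/(F·df₁+df₂)), and retrospective observed power.

## Worked example

```python
from slstream import (
    SYLLABARY_A, build_words, StreamSpec, generate_sequence, place_chirps,
    theoretical_tp, theoretical_within_tp, entropy, make_foils,
    one_sample_t, effect_size_and_power,
)

words = build_words(SYLLABARY_A, "unmixed_low")
seq = place_chirps(generate_sequence(words, StreamSpec(condition="unmixed_low", seed=1)))
model = theoretical_tp(words, "unmixed_low")
foils = make_foils(words, SYLLABARY_A, "unmixed_low", seed=1)
res = one_sample_t(mean=55.9, sd=8.7, n=16)
eta, pw = effect_size_and_power(12.54, 1, 52)
```

prints (via the obvious `print` calls):

```
words: ['dotige', 'tidomi', 'migedo', 'gemiti']
tokens: 240 words / 720 syllables; duration 4.2 min
within-word TP (do->ti): 0.333
boundary successors of dotige: {'tidomi': 0.5, 'migedo': 0.5}
entropy (bits): 1.459
foils: ['dogeti', 'timido', 'midoge', 'getimi']
chance test: t(15) = 2.71, one-tailed p = 0.008
F(1, 52) = 12.54 -> eta_p^2 = 0.194, observed power = 0.935
```

The stream carries 240 word tokens (4.2 min of audio at 350 ms per
syllable); each low-TP within-word transition is 1/3 because a syllable's
word continuation accounts for one of its three positional roles; `dotige`
cannot be followed by itself or by `gemiti` (its final syllable would repeat),
leaving two successors at 0.5 each; the chance test and effect-size lines
reproduce group-level inference from summary statistics alone.

## Command line

`slstream` exposes the stages individually:

```bash
slstream generate-stream --condition mixed --seed 3 --out out/   # events TSV (+ WAV)
slstream stream-report --condition unmixed_low --seed 1          # TPs, entropy, chirps
slstream make-afc --condition mixed --seed 2 --out afc.csv       # foils + 16 trials
slstream simulate-cohort --out out/                              # responses + inference
slstream run-erp --n-per-group 2 --montage reduced --out out/    # adds synthetic EEG
slstream verify                                                  # design-claims check
slstream reproduce-tables --out out/                             # full default run
```

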