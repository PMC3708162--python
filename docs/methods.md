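# Methods

`phonconv` analyses phonetic convergence on steady vowels: how far a
speaker's F0 (vocal pitch) and F1 (vowel height cue) shift toward the values
of an acoustic model speaker, both while the model is heard (convergence)
and afterwards (after-effect).  Because no public recordings exist for this
paradigm, the package pairs the analysis chain with a behavioral simulator
whose ground-truth parameters the chain must recover; every claim the test
suite makes about the analysis is a parameter-recovery claim about that
generative model.

## The experimental design being modeled

Three experiments (tasks) of 24 subjects each — *production* (speak the
vowel named by an orthographic or acoustic cue, no imitation instruction),
*imitation* (explicitly imitate the acoustic cue), *categorization* (speak
on orthographic cues; answer acoustic cues by key press).  Each experiment
runs three blocks, one model speaker per block, each block being
orthographic (3 vowels x 5 trials), acoustic (3 x 10), orthographic (3 x 5)
sub-blocks.  The closing orthographic sub-block of a block doubles as the
opening baseline of the next one, so a subject stores 4 orthographic
sub-blocks and 3 acoustic ones: 150 spoken utterances per
production/imitation subject, 60 spoken plus 90 key presses per
categorization subject, 8,640 spoken utterances for the full design.
Counterbalancing: per experiment the four gender x speaker-set cells hold
six subjects, and each cell's six subjects see all six speaker-block
permutations.  Subjects heard model speakers of their own gender are labeled
*congruent* ("same"); 12 personas are shared between the production and
imitation experiments (same baselines, independently drawn gains).

## Behavioral model

All behavior lives in bark space.  Each subject carries per-vowel baselines
(F0, F1 in Hz), two gain pairs, a trial-noise SD pair, and an omission rate.
The operative baseline is a running state `s` per vowel, initialized at the
subject's baseline:

* acoustic-cue trial:  produced = `s + g_converge * (T - s) + noise`
* orthographic trial:  produced = `s + noise`
* after each exposure block with target T:  `s <- s + g_after * (T - s)`

Because the shared boundary sub-block is produced at the updated state, the
per-subject regression slopes of *both* contrasts equal their generative
gains exactly when noise is zero — the algebraic fixed point the recovery
tests assert at 1e-6.  A model that applied gains to a static baseline
could not satisfy both contrasts simultaneously once sub-blocks are shared.

Defaults are taken from the study populations this design describes: task
gain means (F0, F1) of (0.08, 0.04) / (0.48, 0.13) for convergence and
(0.07, 0.06) / (0.23, 0.04) / (0.07, 0.04) for after-effects; between-
subject gain SDs sized so that group t statistics land in the observed
range; omission rates 2.8 / 1.2 / 1.2 %; baselines drawn around the
population median F0/F1 per task, gender and vowel (15 Hz global F0 scatter,
40 Hz F1 scatter plus 10 Hz per-vowel jitter, F1 clamped to >= 1.25 F0 so
productions stay synthesizable).  Trial noise defaults to (0.004, 0.012)
bark on the printed scale — about 3 Hz of F0 scatter at 220 Hz and 20 Hz of
F1 scatter at 400 Hz, typical within-speaker token-to-token variability for
steady vowels.  What the generator deliberately does not model: reaction
times, intonation contours, voice quality, F2/F3 convergence, social or
gender moderation of gains, and mispronunciations (errors are omissions
only).  Passing recovery tests therefore show the chain is correct for this
linear-gain model, not that real speech obeys it.

## Vowel synthesis

Source-filter: a band-limited sawtooth (harmonics to 0.9 x Nyquist, 1/k
amplitudes) drives a cascade of second-order all-pole resonators — F1 from
the target bank, vowel-typical fixed F2/F3 ((2300, 3000) Hz for /i/,
(2100, 2800) for /e/, (1900, 2600) for /ɛ/), bandwidths 60/90/120 Hz.  A
20 ms onset and 10 ms offset raised-cosine ramp emulates natural vowel
attacks; without it the resonators' ring-up transient can carry the
intensity peak and drag the measurement window onto the vowel edge.  Levels
follow a digital convention (full-scale sine = 96 dB), so the 75 dB default
sits 21 dB below full scale.  Synthesis is a pure function of its
arguments, making corpora byte-reproducible from the seed.

## Measurement chain

Segmentation: 10 ms RMS frames at a 5 ms hop; frames above -25 dB relative
to the loudest frame are active; active runs separated by pauses under
150 ms are merged and runs shorter than 80 ms dropped.  The intensity peak
is the maximal frame (ties to the earliest frame, for determinism); F0 and
F1 are measured over +/- 25 ms around it, clipped to the segment when the
peak sits near an edge.

F0: autocorrelation over the window, peak search in 75-400 Hz, parabolic
lag interpolation, voicing threshold 0.45 on the normalized autocorrelation.
Accuracy on the synthesized target grid is ~1 Hz.

F1: a two-stage estimator.  Stage one is classical LPC — decimation to
10 kHz, pre-emphasis 0.97, Hann window, Burg order 12, polynomial roots,
candidates with bandwidth under 400 Hz, lowest candidate inside
150-1,100 Hz.  Stage one alone is biased toward the strongest harmonic at
high pitch (errors up to ~F0/2 near F0 = 300 Hz, where harmonic spacing far
exceeds any useful tolerance): an all-pole fit weights the spectrum where
the energy is, and a high-pitched voice samples its own envelope too
sparsely.  Stage two therefore refines the candidate in the style of
discrete all-pole modeling: per-harmonic amplitudes are read from a
zero-padded Hann spectrum at multiples of the measured F0, a +6 dB/octave
correction removes the sawtooth source slope, and a model

    log A(f) = c0 + c1 f + logmag(F1, B1) + 2 logmag(Fh, 150 Hz)

(one free resonance plus a fitted higher-pole skirt) is fitted by least
squares over harmonics below min(1.8 kHz, max(3 F1, F1 + 4 F0)).  The band
cap keeps the F2 region out of the skirt approximation.  With refinement
the worst-case error over the 18-vowel target grid drops from ~104 Hz to
under 5 Hz.  If the window is unvoiced the stage-one estimate is returned
unrefined.  Omissions, unsegmentable or unvoiced windows, and formant
failures are flagged per trial; subjects with more than 10% failed trials
are flagged for exclusion.

## Bark scaling

Two variants of the critical-band transform are implemented.  `as_printed`
is `arctan(0.00076 f) + 3.5 arctan((f/7500)^2)`, the expression as printed
in the source analysis; it lacks the conventional factor 13 on the first
term, compressing the speech range ~13-fold relative to the Zwicker &
Fastl scale, which `zwicker_standard` restores.  Both are strictly
monotone with bark(0) = 0, so either is a valid analysis space, and the
generative gain is defined in whichever space is used uniformly — the
variant-consistency tests assert exact recovery under both.  `as_printed`
is the package default for fidelity; stochastic-recovery and calibration
studies run in `zwicker_standard`, where "0.05 bark" of trial noise is a
physically plausible scatter (~3 Hz at 200 Hz) rather than ~5 x the
between-speaker F0 target spread.

## Slope metrics

Per subject, block, sub-block and vowel, valid trials are reduced to a
median in bark (minimum 2 valid trials per cell, else undefined; ortho
cells hold 5 trials, acoustic cells 10).  The shared boundary sub-block is
expanded into both of its analysis roles.  Correlation points per block and
vowel: `x = bark(target) - baseline median`, `y = (acoustic | post) median
- baseline median`, giving up to 9 points per subject, measure, and
contrast; a point is dropped (pairwise, that block x vowel only) when any
constituent median is undefined or flagged.  The per-subject statistic is
the OLS slope (with intercept) through those points.

Outlier passes are single-shot +/- 2 sample-SD rules: first on medians
within (experiment, measure, vowel, block, role) cells across participants
— pooling across vowels instead would systematically flag /ɛ/ F1, so the
cell-wise pooling preserves vowel structure — then on slopes within
(experiment, measure, contrast) groups.  Zero-SD groups flag nothing;
groups under three members cannot support an SD criterion and raise.  The
x-values use the target bank's Hz directly (the bank is the design's own
characterization of its stimuli), not re-measured stimulus audio.

## Group statistics

Between-subjects factorial ANOVA of retained slopes on task and congruency
(statsmodels OLS; Type-II sums of squares by default, appropriate for the
mild unbalance outlier pruning introduces; Type-III with sum-to-zero coding
available), one-sample t-tests of each task's mean slope against zero
(one-tailed "greater", since convergence predicts positive slopes), and
Pearson correlations between paired slope sets — F0 x F1 per task and
contrast, convergence x after-effect, and the production x imitation
overlap subgroup paired by persona.  Correlation pairs are re-pruned per
analysis by the same +/- 2 SD rule on each member.

## Known limitation: under-null slope bias

The baseline median enters both coordinates of every correlation point, so
its noise is shared between x and y and contributes +Var(median noise) to
their covariance.  Under a zero-gain null the slope estimator is therefore
biased upward by roughly `Var(eps_b) / (Var(x) + Var(eps_b))` — and Var(x)
is intrinsically small on this design: targets within a block share F0, and
subjects' per-vowel F1 baselines co-vary with the per-vowel targets, so x
reduces to the speaker-subject mismatch.  At the generator's default trial
noise the measured bias is about +0.014 (F0) and +0.021 (F1), which leaves
the two-factor ANOVA and the correlations calibrated (the bias is common
to all groups and to both correlated variables) but makes the one-tailed
t-tests against zero anticonservative: in the null-calibration study
(1,000 replicates, 8 subjects per cell, zero-mean gains with 0.1
between-subject SD) they reject at ~18% instead of 5%, and the suite
leaves those two checks failing by design rather than hiding the effect
with unrealistically small noise.  The bias shrinks with the trial noise
and vanishes as noise goes to zero; it also implies that small positive
group-mean slopes obtained with this statistic on real data should be
interpreted with this offset in mind.

## Pipeline and reproducibility

Stages (`synth`, `measure`, `slopes`, `stats`, or `run-all`) persist plain
CSV/JSON intermediates, validate input schemas on load, and append SHA-256
checksums to a per-run manifest; a config snapshot is written into every
run, so any artifact is regenerable from config + seed.  Every random
stream descends from the master seed via per-subject `SeedSequence`
children, making corpora insensitive to iteration order and byte-identical
across runs.  Measurement offers two modes: `audio` renders WAV files and
re-estimates F0/F1 through the full acoustic chain (used to validate the
chain; resumable, skipping already-measured trials), while `oracle` takes
the generator's produced Hz values directly — the reference path for
parameter-recovery studies, where estimation error would confound the
recovery of behavioral gains.  Default problem sizes keep the test suite
and the acceptance script at desk scale: recovery studies use 24 subjects
with 50 replicates, the calibration study uses a vectorized replica of the
slope computation for its 1,000 replicates, and audio-chain tests render
corpora of a few hundred utterances.
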