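# phonconv

Phonetic convergence analysis for steady vowels, with a synthetic
experiment generator that makes every stage verifiable by parameter
recovery.

When people hear another speaker's vowels, their own productions drift
toward them — unintentionally during plain production, strongly during
deliberate imitation — and the drift partially persists after the voice is
gone (an after-effect).  `phonconv` implements the standard acoustic
analysis of this phenomenon for researchers in speech production and
auditory-motor psychophysics: from raw vowel audio, through F0/F1
measurement, to per-subject convergence slopes and group inference.
Because the paradigm's human recordings are not publicly available, the
package ships a behavioral simulator with known ground-truth gains; the
test suite demonstrates that the analysis chain recovers them.

## The statistic

For each subject, block *b*, and vowel *v*, productions are summarized by
median F0 and F1 in bark (transform: `arctan(0.00076 f) +
3.5 arctan((f/7500)²)`, with the conventional Zwicker variant — factor 13
on the first term — available by config).  Each of the 9 block × vowel
cells yields one point

```
x(b, v) = bark(target) − median(baseline orthographic sub-block)
y(b, v) = median(acoustic sub-block) − median(baseline orthographic sub-block)
```

(for the after-effect contrast, the post-exposure orthographic sub-block
replaces the acoustic one in *y*).  The per-subject **slope coefficient**
is the OLS slope of *y* on *x*: 0 means no convergence, 1 means full
adoption of the target.  Medians and slopes beyond ±2 SD of their cohort
are pruned once; retained slopes enter a task × congruency ANOVA,
one-tailed t-tests against zero, and Pearson correlations between slope
sets.

Under the package's generative model — productions are
`baseline + gain · (target − baseline) + noise` in bark, with the operative
baseline updated after every exposure block — these slopes equal the
generative gains exactly in the noise-free limit, for both contrasts, and
the suite asserts this to 1e-6.

## Worked example

Run the full default study (3 tasks × 24 simulated subjects) end to end:

```
phonconv --seed 42 --outdir runs/demo run-all
```

or equivalently from Python:

```python
from phonconv import RunConfig
from phonconv.pipeline import run_all
run_all(RunConfig(seed=42, outdir="runs/demo"))
```

The run writes `trials.csv`, `ground_truth.csv`, `measurements.csv`,
`medians.csv`, `points.csv`, `slopes.csv`, `results.json`, and a
human-readable `results.txt` that begins:

```
ANOVA  convergence/f0  (n=46)
  task               F(1, 42) = 64.87, p = 4.702e-10
  congruency         F(1, 42) = 2.07, p = 0.1579
  task_x_congruency  F(1, 42) = 0.56, p = 0.4578
```

Read: after pruning, 46 subjects remain in the 2 × 2 (hence 42 denominator
degrees of freedom); the imitation task produces far stronger F0
convergence than the production task (mean retained slopes 0.535 vs 0.095
in this run, against generative gains of 0.48 and 0.08), while the
speaker/subject gender congruency does nothing — the qualitative pattern
this design was built to detect.  Single-seed runs of 24 subjects are
noisy: individual p-values (especially interactions) vary between seeds.

Stages can also be run separately (`synth`, `measure`, `slopes`, `stats`),
each reading the previous stage's files.  By default measurements are taken
from the generator's produced Hz values (`measurement_mode: oracle`); set
`measurement_mode: audio` with `render_audio: true` to write WAV files and
re-estimate F0/F1 through the full acoustic chain (autocorrelation pitch
tracking; LPC plus harmonic-amplitude refinement for F1, accurate to a few
Hz even for high-pitched voices where plain LPC errs by half a harmonic
spacing).

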