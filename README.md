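# multicue

Simulation and analysis of **multi-item targeted memory reactivation (TMR)**
sleep studies.

During non-REM sleep, replaying a sound that was paired with learned material
biases which memories the sleeping brain consolidates. When one sound is
linked to *several* items (one, two, or six images whose screen locations were
learned before a nap), competing hypotheses predict different per-item
benefits of cueing:

* **Parallel reactivation (PRH)** — every cued item gains the full benefit Δ,
  independent of set size k.
* **Limited capacity (LCH), divided** — each cued item gains Δ/k.
* **LCH, random subset** — each cue repetition reactivates one item sampled
  uniformly from the set; the probability that an item benefits at least once
  in n repetitions is 1 − ((k−1)/k)ⁿ.
* **LCH, biased subset** — one fixed item per set captures the benefit.

`multicue` implements the full analysis chain of such a study as a tested,
seedable pipeline driven by synthetic data, so every stage can be validated
without access to human recordings:

* **design** — constrained spatial layouts on a circular grid (six candidate
  locations per set, real items plus *phantom* locations, within-set
  separation ≥ 400 px), learning-block schedules, performance-balanced cuing
  assignment, and randomized-blocks sleep cue sequences;
* **behavior** — generative placement models under each hypothesis, with
  uniform guessing and set-size-dependent within-set misbinding;
* **scoring** — swap-error classification against all six candidate
  locations (so guesses are scored identically at every set size), accuracy
  errors, lenient correctness, and the sleep benefit (pre − post error);
* **stats** — within-subject ANOVAs with partial η², Tukey HSD, the BIC
  approximation to the Bayes factor (BF₀₁ = exp(ΔBIC/2)), pre-sleep
  regression adjustment, a subsampling robustness procedure, one-way
  random-effects ICC with a permutation test, the within-set max-|Z| outlier
  statistic, and repetition–benefit correlations;
* **eegsim / eeg** — synthetic single-channel NREM EEG (1/f^1.5 noise bed,
  slow oscillation, cue-locked delta-theta bursts and probabilistic sleep
  spindles whose rate grows linearly with set size), and its analysis:
  zero-phase FIR filtering, cue-locked STFT spectrograms (0.25–25 Hz in
  0.25 Hz steps, 500 ms windows, 87.5 % overlap) with percent-change baseline
  correction, Bonferroni t-map clusters, an RMS-threshold spindle detector
  (11–16 Hz, 200 ms moving RMS, 1.5 SD, 0.5–3 s), spindle probability
  timecourses, and linear mixed models of the set-size modulation
  (`Modulation ~ 1 + SetSize + (1 + SetSize | Subject) + (1 | Sound)`).

## Worked example

```python
from multicue.behavior import reactivation_probability
from multicue.pipeline import RunConfig, run_experiment

# the random-subset model's at-least-once probability for a six-item set
for n in (1, 2, 3):
    print(n, round(reactivation_probability(6, n), 2))
# 1 0.17
# 2 0.31
# 3 0.42

cfg = RunConfig(master_seed=2, n_participants=6, eeg_n_passes=2, n_perm=500)
report = run_experiment(cfg)
ben = report["behavior"]["benefit_anova"]
print(round(report["behavior"]["mean_benefit_cued"], 2),
      round(report["behavior"]["mean_benefit_noncued"], 2))
# 8.38 -4.77
print(round(ben["cued"]["p"], 6), round(ben["cued:size_k"]["p"], 2))
# 4e-06 0.81
print(round(report["eeg"]["spindle_probability"]["coef"], 3))
# 0.022
```

The simulated cohort (parallel-reactivation generator, Δ = 8 px) shows the
signature pattern: cued items improve by several pixels while non-cued items
drift, the cuing main effect is highly significant while the cuing × set-size
interaction is not, and the detected spindle probability rises by ≈ 0.02 per
item associated with the cue (generator ground truth 0.05 per injected
spindle, attenuated by detection and the cluster time window at this small
cohort size). Numbers are exactly reproducible for a fixed config.

The same pipeline is available from the shell:

```bash
multicue run-all --seed 2 --out results/demo
multicue compare --models PRH,LCH_divided --cohorts 10 --out results/power.csv
```

## Layout

```
src/multicue/
  design.py     experimental design generation
  behavior.py   generative placement models (the four hypotheses + null)
  scoring.py    swap/accuracy/lenient scoring and the sleep benefit
  stats.py      behavioral statistics
  eegsim.py     synthetic NREM EEG with cue-locked ground truth
  eeg.py        spectral and spindle analysis, mixed models
  pipeline.py   cohort simulation, full-run orchestration, model comparison
  io.py         CSV/JSON/npy round-trips
  cli.py        command-line interface (`multicue ...`)
docs/methods.md   model and algorithm documentation
```
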