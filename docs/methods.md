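# Methods

This note documents the models, algorithms, and numerical choices behind
`multicue`, and what its synthetic-data generators do and do not emulate.

## Experimental design generation

**Grid geometry.** Items live on a circular grid of radius 540 px
(34.6/125 mm per px, so the 100-px training criterion equals 27.7 mm).
Coordinates are continuous, origin at the grid center, x rightward,
y downward. Every set — regardless of its real size k ∈ {1, 2, 6} —
receives **six candidate locations**: k true item locations plus 6 − k
unused *phantom* locations. Constraints: each candidate at least 50 px from
the center and 50 px inside the border; candidates of one set mutually at
least 400 px apart; and each candidate at least 41 px from every true item
location of other sets. Phantoms of different sets are mutually
unconstrained: they are never displayed and exist only so that swap scoring
treats every set size identically.

**Why the 41-px rule binds only true items.** Six points mutually ≥ 400 px
apart inside a disc of usable radius 490 px must form near-hexagonal
configurations with most vertices in the outer ring (roughly radius
340–490 px). That ring can hold ≈ 160 points at 41-px mutual separation
under random sequential placement, but 45 sets × ~5.5 ring vertices ≈ 250
points would be needed if phantoms also repelled each other — beyond the
jamming density of any random sampler. With the rule restricted to the ~90
true items the problem is comfortably feasible.

**Sampler.** Rejection sampling with an informed proposal: a lattice of
equal-area 6-px cells covers the admissible annulus; a proposal picks a
uniformly random currently-feasible cell and jitters within it, so the
proposal is uniform over the feasible region up to discretization; every
accepted point is then verified against the *exact* constraints, so
discretization affects efficiency, never validity. Stuck sets restart; a
full-layout restart cap signals an over-constrained grid
(`LayoutInfeasibleError`).

**Set composition and schedule.** 24 multi-item sets are partitioned at
random into 18 two-item and 6 six-item sets per participant (so set content
is not confounded with size); 21 single-item sets include 3 practice
fillers excluded from scoring. The 90 scored items fill six learning blocks
of 15 such that no two same-set items share a block, two-item sets occupy
consecutive blocks, and six-item sets span all six blocks (randomized
constructive assignment with redraw). Cuing is balanced within each size
class by exhaustive search over all half-splits, minimizing the absolute
difference in incorrectly placed items, then in swap counts, then in summed
pixel error, ties broken uniformly at random. The sleep cue sequence is
randomized blocks: each pass presents the 21 cued sounds plus one novel
sound exactly once in fresh random order, with inter-cue intervals drawn
from {4.5, 5, 5.5} s and onsets accumulating cue duration (0.6 s) + ITI, so
repetition counts never differ by more than one at any truncation point.

## Behavioral generator

**Pre-sleep placements** mix three processes per item:

* with probability `p_guess` (default 0.1) a uniform random guess on the
  grid disc — the process that produces swap-classified errors equally at
  every set size;
* otherwise, with probability `p_confuse · (k − 1)` (default
  `p_confuse` = 0.07), a within-set misbinding: the placement centers on
  another same-set item's location — the only process that can produce the
  genuinely size-dependent swap rates seen in this paradigm (≈ 0.39
  six-item, ≈ 0.15 two-item, ≈ 0.08 one-item pre-sleep in simulation);
* otherwise isotropic Gaussian noise of scale `sigma_pre_px` (45 px) around
  the true location. All placements are clipped to the disc.

**Post-sleep placements** carry each item's *realized* pre-sleep radial
error across sleep. The reactivation model adds a signed change: non-cued
items drift by `forget_px` (+5 px error); cued items improve by Δ
(`delta_px` = 8 px) under PRH, by Δ/k under the divided model, by Δ for
items sampled at least once (uniform one-item-per-repetition draws) under
the random-subset model, and by Δ for one fixed item per set under the
biased-subset model. Two further noise terms are added: item-level
consolidation noise (`sigma_sleep_px` = 8 px) and a per-set shared
consolidation effect (`sigma_set_px` = 8 px; sets differ in how well their
theme consolidates, which is what gives within-set benefits more agreement
than across sets and makes ICC analyses meaningful). The result is floored
at zero and re-expressed in a fresh uniform direction, with the direction
resampled until the placement falls inside the grid — radial clipping would
otherwise bias benefits upward for rim items. Because the radial error
distribution is preserved up to the model change, swap rates stay
comparable across the two tests, as in the paradigm being emulated.

The noise scales were fixed once from two structural requirements the
generator must satisfy simultaneously — enough item-level noise for null
p-values to be continuous and calibrated, and little enough that the
divided-benefit interaction (a 6.7-px spread across set sizes) is
detectable in most 31-participant cohorts — and from the need for nonzero
between-set variance. They are configuration, not estimates of any real
quantity.

**What the behavioral generator does not emulate:** trial-by-trial learning
dynamics, N2-vs-N3 cue timing, set-size-dependent forgetting, serial
position or fatigue effects, and any dependence of misbinding on semantic
similarity. Passing tests therefore show that the *analysis chain* behaves
correctly and discriminates the hypotheses when their signatures are
present at plausible effect sizes — not that real data would show them.

**Training exposure.** Trials-to-criterion per item are 2 + Poisson(1.63)
(mean 3.63, matching the reported mean); each positioning trial plays the
set's sound three times plus two exposure-phase plays per item. Summed per
set, this yields the sound-familiarity covariate, which grows with set
size by construction.

## Scoring

A placement is a **swap error** iff it lies strictly closer to another of
its set's six candidate locations than to the item's own location; exact
ties (measure zero for continuous placements) are not swaps. Swapped
placements carry no accuracy error. **Lenient correctness** is accuracy
error strictly below 100 px. The **benefit** of an item is pre-sleep minus
post-sleep error (positive = improvement), computed only for items
unswapped in *both* tests so the pre/post comparison covers identical item
sets. Summaries aggregate per participant × set size × cuing status, plus
per-set cumulative benefits.

## Behavioral statistics

* **Within-subject ANOVA** by sums-of-squares partitioning; each effect is
  tested against its own subject-interaction error term; no sphericity
  correction (the paradigm's reported integer error dfs imply uncorrected
  tests); partial η² = SS_effect / (SS_effect + SS_error). Verified against
  both a literal loop-based oracle and `pingouin.rm_anova`.
* **Tukey HSD** on the studentized range with the ANOVA error term.
* **Bayes factor** via the BIC approximation, BF₀₁ = exp((BIC_alt −
  BIC_null)/2) with equal prior odds; the interaction BF compares the two
  nested fixed-effects models of the condition cell means (subject
  intercepts, main effects vs. + interaction).
* **Regression adjustment**: forgetting is regressed on pre-sleep error per
  participant; the adjusted score is the residual plus mean forgetting.
* **Subsampling robustness**: repeatedly keep 50 % of items per participant
  per set size, screen out datasets whose pre-sleep set-size effect has
  p < 0.5, and run the benefit ANOVA on each kept dataset; reports the
  share of significant cuing effects, mean/median p, and bias-corrected
  sample skewness of both p distributions. Subsampled datasets of one
  cohort are *dependent*, so the across-dataset significance rate has
  cohort-level variance well above binomial.
* **ICC**: one-way random-effects, single-measure — ICC(1,1) — with the
  unbalanced-ANOVA adjusted group size k₀; the cued/non-cued difference is
  tested by shuffling the item-to-set assignment separately within each
  condition (group sizes preserved), p = (1 + #{|null| ≥ |observed|}) /
  (1 + n_perm), so p can never be exactly zero. The permutation count
  defaults to 10⁴ in pipeline runs and accepts 10⁶ for full-scale runs.
* **Max-|Z| outlier statistic**: within each complete six-item set, z-score
  the six benefits (ddof = 1) and take the maximum absolute value; a
  zero-spread set scores 0 with a warning; cued and non-cued sets are
  compared by unpaired t-test with Cohen's d.
* **Correlations**: Pearson r between per-participant mean cued benefit and
  mean repetitions per size class, plus the variant correlating against the
  at-least-once reactivation probability.
* **Familiarity covariate**: OLS of set-level benefit on
  cuing × size + familiarity, type-II tests.

## Synthetic EEG

The noise bed is Gaussian 1/f^1.5 noise (RMS 15 µV) plus narrowband slow
activity (0.8 ± 0.35 Hz, RMS matched to a 40-µV sinusoid). Narrowband noise
rather than a pure tone keeps short-window low-frequency power stationary,
which percent-change baselines require. Every cue evokes a delta-theta
burst (2–6 Hz, 0.4–0.8 s, 0.3–0.9 s latency) whose peak amplitude is
`20 + 2·k` µV; with probability `0.15 + 0.05·k` it also evokes one spindle
(uniform 11–16 Hz, 0.5–3 s, 0.9–1.4 s latency, 25 µV peak). Bursts use a
tapered-cosine envelope (ramp fraction 0.5): waxing-waning morphology with
a sustained core, so a burst's nominal duration matches the extent a
threshold detector can see. The injected linear laws are the ground truth
the analysis must recover. Not emulated: K-complex morphology, sleep-stage
transitions, arousals, artifacts, multi-channel structure.

## EEG analysis

* **Filtering**: symmetric (linear-phase) Hamming-windowed FIR kernels
  applied by centered FFT convolution (zero phase). Transition bands sit
  *outside* the requested passband, so in-band sinusoids — edges included —
  retain ≥ 95 % amplitude while attenuation one octave out exceeds 20 dB.
* **Spectrograms**: epochs of −0.5 to +4 s around cue onset (the pre-cue
  half-second is required by the baseline window), mean-subtracted, Hann
  STFT with 500-ms windows, 87.5 % overlap (62.5-ms hop), zero-padded to a
  0.25-Hz grid over 0.25–25 Hz.
* **Baseline**: percent change per frequency relative to the 300-ms window
  from −0.5 to −0.2 s (window centers). For per-trial modulations the
  pipeline uses the common-baseline convention (baseline spectrum averaged
  over a participant's trials): a single-window baseline is a chi-squared-
  noisy denominator and destroys single-trial percent-change estimates.
* **Clusters**: one-sample t vs 0 across participants at every
  time-frequency point, Bonferroni-thresholded at α/n_points (α = 0.001),
  8-connected components of common sign (4-connectivity is configurable).
  When a small cohort yields no usable cluster (fewer than 10 bins), the
  pipeline falls back to canonical windows: delta-theta 0.25–11 Hz ×
  0.31–0.87 s, sigma 11.5–17.25 Hz × 0.94–1.44 s.
* **Spindle detector**: band-pass 11–16 Hz, centered 200-ms moving RMS with
  shrinking edge windows, threshold = 1.5 × SD of the band-passed signal
  over artifact-free samples (`threshold_mode='rms_sd'` instead uses
  mean(RMS) + 1.5 × SD(RMS)); maximal suprathreshold runs of 0.5–3 s that
  avoid the exclusion mask become events; an event's peak amplitude is the
  larger of its highest peak and |lowest trough| in the filtered trace.
* **Spindle probability**: fraction of trials with an ongoing detected
  spindle at each time point relative to onset, baseline-subtracted,
  grouped by set size (novel sound = 0).
* **Mixed models**: `statsmodels` MixedLM with numeric set-size coding
  (0/1/2/6). The by-sound crossed random effect is approximated as a
  variance component nested within participant (statsmodels supports one
  grouping factor); the random-effects structure simplifies on fitting
  failure — drop the sound component, then the random slope, then fall back
  to OLS (a single participant always reduces to OLS). Confidence intervals
  are Wald; p-values use a t reference with n − p degrees of freedom.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; per-stage generators derive
from one master seed through independent spawn keys, so identical configs
give byte-identical outputs and any stage can be rerun alone. Cohort-level
simulation studies share one candidate-location layout per run — layout
geometry never enters the statistics — which keeps a 31-participant cohort
under a second. The test suite exercises the pipeline at reduced sizes
chosen as its own defaults: 31-participant behavioral cohorts (40 per model
for discrimination rates, 30 for the biased-subset check), 5-participant ×
2-pass EEG cohorts (12 replicates), 10³–10⁴ permutations in fast mode, and
300–500-s synthetic recordings for detector operating points; full-scale
settings (10⁶ permutations, 500 subsample datasets) are plain configuration
switches.

## Known limitations

* The generator's benefit model is radial and deterministic given the
  latent change; it reproduces the paradigm's measurement scale, not the
  full covariance of real placement errors (in real data the two tests have
  independent motor/retrieval noise).
* Misbound items carry their realized (large) pre-sleep error into the post
  test, so post-sleep swap rates for six-item sets run a few points below
  pre-sleep rates — real data show near-identical rates.
* ICC variants other than ICC(1,1) (e.g., two-way agreement forms) are not
  implemented; the estimator choice is exposed but fixed to the one-way
  form.
* The LMM sound effect is nested, not crossed; with 22 sounds and ≥ 5
  participants the practical difference is small but nonzero.
* EDF export is not provided; recordings round-trip as raw arrays with a
  JSON sidecar.
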