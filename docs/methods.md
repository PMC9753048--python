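# Methods

## The analysis

`semdecode` implements single-trial decoding of a binary semantic
category (abstract vs. concrete words) from intracranial ECoG, and the
spatiotemporal characterization of what drives that decoding.

**Features.** The continuous multichannel recording (microvolts,
canonically 2000 Hz) is re-referenced to the common average, band-pass
filtered to 70–150 Hz, and reduced to its Hilbert-envelope magnitude —
the high-gamma power (HGP) proxy for local cortical activation. Epochs
from −500 to +2000 ms around each word onset are averaged in 250-ms
bins; the six bins covering 0–1500 ms form the feature space, one
dimension per (channel, bin).

**Normalization without leakage.** Features are Z-scored per channel
against the pooled pre-stimulus (−500 to 0 ms) bins of the *training*
trials of each cross-validation fold: μ and σ (population SD, divisor
N) are computed from the 2 × 79 pooled baseline bin powers and applied
to all trials. The held-out trial therefore never influences its own
normalization, mask, or classifier — a contract tested explicitly by
perturbation.

**Decoding.** Leave-one-out cross-validation over the (canonically 80)
trials. Per fold, a two-sided Wilcoxon rank-sum test per dimension
compares the category groups in the training data; dimensions with
p > 0.05 are excluded (p = 0.05 exactly is retained). A linear SVM
(C = 1, no additional scaling — features are already Z-scores) is
trained on the survivors and predicts the held-out trial; accuracy is
the percentage of correct folds. Chance is thresholded with the exact
one-sided binomial tail: the smallest k with P(X ≥ k | n, ½) ≤ 0.05,
i.e. 48/80 = 60.0% for a full session. A conventional reference level
of 65% for this paradigm is kept as a named constant but is never used
as the package's own criterion.

**Characterization.** Two (channel, bin) maps: the deviation index
DI = (a − c)/(a + c) of category-mean HGP (baseline-*ratio* normalized,
so both means are positive and |DI| ≤ 1; positive = abstract-dominant),
and the fold-averaged absolute SVM weight (sum of |w| over folds where
the dimension was retained, divided by the number of folds). Dimensions
excluded by selection carry exactly 0. Maps are averaged over each
region's channels into a region × 6-bin matrix, and across participants
(unweighted; regions missing from a participant are excluded cell-wise).
Cells of the group weight matrix strictly above the mean + SD of all
cells are merged into per-region contiguous windows — the TargetSet.

**Targeted decoding** reruns the identical LOOCV pipeline with the
feature space restricted a priori to the TargetSet (channels via region
labels, bins fully inside a window); rank-sum selection still operates
inside the restriction.

## Design choices where the procedure was open

* **Filter realization**: 4th-order Butterworth per pass, applied
  forward–backward (zero phase), so bin timing is interpretable.
* **Baseline pooling**: the two 250-ms baseline bins are pooled with
  trials into a single per-channel sample rather than normalized
  per-bin — more stable at 79 training trials.
* **σ convention**: population SD throughout the normalization and the
  ± summaries; the packaged worked-example table pins this (its printed
  SD of the full-accuracy column, 7.5, is the population value; the
  sample value would be 8.0). Inferential tests (paired t, Welch t,
  Pearson) use the standard sample-variance formulas.
* **Rank-sum p-values**: exact enumeration when either group has fewer
  than 10 members, tie-corrected normal approximation otherwise.
* **Empty-mask folds** predict the training-set majority with a
  deterministic tie-break (abstract) and are flagged. With balanced
  categories this fallback is systematically wrong (see below), which
  is one reason realistic channel counts matter in simulation.
* **Bin intervals** are half-open [edge, next_edge); the sample at
  exactly 0 ms belongs to the first analysis bin.
* **Trial rejection** replaces visual artifact screening with a
  reproducible criterion: a trial is dropped when its peak absolute raw
  amplitude or its mean envelope variance exceeds k = 5 robust SDs
  (median ± 1.4826·MAD) of the across-trial distribution.
* **Weight maps use |w|** (the mean+SD rule compares magnitudes); signs
  live in the DI. Session-level DI maps use the rank-sum mask computed
  over all trials, since no fold structure applies to a descriptive map.
* **Targeted windows**: both published phrasings of the canonical
  restriction are provided (`canonical_target_set("significance")` =
  IFG 250–1250 ms + SM1 1000–1500 ms; `"extended"` = IFG 250–1500 ms);
  neither is hard-coded as truth and arbitrary windows are accepted.

## The synthetic-session generator

Real recordings of this paradigm are not publicly deposited, so the
generator emulates the study conditions: 20 words per category, each
presented twice in pseudorandom order (80 trials), 500-ms presentation,
2500 ± 500 ms intertrial interval, 2000 Hz sampling. Background noise
is Gaussian, spectrally shaped to 1/f (α = 1, RMS 20 µV) — a standard
stand-in for ECoG background. Category-dependent effects multiply the
70–150 Hz band content of a region's channels by a gain (default 2.0,
i.e. ×4 in-band power) inside a latency window with 50-ms raised-cosine
ramps; scaling the band component of the existing noise, rather than
adding an oscillation, keeps envelope statistics realistic. The
canonical two-effect scenario mirrors the empirical pattern the
pipeline is meant to recover: an abstract-dominant IFG response at
250–1250 ms and a concrete-dominant SM1 response at 1000–1500 ms.

Default sessions use 24 channels (6 each in IFG, SM1, STG and an
"other" pool). Clinical montages are larger (order 100–240 channels);
24 keeps a full 20-seed simulation battery in the minutes range on one
CPU while staying in the regime where per-fold selection virtually
never empties the feature mask. What the generator does **not** model:
evoked low-frequency components, cross-channel covariance, epileptiform
transients (beyond an optional amplitude-burst contaminant used to test
rejection), word-level variability, or per-patient cortical geometry.
Passing tests therefore demonstrate the pipeline's statistical
machinery, not clinical-grade performance on real ECoG.

## Behavior of LOOCV accuracy under the null

Leave-one-out accuracy with per-fold feature selection is **not**
binomial(n, ½) under the null, and the test suite measures this
directly rather than hiding it:

* **Overdispersion (dominant).** Fold predictions share 78 of 79
  training trials, and per-fold selection couples them further;
  session-level null accuracy spreads far wider than the binomial SD
  of 5.6 points, in both directions. The effect persists when i.i.d.
  features are fed straight into `loocv_decode` at larger channel
  counts, so it is a property of the validation scheme, not of the
  signal generator.
* **Mild bias.** With very small feature spaces, balanced leave-one-out
  has an anti-learning pull: removing one trial makes the opposite
  category the training majority, and the empty-mask majority fallback
  is the extreme case (it is always wrong at 39 vs 40). At the default
  24-channel geometry the fallback essentially never triggers and the
  null mean sits close to 50%.
* **CAR crosstalk.** Common average referencing mixes a fraction of
  any regional effect into every channel, so "uninvolved" regions of an
  effect session carry a small systematic deviation index; truly null
  sessions do not.

Consequently the exact binomial threshold is a convention, not a
type-I guarantee for this statistic: a noticeable fraction of null
sessions crosses it, which the null-simulation tests assert against the
binomial expectation and therefore report as failures, by design. The
acceptance script reports the measured crossing fraction. Calibrating
chance exactly would require within-session label permutation at ~100×
the cost; that (not a higher binomial cut) is the principled fix, and
is left out of scope.

## Problem sizes and numerics

Simulation batteries use 20 seeds per condition, 24-channel 80-trial
sessions (~244 s at 2000 Hz each). Butterworth + `sosfiltfilt` keeps
filtering stable; the Hilbert transform uses an FFT length padded to the
next fast size. Degenerate inputs fail loudly: zero baseline variance,
empty trial lists, single-channel referencing, all-trials-rejected,
a + c = 0 in the DI, and empty TargetSets all raise errors rather than
propagate NaNs.

## Known limitations

* The generator's effects are stationary within their window and
  identical across a region's channels; no trial-to-trial latency
  jitter or amplitude variability beyond the background noise.
* Region labels are taken as input metadata; no electrode localization
  is performed.
* The per-fold SVM uses a fixed C = 1; no hyperparameter search.
* Group aggregation weights participants equally regardless of channel
  counts.
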