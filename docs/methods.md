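# Methods

This note documents the models, parameter choices, and numerical decisions
behind `crabtai`, and what the synthetic cohort does and does not emulate.

## Pipeline overview

The package assumes upstream models have already been run: a pose estimator
producing per-frame (x, y, likelihood) for 13 named keypoints (carapace
spines, head, chelipeds, swimming legs), and a behavior classifier
producing a per-frame confidence in [0, 1] for each of three categories —
*anxious*, *demonstration*, *fighting*. Confidences need not sum to one;
the residual mass is "unclassified". The pipeline proceeds:

1. **Bout extraction** — maximal runs of frames with confidence strictly
   above the threshold (default 0.5); runs shorter than the minimum bout
   duration (default 180 ms, converted to frames with a ceiling: 6 frames
   at 30 fps) are discarded. Optional merging of runs separated by short
   gaps is available but off by default. Categories are treated as
   independent traces and may overlap in time; durations are summed per
   category with a per-category clip at the trial length and no
   cross-category renormalization.
2. **Trial summary** — per-category durations, first-attack latency
   (start of the earliest fighting bout; the full trial length when no
   attack occurred, which zeroes the latency reward), and the act count
   (bouts over all three categories by default; a switch restricts it to
   fighting only).
3. **Kinematics** — keypoints below the likelihood threshold (default
   0.95) are masked; interior gaps of at most 5 frames are filled by
   linear interpolation, longer or edge gaps stay missing. The body
   centroid is the mean of the visible carapace keypoints (LBODY, RBOD,
   HEAD; at least two required per frame). X1 (relative movement distance)
   is the summed centroid displacement over valid consecutive frame pairs
   divided by the median LBODY–RBOD distance — carapace width is the only
   size proxy available from the keypoint set, and the normalization makes
   X1 dimensionless and invariant to translation, rotation, and uniform
   pixel rescaling. X2 (freezing) is total time in low-speed runs (speed
   below 0.2 carapace widths/s, central-difference estimator, one-sided at
   the track ends) lasting at least 2 s. The freezing thresholds are
   module defaults, not assay constants: no operational definition of
   freezing is fixed by the assay, so both are exposed in the
   configuration.
4. **Scoring** — five repeated trials per individual are averaged
   field-wise before the index is evaluated. The index is linear in the
   durations at fixed latency and strictly monotone in every component.

## Index weights and their derivation

The default weights (0.14, 0.21, 0.35, 0.30) sum to exactly 1.00. They are
reproduced by `derive_weights`: OLS of aggression frequency on
$D_\text{anxious}, D_\text{demonstration}, D_\text{fighting}$ and the
transformed latency $T_\text{total} - T_\text{first}$ (transformed so the
coefficient is positively signed, matching the reward term), intercept fit
and discarded, coefficients normalized to unit absolute sum. Absolute-sum
normalization is the one choice that maps the printed weight set onto a
sum of 1.00 and guarantees non-negative weights; a negative duration
coefficient therefore loses its sign, and the function warns when that
happens. Rank-deficient designs raise an error naming the offending
predictor.

With the default weights and categories that are *mutually exclusive* in
time, the index supremum is 0.65 (whole trial in the heaviest category
plus an immediate attack); if categories may fully overlap the supremum is
1.00. The package computes the formula verbatim and does not rescale by
default — `tai_upper_bound` provides the attainable maximum for callers
who want scores on [0, 1].

## Validation statistics

* **Normality gate**: Shapiro–Wilk by default (Lilliefors KS selectable);
  parametric branch iff p > α. Two groups on the parametric branch get a
  Welch t-test; everything else goes through Kruskal–Wallis.
* **Stratification**: the ⌊0.25 n⌋ largest scores are HA, the ⌊0.25 n⌋
  smallest LA, the rest MA (50/100/50 at n = 200). Boundary ties are
  broken by stable input order — deterministic and reproducible.
* **ICC**: consistency ICCs from the two-way ANOVA mean squares,
  ICC(C,1) = (MS_R − MS_E)/(MS_R + (k−1) MS_E) and
  ICC(C,K) = (MS_R − MS_E)/MS_R, with F-based confidence intervals. The
  direct ICC(C,K) and the Spearman–Brown transform of ICC(C,1) agree to
  1e-12 by construction; the implementation is cross-checked against
  pingouin in the test suite.
* **Bland–Altman**: limits of agreement mean ± 1.96 SD of the pairwise
  differences; CI of the mean difference ±1.96 SD/√n; the fraction of
  points inside the limits is reported.
* **Clustering**: scikit-learn k-means (10 seeded restarts, best inertia)
  on z-scored (TAI, serotonin); clusters relabeled by descending size so
  cluster 0 is always the majority. Stability is the per-cluster mean of
  the maximum Jaccard overlap between each original cluster and the
  re-clustering of each bootstrap resample (computed on the resampled
  multiset), 100 resamples by default.
* **Pairing analysis**: tie-corrected Kruskal–Wallis with χ² p-values,
  then Dunn's pairwise z tests on mean ranks with the standard
  tie-corrected variance and Bonferroni adjustment over all pairwise
  comparisons. Dunn's test is implemented here directly because no
  installed dependency provides it.

## The synthetic cohort

Each individual carries a latent aggressiveness trait *a* ~ truncated
normal (mean 0.5, SD 0.15) on [0, 1]. Expected category durations are
affine increasing in *a* (anxious 40 + 260 a s, demonstration 30 + 220 a s,
fighting 10 + 290 a s over an 1800-s trial), expected first-attack latency
is $T_\text{total}(1 - 0.85\,a)$, locomotion speed increases and freezing
occupancy decreases in *a*. Trial-to-trial noise is additive Gaussian with
a constant cohort-level scale (25% of the cohort-typical value), applied
to durations and to the latency's *earliness*; constant-variance additive
noise — rather than noise proportional to each individual's mean — keeps
the induced index distribution symmetric, so a 200-individual cohort
passes Shapiro–Wilk at α = 0.05 for the large majority of seeds, as the
assay's normality gate presumes. A profile with zero expected duration
never expresses the behavior.

Within a trial, behavior states follow a semi-Markov renewal process with
exponential dwell times (mean bout 5 s), the simplest process matching a
target occupancy; fighting activity opens exactly at the drawn latency.
Classifier confidence is uniform on (0.8, 1.0) inside true bouts and
(0.0, 0.2) outside. The pose track moves a heading-random-walk centroid
(reflected inside the arena) at the profile's speed, doubled during
fighting and zeroed during freezing spells; keypoints sit at fixed
body-plan offsets (carapace width 120 px) with slowly varying AR(1) jitter
and a 2% likelihood-dropout rate.

Serotonin is affine in *a* (50 + 100 a ng/mL, SD 10) for the majority; a
discordant 20% — drawn from the lower half of the trait distribution —
receives a +110 ng/mL offset, producing the compact
high-serotonin/low-aggression subcluster that k = 2 k-means isolates. The
units are an arbitrary affine scale: only correlations and cluster
geometry matter downstream. Pairing-trial attack counts are negative
binomial (dispersion 2) with context means 7.08 (H-H), 2.25 (M-M), 2.41
(H-L), 0.96 (L-L); the L-L context is zero-inflated with a structural-zero
probability solved numerically so the *total* zero fraction is 0.48 while
the mean is preserved (the NB mean is rescaled by 1/(1−π)).

What the generator does **not** emulate: real two-animal interaction
dynamics (contact, chasing geometry), classifier confusion between similar
categories, camera distortion or identity swaps, and any covariates (size,
molt stage, sex). Passing tests therefore certify the *analysis* — that
the pipeline computes the intended quantities and that its statistics
behave as specified — not the upstream tracking or classification models.

## Numerical choices and scaling

Frame intervals are 0-based and inclusive at both ends; duration =
(end − start + 1)/fps. The minimum bout duration converts to frames as
⌈ms·fps/1000⌉ (computed as a single product to avoid float creep), floored
at one frame. Bout-table readers re-check durations against the frame
interval within half a frame. Constant inputs raise errors rather than
returning NaN (z-score, correlation, normality, ICC without
between-subject variance). Per-individual random streams are keyed by
(master seed, individual id, repeat), so any trial can be regenerated
independently of iteration order.

Tests and examples run frame-level simulations at reduced scale (60–120-s
trials at 10 fps, cohorts of up to 30 individuals for the frame-level
path, 200–500 for summary-level statistics); `SimParams.scaled_to` rescales
the duration links proportionally so occupancy structure is preserved.
These sizes are the package's own choices for fast, deterministic checks;
all default parameters remain those of the full assay (1800 s, 30 fps,
n = 200, five repeats).

## Known limitations

* X1's normalization by carapace width is a documented modeling choice;
  any body-size proxy would do, and the choice is configurable.
* The act count includes bouts of all three categories by default; a
  fighting-only variant is provided because the convention is ambiguous.
* The index is not rescaled to [0, 1]; under exclusive categories its
  attainable maximum with default weights is 0.65.
* Bootstrap Jaccard can be optimistic for very small clusters, which may
  vanish from a resample (such resamples contribute zero stability for
  that cluster).
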