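# Methods

## Problem

Motor-imagery (MI) brain-computer interfaces classify short epochs of brain
activity as "imagining a movement" versus "resting". Classical features are
local band-power descriptors (optionally spatially filtered with common
spatial patterns, CSP). This package implements an alternative built on
*neuronal avalanches*: brief, spatially extended bursts of strong activity.
The central object is the **avalanche transition matrix** (ATM) — a directed
regions × regions matrix whose entry (i, j) estimates the probability that
region j is active one time bin after region i was active, within an
avalanche. The diagonal carries self-persistence. The package provides the
measurement chain, a four-level permutation-statistics suite for detecting
condition-dependent propagation, a decoding benchmark (ATM+SVM vs CSP+SVM),
and a synthetic cohort generator with planted ground truth on which all of
it is validated.

## Measurement chain

1. **Binarization.** Each region's signal is z-scored over time *within each
   trial* (epochs are the analysis unit; per-trial scoring also removes slow
   session drift) and a sample is active when |z| > 3 (default; 2.5–4
   supported). Samples are OR-combined into bins of 1–3 samples; bin
   length 1 is the default. A constant region raises an error naming the
   region and trial rather than propagating NaNs.
2. **Segmentation.** An avalanche is a maximal run of bins in which at least
   one region is active. Trials are segmented independently; avalanches
   touching a trial edge are kept and flagged truncated, as with real
   epoched data.
3. **Transition matrices.** Per avalanche, entry (i, j) = (# frames where i
   is active at t and j at t+1) / (# frames where i is active at t before
   the last bin). Rows whose source never has a successor frame are set to 0
   (not NaN) so averaging is always defined; the count of such rows is
   logged. Single-bin avalanches carry no transitions and are excluded.
4. **Trial-level aggregation.** Two estimators are provided. The default
   **pools transition counts** over a trial's avalanches before normalizing:
   the estimand is a conditional probability, and pooling frames is its
   direct (maximum-likelihood) estimate. The alternative averages
   per-avalanche probability matrices edge-wise (`pooled=False`); because
   undefined rows enter as zeros, that estimator multiplies each entry by
   the source's avalanche-participation rate, which both biases the scale
   and roughly halves detection power on the synthetic benchmark — it is
   kept for comparability with the per-avalanche convention.
5. **Branching ratio.** Per avalanche,
   σᵢ = ∏ⱼ (n(j+1)/n(j))^(1/(Nbin−1)) over successive event counts, and
   σ is the geometric mean of the σᵢ over avalanches. σ ≈ 1 indicates
   near-critical cascades (subcritical < 1 < supercritical). Note the
   product telescopes: σᵢ = (n_last/n_first)^(1/(Nbin−1)), so the estimator
   is conditioned on avalanche shape — see "estimator calibration" below.

## Permutation statistics

All null distributions include the observed statistic, so p ≥ 1/(n_perm+1);
all corrections are Benjamini–Hochberg step-up within the stated family.

- **Subject edge test.** Trial-level ATMs are re-allocated to the two
  conditions (10 000 permutations by default; exhaustive enumeration is
  auto-selected when ≤ n_perm distinct assignments exist). Two-sided p per
  edge on the mean-difference statistic, BH across all R² edges (diagonal
  included). Trials without avalanches are excluded.
- **Group reliability.** The per-edge count of subjects with an individually
  significant edge is compared against re-scattering each subject's
  significant edges uniformly over all R² positions (their number
  preserved), independently per subject and permutation; one-sided p,
  BH across edges.
- **Node concordance.** A region's degree counts incident reliable edges
  (in + out, diagonal once — ATMs are directed). The null places the same
  number of edges uniformly at random; one-sided p per region, BH across
  regions.
- **Hit/miss contrast.** Per edge: |MI−Rest difference over hit trials| −
  |the same over miss trials|; the null shuffles hit/miss labels within each
  condition. One-sided (the hypothesis is directional: successful trials
  should differentiate more), evaluated on the reliable-edge mask, per
  subject, then summarized across subjects by the mean statistic and its
  sign consistency.
- **BCI-score correlation.** Spearman correlation (average ranks on ties),
  per edge across subjects, between the MI−Rest ATM difference and the BCI
  score; coefficients are averaged within each of the 5×5 directed
  functional-area blocks (executive, pre/motor, parietal, temporal,
  occipital; self-blocks included). The null permutes the edge→block
  assignment of the coefficients; two-sided p per block, BH across the 25
  blocks.

A practical caveat: with n permutations the smallest attainable p is
1/(n+1). BH across 4 624 edges at α = 0.05 needs p-values around k·10⁻⁵, so
subject-level and group-level tests are run at 10 000 permutations in the
planted-effect analyses; the false-discovery acceptance check uses 1 000
permutations at both levels, per its design, which makes it conservative.

## Decoding benchmark

Both pipelines share seeded stratified 80/20 shuffle splits (50 by default)
and a linear-kernel SVM with C = 1 (no tuning). ATM features are the full
flattened directed matrix (ATMs are asymmetric; trials without avalanches
enter as zero vectors, flagged). The binarization threshold is selected per
split from {2.5, 3.0, 3.5, 4.0} by inner cross-validation on the training
trials only; per-trial ATM features are trial-local, so precomputing them
per threshold leaks nothing. CSP solves the generalized eigenproblem
C₁w = λ(C₁+C₂)w on Ledoit–Wolf-shrunk class covariances, keeps the 4+4
eigenvalue extremes with a fixed sign convention, and uses log-variance of
the filtered time courses ("average power" up to the standard monotone log
conditioning transform). Per-subject comparison: paired t-test over the 50
shared splits, confirmed by Wilcoxon signed-rank, BH across subjects,
three-way decision with direction. Intra-subject variability is the sd of
accuracy across splits.

## Synthetic cohort generator

The generator stands in for source-reconstructed M/EEG recordings (the
study design it emulates: 20 subjects, 68-region Desikan parcellation, 7-s
epochs at 250 Hz, 48 trials per condition, ~70 % hit rate).

**Cascade model.** A branching process on a directed graph: each region
active at bin t independently triggers region j at t+1 with probability
W[i, j]; the ATM estimand is therefore analytically known. Every row of W
sums to `sigma_target` (default 1: critical — each active region produces
one expected offspring).

**Initiations.** Spontaneous initiations arrive through a common bursty
drive: a bin is "excitable" with probability q = 0.14 and only then each
region initiates with probability μ/R (μ = 0.6), giving a mean rate of
1.24·10⁻³ /region/bin concentrated in bursts. Initiations also fire inside
ongoing avalanches and at trial edges (merged and truncated cascades occur,
as in real epochs).

**Estimator calibration.** Because σᵢ telescopes to
(n_last/n_first)^(1/(d−1)), the estimator is conditioned on how
avalanches start and end: with purely singleton initiations every avalanche
starts at 1 and ends at ≥ 1, forcing σᵢ ≥ 1 (the critical process reads
≈ 1.07); strongly clustered initiations make avalanches start large and
decay (≈ 0.85). The (q, μ) pair above was chosen so the critical 68-region
process reads 1.000 ± 0.005 across seeds, with a per-region active fraction
of ~1–4 % — comfortably below the hard feasibility bound described next.
The calibration is geometry-dependent and is documented for the default 68
regions; the 19-region fast profile runs the same drive.

**Planted effect.** Planted edges model a strong structural pathway
(avalanches preferentially follow white-matter bundles): their rest
propagation probability is 0.08 instead of the diffuse σ/R ≈ 0.015, with
the rest of the source row scaled down to keep the row sum at
`sigma_target`. For the default 68-region geometry the pathway is
premotor → parietal: bilateral caudal-middle-frontal and precentral sources
onto bilateral superior/inferior parietal and left precuneus (20 edges).
During MI the planted probabilities are multiplied by `effect_size`
(default 2) and the row is renormalized again — the task *reroutes*
propagation through the pathway rather than adding activity, keeping global
dynamics (and the branching ratio) matched across conditions. Two
consequences are deliberate: the diffuse entries of planted source rows
also differ slightly between conditions, and second-order co-activation
makes some additional edges *into* the planted targets genuinely
condition-dependent, so those targets are the strongest hubs of the
reliable-edge graph. Miss trials attenuate the MI−Rest weight difference by
`miss_attenuation` (default 0.5; 1 makes hit and miss identically
distributed, 0 removes the effect from misses entirely).

**Subjects and BCI scores.** Per subject, all weights receive element-wise
log-normal jitter (sd 0.1, shared across conditions so the effect stays in
planted rows) and a log-normal "skill" factor (sd 0.25) scales the planted
MI−Rest delta. The BCI score is a logistic function of the realized planted
effect relative to the population pathway strength (slope 1.5) plus seeded
Gaussian noise (sd 0.05), clipped to [0, 1] — a deliberately simple
monotone link; the real quantity it mimics is the fraction of trials in
which a subject controls the feedback cursor. Hit/miss labels are drawn
independently at the cohort-level `hit_rate`; the mild inconsistency with
the score (which, in a real protocol, *is* the hit proportion) is accepted
for contract simplicity.

**Signal embedding.** Continuous signals are Gaussian background noise in
which every sample of an active bin is replaced by a per-(region, trial)
deflection value computed from the realized noise moments such that, after
z-scoring, active samples sit at exactly c z-units with
threshold < c ≤ 1.5·threshold. Re-binarization at the matching threshold
therefore recovers the planted raster bit-exactly on planted cells;
background samples add chance crossings at the 2(1−Φ(t)) rate. The
construction has a hard feasibility bound — z-scores satisfy mean(z²) = 1,
so a fraction f of samples can only all exceed |z| > t if f < 1/(1+t²)
(≈ 0.1 at t = 3) — and raises a labeled error on rasters too dense to
embed. What the generator does **not** emulate: oscillatory (band-limited)
content, 1/f background, autocorrelated noise, volume conduction and field
spread, and the amplitude statistics of real source estimates. Passing
tests therefore demonstrate correctness of the estimators and the
statistical machinery under a known cascade model, not robustness to real
M/EEG artifacts.

## Numerical choices

- Permutation ties are counted with a 10⁻¹² slack so the observed
  assignment's floating-point recomputation registers as a tie.
- Zero-denominator ATM rows → 0; zero-variance CSP mode power is floored at
  machine epsilon (logged); threshold candidates with no avalanches are
  skipped with a warning; threshold ties resolve to the smallest value.
- The "z = |3|^10" reading of the threshold found in some derived texts is
  treated as a typesetting artifact; the threshold is |z| > 3.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; cohorts use `SeedSequence.spawn` per subject. Outputs
  are reproducible from (spec, ground truth, seed).

## Problem sizes in the shipped checks

The acceptance checks run at the study geometry (68 regions, 7-s trials,
20 subjects, 48 trials/condition): the criticality check collects ~2 700
avalanches from 60 resting trials; the false-discovery check averages 10
null cohorts with 1 000 permutations at both levels; the planted-effect
analysis uses 10 000 permutations per stage; the decoding benchmark runs
50 splits on a two-subject strong-effect cohort (effect 3, baseline 0.06,
no miss attenuation — the cleanly separable construction) plus a
label-shuffled chance control. Unit tests use a 19-region / 2-s profile.

## Known limitations

- The branching-ratio estimator is shape-conditioned; it does not order
  sub- vs supercritical regimes reliably at these epoch lengths (short
  epochs are generally ill-suited to avalanche tail estimation), and its
  calibration here is specific to the initiation statistics.
- The group-reliability and node nulls assume exchangeable edge positions;
  spatially structured significance (e.g., distance effects in real data)
  would violate that exchangeability.
- BH is applied within each analysis family; no across-family correction.
- The per-avalanche averaging mode's participation-rate bias is inherent to
  its zero-fill convention, not a bug.
- CSP assumes stationary class covariances within trials; the generator's
  cascades are only approximately stationary at trial scale.
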