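# Methods

This note records the models and procedures implemented in `pssmap`, the
assumptions behind them, and the numerical choices made where the design
was genuinely open.

## Voxel-wise statistical mapping

All three engines test, per voxel, the one-sided hypotheses
H₀: improvement < θ against H₁: improvement ≥ θ on the improvement scores
of the stimulations covering that voxel.  θ defaults to 50 % (the clinical
responder cut for rigidity-type ratings) and is set to 75 % for
tremor-type cohorts.

**Tested-voxel family.** Only voxels with enough usable observations enter
the multiple-comparison family: at least `min_observations` (default 5)
non-zero differences from θ for the Wilcoxon engines, or covering scores
for the Bayesian engine.  Correcting over voxels that could never be
significant only inflates the family size; the floor also avoids
meaningless 1–2 sample tests.

**Wilcoxon signed-rank (`stats.py`).** Zero differences (score = θ) are
discarded before ranking — the classic signed-rank convention.  Because
clinical ratings live on a 12.5 % grid, ties dominate; p-values are
therefore computed from the *conditional* exact null given the observed
midrank pattern, via a generating-function convolution over the 2ⁿ sign
assignments (doubled ranks keep everything integer).  This is exact for
n ≤ 25 usable differences; above that a tie-corrected normal approximation
with continuity correction is used (variance term Σ(t³−t)/48 subtracted).
A voxel with no usable differences reports p = 1.

**FDR correction (WFDR).** Benjamini–Hochberg step-up over the tested
family, via `statsmodels`; significance at corrected p < α = 0.05.

**Permutation correction (WPERM).** Improvement scores are shuffled across
*all* stimulations of the dataset (masks fixed), i.e. the permutation unit
is the stimulation, not the patient.  The voxel statistic is the
tie-corrected standardized W⁺ (comparable across voxels with different
sample sizes); family-wise correction uses the max-statistic null:
corrected p = proportion of permutations — observed arrangement included —
whose family-maximum statistic reaches the voxel's observed statistic.
This is the standard FWE construction for image-wise permutation testing;
the alternative (per-voxel permutation p-values) remains an open
interpretation of the underlying method description.  A per-permutation
row with no usable differences contributes −∞ and can never drive the
maximum.

**Bayesian engine (BAYES).** Model `score ~ N(μ, σ²)` with priors
μ ~ N(θ, 25²), σ ~ HalfNormal(25), both on the 0–100 % scale; 25 spans one
step of the rating scale.  Centering the μ prior at θ makes the prior odds
1, so the directional Bayes factor

BF = [P(μ ≥ θ | data)/P(μ < θ | data)] / [P(μ ≥ θ)/P(μ < θ)]

reduces to the posterior odds.  Posterior masses come from MCMC draws of
μ, prior masses are analytic.  The sampler is Metropolis-within-Gibbs,
vectorized across voxels: the μ-step is an exact conjugate normal draw
given σ; the σ-step is random-walk Metropolis on log σ (step
2.4/√(2n), clipped to [0.05, 1]) against the half-normal prior with the
log-transform Jacobian.  The Gaussian likelihood enters only through
(n, Σx, Σx²), so a sweep costs O(voxels) regardless of coverage depth.
Defaults: 2000 kept draws after 1000 warmup sweeps.  σ's support is
truncated to [0.5, 1000] %: the floor (far below the 12.5 % rating
resolution) keeps voxels whose covering scores are all identical from
collapsing the chain to σ = 0.  With `sigma_fixed` set the sampler reduces
to i.i.d. conjugate draws, which is how it is validated against the closed
form.  The BF is capped at 2·(number of draws)+1 when no draw falls below
θ — finite, seed-stable, and above the decision threshold of 10; a voxel
whose chain produces non-finite draws is treated as not significant.

**Filters.** Significant voxels must additionally be covered by ≥ 25 % of
the patients and carry ≥ 10 % of the maximum per-voxel stimulation count;
comparisons are ≥ on the exact fractional thresholds (no rounding of
0.25·nPat).  Finally, connected components smaller than 1 mm³ are removed
("smaller than" is strict, so an exactly-1 mm³ cluster survives);
connectivity defaults to 6 (faces), with 18/26 selectable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the physics of stimulation:

- **Grid**: 32³ voxels at 1 mm isotropic (voxel-center convention; world
  coordinate = origin + index·voxel size).  Large enough for the 14 mm
  trajectory span plus VTA radii, small enough for desk-scale runs.
- **Ground truth**: an axis-aligned ellipsoid (default semi-axes
  3.5 × 3.5 × 5 mm at the grid center) playing the role of the true
  sweet-spot region.
- **Trajectories**: per patient, two parallel tracks 2 mm apart running
  along z through an entry point jittered around the ground-truth center
  (sd 1.5 mm laterally, 1 mm axially), with candidate stimulation
  positions spanning 14 mm at 1 mm steps — mimicking intra-operative
  exploration.  The ET-like mode concentrates positions near the sweet
  spot (exponential weight, 3 mm decay), mimicking chronic-contact
  screening where only promising positions are programmed.
- **VTAs**: axis-aligned spheres with radius r = 0.5 + 1.5·√amplitude mm,
  amplitude ~ U(0.2, 3) mA.  Monotone growth in amplitude is the one
  property of field-threshold volumes the analysis relies on.
- **Scores**: 100·f^γ with f the VTA fraction inside the ground truth,
  plus N(0, sd²) noise (default sd 10 %), clipped to [0, 100] and
  quantized to the 0/12.5/…/100 rating grid.  γ shapes the marginal
  distribution: γ = 0.50 (PD-like) centers the cohort mean near 50 % with
  a wide spread; γ = 0.40 plus the concentrated ET-like placement yields a
  high-skewed distribution with mean near 70 %.  Both were calibrated once
  against those target means and then frozen.

Cohort presets: PD-like — 36 patients, 12–22 stimulations each (uniform);
ET-like — 61 patients, exactly 4 stimulations each (244 total).

What the generator does *not* emulate: tissue heterogeneity and field
anisotropy (VTAs are spheres), per-patient anatomical variability beyond
trajectory jitter, registration error, rater drift, or any spatial
covariance structure of outcomes beyond the single ellipsoidal focus.
Passing tests therefore demonstrate that the machinery recovers a known
signal under its own assumptions — not clinical fidelity.

## Resampling scheme

Patient chains are additive without replacement: a chain is a random
permutation of the cohort read as nested prefixes of sizes 4, 6, 8, …
(strictly below the cohort size); 10 independent chains by default, and
the full cohort is one shared dataset terminating every chain's curve.
Stimulation subsampling draws exactly nStim ∈ {4, 6, 8, 10, 12} per
patient, three independent times, re-drawn independently at each chain
level (not nested across nPat — the description of the original procedure
leaves this open).  Every dataset is regenerated on demand from
`(master_seed, key)` through per-key `SeedSequence` spawning, so nothing
is stored; on 36 patients the scheme yields 160 + 1 patient datasets and
2415 datasets in total.

## Metric curves and stability

Pairwise metrics between sweet spots A, B:

- vol_diff = 100·|V_A − V_B| / max(V_A, V_B); both empty → 0, one empty → 100;
- dice = 100·2|A∩B| / (|A|+|B|); both empty → undefined, one empty → 0;
- centr_dist = 100·‖c_A − c_B‖ / max(d_A, d_B) with d the
  equivalent-sphere diameter (6V/π)^{1/3}; undefined if either is empty.

The equivalent-sphere diameter was chosen over a max-extent (Feret)
diameter because it is rotation-invariant and stable for ragged voxel
sets.  Undefined values are carried as NaN and excluded from averages;
the empty-set conventions keep curves computable when an engine (often
the permutation one on small datasets) returns empty volumes, without
inventing positions.

For each chain and successive size pair s → s′, all 3×3 cross-pairs of
stimulation re-draws are compared and averaged, then averaged across
chains; the point is indexed at s′.  The across-chain sd and the number
of defined pairs are reported with every point.

A curve's **stability point** is the earliest support point from which
*every* later point stays within 5 percentage points of the final
(full-cohort) value — the persistence reading of "remained below";
a candidate that would be the final point alone does not count, and an
undefined value in the tail vetoes everything before it (an empty-volume
tail is evidence of instability, not of agreement).  The 5-point tolerance
is absolute on the metric's own % scale; a relative rule would break down
near zero.  Tightening the tolerance can only move the stability point to
larger nPat (tested as a property).

## Stability boundary model

Each curve point becomes a record (total = nPat·nStim, label ∈ {0,1}),
labels 1 at and beyond the stability point, all 0 for curves without one.
P(stable) = logistic(β₀ + β₁·total) with weakly-informative N(0, 10²)
priors on the standardized-feature scale (the original analysis states no
priors).  Sampling is random-walk Metropolis with proposal covariance
(2.4²/2)·Σ_Laplace from the mode (found by BFGS and the analytic Hessian);
2000 kept draws after 1000 warmup, acceptance typically 0.3–0.5.
Coefficients are mapped back to the raw scale afterwards.

Per draw with β₁ > 0, the threshold total is T = (logit p* − β₀)/β₁
(p* = 0.5) and the minimum per-patient count at nPat is
max(1, ⌈T/nPat⌉); draws with β₁ ≤ 0 are censored at a cap (default 100)
so the credible interval keeps its meaning, and their fraction is
reported.  Single-class record sets are flagged degenerate and the
boundary reported as not existing.  The ceiling makes each draw's curve a
staircase, so the *mean integer* boundary is non-increasing but convex
only to within the 1-stimulation quantization; the continuous
(`integer=False`) boundary is exactly convex and is what shape checks use.
Model evaluation uses a stratified 70/30 split (stratification keeps small
minority classes in the test set) and classifies by posterior-mean
probability ≥ 0.5, reporting accuracy and F1.

## Problem sizes used in the test suite

The combinatorial and oracle checks run at full study scale (36-patient
cohorts, 2415-dataset plans, 10⁴ permutations against exhaustive
enumeration on a 3-voxel fixture).  The end-to-end pipeline test runs a
deliberately scaled-down configuration — 12 patients on a 16³ grid with a
10 mm trajectory span, stimulation counts (4, 6), 2 chains, 500/250 MCMC
sweeps and 50 permutations — chosen as the smallest setting in which
every stage (all three engines, curves, stability records, boundary fit)
still produces non-trivial output.  Parameter-recovery runs use the
noise-free PD-like preset, where all three engines should and do recover
the planted ellipsoid with Dice ≈ 80–93 against the ground truth.

## Known limitations

- The Bayesian engine's sampler is validated against conjugate and
  quadrature oracles, but it is a fixed-step Metropolis-within-Gibbs, not
  NUTS; very small σ-scales or extreme data could mix slowly.
- The permutation engine's exchangeability unit (stimulation, not
  patient) ignores within-patient score correlation; a within-patient
  scheme would be a straightforward extension.
- Empty-volume conventions for the metrics, while necessary, make curve
  tails for volatile engines depend on those conventions.
- The logistic boundary uses the total stimulation count as its single
  feature; it cannot express interactions where nPat and nStim matter
  separately.
- Synthetic cohorts validate machinery, not clinical claims; none of the
  clinical headline numbers of the motivating study are reproduced here.
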