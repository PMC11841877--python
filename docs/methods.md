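# Methods

This note documents the models and procedures implemented in
`somprofiler`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Synthetic cohort generator

Each latent profile is specified by a per-variable median and IQR on the
native scale plus a girl proportion. Variables are drawn independently
within profile from a truncated normal: the parent's σ is IQR/1.349 (the
normal IQR-to-σ factor) and its location is solved numerically (Brent's
method) so that the distribution *after* truncation to the variable's
bounds has exactly the requested median. Naively centering the parent on
the median biases the realized median by up to 0.5·IQR when the median
sits near a bound (several Likert medians equal the scale maximum);
median-matching removes that bias except at a hard bound, where no
continuous distribution can have its median exactly on the boundary and
the realized median lands as close as the geometry allows (residual bias
≤ 0.11·IQR across the built-in profiles, measured over 100 seeds).

The six built-in profiles encode the published per-cluster medians/IQRs
of the 15 input variables, sizes 29/43/29/35/38/20 (n = 194), and girl
proportions. Four of the six proportions are reported (0.31, 0.657,
0.605 — printed as "60.05%", read as 60.5% — and 0.65); the "balanced"
cluster is set to 0.49 and the remaining cluster to 0.21, the value that
makes the cohort-wide expectation match the overall 48.96% girl share.
Cognitive outcomes use the same scheme; the math-fluency, Digit Span and
Stroop rows follow the published per-cluster table, while academic
achievement and perceived math/language performance are not tabulated at
cluster level in the source and are reconstructed to reproduce the
reported ordering (clusters 1 and 4 highest achievement, cluster 5
lowest; perceived performance flat). Integer outcomes are rounded to the
nearest admissible value, which can shift a printed half-integer median
(e.g. 25.5 responses) by up to half a unit.

What the generator does **not** emulate: within-profile correlation
(variables are conditionally independent — between-profile separation
carries all dependence), item-level questionnaire responses, measurement
error models, and raw accelerations (count traces are scripted bouts).
Passing tests therefore demonstrate that the pipeline recovers structure
of this idealized form; real cohorts with strong within-profile
covariance or heavy-tailed variables may behave differently.

Likert snapping to the instrument grid is off by default (several
published medians are off-grid, e.g. 3.48, so the scores are treated as
continuous); `snap_likert=True` enables it.

The count-trace generator schedules days as sequences of intensity bouts
(each bout's counts/min is validated against its cut-point band) plus
exact-zero non-wear blocks, so the downstream minute classification is
known by construction. 15 s traces split each minute's counts with a
multinomial, preserving the minute total exactly.

## Accelerometer preprocessing

Cut-points (≤ 100 / ≤ 2295 / > 2295 counts·min⁻¹), the ≥ 20-minute zero
run non-wear rule, the ≥ 480-minute valid day and the 3-weekday +
1-weekend participant rule are implemented with the boundary semantics
taken literally from their printed inequalities (100 → sedentary,
2295 → light, 480 min → valid). Zero runs are evaluated on each
participant's concatenated minute stream, so a non-wear segment may span
a day boundary; no nonzero interruptions are tolerated within a run.
Trailing 15 s epochs that do not complete a minute are dropped rather
than zero-padded. "Weekday" and "weekend" are calendar tags on the
series; mean daily MVPA averages over valid days only and raises on
participants who fail the validity rule (signalling exclusion).

## Self-organizing map

Non-toroidal hexagonal sheet; unit (r, c) is embedded at
(c + 0.5·(r mod 2), r·√3/2), so lattice neighbors sit at distance 1 and
interior units have six neighbors. Neighborhood kernels act on the
embedded Euclidean distance: gaussian exp(−d²/2σ²), bubble 1[d ≤ σ],
cut-gaussian (gaussian truncated at σ), Epanechnikov max(0, 1−(d/σ)²).
σ ≤ 0 degenerates to the winner-only indicator, used for the
k-means-equivalence checks. Ties in winner selection always go to the
lowest unit index, for determinism.

**Sizing.** m = ⌈5√n⌉ total units; width = round(√(m/√ρ)) with
ρ = λ₁/λ₂ the ratio of the two leading covariance eigenvalues (capped at
100 for degenerate data); height = ⌈m/width⌉. This is a calibrated
reconstruction — it reproduces the published 12 × 6 grid at n = 194 with
ρ ≈ 4 — not a printed formula; both constants are arguments.

**Standardization.** The inputs mix minutes/day, percentiles and Likert
scores, so each variable is z-scored before training (otherwise BMI
percentile and MVPA dominate the Euclidean metric). Codebooks and
component planes are reported back on native scales by the exact inverse
transform; constant columns pass through unscaled.

**Schedules.** Two phases: rough (σ: max(height, width)/4 → 1,
η₀ = 0.5) and fine-tune (σ: 1 → 0.5, η₀ = 0.05), with σ and η decaying
linearly within each phase (η to zero) — SOM-toolbox-style conventions;
epoch counts default to max(5, 10·m/n) and max(5, 40·m/n). Sequential
training draws cases in a fresh random order each epoch under the run
seed; batch training recomputes all BMUs per epoch and sets each unit to
the kernel-weighted mean of assigned cases, units with zero total weight
keeping their previous vector.

**Quality.** Quantization error = mean case-to-BMU distance; topographic
error = fraction of cases whose first and second BMUs are not lattice
adjacent (the standard definition; a single-unit map has TE = 0 by
convention).

## Ensemble and model selection

The ensemble is the factorial grid repeats × modes × kernels ×
initializations; run seeds are base_seed + run index, so execution order
(or parallelism) cannot change results. Selection minimizes QE × TE;
because a zero product carries no ordering information, ties — including
multiple TE = 0 runs — are broken by lower QE, then by run order. Failed
runs are recorded in the trace with their reason and excluded.

## Codebook clustering

k-means (scikit-learn, Lloyd, k-means++ with 100 restarts by default)
runs on the neuron weight vectors — all of them, including units with no
hits, since the published procedure clusters neural weights rather than
participants. The Davies–Bouldin index is computed in-package:
DB = (1/k)·Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ with Sᵢ the mean member-to-centroid
distance and Mᵢⱼ the centroid distance; coincident centroids raise an
error (that k is skipped in the scan). Ties across k prefer the smaller
k (fewer profiles). Participants inherit their BMU's cluster; per-neuron
hit counts are exported. Cluster summaries use linear-interpolation
quartiles (numpy default), which matters when reproducing IQRs of small
clusters.

## Group statistics

Kruskal–Wallis uses mid-ranks with the standard tie correction (Likert
data guarantee ties); p from χ²(k−1). The ε² = H/(n−1) identity
reproduces every published input-variable effect size within 0.005 (the
rounding of the printed H). Dunn's z uses the tie-corrected pooled
variance N(N+1)/12 − Σ(t³−t)/(12(N−1)) and two-sided normal p-values,
Bonferroni-multiplied by the k(k−1)/2 pairs *within* one variable (no
correction across variables, matching the source analysis). The χ²
independence test applies no continuity correction.

The χ² approximation to the Kruskal–Wallis p is coarse at very small n:
at n = 8 (two balanced groups) it deviates from the exact permutation p
by up to 0.12 mid-distribution, and at n = 6 the permutation lattice is
1/20. The tests therefore validate the approximation where it is used —
the decision tail (exact p ≤ 0.06), where agreement is within 0.02.

**Power utility.** One-way fixed-effects ANOVA omnibus: df₁ = k−1,
df₂ = N−k, noncentrality λ = f²·N; the search returns the smallest N
whose noncentral-F tail beyond the central-F critical value reaches the
target power. By default N is constrained to balanced groups (multiples
of k), the G*Power convention: f = 0.272, k = 4, α = 0.05, power = 0.80
gives N = 152, and f = 0.25 gives the classical 180 (the unconstrained
minimum, 179, is available with `balanced=False`). The group count is an
explicit argument; 4 is the value consistent with the published N = 152.

## Problem sizes used in tests and the acceptance script

The study-scale ensemble (1600 maps) runs in minutes; routine validation
uses reduced but structurally identical runs: cardinality is checked at
repeats = 2 (32 maps) plus the closed-form product for 1600, and
cluster-count recovery uses repeats = 5 (80 maps per seed) over 20 seeds
on the sharpened cohort (IQRs halved), chosen as the smallest ensemble
that keeps the QE × TE selection meaningful across all 16
configurations. Recovery at these sizes is 19–20/20 seeds choosing
k = 6 with ARI ≥ 0.98 against the generative labels.

## Known limitations

- The map-sizing rule is a calibrated reconstruction (see above).
- Sequential training is a Python loop over steps; it is fast at n ≈ 200
  but not optimized for cohorts orders of magnitude larger.
- Only sheet topology and the four listed kernels are implemented; no
  toroidal maps, growing variants, or alternative cluster-validity
  indices beyond Davies–Bouldin.
- The generator emits BMI percentiles directly; computing percentiles
  from growth references is out of scope.
- Missing input values are rejected rather than imputed (the analysis
  assumes complete cases).
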