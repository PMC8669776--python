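# Methods

## The two-group model and the estimation/control dichotomy

`fdrkit` works in the classic two-group setting: each of *m* features is
truly null with probability π0 or non-null with probability π1 = 1 − π0.
Null p-values are Uniform(0, 1); on the Z scale (`z = Φ⁻¹(1 − p/2)` for
two-sided p-values) the null density is f0 ~ N(0, 1) and the marginal is the
mixture F = π0·F0 + π1·F1.  For a rejection region Z, Bayes' theorem gives
the region-wise FDR

    FDR(Z) = Pr(null | z ∈ Z) = π0·F0(Z) / F(Z).

Substituting the empirical step CDF `F̂(Z_i) = rank(p_i)/m` and F0 = p
recovers the BH per-feature estimate `FDR_i = p_i·m/rank(p_i)·π0` — an
identity the test suite asserts against the `adjust` module.

Every adjustment method yields two distinct outputs:

1. **FDR estimates** (`fdr_estimates`): the plug-in formulas
   BH `p·m/rank·π0`, BY `p·m·c(m)/rank·π0`, Bonferroni `p·m·π0`,
   Sidak `(1−(1−p)^m)·π0`, Holm/Hochberg `p·(m+1−rank)·π0`.
   No step-up/step-down smoothing is applied, so these may be non-monotone
   in rank — that non-monotonicity is informative, not a defect.
2. **Adjusted p-values** (`adjusted_pvalues`): the step-smoothed versions
   (BH/BY/Hochberg step-up minima, Holm step-down maxima, Bonferroni and
   Sidak elementwise).  π0 never enters an adjusted p-value: it is an
   estimation-side quantity only.

Both outputs are capped at 1 after all other arithmetic.  Rejection
decisions (`Reject.H0` / `FTR.H0`) always compare adjusted p-values to the
threshold γ (default 0.05).  `step_rejection_set` implements the raw
threshold search on order statistics (e.g. BH: largest *i* with
`p_(i) ≤ γ·i/m`) and is kept deliberately independent of
`adjusted_pvalues` so the two can cross-check each other; the suite verifies
their equivalence on a thousand random vectors.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `threshold` (γ) | 0.05 | rejection level for adjusted p-values |
| `pi0` / `set_pi0` | 1 | null proportion; 1 is the conservative choice |
| `by_corr` | positive | BY dependence flavour (see below) |
| `default_odds` | 1 | prior odds π1/π0 in the FDR lower bound |
| `sidedness` | two.sided | p ↔ Z convention |
| `ties_method` | random | rank tie resolution |
| `hist_breaks` | scott | bins for histogram-based π0 estimation |
| `lambda_grid` | 0.05…0.95 step 0.05 | Storey tuning grid |

**BY under negative dependence.** The harmonic sum `c(m) = Σ_{j≤m} 1/j` is
defined for flexible positive dependence; no separate factor exists for the
negative case, so the package uses the same (most conservative) harmonic sum
for both and exposes `c_by` as an overridable hook.

**Ties.** Ranks feed every rank-based formula; the default `random`
resolution uses the caller's seed or, absent one, a fixed internal seed so
repeated runs agree.  Step procedures operate on sorted order statistics,
which are tie-invariant; tied features always share the same adjusted
p-value.

**p = 0 and other edge cases.** p = 0 is clamped to the smallest positive
normal double inside the quantile transform (after any division by 2), so
Z stays finite and downstream formulas remain defined.  The lower bound is
computed in the stable form `e^(−z²/2)/(e^(−z²/2)+odds)`, which underflows
gracefully to 0 for |z| ≳ 40.  An FDR with zero selections is defined as 0.
Missing p-values are dropped by default and never inflate *m* (unlike
multiplicity corrections that count NAs as features).

## Null-proportion estimators

- **Last Histogram Height** (`last.hist`): bin the p-values into B
  equal-width bins over [0, 1]; with H_B the count in the bin adjacent to 1,
  `π̂0 = min(1, H_B·B/m)`.  Bins are half-open with the final bin closed so
  p = 1 is counted.  B defaults to Scott's rule `h = 3.49·sd(p)·m^(−1/3)`,
  `B = ceil(1/h)`, anchored at 0 and 1; a degenerate spread (sd ≈ 0 or
  h ≥ 1) falls back to `B = ceil(√m)`.
- **Storey**: `π̂0(λ) = #{p_i > λ}/(m(1−λ))` over the λ grid, smoothed and
  read off at the largest λ.  The smoother is an OLS fit on a 3-knot natural
  cubic spline basis (knots at the grid's 0/50/100% quantiles — 3 effective
  degrees of freedom), a deterministic counterpart of the conventional
  df = 3 smoothing spline.  A single-λ grid returns the raw ratio.
- **Pounds**: `π̂0 = min(1, 2·p̄)` — exact when the null mean is 1/2 and
  alternatives sit near 0.
- **set.pi0**: a fixed, user-asserted value; the default of 1 makes every
  FDR estimate conservative.

All estimates are capped into [0, 1]: the raw formulas can exceed 1 by
sampling noise.

## The Gaussian lower bound

For a single feature with test statistic z, the posterior null probability
satisfies `P(null | data) ≥ (1 + (L(θ̂)/L(θ0))·π1/π0)⁻¹`; the package uses
the asymptotic χ² form `(1 + exp(z²/2)·π1/π0)⁻¹`, which needs only z — the
exact likelihood-ratio form is unavailable to a p-value-only interface.  The
bound uses no cross-feature information, so it applies to a single test, and
its supremum 1/(1+odds) is attained at z = 0.  It benchmarks model-based FDR
estimates: an estimate below the bound signals optimistic assumptions.

## Simulation design

`simulate_pvalues` draws, per replicate, `round(m·π0)` null p-values from
Uniform(0, 1) and the rest from either Uniform(0, u) (default u = 0.01, a
sharply skewed alternative) or a Gaussian shift z ~ N(μ, σ) converted to p
under the chosen sidedness (default N(2, 1)).  Features are independent
within and across replicates; output is bit-reproducible under a fixed seed
(`numpy` Generator).

What the generator emulates: the two-group marginal distribution of
p-values at known π0, which is exactly what the π0 estimators and the
control procedures consume.  What it does not emulate: correlated test
statistics, composite or heavy-tailed alternatives, discretely supported
p-values from small-sample exact tests, or estimated (rather than
theoretical) nulls.  Passing benchmarks therefore demonstrate correctness
of the procedures under independence and the stated mixtures, not
robustness to dependence.

Benchmark scales are chosen to keep the full suite fast on one CPU:
π0-recovery grids use 200 replicates of m = 1,000 features, and
empirical-FDR checks use up to 1,000 replicates of m = 100; both are
configuration switches (`SimulationSpec.reps`, `.m`), not limits.
Monte-Carlo assertions use three standard-error bands around nominal
levels.  Evaluation cells derive their seeds from one root generator, so a
whole grid is reproducible from a single integer.

## Known limitations

- π0 estimators other than the four above (e.g. iterative or
  regression-based variants) are out of scope.
- The two-group model is Gaussian/Gaussian; f1 is not estimated from data.
- Rejection regions for the region-wise FDR are one- or two-tailed
  half-lines, not arbitrary sets.
- q-values, local fdr curves, and resampling-based FWER procedures are not
  provided.
- The `less` sidedness maps p through Φ⁻¹(p) (increasing in p) — the natural
  mirror for left-tailed tests; it is a convention choice, since only the
  two-sided and right-tailed transforms are standard.
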