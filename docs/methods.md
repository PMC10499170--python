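# Methods

## Model and tests

Data are balanced one-way within-subject layouts: N subjects each measured
under K conditions, rows drawn i.i.d. from N(μ, Σ). The fit is the additive
two-way decomposition with one observation per cell,

    SS_total = SS_treatment + SS_subject + SS_residual,
    F = [SS_treatment/(K−1)] / [SS_residual/((K−1)(N−1))],

and three p-values are always computed from the continuous F distribution
(regularized incomplete beta, so non-integer df are exact):

- unadjusted, at df (K−1) and (K−1)(N−1);
- Greenhouse-Geisser, at df multiplied by ε̂;
- Huynh-Feldt, at df multiplied by min(ε̃, 1).

ε̂ is the moment estimator applied to the divisor-(N−1) sample covariance S:

    ε̂ = K²(s̄_diag − s̄)² / [(K−1)(ΣΣ s_jj′² − 2K Σ_j s̄_j·² + K² s̄²)],

algebraically identical to Box's eigenvalue form
(Σλ)²/[(K−1)Σλ²] over the spectrum of C·S·C; the package implements both and
the test suite verifies their agreement to 1e−10 on randomized inputs. ε̃
uses the single-group Huynh-Feldt transformation

    ε̃ = [N(K−1)ε̂ − 2] / [(K−1)(N − 1 − (K−1)ε̂)],

which satisfies ε̃ ≥ ε̂ with equality exactly at the lower bound 1/(K−1) and
may exceed 1; the raw value is reported and the capped value used for the
p-value. No sphericity pre-test gates the corrections: all three p-values
are computed for every replication, matching how the study conditions are
evaluated. Mauchly's test is deliberately out of scope.

## Covariance construction

ε depends on Σ only through the centered spectrum, so matrices are built in
a fixed orthonormal basis {q₁ = 1/√K, q₂…q_K normalized Helmert contrasts}:

    Σ = q₁q₁′ + Σᵢ λᵢ q_{i+1} q_{i+1}′.

- Interior targets use the geometric spectrum λᵢ = r^(i−1), r ∈ (0, 1]. Its
  ε is strictly increasing in r (verified by a monotonicity test), so Brent
  root-finding on r hits any target; construction is deterministic.
- ε = 1 gives r = 1, i.e. the identity matrix.
- A target exactly at the lower bound 1/(K−1) would require a singular
  matrix (rank-1 centered spectrum). It is realized instead by the flat-tail
  spectrum (1, δ, …, δ) with δ = 1e−9, which lands ~1.3e−9 above the bound —
  inside the 1e−8 construction tolerance — while keeping the smallest
  eigenvalue at 1e−9, comfortably above the positive-definiteness threshold
  (smallest eigenvalue > 1e−12 × largest). The same flat-tail family, solved
  in closed form, covers off-grid targets so close to the bound that the
  geometric family's smallest eigenvalue (r^(K−2)) would fall below 1e−10.

The subject-direction eigenvalue (on q₁) is fixed at 1; it does not affect ε
or the F statistic and only enters the trace used for effect-size scaling.

Because the study's conclusions flow through ε (Box's approximation makes
the null distribution of F depend on Σ essentially through ε alone), results
from this family are expected to match results from any other family with
the same ε values up to Monte Carlo error. That is an assumption inherited
from the approximation, not a theorem; it is the reason a deterministic,
monotone one-parameter family was preferred over mimicking any particular
unstructured matrices.

## Sampling, grids and effect sizes

Blocks are generated as L·z + μ with L the lower Cholesky factor and z
standard normal. The Type I error design crosses K ∈ {3, 4, 6} with target
ε̂ grids {0.50…1}, {1/3, 0.40…1}, {0.20, 0.30…1} and 19 sample sizes
10–300: 437 conditions, all with μ = 0, α = 0.05, 10,000 replications each.

The power design uses three mean patterns per K — one mean raised
(1,…,1,2), half raised when K is even / the middle mean raised when K is
odd, and a linear trend with equal increments — crossed with each K's ε grid
excluding its lower-bound level (there ε̃ = ε̂ and the two corrections are
identical) and the same sample sizes: 1,140 conditions. Pattern deviations
are scaled so the population Cohen's f,

    f = sd(μ) / σ̄,   σ̄ = √(trace(Σ)/K),

equals 0.25 (a medium effect); scaling uses the population σ, and the
realized per-sample f is recorded alongside each condition for comparison.
Only the deviations matter to the within-subject F, so scaled vectors are
centered.

## Seeding and reproducibility

A single master seed governs a run. Each condition derives its own stream
via `SeedSequence([master_seed, condition_index])`, so any condition is
reproducible in isolation and results are bit-identical for any worker
count or execution order. Within a condition, replications are processed in
vectorized batches (capped at ~4M doubles, i.e. 32 MB per batch); the
underlying PCG64 stream is consumed sequentially, so batch partitioning does
not affect results either.

## Evaluation

Empirical rates are classified by Bradley's criteria with closed intervals:
robust if the rate lies in [2.5, 7.5] (liberal criterion) or [4.5, 5.5]
(stringent), liberal above, conservative below. Endpoint inclusivity is a
convention; boundary hits are vanishingly rare at 10,000 replications. The
robustness table groups null conditions by their target-ε label across K and
N, excludes each K's lower-bound level, and reports per-test percentages of
conditions in each class (denominators 19 / 38 / 38 / 57×5 across the
0.30–1 rows), rounded to one decimal.

The recommendation rule maps an observed ε̂ to a test: below 0.60 → F-GG;
0.60–0.90 → F-HF; strictly between 0.90 and 1 → F-HF with an advisory note
(the unadjusted test is still mildly liberal there); exactly 1 → F. The
open interval (0.90, 1) is an interpretation: the boundary between "use
F-HF" and "use F" is only defined by the grid at 0.90 and 1.

## Numerical choices

- Covariance validation: symmetry to 1e−10 relative; smallest eigenvalue
  > 1e−12 × largest; strictly positive diagonal.
- ε̂ is clipped at 1 in the ANOVA paths: round-off can push the moment
  formula a few ulp past 1 for near-spherical samples.
- ε̂ of a sample covariance skips the positive-definiteness check (rank
  min(N−1, K) suffices for the estimator; the grid's smallest N = 10 keeps
  even K = 6 full-rank).
- Degenerate inputs raise: all-equal covariance entries (ε undefined), zero
  residual sum of squares (columns differing by exact per-subject
  constants), N too small for the ε̃ denominator.
- Construction tolerance 1e−8 on realized ε; root-find tolerance 1e−15.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly as designed:
multivariate normality, a common covariance across subjects, balanced
complete data, and sphericity violations spanning the full ε range. It does
not emulate non-normal marginals, heterogeneous subjects, missing data,
between-subject factors, or covariance families with the same ε but
different higher-order structure. Passing tests therefore certify the
behaviour of the three tests under normal-theory sphericity violations
only; robustness statements do not automatically transfer to skewed or
heavy-tailed data.

## Problem sizes used by the test suite

The test suite runs the full 437-condition grid once at 3,000 replications
per condition (master seed 0, ~35 s) and widens the stochastic bounds by
three binomial standard errors at that replication count; targeted
single-condition checks (exactness under sphericity) use the full 10,000.
`scripts/acceptance.py` always uses 10,000 replications per condition.

## Known limitations

- F-GG is genuinely conservative at small N with large K and ε near 1: in
  the full grid run the smallest GG rejection rate (K = 6, N = 10, ε = 1)
  falls slightly below the 2.5% liberal-criterion floor (long-run rate
  ≈ 2.4%). The envelope claim "GG always within [2.5, 7.5]" is therefore
  marginal at that single cell; users with K ≥ 6 and N ≤ 10 should expect
  F-GG to be conservative rather than merely robust.
- Robustness-table cells whose true rates sit near the stringent bounds
  4.5/5.5 flip classes under Monte Carlo noise; only cells whose rates are
  far from the bounds (e.g. unadjusted F at ε ≤ 0.60, 100% liberal) are
  reproducible exactly.
- The ε grid uses the rounded target values; constructed matrices share
  these ε values but not any particular off-diagonal structure.
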