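# Methods

## Model and assumptions

For one SNP and K traits, the per-trait GWAS Z-scores are modelled as
**Z** ~ MVN(μ, Σ) with unit variances; Σ is the correlation of null
Z-scores across traits, assumed constant across SNPs.  This is the standard
asymptotic model for summary statistics from one cohort or from overlapping
cohorts; Σ absorbs both phenotypic correlation and sample overlap.  The
joint null is μ = 0.  All four tests depend on the data only through |Z|
and on Σ only through even functions of its entries, so they are invariant
to trait permutations and to per-trait sign conventions (which are
arbitrary — a trait and its negative are the same measurement).

## Statistics

Let S(t) = Σₖ 1{|Zₖ| ≥ t} (closed inequality) and p₀(t) = 2Φ̄(t).

**GHC.**  sup over t ≥ t₀ of (S(t) − K·p₀(t)) / √(var S(t)), where
var S(t) = K·p₀(1−p₀) + Σ_{i≠j} cov(1{|Zᵢ|≥t}, 1{|Zⱼ|≥t}) and the pair
covariances are bivariate-normal quadrant probabilities computed through
Owen's T function (absolute accuracy ~1e-15, good relative accuracy deep in
the tails).  The supremum of this process over t is attained at the observed
order statistics, so it is evaluated on that finite candidate set.  The
truncation default is t₀ = 0 (user-overridable); the 0/0 limit at t = 0 is
defined as 0.  Ties among |Z| are handled by stable rank ordering and are
harmless because the larger-count candidate dominates at a tied threshold.

**GBJ.**  For rank k with order statistic t = |Z|₍K−k+1₎, the mean shift
μ̂ₖ solves k/K = Φ̄(t−μ̂) + Φ̄(t+μ̂) (bracketed bisection on [0, t+10],
tolerance below 1e-10; 0 is returned when 2Φ̄(t) ≥ k/K).  The term is the
log ratio of P(S(t) = k) under the fitted common mean versus under the null,
each an extended beta-binomial (below) with variance matched to Σ under the
respective mean; the term is active only when 2Φ̄(t) < k/K.  GBJ is the
maximum over active ranks, floored at 0.

*Rank range.*  The default range is k = 1..K−1 ("auto").  At k = K the
defining equation targets k/K = 1, which is reached only as μ̂ → ∞; the
numerator then degenerates to a point mass and the rank-K term distorts the
deep-tail crossing probability by a factor ≈ 2.  Restricting to the ranks
whose mean-shift equation has a finite root both removes the degeneracy and
reproduces published reference values for 3-trait examples.  `"full"`
(1..K, with the degenerate μ̂ = ∞ limit) and `"half"` (1..⌊K/2⌋, the
sparse-focused variant) remain available; K = 1 always keeps its single
rank.

*Sign alignment.*  The common-mean numerator's pair covariances are not even
in σᵢⱼ (flipping one trait maps mean (μ,μ), correlation ρ to (μ,μ), −ρ).
To keep the statistic sign-invariant, the numerator couples each pair
through |σᵢⱼ| — equivalent to aligning the unknown per-trait shift signs
with the correlation, pair by pair.  The p-value is almost unaffected
(relative changes ~1e-6) because the boundary inversion uses the same term
function.

**MinP.**  p = P(max |Zₖ| ≥ c) at the observed c = max|z|, i.e. one minus a
multivariate normal rectangle probability.  Computed by regime:
K = 1 closed form; K = 2 exact inclusion–exclusion with Owen's T;
K = 3 deterministic Gauss–Legendre conditioning quadrature (one conditioning
variable, bivariate inner probabilities); K ≥ 4 exchangeable with ρ ≥ 0 a
one-factor quadrature; other K ≥ 4 the scipy Genz rectangle algorithm with a
fixed internal seed (bit-reproducible).  When the Bonferroni bound K·p₀(c)
falls below 1e-4 the union switches to truncated inclusion–exclusion ending
at the triple term (triples by conditioning quadrature); the truncation
error is bounded by the quadruple sum, negligible at such thresholds, and
the result keeps full relative accuracy at genome-wide tails where
"1 − rectangle" would lose all precision.

**OMNI.**  Equal-weight Cauchy combination of the GBJ, GHC and MinP
p-values: T = ⅓Σ tan{(0.5−pᵢ)π}, p = ½ − arctan(T)/π.  For pᵢ < 1e-16 the
tangent is replaced by its asymptote 1/(pᵢπ) and for T > 1e15 the p-value by
1/(πT); both guards preserve relative accuracy where the direct expressions
overflow.  Combining identical p-values returns them exactly.  A component
p of exactly 0 returns 0 with a warning.

## Extended beta-binomial

The count S(t) for correlated scores is approximated by the Prentice
extended beta-binomial: mean n·p, variance n·p(1−p)(1+(n−1)γ), where γ is
the common pairwise correlation of the exceedance indicators.  The pmf uses
the product parameter θ = γ/(1−γ): pmf(s) ∝ C(n,s)·Π(p+jθ)·Π(1−p+jθ), a
proper distribution (summing to one by a Vandermonde identity) whenever all
factors are non-negative, i.e. θ ≥ −min(p, 1−p)/(n−1).  γ = 0 recovers the
binomial exactly.  γ is always chosen by matching the count variance
implied by Σ; if the matched value leaves the validity region it is clamped
to the nearest valid value (this occurs only for strongly negative implied
dispersion at moderate thresholds and is diagnosed internally).

## Boundary-crossing p-values

For a supremum statistic g, the p-value is P(∃k : S(t_k) ≥ k) where t_k is
the smallest threshold at which rank k's term reaches g (the boundary is
non-increasing by construction; a final running-minimum pass enforces it
against rounding).  Inversion is by bracketed Brent iteration for single
SNPs (xtol 1e-12) and by dense per-rank grids (3000 points to t = 12,
monotonized by a running maximum, linearly interpolated) for batched
evaluation; the two paths agree to well below Monte-Carlo resolution.
Ranks whose term cannot reach g get an infinite threshold and cannot
trigger.  Statistics at or below their attainable minimum return p = 1, +∞
returns 0.

The crossing probability itself:

* **Exchangeable Σ, ρ ≥ 0** (includes Σ = I): exact.  Conditional on the
  shared factor W (Zₖ = √ρ·W + √(1−ρ)·εₖ), the indicators are iid, the
  count sequence across nested thresholds is an exact binomial Markov
  chain, and the conditional crossing mass is integrated over W with 48
  Gauss–Legendre nodes on [−9, 9].  The chain accumulates the *crossed*
  mass directly (incomplete-beta survival functions), so deep-tail values
  retain full relative precision.
* **General Σ**: the counts are approximated by a Markov chain whose
  increments are EBBs with dispersion chosen, via a variance recursion, so
  that every marginal count variance equals var S(t_k) under Σ.  The chain
  is exact at Σ = I and its first two marginal moments are exact
  everywhere; deep tails are dominated by the low-rank terms, which the
  matched dispersion reproduces at the pair level.  Accuracy was verified
  against Monte-Carlo exceedance rates (3 binomial SE at 1e5 draws) for
  K ≤ 5 and against a quadrature decomposition of the crossing event at
  genome-wide tails.

Because GBJ (and hence OMNI) has an atom at statistic 0 — no rank active —
its null p-value distribution has an atom at 1: it is exactly calibrated at
any rejection level actually attainable and conservative (super-uniform)
above, which the test suite checks in place of a plain uniformity test.

## Correlation estimation and harmonization

Σ is estimated as the Pearson correlation of the per-SNP Z-score vectors
over (approximately) independent SNPs.  LD pruning itself is out of scope —
the caller supplies an independent-SNP whitelist — and an optional |Z| cap
can exclude strong signals (default: no cap).  The estimate is symmetrized,
unit-diagonal, and eigenvalue-clipped to the nearest PSD matrix when
sampling noise makes it indefinite; estimates from fewer than 1e3 SNPs warn.
Harmonization intersects SNPs across traits (complete cases only), aligns
effect alleles to a reference trait — flipping Z where the pair is swapped,
directly or on the opposite strand — and by default drops strand-ambiguous
palindromic (A/T, C/G) SNPs, logging every action.

## Simulation design

The generator draws Z ~ MVN(μ, Σ) directly: it emulates exactly the
asymptotic summary-statistic model, with the published study conditions as
defaults (exchangeable ρ ∈ {0.1, 0.3, 0.5}; K ∈ {2, 3, 4, 10, 20}; signal
means of magnitude 2; α = 0.05 with 1e3 replicates for power, up to 1e4+
for small-α calibration; tests evaluated with the true Σ).  One of the two
published 3-trait power matrices is printed with inconsistent (0.30 / 0.50)
symmetric entries; the package symmetrizes by averaging to 0.40.  What the
generator does *not* emulate: finite-sample non-normality of Z-scores, LD
between SNPs, heterogeneous per-SNP effect distributions, or error in the
estimated Σ (an `estimate_sigma` option interposes the estimator for
end-to-end checks).  Passing simulations therefore validate the tests under
their own asymptotic model, not robustness to violations of it.
Per-cell seeds derive from a master seed plus a scenario hash, so cells are
reproducible and mutually decorrelated.  The degenerate level α = 1 is
defined to reject everything.

## Numerical choices and edge cases

* K = 1: all four tests reduce to the two-sided p-value 2Φ̄(|z|) (the
  crossing engine yields this identity; OMNI combines three equal values).
* All-zero Z with t₀ > 0: GHC falls back to the largest |z| with a warning.
* Thresholds above 40 are treated as infinite (2Φ̄ underflows).
* P-values below 1e-300 are floored and flagged in scan output rather than
  reported as 0.
* Degenerate |ρ| = 1 pairs are permitted; pair covariances remain finite.
* Scan reruns on identical inputs are byte-identical (all internal seeds
  fixed).

## Problem sizes

The test suite and the acceptance script use the published replicate counts
where stated (1e3 for the α = 0.05 cells, 1e4 for the K = 10, α = 0.01
cell) and 1e5 null draws for Monte-Carlo oracle comparisons; the worked
single-SNP examples are exact deterministic computations.  Genome-scale
inputs (millions of SNPs) are supported by the batched evaluation path,
whose per-SNP cost is dominated by a K²-state dynamic program.

## Known limitations

* The general-Σ crossing probability is an approximation; its bulk accuracy
  was verified to ~1% relative for K ≤ 5 and moderate correlation, but very
  large K with strong, highly non-exchangeable correlation is less tested.
* The Cauchy combination's null distribution is itself approximate at
  non-tail levels, producing mild OMNI anti-conservatism (observed rejection
  ~0.013 at nominal 0.01 for K = 10, ρ = 0.3 — consistent with published
  behaviour of the combination).
* Sample-overlap-aware corrections beyond the sample-correlation estimator,
  LD computation from genotypes, and multi-SNP (set-based) extensions are
  out of scope.
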