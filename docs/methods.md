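# Methods

## The factor model and the data-generating process

All evaluation data are drawn from population factor models in standardized
form. A design cell fixes the true number of factors k, the sample size n,
the indicators per factor (vpf, so p = k·vpf), the inter-factor correlation
ρ (all off-diagonals of the k×k factor correlation matrix Φ), and two
loading-magnitude bins. Each variable gets one primary loading drawn
uniformly from its bin (small [0.35, 0.5], medium [0.5, 0.65], large
[0.65, 0.8]) on its assigned factor, and a cross-loading on every other
factor from the cross bin (zero, small [0, 0.1], medium [0.1, 0.2]).
Uniquenesses are ψ_i = 1 − (LΦLᵀ)_ii, so the implied covariance
Σ = LΦLᵀ + diag(ψ) is a correlation matrix, and observations are i.i.d.
N(0, Σ).

**Admissibility and rejection granularity.** A draw is admissible when every
uniqueness exceeds 0.05 and Σ is positive definite. Because a variable's
communality depends only on its own loading row, rejection is applied row by
row: each row is redrawn until admissible (budget 5000 draws), then the
assembled model is checked for positive definiteness (budget 100 redraws).
Row-wise rejection draws from exactly the same conditional distribution as
rejecting whole loading matrices — the rows are independent given Φ — but
stays feasible in the saturated corner of the design (k = 5, ρ = 0.5, large
primary and medium cross-loadings), where only ~2% of individual rows are
admissible and a jointly admissible matrix essentially never occurs by
chance.

**Grid enumeration.** The full crossing of the design axes, with the
inapplicable axes collapsed for k = 1 (ρ = 0, no cross-loadings), yields
18 + 324 = 342 conditions. The exclusion rules are configurable; the default
is the plain crossing.

## The comparison-population generator

Both CD and CDF rest on the same generator: given empirical data and a
candidate count f, build a finite population (default 10 000 rows) whose
correlation matrix approximates the empirical one under an f-component
(unrotated, orthogonal) model while every column's marginal distribution is
a bootstrap resample of the empirical column.

The generator iterates on an intermediate correlation matrix R_int,
initialized at the empirical R. Each iteration extracts the leading f
eigenpairs of R_int (eigenvalues clipped at zero), forms component loadings
L = V_f √λ_f and unique variances 1 − communality (floored at zero),
generates scores shared + unique from standard normals, and imposes the
fixed marginals by rank substitution — within each column the sorted
bootstrap values replace the generated values in rank order, which preserves
the marginal multiset exactly while keeping the generated rank structure.
Fit is the RMSR over the p(p−1)/2 off-diagonal residuals between the
empirical and the population's correlations (distinct from CD's RMSR over
eigenvalues). On improvement the candidate is kept and R_int steps toward
the residual (step starts at 1.0); on failure the best R_int is restored,
the step halves, and a stalled trial is counted. The search stops after 5
consecutive stalled trials or 300 iterations and returns the best candidate.
If R_int drifts indefinite, it is repaired by clipping its spectrum at zero
and renormalizing the diagonal (logged at debug level). Replicate data sets
are simple random samples of n rows without replacement within a sample and
independent across samples.

## The three retention criteria

**CD.** One population per candidate f, reused for all N_rep samples; each
sample's fit is the RMSR between its eigenvalue profile (full correlation
matrix, principal-component convention) and the empirical profile. The
sequential test is an unpaired one-tailed Mann–Whitney U ("(f+1)-factor
RMSRs stochastically smaller than f-factor RMSRs"), exact by enumeration for
combined sizes ≤ 12 without ties, otherwise the tie- and
continuity-corrected normal approximation. The estimate is the last f whose
improvement test was significant at α; reaching k_max (default 8) with all
tests significant returns k_max with a `censored` flag so bias analyses
still get a numeric estimate.

**CDF.** Populations for all f = 1..k_max are generated up front; N_rep
samples per population are summarized by the feature vector below and train
a random forest (500 trees, ⌊√(#features)⌋ split candidates, unrestricted
depth, bootstrap per tree, out-of-bag accuracy recorded). The empirical
feature vector is classified; k̂ is the class with the largest vote share,
ties resolving to the smallest count (the underfactoring-averse convention).
Vote shares are exposed as diagnostics.

**Feature set.** n, p, p/n; the full eigenvalue profile λ₁..λ_p; cumulative
explained-variance proportions for the first min(p, 10) eigenvalues (capped
so the schema is stable across the design's range of p); counts of
eigenvalues above 1 and above 0.7; det R; Frobenius, induced-1, max-entry
and spectral norms of R; mean and SD of the off-diagonal |r|; Gini and Kolm
(aversion 1) inequality of the off-diagonal |r|; and the proportion of
|r| ≥ 0.3. Within one CDF run all comparison sets share (n, p), so those
two features are constants for the forest; they are kept in the schema so
feature tables from different data sets remain comparable.

**EKC.** References ref_j = max{[(p − Σ_{i<j} λ_i)/(p − j + 1)]·(1+√(p/n))²,
1}; k̂ is the length of the initial run of eigenvalues strictly above their
references (a stopping index, not a count of scattered exceedances). The raw
estimate may be 0; study aggregation floors it at 1, since a retention
criterion must propose at least one factor. n is used as-is (no n−1
correction); at the design's sample sizes the distinction is far below
sampling noise.

## The evaluation harness

Each (condition, replication) cell generates one data set from a
cell-specific seed stream; every method receives that same data set with its
own derived stream (paired design, which sharpens method contrasts).
Records journal to JSON lines, so interrupted runs resume without repeating
finished cells, and cell streams are derived from (master seed, condition
index, replication) so results do not depend on execution order. Aggregation
computes accuracy (exact recovery rate), bias (mean k̂ − k), and
under-/overfactoring rates, which partition to 1 by construction. The
agreement analysis joins two methods on their shared cells and reports the
agreement rate, the accuracy of the shared answer given agreement, and
frequency/conditional accuracy per level of k̂_A − k̂_B.

## Problem sizes and the smoke grid

Full-fidelity settings (N_rep in the thousands, populations of 10 000+) make
a single CDF application a minutes-scale computation and the full grid a
batch job. The shipped smoke configuration is a stratified 12-condition
subset — four cells per true k spanning both vpf levels, all sample sizes,
orthogonal and correlated factors, and all three primary-loading bins, with
the k = 1 cells weighted toward few variables and weak loadings (the hardest
one-factor stratum) and the k = 5 cells toward correlated, weakly measured
structure (where method differences are largest). Desk-scale budgets are CD
α = .05 / N_rep = 100, CDF N_rep = 200, populations of 2000 rows; the
acceptance script runs this grid at 10 replications in ~7 minutes on one
CPU, and the test suite at 6 replications. At these budgets absolute
accuracies are well below full-scale values — CD's sequential test loses
power and underfactors more, and the hard-corner weighting lowers every
method — so the quantities to read are the orderings and signs, not the
levels.

## What the generator does and does not emulate

The simulator produces exactly standardized multivariate normal data with
independent-cluster-plus-cross-loading structure and equicorrelated factors.
It does not produce non-normal or ordinal indicators, missing data,
model-error populations (e.g., minor nuisance factors), or unequal loadings
within a bin beyond the uniform draw. Passing results therefore speak to
the methods' behavior under a correctly specified normal factor model;
robustness to categorical indicators or distributional misfit is outside
this package's evidence.

## Known limitations and open choices

- Whether replicate comparison data sets should be drawn with or without
  replacement from the population is not settled usage; this implementation
  samples rows without replacement within each replicate, with independent
  draws across replicates.
- The Mann–Whitney comparison treats the f- and (f+1)-factor RMSR samples as
  unpaired, which matches their construction here (independent draws).
- Tree-vote ties resolve downward; with 500 trees ties are rare and the
  convention matters only in pathological cases.
- In this implementation CDF does not display the strong one-factor
  overfactoring sometimes reported for forest-based retention at small
  N_rep and large n; one-factor accuracy here tracks classical CD closely.
  The per-condition diagnostics the harness records make that behavior easy
  to monitor on new configurations.
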