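# Methods

## Problem setting

Two populations of a diploid outbreeding species exchange migrants and
have diverged only weakly (genome-wide F_ST of order 0.01). Sample sizes
are small — the emulated design is 11 + 7 sequenced individuals — and the
question is which SNPs are more differentiated between habitats than
population structure and drift explain. Everything downstream of a joint
multi-sample VCF is in scope; read mapping, variant calling and genotype
likelihoods are upstream tools this package deliberately does not
reimplement.

## Site filters

Four hard rules, applied in a fixed order so that per-rule tallies are
well defined:

1. **Depth mask** — a genotype with DP < `min_depth` (default 4) is set
   to missing. Masking precedes the missing-rate test so low-coverage
   calls count against a site. The per-genotype reading of "minimum
   coverage" is a design choice; a site-mean reading would be laxer, and
   switching to it only needs a different mask in `apply_filters`.
2. **Bi-allelic restriction** — multi-allelic records are read intact
   (dosage = count of non-reference alleles) but dropped here;
   decomposition is out of scope.
3. **Missing rate** — per-site missing fraction ≤ `max_missing_rate`
   (default 0.05). At 18 samples this is strict: one missing genotype is
   5.6%, so effectively only fully called sites pass. That is the
   intended behaviour of a 5% rule at this sample size, and tests and
   the acceptance script inherit it.
4. **Folded MAF** — min(p, 1−p) ≥ `min_global_af` (default 0.05) over
   non-missing genotypes. The folded reading is the population-genetics
   convention; an unfolded rule would keep alt-frequency-0.96 sites that
   carry the same information as alt-frequency-0.04 sites it discards.

Filtering is idempotent, never alters a retained dosage except by depth
masking, and reports counts that sum to the input site count (enforced
in the `FilterReport` constructor).

## PCA and the PC1 covariate

Genotype PCA is an SVD of the samples × sites dosage matrix after
per-site mean imputation of missing cells and centring by 2p̂. The
default `patterson` scaling divides each site by √(p̂(1−p̂)), the
binomial standard deviation, which equalises site contributions and is
standard for genotype data; `center_only` is available because generic
PCA tools differ here and the choice moves the variance-explained
percentages. Monomorphic sites are dropped in `patterson` mode (zero
information, undefined scale). Mean imputation guarantees a missing cell
contributes exactly zero to every between-sample difference — the least
assumptive choice, at the cost of shrinking admixed or low-coverage
samples toward the centroid. Axis signs are fixed deterministically
(largest-magnitude loading positive); they are the only indeterminacy.

Within-group cohesion is summarised as the mean ± sd of pairwise
Euclidean distances among a group's projections over all retained axes
(no axis cutoff; population sd, so a two-sample group reports sd 0).

## KING-robust kinship

For each sample pair, over jointly called sites:
φ = (N_het,het − 2·N_opposite-homozygote) / (N_het(i) + N_het(j)).
This estimator needs no allele-frequency estimates, which is what makes
it robust under structure; duplicates give exactly 0.5, parent–offspring
≈ 0.25, and cross-population pairs go negative. The diagonal is fixed at
0.5 by convention. Values are clipped to [−1, 0.5]; a pair with no
heterozygous calls at all is undefined (NaN, with a warning).

## Weir–Cockerham F_ST

Per site, variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed
from per-population sample sizes, alt-allele frequencies and observed
heterozygote frequencies via the standard n̄ / n_c / p̄ / s² / h̄
formulation (written out in `diff_stats.py`); θ = a/(a+b+c). Choices:

- Negative per-site θ is **retained**, not truncated: truncation would
  bias the top-decile threshold used for candidate curation.
- Sites with a+b+c ≤ 0 or an entirely missing population have undefined
  θ and are excluded from the quantile, but defined components still
  enter the genome-wide sums.
- The genome-wide value is the ratio of averages Σa/Σ(a+b+c) — much less
  biased at low-information sites than averaging per-site ratios.
- The outlier threshold is the empirical 0.90 quantile under numpy's
  linear interpolation rule (recorded in the output), with **strict**
  inequality for the above-threshold mask; quantile conventions differ
  across tools and change the threshold at the third decimal.

## The association scan

Each individual's alt-allele count at a SNP is a binomial response with
2 trials. Two nested logistic models are fitted (intercept + PC1;
intercept + PC1 + binary site label) by iteratively reweighted least
squares, batched across all SNPs at once: the design matrix is shared
within a replicate, missing genotypes enter with zero weight, and the
per-SNP 2×2 / 3×3 normal equations are solved in a stacked array. This
is what makes L × (n_perm + 1) model fits cheap (a 2000-SNP scan with
100 permutations takes a few seconds on one core).

Numerical choices: max 50 IRLS iterations, convergence when the deviance
changes by < 1e-8, linear predictor clipped at ±30 (so complete
separation — common at strongly differentiated sites with 18 samples —
plateaus instead of overflowing), a 1e-10 ridge on the normal equations
to survive degenerate weights, and a `boundary` flag when any fitted
|logit| exceeds 15. Non-converged or boundary fits keep their deviance
at the last iterate; the scan reports per-SNP convergence counts so
users can mask unstable sites rather than having them silently dropped.

The LRT statistic is deviance(null) − deviance(full), floored at 0,
with a χ²(1) p-value. That reference distribution is not trusted at
these sample sizes; it is only a monotone transform feeding the
permutation comparison:

- Each replicate draws one uniform permutation of the label vector over
  individuals and applies it to **every** SNP — preserving between-SNP
  correlation in the null and keeping the cost linear in n_perm. PC1 is
  not recomputed under permutation: it is the structure covariate, and
  only the habitat assignment is exchangeable under the null.
- Per SNP, significance requires the real p-value to **strictly** beat
  at least ⌈0.95·n_perm⌉ of that SNP's own permuted p-values. Ties fail;
  an uninformative SNP whose p-value is 1 under every labelling is never
  significant. A pooled mode (real p compared against all SNPs' permuted
  p-values) is available behind a flag for users who prefer a common
  null.
- The real labelling is not excluded from the permutation draw (sampling
  is uniform over arrangements), and no multiple-testing correction is
  applied beyond the permutation rule and the F_ST intersection.

Candidates are the SNPs significant in the scan **and** strictly above
the F_ST top-decile threshold; the candidate set is by construction a
subset of both.

## The simulator

Balding–Nichols rather than a coalescent: it parameterises the one
structure statistic the pipeline estimates (population frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F) around a Uniform(0.05, 0.95) ancestral
draw, so expected F_ST ≈ F), needs no external machinery, and produces
independent sites — matching the scan's per-SNP model. Defaults are the
emulated study conditions: 11 + 7 individuals, 5000 sites, F = 0.0084,
16 planted loci at divergence 0.6, 20% admixed individuals with up to
50% ancestry from the other population, 5% missing genotypes, constant
depth 10.

Planted loci use an exact symmetric offset ±d/2 around an ancestral
value redrawn from the subinterval where the offset stays inside
[0.01, 0.99], so the gap is exactly d and both populations remain
polymorphic; an infeasible divergence raises with a suggestion to widen
the bounds. Admixture is per-allele: each of an individual's two alleles
comes from population 1's frequency with probability q, which yields the
continuous PC1 gradient of gene-flow-connected samples.

What the simulator does **not** emulate: linkage disequilibrium,
demographic history, variable depth, genotyping error, and reference
bias. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed model, not that real data meet
those assumptions — with LD, for instance, the effective number of
independent tests is smaller and candidate SNPs cluster.

## Validation design and problem sizes

The test suite checks every estimator against an independent oracle:
step-by-step scalar evaluation of the variance-component formulas,
numerical maximisation (BFGS + Nelder–Mead) of the binomial
log-likelihood, brute-force eigendecomposition for PCA, exhaustive
enumeration for distances and set intersections, and Mendelian
simulation for kinship. Simulation-based checks run at reduced but
statistically meaningful sizes chosen to keep the default suite around a
minute: permutation calibration at L = 2000 × 10 seeds × 100
permutations (mean null significance rate must land in [0.01, 0.09]
around the ~5% the 95%-rule implies), parameter recovery at
F ∈ {0.005, 0.01, 0.05} × 50 seeds × L = 5000 (median relative error
≤ 25%), planted-outlier power over 10 seeds (≥ 80% of planted loci in
the top decile on average). Recovery checks switch admixture off,
because admixed individuals are gene flow after divergence and
systematically lower realised F_ST below the divergence parameter being
recovered — a property of the model, not an estimator error.

## Known limitations

- Per-SNP fits with 18 individuals separate easily; boundary fits are
  flagged, not resolved (no Firth correction).
- The scan path supports exactly two populations (the component math
  handles r ≥ 2).
- The 5% missing-rate rule interacts with sample size as described
  above; users with few samples who want to keep singly missing sites
  must raise `max_missing_rate` explicitly.
- `--threads` is accepted for interface stability but the implementation
  is single-threaded NumPy; results are independent of it by
  construction.
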