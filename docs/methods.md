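# Methods

## The statistical model

`gxeblup` fits mixed linear models for line-by-environment trial records

    y_ij = mu + E_i + L_j + g_j + a_j + gE_ij + aE_ij + e_ij

in which every non-fixed term is random with a known covariance kernel.
Environments (company-year-location cells) and lines enter with identity
covariance; the genomic breeding value g uses the VanRaden relationship
matrix G built from SNP dosages; the pedigree breeding value a uses the
numerator relationship matrix A; and the two genotype-by-environment terms
use record-level Hadamard products, e.g. Cov(gE) = (Zg G Zg') ∘ (Ze Ze')
σ²gE. Including both the line effect L and the additive terms partitions
genetic variance into additive (marker/pedigree) and non-additive residual
genetic components; including both g and a partitions the additive variance
into what markers and pedigree each capture (`partition_additive` reports
the shares VR_G and VR_A). The six named models (ELG, ELG-GxE, ELA, ELA-AxE,
ELGA, ELGA-GxE-AxE) are subsets of the full term set.

### Relationship matrices

*Marker QC.* Markers are dropped if monomorphic among non-missing calls or
if more than 10% missing (a marker at exactly 10% is kept; the threshold is
strict). Remaining holes are imputed by drawing from the marker's empirical
genotype-code distribution, with an RNG stream keyed by (seed, marker index)
so the result is independent of column processing order. Allele frequencies
for centering are computed from the observed (pre-imputation) calls so the
imputation draws cannot shift the centering target.

*G.* The default is the classical centered VanRaden form
G = XcXc'/(2Σp(1−p)). A `centered-standardized` mode (unit-variance columns,
divided by marker count) is exposed because both variants circulate in the
literature under the same name; the centered form is the one whose printed
denominator matches the formula above. The grand sum of a self-centered G is
zero by construction.

*A.* Built by the tabular recursion (founders: diagonal 1; offspring row =
half the parents' rows; diagonal 1 + half the parents' relationship).
Unknown parents are unique unrelated non-inbred founders. For fully inbred
line programs the `assume_fully_inbred` option (default in the pipeline)
rescales to the identity-by-descent probability scale — diagonal forced to
1, off-diagonals a_ij/√(a_ii a_jj) — giving entries in [0, 1] that are
directly interpretable as IBD probabilities between homozygous lines. The
raw tabular matrix remains available for testing against gene-dropping
expectations.

## Gibbs sampler

Each random term's record-level kernel is eigendecomposed once
(K = U D U'); in that rotated basis the effect coordinates are a priori
independent, U has orthonormal columns, and the full conditional update is a
set of independent scalar normals — two matrix-vector products per term per
iteration. Numerical details:

- Eigenvalues below 1e-8 of the largest are truncated (rank-deficient
  kernels, e.g. line kernels with fewer lines than records, are handled
  exactly on their support).
- The interaction kernels are block-diagonal over environments (the
  environment-incidence Hadamard factor zeroes all cross-environment
  entries), so their eigenbases are computed per environment block and
  stored sparse. This is exact, not an approximation, and makes the cost
  scale with the largest environment rather than the record count.
- Variances get scaled inverse-chi-square full conditionals; fixed effects
  (intercept, optionally the breeding-program covariate in across-company
  analyses) have flat priors and a joint normal update.
- A recentering move shifts the mean of each identity-kernel term (E, L)
  into the intercept each sweep. The move preserves the posterior (the
  likelihood is invariant, the shift is sampled from its own conditional)
  and removes the slow random walk between the intercept and the term
  means that otherwise dominates the autocorrelation of E.
- A chain that drives the residual variance beyond 1e12 times the phenotypic
  variance aborts with a divergence error.

*Priors.* Scaled inverse-chi-square with df = 5 per variance; each term's
scale is set so its prior mode equals an equal share of half the sample
phenotypic variance, normalized by the kernel's mean diagonal (the R² = 0.5
convention of standard Bayesian genomic-prediction software); the residual
gets the other half. These are weakly informative at trial scale but not at
toy scale — see *Calibration* below.

*Defaults.* 12,000 iterations, 2,000 burn-in, thinning 5. Reported
estimates are posterior means. Validation experiments in the test suite use
shorter chains (listed per experiment) after checking quarter-by-quarter
stability of the variance traces.

*Correctness checks.* With variances held fixed, posterior-mean effects are
compared against the direct GLS/mixed-model-equations solution (dense-matrix
oracle) using per-effect batch-means Monte-Carlo standard errors. The full
sampler's marginal posterior of the variances was verified against a
brute-force grid posterior on a small conjugate instance (agreement to four
decimals).

## Prediction and cross-validation

Breeding values for unphenotyped lines come from kernel regression on the
relationship matrix: ĝ_new = G(new, train) G(train, train)⁺ ĝ_train
(pseudo-inverse on the truncated eigenbasis); interaction effects for a new
line in an observed environment are predicted the same way within the
environment block. Three prediction compositions exist:

- `breeding_value`: ĝ + â — used for forward schemes (CV0, CV00), where the
  validation year is unobserved and environment or interaction contributions
  are undefined (zero).
- `breeding_value_interaction`: adds ĝE + âE for observed environments —
  the CV1/across-company default. The environment main effect is
  deliberately excluded from correlated predictions: with per-genotype
  aggregation, crediting Ê would correlate the trial layout (which
  environments a genotype happened to be in) with itself and manufacture
  "ability" even at zero heritability; the zero-genetic-variance null
  experiment confirms ability ≈ 0 under this composition.
- `full`: adds Ê and L̂ — used when forecasting actual phenotype levels.

CV1 deals lines (all their records together) into k = 10 folds by default;
CV0 trains on all years before the target year; CV00 additionally restricts
validation to lines never seen before the target year and excludes all
target-year records from training. Ability is the Pearson correlation of
one (mean observed, predicted) pair per validation genotype, averaged over
folds, with the SE of the fold correlations; a record-level pairing is
available as an option. Across-company CV mixes both programs in training,
validates on one program's lines only, and adds the breeding program as a
fixed covariate.

## Heritability from unbalanced data

    h² = (σ²g + σ²a)/σ²y,   H² = (σ²L + σ²g + σ²a)/σ²y,
    σ²y = σ²L + σ²g + σ²a + σ²gE/mh + σ²aE/mh + σ²R/ph

with mh and ph harmonic means over genotypes of environment and plot counts
(plot counts default to record counts when plot-level replication is not
recorded). The line variance is included in σ²y: a phenotypic variance that
excludes a genetic component it is meant to normalize would allow H² > 1.
Absent model terms contribute zero. On balanced designs the formula reduces
exactly to the textbook closed form.

## Synthetic data generator

The generator emulates a two-company line-testing program: a shared founder
pool; biparental crosses giving full-sib subfamilies (sizes from a shifted
geometric distribution clipped to 2–24, right-skewed as in real programs)
plus singleton crosses; inbred-line development by several generations of
single-seed descent; SNP genotypes by gene dropping with Haldane
recombination (uniform marker spacing, one Morgan per chromosome); lines
split between the companies and phenotyped in a random subset of their own
company's environments (each cell kept with probability 1 − missing
fraction, at least one per line). Phenotypes are drawn from the full
interaction model above with user-set variance components; by default the
genomic and pedigree channels are drawn independently from G and A (a
`combined` mode draws a single additive value from G for workflows that
treat g/a as a fit-time decomposition).

Defaults are study-scale: ~900 lines (186 families + 86 singletons from 60
founders), 5,000 markers on 7 chromosomes, 14 environments (one company
with 3 years × 3 locations, the other 3 years × 2/1/2 locations), 55% of
line-environment cells missing (≈ 3.4 records per line), intercept 10.48 and
variance components (0.58, 0.02, 0.04, 0.03, 0.01, 0.01, 0.10) for
(E, L, g, a, gE, aE, residual) — the magnitudes of a protein-content
analysis where environment dominates and genetic effects are small.

What the generator does *not* emulate: QTL architecture (genetic values are
kernel draws, not marker-effect sums), selection during line development,
founder linkage disequilibrium beyond what gene dropping induces, and
location-specific management trends. Passing tests therefore demonstrate
the estimators are correct for the stated model, not that the model is
adequate for any particular real trial system.

## Calibration and validation experiments

`gxeblup.validation` packages three end-to-end experiments (used by the
test suite and the reproduction script):

- **Credible-interval recovery** — simulate at the default truth, fit the
  generating model, count how often each true variance lands in its central
  90% credible interval over seeded replicates. At the reduced experiment
  scale (~420 lines, 14 environments, ~1,500 records; chains 4,000/1,000)
  the well-identified components (E, g, a, gE) sit near nominal coverage,
  but the weakly identified ones do not: the pedigree-by-environment
  variance is near-confounded with the residual and with the marker
  interaction channel, and along that likelihood ridge the df = 5
  equal-share prior (mode ≈ 0.06 per term against truths of 0.01–0.02)
  pulls the posterior away from the truth. This persists at the full
  ~900-line scale and with well-mixed long chains, and weakening the prior
  moves the estimates toward truth — i.e. the intervals are the correct
  posterior, and the shortfall is frequentist under-coverage of Bayesian
  intervals for weakly identified variance components, a known phenomenon
  rather than a sampler defect. The corresponding test asserts nominal
  coverage and is expected to fail for those components; it is kept as an
  honest record of this limitation.
- **CV1 null** — zero genetic variance; mean ability over replicates should
  be within two standard errors of zero (it is).
- **Scheme-dependent interaction gain** — with substantial true
  marker-by-environment variance, the interaction model beats the
  main-effect model under CV1 (environments observed, interactions
  predictable) while the CV00 gain is smaller (year unobserved,
  interactions unpredictable).

Problem sizes for all experiments were chosen as the smallest at which the
properties under test are identifiable; each is stated in the experiment's
signature and defaults.

## Known limitations

- No REML/EM alternative estimator; no model-comparison criteria; kernel
  (RKHS) parameterization only — equivalent to marker-effect models for
  prediction but it does not produce per-marker effect estimates.
- The pedigree module does not compute A-inverse (not needed for
  kernel-based sampling) and does not reconcile pedigree against markers.
- Imputation is marginal per marker; no LD-aware imputation.
- Weakly identified variance components (small interaction variances in
  unbalanced designs) carry prior influence at any realistic scale; report
  credible intervals, not point estimates, for those.
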