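# Methods

## The problem

Genome-wide marker-wise association in family-based cohorts must cope with
the dependence that family structure induces between individuals.  If the
relationship structure is known, the textbook remedy is a linear mixed
model with a family random effect whose covariance is proportional to the
kinship (relationship) matrix.  When it is not known, two pragmatic coping
strategies exist: treat everyone as independent, or keep one randomly
drawn representative per family and analyze the subsample as independent.
This package implements all three strategies on a common simulation and
comparison harness, so that their ranking behavior — which markers each
strategy places in its top-k set, how much the sets overlap, and how many
true signals each recovers — can be studied under a known generating
model.

## Generating model

For marker j the response vector over n individuals is

    y_j = delta_j * 1 + mu_j + eps_j,
    mu_j ~ N(0, sigma2_mu * K),   eps_j ~ N(0, sigma2_eps * I_n),

so Cov(y_j) = sigma2_mu * K + sigma2_eps * I_n.  K is block-diagonal by
family; within a family it is exchangeable with unit diagonal and
off-diagonal `within_value` (0.5 = full siblings).  `delta_j` equals
`effect_delta` for the `m_causal` causal markers (drawn without
replacement from the marker index by the dataset seed) and 0 otherwise,
i.e. the alternative is a shifted response mean.  Markers are independent
given K.

Matrix convention: we store the *relationship* matrix K = 2 Phi (unit
diagonal for non-inbred individuals, 0.5 between full siblings), where Phi
is the kinship-coefficient matrix.  Any overall scale of K is absorbed
into sigma2_mu, so the convention is free; it is fixed once and used
everywhere.  Founders are assumed non-inbred and unrelated across
families; simulated families are pure sibships (founders latent), so the
pedigree-derived K restricted to siblings equals the exchangeable block
matrix exactly (this identity is tested).  Individuals are ordered
family-major (families in order of first appearance, insertion order
within family) and all matrices and vectors share that ordering.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `n_families` | 200 | sibship families |
| `family_size` | 5 | siblings per family (n = 1000) |
| `m_markers` | 1000 | markers per study |
| `m_causal` | 10 | markers under the alternative |
| `effect_delta` | 0.5 | mean shift under the alternative |
| `sigma2_mu` | 1.0 | family (polygenic) variance |
| `sigma2_eps` | 1.0 | residual variance |
| `within_value` | 0.5 | within-family relationship (full sibs) |

The family sizes, variance components and effect size are design choices
of this package (the comparison they support is qualitative): family_size
5 makes n a round 1000; unit variance components split phenotypic variance
evenly between family and residual sources, a heritability-like fraction
of 0.5 that is typical for the quantitative traits this design emulates.
With these values the per-marker Wald statistic of the kinship option at a
true effect is delta * sqrt(1' V^-1 1) ≈ 7.9 (and ≈ 5 for the
representative option at n = 200), so all three options operate near power
1 for individual causal markers; the interesting differences are in the
*ranking* behavior — which null markers fill the rest of the top-k set —
and in false-positive control, not in raw power.  A consequence worth
stating: with equal-size exchangeable families the vector of ones is an
eigenvector of V, so the kinship-option GLS intercept estimate coincides
with the plain mean used by the independence option, and those two options
differ only through their standard errors.  The kinship and independence
top-k sets therefore overlap heavily by construction of the design, while
the representative option, ranking on a 200-individual subsample, diverges
— which is exactly the regime the comparison harness is built to exhibit.

`mode="covariate"` is an extension that embeds the signal in the
coefficient of a continuous exposure within a realistic fixed-effect
design (intercept, exposure, age 20–80, balanced binary sex and site, and
four orthonormal mean-zero PC-like columns, 9 columns in total); the
tested coefficient is then the exposure's.  Mean-shift mode is the
default and is what the acceptance checks use.

## Kinship computation

`kinship_from_pedigree` implements the standard recursion on a
parents-first ordering: Phi_ii = (1 + Phi_{f,m})/2 and
Phi_ij = (Phi_{i,f(j)} + Phi_{i,m(j)})/2 with founders unrelated and a
missing parent contributing zero.  It is validated against an independent
gene-dropping oracle (Monte-Carlo transmission of uniquely labeled founder
alleles, expected allele sharing over 1e5 loci) on random pedigrees;
agreement is required within 3 Monte-Carlo standard errors entrywise.
Inbreeding loops and X-linked kinship are out of scope.

## Variance components

**REML (default).**  One symmetric eigendecomposition K = U D U' per
(design, kinship) pair diagonalizes the covariance; after rotating y and X
by U' the restricted likelihood is profiled down to the variance ratio
lambda = sigma2_mu / sigma2_eps.  The profile is maximized on
log lambda ∈ [−10, 10]: a 100-point coarse grid followed by bounded
scalar refinement (absolute tolerance 1e-8 on log lambda).  Degenerate
cases:

* flat profile (e.g. K = I, where only the total variance is identified):
  likelihood ties within 1e-10 resolve to the lower boundary, giving
  sigma2_mu = 0 and sigma2_eps = the residual mean square — so the kinship
  option collapses exactly onto the independence option when K = I;
* optimum at the upper grid edge: lambda is clamped there and flagged;
* constant response (zero residual variation): both components 0.

All boundary resolutions set `boundary=True` in the output so downstream
consumers can audit them.  Because the whole grid is evaluated in one
vectorized pass across markers, a 1000-marker study fits in a few seconds;
single-marker and batched paths share the same grid-and-refine code and
agree to the refinement tolerance.

**ANOVA / method of moments.**  A Haseman–Elston-type estimator kept for
comparison: regress the off-diagonal products of OLS residuals e_i e_j on
K_ij without intercept to get sigma2_mu, then sigma2_eps = residual mean
square − sigma2_mu (K has unit diagonal).  Negative estimates clamp to
zero with the boundary flag.  It requires variation in the off-diagonal of
K and is noticeably noisier than REML on unbalanced designs (tested); it
is unbiased up to the OLS-projection term of order p/n, which is
negligible at the study sizes used here.

## Per-marker testing

Fixed effects are estimated by GLS under the plugged-in covariance
V = sigma2_mu K + sigma2_eps I (computed spectrally for the kinship
option, via Cholesky in the generic `gls_fit`); the representative and
independence options reduce to OLS with the classical variance estimate.
The tested coefficient is the intercept (mean-shift mode) or the exposure
(covariate mode).  Wald p-values use the standard normal reference for all
options — n is at least 200 throughout — with an optional Student-t
reference (residual degrees of freedom) intended for the representative
option at small family counts.  Variance components are re-estimated
independently per marker; nothing is shared across markers except the
eigendecomposition of K, which is marker-free.

## Comparison harness

Significance is defined by top-k rank (ascending p, ties broken by marker
index), k = 20 for the simulation protocol and k = 100 for cohort-scale
tables.  For three options A = representative, B = kinship,
C = independence the harness reports the 7 exclusive Venn regions, truth
recovery (true positives and FDR = fraction of the reported set that is
not a true signal), a nestedness diagnostic (the idealized expectation
A ⊆ B ⊆ C is reported on, never asserted — it fails in practice and the
escape counts quantify how), and the hybrid strategy: the intersection of
the independence and representative top-k sets, the recommended fallback
when kinship coefficients are unavailable.

`run_study` replicates the full pipeline: per replicate it simulates a
dataset, fits kinship and independence once and the representative option
once per representative draw (default 3 replicates × 5 draws), and
aggregates region counts and recovery metrics with sample mean and SD
(ddof = 1) across runs.  Averages could reasonably be taken over
replicates, over draws, or over both; the per-run table keeps both axes so
either marginal can be recomputed, and the bundled aggregate pools them.  All seeds derive from the study seed through a splittable
`SeedSequence` counter scheme ((seed, replicate) for simulation,
(seed, replicate, 1000 + draw) for representative draws) and are logged in
the report.

## What the simulation does and does not emulate

The generator reproduces the *structure* that matters to the comparison:
sibship families with known exchangeable relatedness, marker-wise
responses with a family variance component, sparse mean-shift signals, and
(optionally) a realistic covariate block.  It does not simulate genotypes,
allele frequencies, linkage disequilibrium, methylation chemistry, or
varying family sizes; real cohorts have all of these.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
ordering of the strategies under the stated model — not quantitative
transfer of any overlap count to a particular real dataset.

## Numerical choices

* Eigenvalues of K are clipped at zero after `eigh`; K is accepted if its
  smallest eigenvalue is ≥ −1e-8 (relative) and declared PSD at −1e-10 in
  the container's own check.
* GLS never inverts V explicitly: Cholesky solves, with a
  condition-number diagnostic on failure.
* p-values are floored at 1e-300 to stay in (0, 1].
* Kinship TSV files print ≥ 10 significant digits so round-trips preserve
  the matrix to working precision.
* Batched and single-marker REML differ only by floating-point
  accumulation order; downstream quantities agree to ~1e-6 relative, which
  is far below any statistical resolution used here.

## Problem sizes used by the checks

The replicated comparison study runs 20 replicate studies × 5
representative draws at the default design (20,000 kinship REML fits in
total); type-I error uses 5000 null markers; REML recovery uses 100–200
replicates at n = 1000; the gene-dropping oracle drops 1e5 loci per
pedigree.  These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands while keeping a full run in the low minutes on one CPU.

## Known limitations

* Equal family sizes make the intercept GLS and OLS estimates coincide
  (see above); with unequal families the kinship option would also
  dominate on efficiency of the point estimate.  The package supports
  arbitrary K, but the bundled generator only produces balanced sibships.
* The Wald/normal reference slightly inflates the kinship option's type-I
  error at small family counts (the effective degrees of freedom are the
  number of families); at the default 200 families the inflation is within
  the tested 3-SE band.
* Per-marker REML at the grid edges is clamped, not profiled further; with
  1000 individuals this affects only markers whose family variance is
  estimated at zero, where the model collapses to OLS anyway.
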