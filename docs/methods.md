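# Methods

## Model

For one analysis unit (a SNP or a gene) with g genetic variants and p
disease traits, the canonical correlations between the genotype block X and
trait block Y are the singular values of
W = Σ_XX^(−1/2) Σ_XY Σ_YY^(−1/2).  With individual-level data the blocks
would be the sample moments of one dataset; here they are estimated from
three different sources:

- **Σ_XY** (g×p): standardized regression coefficients
  β_std = β / (SE·√n).  For standardized genotype and phenotype, the
  univariate OLS identity gives β/SE ≈ √n·cor(x, y), so β_std approximates
  the genotype–trait correlation.  This is verified in the test suite by the
  regression-identity check (agreement with the sample correlation within
  2/√n).
- **Σ_XX** (g×g): the Pearson correlation of reference-panel dosage columns.
  The reference panel must match the study ancestry; it is the only
  genotype-level input.
- **Σ_YY** (p×p): the Pearson correlation between the columns of the
  standardized-beta matrix, computed over **all** harmonized SNPs, before
  pruning.  Under the null, per-study z-scores are proportional to the
  phenotypic correlation structure (shared controls aside); the estimate
  improves with the number of SNP rows, which is why it uses the full
  harmonized set even though the scans run on the pruned subset.

Significance: Wilks' Λ = Π(1−r_i²) over all min(g, p) canonical
correlations, with Bartlett's approximation
χ² = −(n_eff − 1 − (g+p+1)/2)·ln Λ on g·p degrees of freedom.  The p-value
construction is validated by null simulation (KS uniformity and binomial
bounds on type-I error at α = 0.05) rather than by citation; a
leading-root-only variant was considered and rejected because the
all-roots statistic is the standard likelihood-ratio analogue and calibrates
correctly in the null simulations.

The central correctness oracle is exact equivalence: when the three blocks
are the sample moments of one individual-level dataset, `cca_from_cov` must
match a textbook individual-level CCA (independent QR/SVD code path in
`simulate.oracle_cca`) to 1e−8 in r.  Observed agreement is ~1e−15.

## Positive semidefiniteness

Blocks estimated from different samples need not cohere into a PSD matrix.
`shrink_to_psd` multiplies every off-diagonal entry of the **full** matrix
(including Σ_XY) by factor 0.999 per iteration until the smallest
eigenvalue exceeds −1e−8, then rebuilds the blocks from the shrunk matrix.
Shrinking the full matrix rather than individual blocks keeps the three
blocks mutually consistent.  The loop is guaranteed to terminate (as the
off-diagonals → 0 the matrix approaches the identity); for the 2×2 case
with off-diagonal c > 1 the iteration count has the closed form
⌈log((1−tol)/c)/log(0.999)⌉, asserted exactly in the tests.

Numerical guards: canonical correlations are clipped to [0, 1−1e−8] so
ln Λ is finite; Σ_XX whitening adds a ridge εI with
ε = max(0, 1e−6 − λ_min) for near-singular gene blocks (large genes can
exceed the reference-panel rank; a warning is emitted when
g ≥ n_reference).

## Effective sample size

Studies differ in n.  The default n_eff is min over studies (conservative:
the chi-square scale factor is linear in n_eff, so the smallest cohort
bounds the claimed evidence); harmonic and arithmetic means are available
via configuration (`n_eff_rule`).

## Harmonization

The first study fixes the effect-allele convention.  Matching is on the
unordered allele pair: identical orientation keeps β, swapped orientation
flips its sign, anything else is dropped and logged.  Strand-ambiguous A/T
and C/G SNPs are dropped by default (`ambiguous_policy="keep"` retains
them) — without allele frequencies the strand cannot be resolved, and the
intended use case is single-ancestry panels where frequency-based rescue
adds little.  Harmonize is idempotent on its own output (re-reading a
written panel re-harmonizes with `keep`, since the policy was already
applied).

## LD pruning

PLINK `--indep-pairwise`-style: per chromosome, SNP-count windows of 50
advancing by 5 over the currently surviving SNPs; within a window each pair
with r² > 0.2 loses its smaller-MAF member (equal MAF: the later-positioned
SNP is removed, keeping the procedure deterministic and order-stable);
passes repeat to a fixed point.  The suite verifies by brute force that no
surviving pair within any 50-SNP window exceeds r² = 0.2, and that pruning
is a fixed point and invariant to individual ordering.

## Gene-based per-disease test

The statistic for a gene with member z-scores z (β/SE) is T = Σ z_i².
Under the null z ~ MVN(0, Σ_XX), so the null distribution of T is simulated
by Cholesky sampling; p = (#{null ≥ T} + 1)/(n_sims + 1), floored at
1/(n_sims+1).  The default n_sims = 10⁶ makes the floor 1e−6, matching the
convention of the gene-based association services whose outputs this test
mirrors.  Simulation is staged (10³ → 10⁶) with early stop once the
relative standard error of p̂ falls below 10%, so null cells are cheap and
significant cells run the full budget.  Calibration anchors: the 1-SNP gene
reduces to the analytic χ²₁ tail; complete LD collapses a 2-SNP gene to the
same one-degree test.

Gene membership uses the gene list's 1-based, both-ends-inclusive intervals
with no flanking window, and (in the pipeline) the pruned SNP set, so the
multivariate and per-disease scans see the same gene definitions.

## Refinement

A gene is selected as pleiotropic iff its gene-level CCA p-value is
**strictly below** α/m_genes and its gene-based p-value is **≤** the
per-disease cutoff (default 1e−6) for ≥1 disease; ≥2 diseases sets the
multi-disease flag.  The asymmetric comparisons are deliberate: Monte-Carlo
p-values sit exactly at the floor when the statistic beats every null draw,
and a floored value counts as an association.  Thresholds default to α
divided by the run's own tested-SNP and tested-gene counts; the constants
1.21e−6 and 4.34e−6 in the tests are simply 0.05/41,274 and 0.05/11,516,
the counts of the bundled example.  Confirmed/novel status is an input
annotation (literature curation is out of scope); unmapped genes are
`unknown`.

## Synthetic data

`simulate` emulates the study conditions the pipeline targets: p traits
measured in disjoint cohorts of configurable sizes (mirroring independent
consortia; the per-trait regressions are then independent given genotype),
blockwise LD, and a small set of causal genes whose member SNPs all carry a
per-SNP effect (standardized-genotype scale) on a chosen subset of traits.

Genotypes are thresholded latent Gaussians: per block, a latent AR(1)
vector (decay `block_rho`) is dichotomised at each SNP's MAF quantile,
twice per individual, and summed — a cheap mechanism that yields Hardy-
Weinberg dosages with tunable LD decay.  Note the dosage correlation is
attenuated relative to the latent rho (tetrachoric-vs-Pearson effect), so
`block_rho` is an upper bound on adjacent LD; tests therefore assert
monotonicity in rho rather than equality.  What the generator does **not**
emulate: realistic demography and allele-frequency spectra, imputation
noise, case-control ascertainment, overlapping controls between studies
(so Σ_YY ≈ I under the null here, while real co-published GWAS can share
controls), and genomic control.  Passing tests demonstrate correctness of
the statistical machinery under the stated model, not robustness to those
real-data artefacts.

Default study conditions (used by the recovery checks and the acceptance
script): 60 genes × 8 SNPs, 5 traits, 5,000 individuals per cohort, 400
reference individuals, block_rho 0.5, MAF ∈ (0.05, 0.5), 3 causal genes
with per-SNP standardized effect 0.05 (per-trait genetic variance ≈ 3%,
per-SNP z ≈ 3.5 at n = 5,000 — strong but realistic for the consortium
sample sizes emulated).  Problem sizes for the calibration suites (2,000
SNPs × 3 traits for the null scan; 1,000 SNPs for the pruning audit; 20
replicate seeds for recovery) were chosen as the smallest sizes at which
the binomial/KS bounds are informative.

## Reproducibility

Every generator is a pure function of (config, seed); the pipeline derives
per-(gene, disease) Monte-Carlo streams from a single spawned seed
sequence, so a fixed seed reproduces byte-identical outputs.  Stage outputs
land in the run directory with a manifest (config digest, counts, wall
times) and a parameter sidecar; `resume=True` reloads existing stage files.

## Known limitations

- No correction for sample overlap between studies when estimating Σ_YY.
- n_eff as a scalar ignores per-SNP sample-size variation (a per-SNP N
  column is reduced to the study median with a warning).
- The gene-based test is the plain sum-of-chi-squares statistic; exact
  analytic mixtures (Davies/Imhof) and top-k variants are out of scope.
- Strand-ambiguous SNPs are dropped, never frequency-resolved.
- kb-based pruning windows and LD estimated from summary statistics are not
  supported; windows are SNP-count based.
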