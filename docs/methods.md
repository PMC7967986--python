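# Methods

## Model

Each sample's microbiota is modelled as a mixture of K latent
subgroups. With O samples, V OTUs and N_i reads in sample i:

- θ_i ~ Dir(α) (symmetric), the sample's subgroup proportions;
- φ_k ~ Dir(β) (symmetric), the subgroup's OTU distribution;
- every read draws a subgroup from θ_i, then an OTU from φ of that
  subgroup.

The model deliberately ignores read order and within-sample structure
(bag-of-reads), and assumes the rescaled integer matrix can be treated
as ~factor tokens per sample. Subgroup labels are unidentifiable
(any permutation of k is equally likely a priori), so every comparison
against planted parameters matches subgroups by maximum-weight
bipartite matching first, and the fully Bayesian posterior mean of θ is
exactly uniform on tiny corpora — the enumeration check therefore
also compares the posterior mean of φ, which is label-symmetric but
varies over OTUs.

## Preprocessing

1. **Total-count normalization**: each sample row divided by its total,
   making rows relative abundances (library-size correction).
2. **Abundance/prevalence filter**: an OTU is kept when its relative
   abundance strictly exceeds the abundance threshold (default 0.1%) in
   at least ceil(prevalence × n_samples) samples (default prevalence
   1%). The joint reading — abundance within a sample decides whether
   that sample counts toward prevalence — is the standard one. Both
   thresholds are arguments; the filter is monotone in each.
3. **Renormalize, then integer rescale**: rows are renormalized after
   filtering and multiplied by a factor (default 1000), rounding
   half-away-from-zero. Renormalizing first is a package choice (it is
   not implied by the filter), made so each step is independently
   testable and integer rows sum to ≈ the factor; a 1e-9 guard in the
   rounding keeps decimal halves from falling below .5 in binary.

## Gibbs sampler

Collapsed Gibbs over per-read subgroup assignments with the standard
conditional (doc-subgroup count + α)(subgroup-OTU count + β)/(subgroup
total + Vβ). Defaults are the common Griffiths–Steyvers settings:
α = 50/K, β = 0.1, 2000 sweeps, 1000 burn-in, posterior means over
every 10th retained sweep. All are exposed in `LdaHyperparams`; the
sampler is bit-reproducible given the seed (the kernel seeds its own
RNG). The inner loop is numba-compiled; a 200-sample × 100-OTU ×
1000-read fit at the default sweep count takes ~10 s on one CPU.

Held-out evaluation folds in: θ for held-out samples is re-estimated by
Gibbs with φ fixed at the training point estimate (document completion
is not attempted — fold-in is the simplest defensible held-out
perplexity). `select_k_cv` partitions samples into seeded folds and
returns the per-K mean held-out perplexity/log-likelihood curve; it
does **not** auto-select K, because in practice the curve improves
without a clear optimum and is read by inspecting jumps. An optional
largest-relative-improvement flag is provided, off by default.
`refit_best_of_m` fits m models from seeds derived via `SeedSequence`
and keeps the highest training log-likelihood — the only criterion
comparable without a validation split.

## Dirichlet regression

Common parametrization: log a_ik = x_iᵀγ_k, full coefficient vector per
subgroup, no reference subgroup and no separate precision submodel (the
log link identifies the model; a common shift across subgroups changes
total precision and hence the likelihood). The log-likelihood, gradient
and observed information are analytic; optimization is L-BFGS-B from a
moment start (intercepts set from the method-of-moments Dirichlet fit
to the mean composition, other coefficients zero), and Wald standard
errors come from the inverse observed information at the optimum.
Linear predictors are clipped at ±30 during line search only, to guard
exp overflow far from the optimum.

Continuous predictors are divided by their sample SD when
`standardize=True` (the default), so coefficients read per SD; this
makes results invariant to the predictor's units. Categorical
predictors enter as dummies against a declared reference level. Rows
with missing values in any used variable are dropped and counted.
Compositions touching the simplex boundary (entries ≤ 1e-12) are
squeezed with y' = (y(n−1) + 1/K)/n — LDA thetas are interior by
construction, but serialized matrices may round to 0.

Calibration measured by simulation (n = 500, K = 3, precision 10): the
planted per-SD effect of 0.5 is recovered with mean error well inside
±0.1, and the null rejection rate of the Wald test at the 0.05 level is
≈ 6% — the mild anti-conservatism typical of Wald intervals at this
sample size. Batteries fit one model per exposure and share a
Bonferroni correction with m = number of exposures (not exposure ×
subgroup cells); per-exposure exclusion rules (e.g. dropping non-fasted
samples for lipid models) are declared as boolean covariate columns.

## Characterization

- **Top genera**: φ collapsed to genus level (columns summed by genus;
  mass conserved exactly), ranked descending with lexicographic
  tie-break; the unknown-genus `NA` category is excluded from the
  ranked list but its percentage is always reported.
- **Subgroup summaries**: per-subgroup medians/IQRs of θ, per-sample
  maxima, and counts of subgroups with probability strictly over
  {1%, 10%, 25%} per sample.
- **Subgroup clustering**: Ward linkage on Euclidean distances of
  log(φ + 1e-6) over the *full* K × V matrix (not the genus collapse,
  so OTU-level differences between subgroups sharing genera still
  separate them). Natural log and a 1e-6 pseudocount are package
  choices (φ is strictly positive after smoothing, but serialized
  matrices may round); both are arguments. The dendrogram is exported
  as newick.
- **OTU-set fractions**: for named OTU lists (e.g. OTUs that lose
  circadian rhythmicity in metabolic disease, consumed as ID lists),
  the summed φ mass per subgroup, as a percentage. Disjoint partitions
  sum to 100% per subgroup by construction; unknown IDs raise by
  default and can be demoted to a warning.

## Enterotype comparison arm

Genus-collapsed profiles, pairwise Jensen–Shannon distance (scipy's
square-root metric, natural log, 1e-9 pseudocount because genus
profiles contain zeros), and classic PAM (deterministic BUILD + SWAP on
the precomputed distance matrix — written here because no installed
package provides PAM). Clusters are named C1..Ck in decreasing size
order and annotated with their top mean-abundance genus. Membership is
then regressed on exposures with statsmodels' multinomial logit against
a declared reference cluster, reporting per-SD odds ratios with Wald
95% CIs; with two clusters this reproduces binary logistic regression
to ~1e-6, which the tests exploit as an oracle.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: LDA
corpora with block-structured φ (the `separation` argument controls
vocabulary overlap; 1 = disjoint), θ either Dir(α) or linked to
covariates through a_ik = precision·exp(x_iᵀγ_k), correlated continuous
covariates via a Cholesky factor, taxonomy maps with a configurable
unknown-genus fraction, disjoint OTU sets, and 5-level disease-like
categoricals at stated prevalences. Desk-scale defaults (300 × 120,
K = 5, 1000 reads/sample) keep the suite in minutes; a cohort-scale
preset (2000 × 1713, K = 20) exists but is not exercised by the tests.
What the generator does *not* emulate: sequencing noise and batch
effects, compositional artefacts of DNA extraction, the measurement
model behind food-frequency covariates, or real phylogenetic structure
in the taxonomy. Passing recovery tests therefore show the estimators
are correct under the model's own assumptions, not that real data meet
those assumptions.

## Numerical and degenerate-input choices

- All-zero samples are an error everywhere a positive total is needed
  (normalization, LDA), named in the message.
- K exceeding the vocabulary is allowed with a warning.
- Zero-variance predictors are an error (no SD to scale by).
- Seeds: every stochastic routine takes one; derived seeds use
  `numpy.random.SeedSequence` and stay below 2^31.
- Test problem sizes: recovery tests use 30–200 samples; the long-chain
  enumeration check uses 10,000 retained sweeps on a 6-read corpus; CV
  checks use 500-sweep chains — sizes chosen to make each statistical
  property measurable in seconds to a couple of minutes.

## Known limitations

- Variational inference, asymmetric priors and hyperparameter
  optimization of α/β are out of scope; so are FDR-style corrections
  and alternative compositional regressions (logistic-normal,
  multinomial logit on θ).
- The Wald tests are mildly anti-conservative at moderate n (see
  calibration above); likelihood-ratio tests are not implemented.
- PAM is exact but O(k·n²) per swap; it targets cohort-sized n (a few
  thousand), not tens of thousands of samples.
- OTU tables are read as TSV; BIOM files must be converted upstream.
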