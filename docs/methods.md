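# Methods

## Model and closed-form marginal likelihood

The core model treats all effects as Gaussian with variance ratios relative
to a common residual scale σ²ₑ: covariate effects with ratio φ, candidate
variant effects with ratio γ, a polygenic effect with ratio η structured by
a relationship matrix G, and a heteroskedastic residual e ~ N(0, σ²ₑ R)
with R diagonal.  The residual weights encode phenotype reliability:
an observation with reliability r² (the squared accuracy of a deregressed
breeding value) carries residual variance proportional to R_ii = 1/r² − 1,
so r² → 1 means an exact genetic-merit observation.  σ²ₑ carries a Jeffreys
prior and is integrated out analytically; φ, γ, η are treated as known.

Whitening is done once per dataset: V = ηG + R is factorised by symmetric
eigendecomposition, eigenvalues below 10⁻¹⁰ of the largest are floored
there, and M = V^(−1/2) maps the model to i.i.d. residuals.  The log
Jacobian −½ log|V| is retained so marginal likelihoods stay comparable
across variance specifications.  On whitened data, with W the design,
D the diagonal of prior ratios, and Q = y'(I + WDW')⁻¹y,

    log P(D|M) = −½ log|V| − (n/2) log π + log Γ(n/2)
                 − ½ log|I + WDW'| − (n/2) log Q,

evaluated through the Woodbury identity with a Cholesky factorisation of
D⁻¹ + W'W.  The added D⁻¹ ridge keeps duplicated or collinear variant
columns well-conditioned.  Differences of this quantity between nested
variant sets are exact log Bayes factors; the Jeffreys prior makes them
invariant to rescaling the phenotype.

Forward selection scores every candidate in one pass by rank-one updates of
that Cholesky factor (O(m q²) per iteration for m candidates and q columns
in the model), which is what makes desk-scale loci with thousands of
variants cheap without approximations.

## Conditional p-values

With φ = γ = 10⁸ the variant effects act as fixed effects and the Bayes
factor for one added variant is a monotone function of the partial F
statistic on the whitened data; the default backend therefore reports the
partial F-test (1 df) p-value, which is the exact φ, γ → ∞ limit and
matches ordinary least squares when η = 0 and R = I.  A Monte-Carlo backend
is provided that instead locates the observed scale-normalised Bayes factor
(log BF + ½ log γ, which has a finite large-γ limit) in a sample of null
Bayes factors drawn from the fitted null model; the two agree within
Monte-Carlo error and the sampling route exists mainly as a cross-check and
for non-standard designs.

Variants whose whitened dosage has squared correlation above 0.9999² with
the current design are rejected as degenerate rather than scored, which
prevents repositioning from oscillating between numerically identical
columns.

## Variance parameters

η is estimated once per trait from the null model (no candidate variants)
by profile REML: after scaling by R^(−1/2) and rotating into the eigenbasis
of R^(−1/2) G R^(−1/2), the restricted likelihood is evaluated on a
65-point grid (η = 0 plus 64 log-spaced points in [10⁻⁵, 10⁵]) and refined
by golden-section search.  The association scan re-optimises the ratio for
every marker on the same rotated data (a GEMMA-style exact scan; the grid
is shared across markers and only the marker-dependent inner products are
recomputed), with an EMMAX-style fixed-ratio mode behind a flag when speed
matters more than exactness.  Including η = 0 in the grid makes the
no-structure case collapse to (weighted) least squares exactly.

## Fine-mapping procedure

Loci are built by spanning all lead positions from single- and multi-trait
scans and extending 1 Mb in both directions (clipped at position 1), giving
candidate regions of at least 2 Mb.  The stopping rule for forward
selection is (2 logBF + 1) < 2 log(m_eff) with m_eff the Li–Ji effective
number of tests from the eigenvalues λ of the variant correlation matrix,
Σ[1(λ ≥ 1) + (λ − ⌊λ⌋)].  Repositioning then revisits each signal's lead
given all others, sweeping in selection order until a full sweep changes
nothing (at most 20 sweeps; if oscillation persists, the best-scoring
configuration visited is returned with a warning).  Ties in candidate
scores are broken by genomic position, then identifier, making runs
deterministic.

Each signal's candidate set contains variants in LD r² ≥ 0.3 with its lead
and r² ≤ 0.25 with every other lead.  Both thresholds are configurable; the
defaults mirror the region-construction rationale (r² > 0.3 captures most
variants linked to a lead) and the signal-independence criterion
(lead–lead r² > 0.25 marks dependence).  PPCs are normalised in log space,
so underflow cannot occur; their sum over a candidate set is 1 to 1e−10 by
construction.  Credible sets take PPC-descending prefixes with ties broken
by position, using a 1e−12 tolerance on the cumulative mass so that exact
rational levels (e.g. uniform PPCs at level 0.95) behave as intended.

Post-filters reproduce the quality edits used for dense imputed data:
loci with more than 3 signals are dropped entirely (a symptom of inflated
scans), signals whose candidate set has ≤ 10 distinct hard-called genotype
columns are dropped (small clusters of identical columns indicate
imputation artifacts), and signals whose lead conditional p exceeds 5e−7
are dropped.  The enrichment-eligible subset additionally excludes signals
from traits with squared correlation > 0.5 to an included trait and signals
whose lead has LD r² > 0.25 with an included lead, because the enrichment
likelihood assumes independent signals.

## Enrichment estimation

q_C is the genome-wide frequency of category C.  The likelihood for p_C is
a product over independent signals of a mixture over which variant is
causal; because equal-prior PPCs are proportional to the per-variant
marginal likelihoods, the likelihood needs only those PPCs.  EM maximises
it exactly: the E-step reweights each signal's PPCs by p_c/q_c and
renormalises (identical to the prior-update step used in fine-mapping —
shared code path, so estimation and prior construction cannot drift), and
the M-step sets p_C to the mean per-signal responsibility mass in C.
Iterates stay on the simplex and the likelihood is non-decreasing;
convergence is declared at max |Δp| < 1e−8 (cap 10⁴ iterations, error with
trace beyond).  EM is used instead of generic constrained optimisation
because the mixture structure makes it exact, monotone, and free of tuning.

Bootstrap confidence intervals resample signals with replacement 1000
times; resampling is implemented as multinomial signal weights so all
resamples share one vectorised EM.  Categories with genome-wide frequency
below 1% and no PPC mass are removed before resampling (they cause
non-convergence and carry no information).  The permutation test for a
ratio of enrichments between two signal groups permutes group labels and
uses a two-sided add-one-corrected p-value on |log ratio|; permutations
with undefined ratios are dropped, with a warning if they exceed 10%.

## Synthetic data

The generator emulates the statistical structure the model assumes, at desk
scale:

- **Genotypes**: haplotypes from a first-order allele-copying chain within
  LD blocks — each allele copies its left neighbour with probability
  `ld_rho` (default 0.95, giving the dense multi-variant LD neighbourhoods
  typical of sequence data in livestock; adjacent-variant correlation ≈
  ld_rho) or is drawn fresh at the block's allele frequency
  (U(0.05, 0.95)).  Copying was chosen over Gaussian thresholding because
  it yields valid 0/1/2 genotypes with controllable block LD and extends
  naturally to relatedness.  Families are full-sib groups: children inherit
  recombinant parental haplotypes (switch probability 0.01 per adjacent
  variant), giving realised GRM entries near 0.5 for full sibs.
- **Phenotypes**: y = Zβ + g + e on the σ²ₑ = 1 scale.  The polygenic term
  is a sum of small random marker effects scaled to variance η =
  h²/(1 − h²); the residual of individual i has variance 1/r²ᵢ − 1 with
  reliabilities drawn from U(0.5, 0.95).  That makes supplying the true
  reliabilities exactly the correctly specified weighted analysis, which is
  what lets the calibration tests (λ within [0.95, 1.05] on structured
  nulls) bite.  Effect sizes are specified in phenotypic SD; the phenotypic
  variance is solved for self-consistently from the effect sizes, η, and
  the mean residual variance.
- **Annotations**: causal variants' categories are drawn from p_C,
  non-causal from q_C — exactly the generative model the enrichment
  likelihood assumes; defaults are two categories with q = (0.1, 0.9) and
  p = (0.5, 0.5), i.e. a planted five-fold enrichment.
- **Enrichment signals**: `simulate_enrichment_signals` produces
  independent single-causal mini-loci and computes their equal-prior PPCs
  through the actual model machinery, so the PPC vectors entering
  enrichment tests are real posteriors, not stylised ones (a stylised
  generator with fixed PPC mass on the causal variant is miscalibrated and
  biases the MLE — this was observed, not hypothesised).

What the generator does **not** emulate: coalescent allele-frequency
spectra, imputation error, X-chromosome inheritance, selection, or
ascertainment.  Passing tests therefore demonstrate correctness of the
machinery and calibration under the assumed model, not robustness to the
many ways real cattle data violate it.

## Problem sizes and numerical choices in the validation suite

The statistical checks use sizes chosen to make their targets estimable
with comfortable Monte-Carlo margins: credible-set coverage uses 200
single-causal loci at n = 2000, m = 300 with the effect calibrated to ~80%
selection power (0.175 phenotypic SD); null family-wise control uses 200
pure-noise loci at n = 1000, m = 500; the multi-trait type-I error uses
10⁴ replicates with a planted three-trait correlation; the structured-null
λ check uses n = 600 (60 five-sib families), m = 6000 in weak LD so the
median-based λ has small sampling error; enrichment recovery uses 250
signals and nested bootstrap coverage 100 outer replicates of 500
resamples.  The acceptance script uses the same designs at the same or
slightly reduced replicate counts.

Reliability r² = 1 maps to a residual weight floored at 10⁻⁶ to keep
ηG + R invertible when η = 0.  Genomic-control λ is the median 1-df
chi-square quantile ratio.  Trait clustering uses average linkage on
1 − |correlation| (the conventional default; recorded in output metadata).
HWE filtering uses a 1-df chi-square on hard calls, rounding imputed
dosages for the test only.  Coordinates are 1-based closed everywhere
internally; BED is converted at the boundary; variants are keyed
`chrom:pos:ref:alt`.

## Known limitations

- Additive dosage coding only; no dominance or imprinting designs.
- Single-annotation enrichment; overlapping annotations are analysed
  separately (or via explicit cross-product categories), not jointly.
- The scaled Bayes factor's null distribution is sampled, not closed-form;
  the F-test backend is exact only in the large-φ, γ limit (which is the
  recommended and default fine-mapping setting).
- `gene_ppc` lets a variant contribute to every overlapping gene, so
  summing gene PPCs across overlapping genes can exceed the per-signal
  total of 1.
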