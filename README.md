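# finemapkit

Bayesian fine-mapping of quantitative-trait loci for studies with related
individuals and unequally reliable phenotypes — the situation typical of
livestock GWAS, where phenotypes are deregressed breeding values (deregressed
PTAs) with per-animal reliabilities and the population carries strong family
structure and long-range LD.

`finemapkit` provides, as a library and a CLI:

- **single-trait mixed-model association scans** with reliability-weighted
  residuals and an exact per-marker variance-component optimisation;
- **multi-trait chi-square tests** built from signed t-values and the
  trait-correlation matrix they imply, plus trait clustering;
- **Bayesian fine-mapping**: forward selection of independent signals,
  lead repositioning, per-variant posterior probabilities of causality
  (PPC), and 95% credible variant sets, all from closed-form marginal
  likelihoods (no MCMC);
- **enrichment of causal effects** in functional-annotation categories via
  an empirical-Bayes EM estimator, percentile-bootstrap confidence
  intervals, and annotation-informed priors that feed back into the PPCs;
- a **synthetic-data module** generating LD-structured genotypes, families,
  reliability-weighted phenotypes, and annotation categories with planted
  causal enrichment, so every statistical claim is testable end to end.

## Model

The fine-mapping model for a phenotype vector **y** (length *n*) is

```
y = X b + Z a + g + e
b ~ N(0, φ σ²ₑ I)          covariates (intercept included)
a ~ N(0, γ σ²ₑ I)          candidate-variant effects (dosages 0/1/2 in Z)
g ~ N(0, η σ²ₑ G)          polygenic effect, G the genomic relationship matrix
e ~ N(0, σ²ₑ R)            residual; R_ii = 1/r²ᵢ − 1 from reliability r²ᵢ
P(σ²ₑ) ∝ 1/σ²ₑ             Jeffreys prior
```

φ, γ, η are treated as known variance ratios; η = h²/(1 − h²) is estimated
once from the null model by restricted maximum likelihood.  After whitening
with M = (ηG + R)^(−1/2), the marginal likelihood P(D|M) has a closed form,
so Bayes factors between nested variant sets are exact, and with
φ = γ = 10⁸ the conditional test of a new variant reduces to the partial
F-test on the whitened data.

Forward selection adds the variant with the largest conditional Bayes
factor until (2 logBF + 1) < 2 log(m_eff), where m_eff is the Li–Ji
effective number of independent variants in the locus.  For signal *i* with
lead *lᵢ* and candidate set *Sᵢ*, the PPC of variant *v_ij* is

```
P(Mᵢ = v_ij | y) ∝ P(y | X, Z, Mᵢ = v_ij, S_l \ {lᵢ}) · P(Mᵢ = v_ij)
```

normalised over *Sᵢ*; the 95% credible set is the minimal PPC-descending
prefix reaching 0.95.  For an annotation with categories *C*, the prior
P(Mᵢ = v_ij) ∝ p_c/q_c, where q_C is the genome-wide category frequency,
p_C the probability that a causal variant falls in *C* (estimated by EM
across independent signals), and E_C = p_C/q_C the enrichment of causal
effects.

## Worked example

```python
import numpy as np
from finemapkit.synthetic import SimulationConfig, simulate_dataset
from finemapkit.finemap import build_locus, fine_map_locus
from finemapkit.model_core import ModelSpec, reliability_to_weight

cfg = SimulationConfig(seed=7, n_individuals=2000, n_variants=300,
                       causal_effect_sd=0.25, h2_polygenic=0.0)
ds = simulate_dataset(cfg)
print("planted causal:", ds.truth["causal_ids"][0])

ids, y, r2 = ds.panel.observed("trait1")
spec = ModelSpec(covariates=np.ones((len(y), 1)),
                 residual_weights=reliability_to_weight(r2))
locus = build_locus([("1", 150_000)], ds.genotypes, trait="trait1")
print(f"locus: {locus.genotypes.n_variants} variants, m_eff = {locus.m_eff:.1f}")

result = fine_map_locus(locus, y, spec)
for i, sig in enumerate(result.signals, 1):
    print(f"signal {i}: lead {sig.lead}  2logBF = {2*sig.log_bf:.1f}  "
          f"conditional p = {sig.conditional_p:.2e}")
    print(f"  candidate set: {len(sig.candidate_ids)} variants; "
          f"95% credible set: {len(sig.credible)} variants")
```

prints

```
planted causal: 1:4000:A:C
locus: 300 variants, m_eff = 87.0
signal 1: lead 1:4000:A:C  2logBF = 104.6  conditional p = 2.32e-30
  candidate set: 16 variants; 95% credible set: 1 variants
```

The planted causal variant is recovered as the lead of the single
fine-mapped signal: its conditional Bayes factor passes the Bonferroni-style
stopping rule by a wide margin (2logBF = 104.6 against a threshold of
2 log 87 ≈ 8.9), and its PPC of 0.998 makes the 95% credible set a single
variant.

The same analysis is available from the shell:

```sh
finemapkit simulate --out data --seed 7
finemapkit scan --genotypes data/genotypes.vcf --phenotypes data/phenotypes.tsv \
    --trait trait1 --out scan.tsv
finemapkit peaks --scan scan.tsv --trait trait1 --out peaks.tsv
finemapkit finemap --genotypes data/genotypes.vcf --phenotypes data/phenotypes.tsv \
    --trait trait1 --chrom 1 --lead-pos 150000 --out ppc.tsv
```

and `finemapkit pipeline --config cfg.yaml --out run/ --seed 1` chains
scan → peaks → multi-trait test → fine-mapping (equal prior) → enrichment →
fine-mapping (annotation prior), writing a manifest of every stage.

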