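# admixpower

Mechanistic genotype–phenotype simulation for genome-wide association
studies (GWAS) in **two-way admixed populations**.

Most GWAS are run in single-ancestry cohorts, which limits both
discovery and the portability of polygenic scores to other populations.
`admixpower` is for statistical geneticists who want to quantify, under
a controlled generative model, how much discovery power and
cross-population transferability a GWAS gains (or loses) when the study
cohort is admixed — e.g. an African-American-like population with ~75%
West-African and ~25% European ancestry — compared to the two
homogeneous source populations at the same sample size.

## The model

Per replicate, for an admixed cohort and its two source cohorts:

1. **Global ancestry** θᵢ ~ Beta(a, b), parameterized by its mean *m*
   and variance *v* (method of moments: a = m(m(1−m)/v − 1),
   b = a(1−m)/m). Source cohorts are the degenerate cases θ ≡ 1 and
   θ ≡ 0.
2. **Local ancestry** at each of *n* LD-independent loci: each haplotype
   copy is Bernoulli(θᵢ), so Population-1 haplotype counts are
   Binomial(2, θᵢ).
3. **Allele frequencies** under the Balding–Nichols model: ancestral
   frequency pₛ ~ Unif(0.001, 0.999), then
   p₁ₛ, p₂ₛ ~ Beta(pₛ(1−F)/F, (1−pₛ)(1−F)/F) independently, with
   per-locus F_ST either fixed or MAF-linked,
   F = F_bg + (1 − MAF)·δ (δ = 0.3), reflecting stronger drift of
   ancestrally rare alleles. Non-causal loci keep the genome-wide
   background F_bg = 0.2.
4. **Genotypes**: per-haplotype Bernoulli draws at p₁ₛ or p₂ₛ according
   to local ancestry; dosage = sum over the two copies.
5. **Trait**: *w* causal loci with |N(0,1)| effect magnitudes; the sign
   is +1 with probability p₁ₛ/(p₁ₛ+p₂ₛ), coupling the trait to
   Population-1 ancestry (directional divergence). True PRS = Σ dosage·β.
   Environment = ancestry-weighted Gaussian noise (θ·ε₁ + (1−θ)·ε₂) or a
   linear ancestry confounder plus noise, scaled so Var(env) =
   Var(PRS)(1−h²)/h². Quantitative phenotype = PRS + env; dichotomous
   phenotypes threshold the liability at the empirical (1−prevalence)
   quantile.
6. **Association**: per-locus linear (quantitative) or logistic
   (dichotomous) regression, with global ancestry as a covariate in the
   admixed cohort. Power = proportion of causal loci with p ≤ α; the
   false positive rate is the same proportion over null loci.

On top of this the package orchestrates power grids over sample size,
F_ST and h², reciprocal replication between the admixed cohort and
Population 1, cross-population polygenic-score (PRS) portability
matrices, and a genotype-free power estimate for trait-vs-ancestry
correlations.

## Worked example

```python
import numpy as np
from admixpower import (
    ExperimentGrid, load_config, run_power_grid, power_ratio_table,
)

cfg = load_config()            # standard setting: m=0.75, 1000 loci,
                               # 100 causal, FST 0.2+, h2=0.5
grid = ExperimentGrid(
    sample_sizes=[1000],
    fst_values=[0.2, 0.5, 0.8],   # fixed causal-locus FST sweep
    trait_types=["quantitative"],
    n_reps=8,
)
df = run_power_grid(grid, cfg, master_seed=7)
print(df.groupby(["fst", "population"])["power"].mean().round(3))
print(power_ratio_table(df).groupby("fst")["power_ratio"].mean().round(2))
```

Output:

```
fst  population
0.2  admixed       0.356
     pop1          0.366
     pop2          0.351
0.5  admixed       0.280
     pop1          0.219
     pop2          0.244
0.8  admixed       0.224
     pop1          0.106
     pop2          0.103
Name: power, dtype: float64
fst
0.2    1.01
0.5    1.21
0.8    2.17
Name: power_ratio, dtype: float64
```

Reading: at causal-locus F_ST 0.2 the admixed cohort discovers causal
variants at roughly the same rate as the source cohorts (ratio ≈ 1),
but as the source populations diverge, causal alleles drift to extreme
frequencies there while remaining at intermediate, detectable
frequencies in the admixed cohort — at F_ST 0.8 the admixed cohort is
over twice as powerful as the average source cohort.

The same machinery is available from the shell:

```bash
admixpower --seed 7 --out-dir out power-grid
admixpower --seed 7 --out-dir out simulate          # VCF + phenotype TSV
admixpower --seed 7 replication --n-reps 20
admixpower --seed 7 anc-trait-power --incidence 0.1 --effect 2.0 --n 1000
```

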