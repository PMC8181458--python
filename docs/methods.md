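# Methods

This note documents the generative model, the defaults and why they
were chosen, the numerical conventions, and what the simulations do and
do not establish about real admixed-cohort GWAS.

## Generative model

**Ancestry.** Global ancestry θ (the Population-1 genome fraction of an
admixed individual) is Beta-distributed with mean *m* and variance *v*;
the Beta shapes are recovered by the method of moments, so the sampled
distribution has exactly the requested moments. Feasibility requires
0 < v < m(1−m). Draws are clipped to [10⁻⁶, 1−10⁻⁶] so downstream
binomial sampling and regressions remain well-posed. Local ancestry at
each locus is two independent Bernoulli(θ) haplotype draws; loci are
LD-independent by construction — there is no recombination map, no
chromosome structure, and no generation-by-generation admixture
dynamic. The source populations are the degenerate cases θ ≡ 1 and
θ ≡ 0, which guarantees all three cohorts share identical locus
frequencies.

**Allele frequencies.** One ancestral frequency per locus,
pₛ ~ Unif(0.001, 0.999), diverges into the two source populations by a
single Balding–Nichols event: p₁ₛ and p₂ₛ are independent draws from
Beta(pₛ(1−F)/F, (1−pₛ)(1−F)/F), with mean pₛ and variance pₛ(1−pₛ)F.
Causal loci take either a fixed trait F_ST (for divergence sweeps) or
the MAF-linked value F = F_bg + (1 − MAF)·δ with MAF = min(pₛ, 1−pₛ);
non-causal loci always take the genome-wide background F_bg. The
effective F_ST is clamped to [10⁻⁴, 1−10⁻⁴] because the increment can
push the sum past 1 at large backgrounds, which would make the Beta
shapes negative. Exact fixation of p₁ₛ/p₂ₛ is allowed (it is the
mechanism behind undiscoverable loci in source cohorts); the only
exception is a causal locus with both frequencies exactly zero, which
would make the effect-sign probability undefined and is redrawn.

**Trait architecture.** Effect magnitudes at the *w* causal loci are
|N(0,1)|; the sign is +1 with probability p₁ₛ/(p₁ₛ+p₂ₛ) (a normalized
Bernoulli trial — the alternative min(p₁/p₂, 1) reading is available as
`trait.sign_mode: ratio_capped` for sensitivity analysis). This couples
effect direction to which source population carries the allele more
often, producing directional trait divergence between the source
populations and a positive trait–ancestry correlation in the admixed
cohort — the phenomenon the framework exists to study.

**Environment.** Two modes:

- `gaussian_anc` (default): env = θ·ε₁ + (1−θ)·ε₂ with ε₁, ε₂ i.i.d.
  Gaussian — ancestry-weighted environmental noise.
- `linear_anc`: env = λθ + ε, where the λ-term is scaled to explain
  `trait.env_anc_fraction` of total phenotypic variance (a
  socioeconomic-confounder-style term, up to 1 − h²).

Free scales are solved *empirically* in the simulated cohort so
Var(env) equals Var(PRS)(1−h²)/h² exactly — there is no closed-form
variance formula for the PRS under this architecture, and empirical
scaling makes the realized narrow-sense heritability match the target
almost exactly (the only slack is the sampling covariance between PRS
and environment, O(N^−1/2)). In a homogeneous cohort (θ constant) both
modes collapse to plain Gaussian noise.

`trait.env_scale_reference` controls the cross-cohort anchoring:

- `admixed` (default): the environmental variance computed from the
  admixed cohort is reused for both source cohorts, keeping all three
  phenotypes on one scale. Source-cohort heritability is then emergent
  (lower than the target when divergence shrinks their genetic
  variance).
- `cohort`: every cohort scales its own environment, so h² holds
  exactly within each population, at the cost of different absolute
  phenotype scales across cohorts.

This choice is consequential and genuinely open: the admixed-anchored
default reproduces the power-enrichment behavior (source cohorts carry
environmental noise comparable to the admixed cohort, so their
power deficit comes from allele-frequency extremity), while the
per-cohort alternative quiets the source cohorts and strongly favors
replication of admixed discoveries in Population 1. No single anchoring
reproduces every asymmetry one might expect simultaneously; see
"Limitations" below.

**Phenotype.** Quantitative: y = PRS + env. Dichotomous: the liability
y is cut at its empirical (1 − prevalence) quantile, giving exactly
round(N · prevalence) cases (ties broken by stable rank order). The
empirical quantile is used rather than a Gaussian threshold because the
liability is a finite mixture, not Gaussian. There is no case-control
ascertainment: scans analyze the full cohort at its prevalence.

**Association testing.** Per-locus linear or logistic regression with a
two-sided Wald test on the dosage term (conventional GWAS practice;
likelihood-ratio tests would change nothing material at these sample
sizes). The admixed scan includes θ as a fixed-effect covariate; source
cohorts are scanned without covariates — the true ancestry is known, so
no PCA proxy is needed. Significance uses p ≤ α inclusive. Power is
counted over *all* causal loci (a locus monomorphic in the analyzed
cohort is an undiscoverable causal locus, not a removed one), and the
false positive rate over all null loci, separately per cohort.

## Numerical choices

- Genome scans are exact batched computations, not per-locus library
  fits: linear scans use Frisch–Waugh–Lovell residualization (exact
  OLS; t-distributed Wald p with N−k df), logistic scans run
  Newton–Raphson simultaneously across loci (convergence tolerance
  10⁻⁸, iteration cap 100, normal Wald p). Agreement with statsmodels
  OLS/Logit is pinned by tests.
- Logistic separation (common at extreme frequencies with 5% case
  prevalence) is detected via divergence of the dosage coefficient
  (|β| > 50 on the log-odds scale), singular Hessians, or hitting the
  iteration cap; such loci are flagged untested, never penalized.
- MAF filtering is per-cohort and inclusive at the threshold
  (MAF ≥ 5% passes).
- The Weir–Cockerham F_ST estimator (two-population variance
  components, diploid, with observed heterozygosity) reports per-locus
  values and the ratio-of-averages multi-locus estimate, untruncated;
  loci monomorphic in both samples are excluded. It serves as an
  internal oracle: it recovers the generative F within ±0.02 at 10⁴
  loci (tested for F ∈ {0.1, 0.2, 0.5, 0.8}).
- All randomness flows from one master seed through
  `numpy.random.SeedSequence` children keyed by (experiment, cell,
  repetition, population); repetitions may run in parallel and results
  are identical and ordered regardless of scheduling.

## Defaults and presets

| Parameter | Default | Rationale |
|---|---|---|
| ancestry mean m | 0.75 | African-American-like two-way admixture |
| ancestry variance v | 0.02 | free parameter (sd ≈ 0.14); configurable |
| loci n / causal w | 1000 / 100 | standard polygenic architecture |
| background F_ST | 0.2 | genome-wide divergence between source populations |
| δ (MAF-linked increment) | 0.3 | extra drift of ancestrally rare alleles |
| h² | 0.5 | mid-range narrow-sense heritability |
| prevalence | 0.05 | liability threshold for dichotomous traits |
| α levels | 0.05 (up to 5e−8) | relative power comparisons are stable across stringency |

The `chilean` preset models an Indigenous-American/European admixture
with source-population F_ST 0.18; its ancestry mean 0.55 and variance
0.02 are preset assumptions, not estimates. `*-small` presets are
200-individual × 200-locus fixtures for tests, generated through the
full pipeline.

Experiment defaults are desk-scale: sample-size grid {10³, 5·10³, 10⁴}
and 20 repetitions (the framework accepts 10⁶ individuals and 50+
repetitions via configuration; the desk-scale grids already separate
the effects of interest cleanly). Replication and PRS-portability
experiments default to 1000 causal loci, MAF ≥ 5%, training N = 10⁴ and
test N = 10³ per cohort.

## What the simulations show — and what they do not

The synthetic cohorts emulate: ancestry-structured genotype variation
under a single divergence event, directional polygenic architecture
tied to that divergence, ancestry-correlated environments, and
cohort-level GWAS with ancestry correction. They deliberately omit: LD
and tagging (every locus is causal or null, never a proxy), realistic
site-frequency spectra, post-admixture selection, k-way admixture,
dominance/epistasis/G×E effect heterogeneity, case-control
ascertainment, and genotyping error. Passing tests therefore establish
internal statistical properties of this model family — calibration of
type-I error, frequency-intermediacy-driven power enrichment, moment
recovery of the generators — not quantitative predictions for any real
cohort, where LD, ascertainment bias and demographic detail move the
absolute numbers.

## Limitations

- The admixed power enrichment and the replication/PRS-portability
  asymmetries respond in opposite directions to the environment-scaling
  anchor (`trait.env_scale_reference`): with the default admixed anchor
  the enrichment reaches ≥ 2-fold at high divergence and type-I error
  stays at 5%, but reciprocal replication between the admixed cohort
  and Population 1 is approximately symmetric; with the per-cohort
  anchor the replication asymmetry is strong while the power-ratio
  collapses toward 1. Within this model family both behaviors cannot be
  produced by one anchoring at the default ancestry variance.
- Any polygenic score *tested* in the admixed cohort gains an
  ancestry-mediated correlation with the true score (both correlate
  with θ), inflating apparent cross-population accuracy into the
  admixed cohort; this grows with the ancestry variance v.
- Logistic scans at N = 1000 with 5% prevalence flag a few percent of
  loci as separated/untested; these count as non-discoveries, slightly
  deflating dichotomous power at extreme frequencies.
- Wilcoxon tests across repetitions treat repetitions as exchangeable
  units; with shared seeds across cohorts a paired signed-rank variant
  is available (`paired=True`).
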