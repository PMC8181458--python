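"""Trait architecture: causal effects, polygenic scores, environment, phenotype.

Effect magnitudes at causal loci are |N(0, 1)| draws; the sign of each
effect is tied to which source population carries the allele more often
(positive with probability p1 / (p1 + p2)), which induces directional
divergence of the trait between the source populations and a positive
correlation between the trait and Population-1 global ancestry in the
admixed cohort.

The non-genetic component is either ancestry-weighted Gaussian noise
(``gaussian_anc``: theta * e1 + (1 - theta) * e2 with e1, e2 i.i.d.
Gaussian) or a linear ancestry confounder plus noise (``linear_anc``:
lambda * theta + e).  In both modes the free scales are solved
empirically so the realized non-genetic variance equals
Var(PRS) * (1 - h2) / h2, making the realized narrow-sense heritability
match the target almost exactly.  In a homogeneous source cohort (theta
constant) both modes collapse to plain Gaussian noise at the same total
variance.

Quantitative phenotypes are the direct sum of the genetic score (true
PRS) and the environmental score; dichotomous phenotypes threshold that
liability at its empirical (1 - prevalence) quantile, so a cohort of N
individuals has exactly round(N * prevalence) cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeSet, LocusFrequencies

__all__ = [
    "TraitArchitecture",
    "PhenotypeSet",
    "draw_causal_indices",
    "assign_effects",
    "compute_prs",
    "simulate_environment",
    "assemble_phenotype",
]

ENV_MODES = ("gaussian_anc", "linear_anc")
TRAIT_TYPES = ("quantitative", "dichotomous")


@dataclass(frozen=True)
class TraitArchitecture:
    """Causal-locus indices, signed weights, and variance-partition targets.

    Parameters
    ----------
    causal_idx
        Unique indices of the ``w`` causal loci out of ``n`` total.
    weights
        Signed per-causal-locus effects; magnitudes are |N(0,1)| draws.
    h2
        Target narrow-sense heritability in (0, 1].
    env_mode
        ``"gaussian_anc"`` or ``"linear_anc"``.
    env_anc_fraction
        linear_anc only: fraction of total phenotypic variance explained
        by the linear ancestry term, in [0, 1 - h2].
    prevalence
        Case fraction for dichotomous traits, in (0, 1).
    """

    causal_idx: np.ndarray
    weights: np.ndarray
    h2: float
    env_mode: str = "gaussian_anc"
    env_anc_fraction: float = 0.0
    prevalence: float = 0.05

    def __post_init__(self) -> None:
        causal = np.asarray(self.causal_idx, dtype=np.intp)
        if np.unique(causal).size != causal.size:
            raise ValueError("causal indices must be unique")
        if causal.size != np.asarray(self.weights).size:
            raise ValueError("one weight per causal locus required")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.env_mode not in ENV_MODES:
            raise ValueError(f"env_mode must be one of {ENV_MODES}")
        if not 0.0 <= self.env_anc_fraction <= 1.0 - self.h2 + 1e-12:
            raise ValueError("env_anc_fraction must lie in [0, 1 - h2]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class PhenotypeSet:
    """Per-individual genetic score, environmental score, and phenotype."""

    prs_true: np.ndarray
    env_score: np.ndarray
    y_quant: np.ndarray
    y_binary: np.ndarray | None = field(default=None)

    @property
    def n_individuals(self) -> int:
        return self.prs_true.shape[0]


def draw_causal_indices(
    n_loci: int, n_causal: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly choose ``n_causal`` distinct causal loci out of ``n_loci``."""
    if not 1 <= n_causal <= n_loci:
        raise ValueError("need 1 <= n_causal <= n_loci")
    return np.sort(rng.choice(n_loci, size=n_causal, replace=False))


def assign_effects(
    freqs: LocusFrequencies,
    causal_idx: np.ndarray,
    rng: np.random.Generator,
    *,
    sign_mode: str = "normalized",
) -> np.ndarray:
    """Draw signed causal-effect weights tied to population frequencies.

    Magnitudes are |N(0, 1)|.  The sign of each weight is the outcome of a
    Bernoulli trial whose success (``+1``) probability depends on the
    allele's frequencies in the two source populations:

    - ``"normalized"`` (default): P(+1) = p1 / (p1 + p2)
    - ``"ratio_capped"``: P(+1) = min(p1 / p2, 1) (for sensitivity checks;
      degenerates to +1 whenever p1 >= p2)

    Either way, alleles favored in Population 1 tend to receive positive
    weights, which couples the trait to Population-1 ancestry.
    """
    causal_idx = np.asarray(causal_idx, dtype=np.intp)
    p1 = freqs.p1[causal_idx]
    p2 = freqs.p2[causal_idx]
    if np.any(p1 + p2 == 0.0):
        raise ValueError(
            "sign probability undefined where p1 + p2 == 0; redraw those loci"
        )
    if sign_mode == "normalized":
        prob_pos = p1 / (p1 + p2)
    elif sign_mode == "ratio_capped":
        prob_pos = np.minimum(np.divide(p1, p2, out=np.ones_like(p1), where=p2 > 0), 1.0)
    else:
        raise ValueError("sign_mode must be 'normalized' or 'ratio_capped'")
    magnitude = np.abs(rng.standard_normal(causal_idx.size))
    sign = np.where(rng.random(causal_idx.size) < prob_pos, 1.0, -1.0)
    return magnitude * sign


def compute_prs(
    genotypes: GenotypeSet | np.ndarray, architecture: TraitArchitecture
) -> np.ndarray:
    """True polygenic score: additive weighted dosage sum over causal loci."""
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeSet) else genotypes
    causal = np.asarray(architecture.causal_idx, dtype=np.intp)
    if causal.size and causal.max() >= dosages.shape[1]:
        raise ValueError("causal index out of range for genotype matrix")
    return dosages[:, causal].astype(float) @ np.asarray(architecture.weights, float)


def simulate_environment(
    theta: np.ndarray,
    prs_true: np.ndarray,
    architecture: TraitArchitecture,
    rng: np.random.Generator,
    *,
    env_var: float | None = None,
) -> np.ndarray:
    """Simulate the non-genetic score at the variance the heritability implies.

    The target non-genetic variance is ``Var(prs_true) * (1 - h2) / h2``,
    or ``env_var`` when given — pass the admixed cohort's value as
    ``env_var`` when simulating the source cohorts so all three cohorts
    share one environmental scale.

    gaussian_anc: raw_i = theta_i * e1_i + (1 - theta_i) * e2_i with e1,
    e2 i.i.d. standard normal, rescaled so the empirical variance equals
    the target exactly.  linear_anc: a centered lambda * theta term scaled
    to explain ``env_anc_fraction`` of the total phenotypic variance, plus
    independent Gaussian noise carrying the remainder of the non-genetic
    variance; with constant theta the ancestry term vanishes and all the
    variance goes to the noise.
    """
    theta = np.asarray(theta, dtype=float)
    prs_true = np.asarray(prs_true, dtype=float)
    n = theta.shape[0]
    if architecture.h2 >= 1.0:
        return np.zeros(n)
    if env_var is None:
        v_g = float(np.var(prs_true))
        if v_g <= 0.0:
            raise ValueError(
                "Var(prs_true) = 0: cannot scale environment to a heritability "
                "target; pass env_var explicitly"
            )
        env_var = v_g * (1.0 - architecture.h2) / architecture.h2
    env_var = float(env_var)

    if architecture.env_mode == "gaussian_anc":
        raw = theta * rng.standard_normal(n) + (1.0 - theta) * rng.standard_normal(n)
        return raw * np.sqrt(env_var / np.var(raw))

    # linear_anc: total phenotypic variance implied by the env target
    v_p = env_var / (1.0 - architecture.h2)
    anc_var_target = architecture.env_anc_fraction * v_p
    noise_var_target = env_var - anc_var_target
    noise = rng.standard_normal(n)
    noise *= np.sqrt(noise_var_target / np.var(noise))
    theta_c = theta - theta.mean()
    v_theta = float(np.var(theta_c))
    if anc_var_target > 0.0 and v_theta > 0.0:
        anc_term = theta_c * np.sqrt(anc_var_target / v_theta)
    else:
        # homogeneous cohort (or zero ancestry share): plain noise at full scale
        anc_term = np.zeros(n)
        if np.var(noise) > 0.0:
            noise *= np.sqrt(env_var / np.var(noise))
    return anc_term + noise


def assemble_phenotype(
    prs_true: np.ndarray,
    env_score: np.ndarray,
    trait_type: str = "quantitative",
    prevalence: float | None = None,
) -> PhenotypeSet:
    """Combine genetic and environmental scores into the phenotype.

    Quantitative traits are the direct sum.  Dichotomous traits apply a
    liability threshold at the empirical (1 - prevalence) quantile of the
    cohort's liability scores: exactly ``round(N * prevalence)``
    individuals — those with the highest liabilities, ties broken by rank
    order — become cases.
    """
    if trait_type not in TRAIT_TYPES:
        raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")
    y = np.asarray(prs_true, float) + np.asarray(env_score, float)
    if trait_type == "quantitative":
        return PhenotypeSet(prs_true=prs_true, env_score=env_score, y_quant=y)
    if prevalence is None or not 0.0 < prevalence < 1.0:
        raise ValueError("dichotomous traits require prevalence in (0, 1)")
    n = y.shape[0]
    n_cases = int(round(n * prevalence))
    order = np.argsort(y, kind="stable")
    y_binary = np.zeros(n, dtype=np.int8)
    if n_cases > 0:
        y_binary[order[n - n_cases :]] = 1
    return PhenotypeSet(prs_true=prs_true, env_score=env_score, y_quant=y, y_binary=y_binary)
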