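"""Allele-frequency and genotype simulation under the Balding–Nichols model.

Each locus carries an ancestral allele frequency ``p_s`` drawn uniformly
on [0.001, 0.999].  The two present-day source populations inherit
frequencies ``p1_s, p2_s`` drawn independently from the Balding–Nichols
Beta distribution

    Beta( p_s * (1 - F) / F,  (1 - p_s) * (1 - F) / F )

whose mean is ``p_s`` and variance ``p_s * (1 - p_s) * F``, so ``F``
plays the role of the fixation index F_ST between the populations.

F_ST at a locus can be fixed, or tied to the ancestral minor allele
frequency through ``F = F_background + (1 - MAF) * delta``, reflecting
that ancestrally rarer variants drift apart more easily (for example
under a severe bottleneck in one derived population).

Diploid genotypes are per-haplotype Bernoulli draws using the allele
frequency of whichever source population the haplotype's local ancestry
points to.  A Weir–Cockerham F_ST estimator is included as a validation
oracle that recovers the generative ``F`` from sampled genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry import POP1

__all__ = [
    "LocusFrequencies",
    "GenotypeSet",
    "draw_ancestral_freqs",
    "effective_fst",
    "draw_population_freqs",
    "build_locus_frequencies",
    "sample_genotypes",
    "wc_fst_estimate",
    "WcFstResult",
]

#: Clamp bound for effective F_ST so Balding–Nichols Beta shapes stay positive.
FST_EPS: float = 1e-4

#: Support of the ancestral allele-frequency distribution.
ANCESTRAL_FREQ_LOW: float = 0.001
ANCESTRAL_FREQ_HIGH: float = 0.999


@dataclass(frozen=True)
class LocusFrequencies:
    """Per-locus ancestral and population-specific allele frequencies.

    Attributes
    ----------
    p_anc
        Ancestral allele frequency ``p_s`` per locus, in (0, 1).
    fst
        Effective F_ST per locus used for the Balding–Nichols draw.
    p1, p2
        Present-day allele frequencies in Population 1 and Population 2.
    """

    p_anc: np.ndarray
    fst: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.p_anc.shape[0]


@dataclass(frozen=True)
class GenotypeSet:
    """Diploid dosages with the local ancestry and frequencies that made them."""

    dosages: np.ndarray  # (n_individuals, n_loci) allele counts in {0, 1, 2}
    local: np.ndarray  # (n_individuals, n_loci, 2) local-ancestry origins
    freqs: LocusFrequencies

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]


def draw_ancestral_freqs(n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. ancestral allele frequencies ~ Uniform(0.001, 0.999)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return rng.uniform(ANCESTRAL_FREQ_LOW, ANCESTRAL_FREQ_HIGH, size=n_loci)


def effective_fst(
    p_anc: np.ndarray | float, fst_background: float, delta: float
) -> np.ndarray | float:
    """MAF-linked effective F_ST: ``F_bg + (1 - MAF) * delta``, clamped.

    ``MAF = min(p, 1 - p)`` is the ancestral minor allele frequency.  With
    ``delta = 0`` this is the fixed-F_ST mode and returns the background
    value unchanged (up to the clamp).  The result is clamped to
    ``[FST_EPS, 1 - FST_EPS]`` because with large background values the
    increment can push F_ST beyond 1, which would break the Beta shapes.
    """
    if not 0.0 < fst_background < 1.0:
        raise ValueError("fst_background must lie in (0, 1)")
    if delta < 0.0:
        raise ValueError("delta must be >= 0")
    p = np.asarray(p_anc, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    fst = np.clip(fst_background + (1.0 - maf) * delta, FST_EPS, 1.0 - FST_EPS)
    return float(fst) if np.isscalar(p_anc) else fst


def draw_population_freqs(
    p_anc: np.ndarray, fst: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (p1, p2) independently from the Balding–Nichols Beta per locus."""
    p = np.asarray(p_anc, dtype=float)
    f = np.broadcast_to(np.asarray(fst, dtype=float), p.shape)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must lie in (0, 1)")
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("fst must lie in (0, 1)")
    ratio = (1.0 - f) / f
    a = p * ratio
    b = (1.0 - p) * ratio
    return rng.beta(a, b), rng.beta(a, b)


def build_locus_frequencies(
    n_loci: int,
    causal_idx: np.ndarray,
    rng: np.random.Generator,
    *,
    fst_background: float = 0.2,
    delta: float = 0.3,
    fst_fixed: float | None = None,
) -> LocusFrequencies:
    """Draw the full frequency table for one simulated replicate.

    Causal loci receive the trait F_ST — either the MAF-linked flexible
    value ``F_bg + (1 - MAF) * delta`` or, when ``fst_fixed`` is given,
    that constant — while non-causal loci always receive the genome-wide
    background F_ST.  Causal loci that come out with both population
    frequencies exactly zero (sign-assignment would be undefined there)
    are redrawn.
    """
    p_anc = draw_ancestral_freqs(n_loci, rng)
    fst = np.full(n_loci, float(fst_background))
    causal_idx = np.asarray(causal_idx, dtype=np.intp)
    if fst_fixed is not None:
        if not 0.0 < fst_fixed < 1.0:
            raise ValueError("fst_fixed must lie in (0, 1)")
        fst[causal_idx] = fst_fixed
    else:
        fst[causal_idx] = effective_fst(p_anc[causal_idx], fst_background, delta)
    p1, p2 = draw_population_freqs(p_anc, fst, rng)
    # redraw degenerate causal loci where both populations lost the allele
    for _ in range(100):
        bad = causal_idx[(p1[causal_idx] + p2[causal_idx]) == 0.0]
        if bad.size == 0:
            break
        p1[bad], p2[bad] = draw_population_freqs(p_anc[bad], fst[bad], rng)
    return LocusFrequencies(p_anc=p_anc, fst=fst, p1=p1, p2=p2)


def sample_genotypes(
    local: np.ndarray, freqs: LocusFrequencies, rng: np.random.Generator
) -> GenotypeSet:
    """Sample diploid allele dosages conditional on local ancestry.

    Each haplotype copy carries a Bernoulli draw with success probability
    ``p1`` or ``p2`` at the locus, according to that copy's local-ancestry
    origin; the dosage is the sum over the two copies.
    """
    local = np.asarray(local)
    if local.ndim != 3 or local.shape[2] != 2:
        raise ValueError("local ancestry must have shape (n_individuals, n_loci, 2)")
    if local.shape[1] != freqs.n_loci:
        raise ValueError(
            f"locus count mismatch: local ancestry has {local.shape[1]} loci, "
            f"frequencies have {freqs.n_loci}"
        )
    hap_freq = np.where(local == POP1, freqs.p1[None, :, None], freqs.p2[None, :, None])
    alleles = rng.random(local.shape) < hap_freq
    dosages = alleles.sum(axis=2).astype(np.int8)
    return GenotypeSet(dosages=dosages, local=local, freqs=freqs)


@dataclass(frozen=True)
class WcFstResult:
    """Per-locus and multi-locus (ratio-of-averages) Weir–Cockerham estimates."""

    per_locus: np.ndarray  # NaN at loci monomorphic in both samples
    overall: float


def wc_fst_estimate(
    dosages_pop1: np.ndarray, dosages_pop2: np.ndarray
) -> WcFstResult:
    """Weir–Cockerham (1984) theta-hat between two diploid samples.

    Variance-components estimator for two populations from biallelic
    diploid genotype matrices over the same loci.  The multi-locus
    estimate is the ratio of averages sum(a) / sum(a + b + c); loci
    monomorphic in both samples contribute nothing and are NaN per locus.
    The estimator is not truncated, so undifferentiated loci can go
    slightly negative.
    """
    g1 = np.asarray(dosages_pop1, dtype=float)
    g2 = np.asarray(dosages_pop2, dtype=float)
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != g2.shape[1]:
        raise ValueError("need two (n_individuals, n_loci) matrices over the same loci")
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each population needs at least 2 individuals")

    r = 2.0
    n1, n2 = float(g1.shape[0]), float(g2.shape[0])
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)

    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    h1 = (g1 == 1).mean(axis=0)  # observed heterozygote frequency
    h2 = (g2 == 1).mean(axis=0)

    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0

    denom = a + b + c
    polymorphic = denom != 0.0
    per_locus = np.full(g1.shape[1], np.nan)
    per_locus[polymorphic] = a[polymorphic] / denom[polymorphic]
    if not np.any(polymorphic):
        raise ValueError("all loci are monomorphic in both samples")
    overall = float(a[polymorphic].sum() / denom[polymorphic].sum())
    return WcFstResult(per_locus=per_locus, overall=overall)
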