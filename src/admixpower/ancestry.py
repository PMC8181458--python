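"""Global- and local-ancestry sampling for a two-way admixed population.

Global ancestry (the genome-wide fraction ``theta`` of an individual's
genome inherited from source Population 1) is modeled as a Beta random
variable parameterized by its mean ``m`` and variance ``v`` — the
method-of-moments parameterization, so the Beta distribution reproduces
the requested moments exactly.  Local ancestry (the source population of
each haplotype copy at each locus) is then drawn per haplotype as an
independent Bernoulli(theta) trial over a set of LD-independent loci.

The ancestral (non-admixed) source populations are represented as the
degenerate cases ``theta == 1`` (Population 1) and ``theta == 0``
(Population 2), so the same genotype sampler serves all three cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "POP1",
    "POP2",
    "AdmixtureSpec",
    "beta_shapes_from_moments",
    "sample_global_ancestry",
    "sample_local_ancestry",
    "constant_ancestry",
]

#: Local-ancestry codes for the two source populations.
POP1: int = 1
POP2: int = 2

#: Global-ancestry draws are clipped into [THETA_EPS, 1 - THETA_EPS] so the
#: downstream Bernoulli/binomial sampling and regression scans stay
#: well-posed even for extreme Beta shapes.
THETA_EPS: float = 1e-6


@dataclass(frozen=True)
class AdmixtureSpec:
    """Population-level ancestry parameters for one admixed cohort.

    Parameters
    ----------
    mean
        Mean ``m`` of the Population-1 global ancestry fraction, in (0, 1).
    variance
        Variance ``v`` of the global ancestry fraction.  Must satisfy
        ``0 < v < m * (1 - m)``; outside this range the implied Beta
        shapes are non-positive.
    n_individuals
        Cohort size, at least 1.
    """

    mean: float
    variance: float
    n_individuals: int

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError(f"ancestry mean must lie in (0, 1), got {self.mean}")
        bound = self.mean * (1.0 - self.mean)
        if not 0.0 < self.variance < bound:
            raise ValueError(
                "ancestry variance must lie in (0, m*(1-m)) = "
                f"(0, {bound:.6g}), got {self.variance}"
            )
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    @property
    def beta_shapes(self) -> tuple[float, float]:
        return beta_shapes_from_moments(self.mean, self.variance)


def beta_shapes_from_moments(m: float, v: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) with mean exactly ``m`` and variance ``v``.

    Uses the method-of-moments identities
    ``a = m * (m * (1 - m) / v - 1)`` and ``b = a * (1 - m) / m``.

    Raises
    ------
    ValueError
        If ``m`` is outside (0, 1) or ``v >= m * (1 - m)`` (infeasible
        variance for a Beta distribution) or ``v <= 0``.
    """
    if not 0.0 < m < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {m}")
    if not 0.0 < v < m * (1.0 - m):
        raise ValueError(
            f"variance must lie in (0, m*(1-m)) = (0, {m * (1 - m):.6g}), got {v}"
        )
    nu = m * (1.0 - m) / v - 1.0  # total concentration a + b
    return m * nu, (1.0 - m) * nu


def sample_global_ancestry(spec: AdmixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-individual global ancestry fractions theta ~ Beta(a, b).

    Returns a float array of length ``spec.n_individuals`` with entries in
    ``[THETA_EPS, 1 - THETA_EPS]``.
    """
    a, b = spec.beta_shapes
    theta = rng.beta(a, b, size=spec.n_individuals)
    return np.clip(theta, THETA_EPS, 1.0 - THETA_EPS)


def constant_ancestry(value: float, n_individuals: int) -> np.ndarray:
    """Degenerate global-ancestry vector for a homogeneous source cohort.

    ``value=1.0`` represents Population 1, ``value=0.0`` Population 2.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("ancestry fraction must lie in [0, 1]")
    return np.full(n_individuals, float(value))


def sample_local_ancestry(
    theta: np.ndarray, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample per-haplotype local-ancestry origins given global ancestry.

    Each of the two haplotype copies at each of ``n_loci`` LD-independent
    loci is an independent Bernoulli(theta_i) draw of POP1 vs POP2, so the
    Population-1 haplotype count at a locus is Binomial(2, theta_i).

    Returns
    -------
    numpy.ndarray
        uint8 array of shape ``(n_individuals, n_loci, 2)`` with entries in
        ``{POP1, POP2}``.
    """
    theta = np.asarray(theta, dtype=float)
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    u = rng.random((theta.shape[0], n_loci, 2))
    origins = np.where(u < theta[:, None, None], POP1, POP2)
    return origins.astype(np.uint8)
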