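"""Per-locus association scans and power / false-positive summaries.

Quantitative traits are scanned with per-locus linear regression,
dichotomous traits with per-locus logistic regression, optionally with
global ancestry as a fixed-effect covariate (the convention for the
admixed cohort, where uncorrected population structure inflates false
positives).  Two-sided Wald tests on the dosage coefficient.

Power is the proportion of causal loci reaching significance; the false
positive rate is the same proportion over the non-causal loci.  Loci
removed by the MAF filter, monomorphic in the analyzed cohort, or with
non-converged logistic fits are untested and count as non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._regression import linear_scan_stats, logistic_scan_stats
from .genotype import GenotypeSet
from .trait import PhenotypeSet

__all__ = [
    "AssocTable",
    "PowerSummary",
    "assoc_scan",
    "maf_filter",
    "significant_mask",
    "power_estimate",
    "false_positive_rate",
]


@dataclass
class AssocTable:
    """Per-locus effect estimates and Wald p-values from one scan."""

    beta: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    tested: np.ndarray
    mode: str
    n_obs: int

    @property
    def n_loci(self) -> int:
        return self.p_value.shape[0]

    def to_frame(
        self, causal_idx: np.ndarray | None = None, population: str | None = None
    ) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "locus_id": np.arange(self.n_loci),
                "beta_hat": self.beta,
                "se": self.se,
                "p_value": self.p_value,
                "tested": self.tested,
            }
        )
        if causal_idx is not None:
            is_causal = np.zeros(self.n_loci, dtype=bool)
            is_causal[np.asarray(causal_idx, dtype=np.intp)] = True
            df.insert(1, "is_causal", is_causal)
        if population is not None:
            df["population"] = population
        return df


@dataclass
class PowerSummary:
    """Across-repetition mean/SD of power and mean false positive rate."""

    power_mean: float
    power_sd: float
    fpr_mean: float
    n_reps: int
    alpha: float


def maf_filter(genotypes: GenotypeSet | np.ndarray, threshold: float) -> np.ndarray:
    """Mask of loci whose sample MAF is >= threshold (inclusive) in this cohort.

    Filtering is per-cohort: the same locus may pass in the admixed cohort
    and fail in a source cohort.  ``threshold = 0`` keeps every
    polymorphic and monomorphic locus (the mask is about frequency only;
    monomorphy is handled by the scan itself).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeSet) else genotypes
    freq = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    # guard the boundary against float summation noise
    return maf >= threshold - 1e-12


def assoc_scan(
    genotypes: GenotypeSet | np.ndarray,
    phenotype: PhenotypeSet | np.ndarray,
    covariate_theta: np.ndarray | None = None,
    mode: str = "linear",
    tested_mask: np.ndarray | None = None,
) -> AssocTable:
    """Scan every locus for association with the phenotype.

    Parameters
    ----------
    genotypes
        ``GenotypeSet`` or an (n_individuals, n_loci) dosage matrix.
    phenotype
        ``PhenotypeSet`` (``y_quant`` used for linear, ``y_binary`` for
        logistic) or a raw response vector.
    covariate_theta
        Optional global-ancestry covariate (admixed cohort); the source
        cohorts are scanned without covariates.
    mode
        ``"linear"`` or ``"logistic"``.
    tested_mask
        Optional per-locus mask (e.g. from :func:`maf_filter`); masked-out
        loci are reported untested.
    """
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeSet) else genotypes
    dosages = np.asarray(dosages)
    if isinstance(phenotype, PhenotypeSet):
        if mode == "logistic":
            if phenotype.y_binary is None:
                raise ValueError("logistic scan requires a dichotomous phenotype")
            y = phenotype.y_binary
        else:
            y = phenotype.y_quant
    else:
        y = np.asarray(phenotype)
    if y.shape[0] != dosages.shape[0]:
        raise ValueError(
            f"phenotype length {y.shape[0]} != genotype rows {dosages.shape[0]}"
        )
    if mode == "linear":
        s = linear_scan_stats(dosages, y, covariate_theta, tested_mask)
    elif mode == "logistic":
        s = logistic_scan_stats(dosages, y, covariate_theta, tested_mask)
    else:
        raise ValueError("mode must be 'linear' or 'logistic'")
    return AssocTable(
        beta=s.beta,
        se=s.se,
        p_value=s.p_value,
        tested=s.tested,
        mode=mode,
        n_obs=dosages.shape[0],
    )


def significant_mask(table: AssocTable, alpha: float) -> np.ndarray:
    """Per-locus significance at level alpha (inclusive); untested loci False."""
    with np.errstate(invalid="ignore"):
        sig = table.p_value <= alpha
    return np.where(table.tested, sig, False)


def _proportion_significant(
    tables: Sequence[AssocTable], locus_idx: np.ndarray, alpha: float
) -> np.ndarray:
    locus_idx = np.asarray(locus_idx, dtype=np.intp)
    if locus_idx.size == 0:
        raise ValueError("need at least one locus")
    return np.array(
        [float(significant_mask(t, alpha)[locus_idx].mean()) for t in tables]
    )


def power_estimate(
    tables: Sequence[AssocTable],
    causal_idx: np.ndarray,
    alpha: float,
    noncausal_idx: np.ndarray | None = None,
) -> PowerSummary:
    """Mean and SD across repetitions of the causal-discovery proportion.

    The denominator is all causal loci (untested ones count as missed),
    matching the definition of power as the proportion of causal variants
    reaching significance.  SD uses the n-1 denominator.
    """
    if len(tables) < 1:
        raise ValueError("need at least one repetition")
    per_rep = _proportion_significant(tables, causal_idx, alpha)
    fpr = np.nan
    if noncausal_idx is not None:
        fpr = float(false_positive_rate(tables, noncausal_idx, alpha)[1])
    sd = float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else 0.0
    return PowerSummary(
        power_mean=float(per_rep.mean()),
        power_sd=sd,
        fpr_mean=fpr,
        n_reps=len(tables),
        alpha=alpha,
    )


def false_positive_rate(
    tables: Sequence[AssocTable], noncausal_idx: np.ndarray, alpha: float
) -> tuple[np.ndarray, float]:
    """Per-repetition and mean proportion of null loci reaching significance."""
    per_rep = _proportion_significant(tables, noncausal_idx, alpha)
    return per_rep, float(per_rep.mean())
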