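"""Run configuration: validated nested settings with standard-scenario defaults.

The default configuration is the "standard" scenario used throughout the
simulation experiments: an African-American-like admixed cohort (mean
75% Population-1 ancestry), 1000 LD-independent loci of which 100 are
causal, genome-wide background F_ST 0.2 with MAF-linked increment
delta = 0.3 at causal loci, narrow-sense heritability 0.5,
ancestry-weighted Gaussian environment, and a 5% liability threshold
for dichotomous traits.

Configuration files are YAML; unknown keys are rejected with an error
listing every offending key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "AncestryConfig",
    "LociConfig",
    "FstConfig",
    "TraitConfig",
    "AssocConfig",
    "RunConfig",
    "ExperimentGrid",
    "load_config",
    "config_hash",
    "PRESETS",
    "preset_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AncestryConfig(_Strict):
    """Global-ancestry distribution of the admixed cohort."""

    mean: float = Field(0.75, gt=0.0, lt=1.0)
    variance: float = Field(0.02, gt=0.0)
    n_individuals: int = Field(1000, ge=1)

    @model_validator(mode="after")
    def _feasible_variance(self) -> "AncestryConfig":
        bound = self.mean * (1.0 - self.mean)
        if self.variance >= bound:
            raise ValueError(
                f"ancestry.variance must be < mean*(1-mean) = {bound:.6g}"
            )
        return self


class LociConfig(_Strict):
    n_total: int = Field(1000, ge=1)
    n_causal: int = Field(100, ge=1)

    @model_validator(mode="after")
    def _causal_within_total(self) -> "LociConfig":
        if self.n_causal > self.n_total:
            raise ValueError("loci.n_causal must be <= loci.n_total")
        return self


class FstConfig(_Strict):
    """F_ST at causal loci: flexible (background + MAF-linked delta) or fixed.

    ``fixed`` is mutually exclusive with the delta mode; when set, causal
    loci get that constant while non-causal loci keep the background.
    """

    background: float = Field(0.2, gt=0.0, lt=1.0)
    delta: float = Field(0.3, ge=0.0)
    fixed: Optional[float] = Field(None, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _exclusive_modes(self) -> "FstConfig":
        if self.fixed is not None and self.delta != 0.0:
            raise ValueError(
                "fst.fixed is mutually exclusive with the delta mode; "
                "set fst.delta to 0 when fixing causal-locus F_ST"
            )
        return self


class TraitConfig(_Strict):
    type: Literal["quantitative", "dichotomous"] = "quantitative"
    h2: float = Field(0.5, gt=0.0, le=1.0)
    prevalence: float = Field(0.05, gt=0.0, lt=1.0)
    n_causal: Optional[int] = None  # alias for loci.n_causal, kept for TSV configs
    env_mode: Literal["gaussian_anc", "linear_anc"] = "gaussian_anc"
    env_anc_fraction: float = Field(0.0, ge=0.0)
    sign_mode: Literal["normalized", "ratio_capped"] = "normalized"
    # "admixed": one environmental variance for all cohorts, anchored to the
    # admixed cohort's genetic variance (keeps phenotypes on one scale);
    # "cohort": each cohort realizes the target h2 exactly on its own.
    env_scale_reference: Literal["admixed", "cohort"] = "admixed"

    @model_validator(mode="after")
    def _env_fraction_within_budget(self) -> "TraitConfig":
        if self.env_anc_fraction > 1.0 - self.h2 + 1e-12:
            raise ValueError("trait.env_anc_fraction must be <= 1 - trait.h2")
        return self


class AssocConfig(_Strict):
    alpha: list[float] = Field(default_factory=lambda: [0.05])
    maf_threshold: float = Field(0.0, ge=0.0, le=0.5)

    @model_validator(mode="after")
    def _alpha_range(self) -> "AssocConfig":
        for a in self.alpha:
            if not 0.0 < a <= 1.0:
                raise ValueError(f"assoc.alpha entries must lie in (0, 1], got {a}")
        return self


class ExperimentGrid(_Strict):
    """Grid for the power experiments (sample size x F_ST x h2 x trait type)."""

    sample_sizes: list[int] = Field(default_factory=lambda: [1000, 5000, 10000])
    fst_values: Optional[list[float]] = None  # fixed-F_ST sweep; None = flexible mode
    h2_values: list[float] = Field(default_factory=lambda: [0.5])
    trait_types: list[Literal["quantitative", "dichotomous"]] = Field(
        default_factory=lambda: ["quantitative"]
    )
    n_reps: int = Field(20, ge=2)
    alpha_levels: list[float] = Field(default_factory=lambda: [0.05])

    @model_validator(mode="after")
    def _validate(self) -> "ExperimentGrid":
        if self.fst_values is not None:
            for f in self.fst_values:
                if not 0.0 < f < 1.0:
                    raise ValueError("experiment.fst_values must lie in (0, 1)")
        for h2 in self.h2_values:
            if not 0.0 < h2 <= 1.0:
                raise ValueError("experiment.h2_values must lie in (0, 1]")
        return self


class RunConfig(_Strict):
    """Top-level validated configuration; defaults are the standard scenario."""

    ancestry: AncestryConfig = Field(default_factory=AncestryConfig)
    loci: LociConfig = Field(default_factory=LociConfig)
    fst: FstConfig = Field(default_factory=FstConfig)
    trait: TraitConfig = Field(default_factory=TraitConfig)
    assoc: AssocConfig = Field(default_factory=AssocConfig)
    experiment: ExperimentGrid = Field(default_factory=ExperimentGrid)
    master_seed: int = 0

    @model_validator(mode="after")
    def _reconcile_trait_causal(self) -> "RunConfig":
        if self.trait.n_causal is not None and self.trait.n_causal != self.loci.n_causal:
            raise ValueError(
                "trait.n_causal conflicts with loci.n_causal; set only one"
            )
        return self


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML config file; missing keys get defaults.

    An empty (or absent) file yields the full standard-scenario defaults.
    Schema violations raise a ``ValueError`` listing every offending key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = loaded
    data.update(overrides)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid configuration: {problems}") from err


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the configuration."""
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# Bundled scenario presets.  "standard" mirrors the default configuration;
# "chilean" models an Indigenous-American/European admixture with source-
# population F_ST 0.18 (the ancestry mean/variance are preset assumptions,
# see docs/methods.md).  The *-small variants are 200 x 200 test fixtures.
PRESETS: dict[str, dict] = {
    "standard": {},
    "chilean": {
        "ancestry": {"mean": 0.55, "variance": 0.02},
        "fst": {"background": 0.18, "delta": 0.3},
    },
    "standard-small": {
        "ancestry": {"mean": 0.75, "variance": 0.02, "n_individuals": 200},
        "loci": {"n_total": 200, "n_causal": 20},
    },
    "high-fst-small": {
        "ancestry": {"mean": 0.75, "variance": 0.02, "n_individuals": 200},
        "loci": {"n_total": 200, "n_causal": 20},
        "fst": {"background": 0.2, "delta": 0.0, "fixed": 0.8},
    },
    "chilean-small": {
        "ancestry": {"mean": 0.55, "variance": 0.02, "n_individuals": 200},
        "loci": {"n_total": 200, "n_causal": 20},
        "fst": {"background": 0.18, "delta": 0.3},
    },
}


def preset_config(name: str, **overrides) -> RunConfig:
    """Instantiate one of the bundled scenario presets by name."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    data = json.loads(json.dumps(PRESETS[name]))  # deep copy
    data.update(overrides)
    return RunConfig.model_validate(data)
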