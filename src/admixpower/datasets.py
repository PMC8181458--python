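"""Small deterministic simulated cohorts for tests and examples.

These go through the real simulation pipeline (nothing is mocked or
pre-stored); they are merely small (200 individuals x 200 loci) so test
suites stay fast.
"""

from __future__ import annotations

from .config import preset_config
from .pipelines import RepetitionData, simulate_repetition

__all__ = ["FIXTURE_PRESETS", "fixture_cohorts"]

FIXTURE_PRESETS = ("standard-small", "high-fst-small", "chilean-small")


def fixture_cohorts(preset_name: str, seed: int) -> RepetitionData:
    """Simulate the three 200x200 cohorts for one of the small presets.

    Deterministic in ``seed``; returns the full RepetitionData bundle
    (shared frequencies and architecture plus admixed/pop1/pop2 cohorts
    with genotypes and phenotypes).
    """
    if preset_name not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; choose from {FIXTURE_PRESETS}"
        )
    cfg = preset_config(preset_name, master_seed=int(seed))
    return simulate_repetition(cfg, int(seed))
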