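"""Writers for simulated cohorts: TSV, VCF 4.2, and JSON run manifests.

The VCF export uses synthetic coordinates (contig ``chr1``, positions
spaced 1 Mb apart) because the simulated loci are LD-independent and
carry no reference-genome identity — this is stated loudly in the
header.  Besides the GT genotype field, each sample carries a custom
``LA`` FORMAT field with the two local-ancestry origins (one digit per
haplotype: 1 = Population 1, 2 = Population 2), and each record's INFO
carries the generative population frequencies and effective F_ST.
"""

from __future__ import annotations

import datetime
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .genotype import GenotypeSet
from .pipelines import SimulatedCohort

__all__ = [
    "write_ancestry_tsv",
    "write_phenotypes_tsv",
    "write_assoc_tsv",
    "write_vcf",
    "write_manifest",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}
_VCF_POS_SPACING = 1_000_000


def write_ancestry_tsv(theta: np.ndarray, path: str | Path) -> None:
    """One row per individual: individual_id, theta_pop1."""
    df = pd.DataFrame(
        {"individual_id": [f"ind{i:06d}" for i in range(len(theta))],
         "theta_pop1": np.asarray(theta, float)}
    )
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(cohort: SimulatedCohort, path: str | Path) -> None:
    """Per-individual ancestry, scores, and phenotype values."""
    ph = cohort.phenotypes
    df = pd.DataFrame(
        {
            "individual_id": [f"ind{i:06d}" for i in range(ph.n_individuals)],
            "theta": cohort.theta,
            "prs_true": ph.prs_true,
            "env_score": ph.env_score,
            "y_quant": ph.y_quant,
        }
    )
    if ph.y_binary is not None:
        df["y_binary"] = ph.y_binary
    df.to_csv(path, sep="\t", index=False)


def write_assoc_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_vcf(genotypes: GenotypeSet, path: str | Path) -> None:
    """Export a GenotypeSet as VCF 4.2 with synthetic coordinates.

    Positions are 1-based and spaced 1 Mb on contig chr1; REF/ALT are
    placeholder alleles A/T with the dosage counting ALT copies.  The LA
    FORMAT field preserves haplotype order even though GT is written
    unphased.
    """
    freqs = genotypes.freqs
    n, m = genotypes.n_individuals, genotypes.n_loci
    samples = [f"ind{i:06d}" for i in range(n)]
    dosages = genotypes.dosages
    local = genotypes.local
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=admixpower-{__version__}",
        "##reference=none",
        "##WARNING=Fully synthetic simulated genotypes: contig, positions and "
        "alleles are placeholders with no reference-genome meaning",
        f"##contig=<ID=chr1,length={(m + 1) * _VCF_POS_SPACING}>",
        '##INFO=<ID=P1AF,Number=1,Type=Float,Description="Population 1 allele frequency">',
        '##INFO=<ID=P2AF,Number=1,Type=Float,Description="Population 2 allele frequency">',
        '##INFO=<ID=FSTS,Number=1,Type=Float,Description="Effective FST used at this locus">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (unphased)">',
        '##FORMAT=<ID=LA,Number=1,Type=String,Description="Local ancestry per haplotype, '
        'one digit each (1=Population 1, 2=Population 2); haplotype order preserved">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for s in range(m):
        info = (
            f"P1AF={freqs.p1[s]:.6g};P2AF={freqs.p2[s]:.6g};FSTS={freqs.fst[s]:.6g}"
        )
        fields = [
            "chr1",
            str((s + 1) * _VCF_POS_SPACING),
            f"sim{s:06d}",
            "A",
            "T",
            ".",
            "PASS",
            info,
            "GT:LA",
        ]
        la = local[:, s, :]
        fields.extend(
            f"{_GT[int(dosages[i, s])]}:{la[i, 0]}{la[i, 1]}" for i in range(n)
        )
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(
    cfg: RunConfig,
    path: str | Path,
    outputs: list[str],
    started: datetime.datetime,
    master_seed: int | None = None,
) -> dict:
    """Write the JSON run manifest atomically (temp file + rename).

    Records everything needed to reproduce the run bitwise: the config
    hash, the master seed, and the software version.
    """
    manifest = {
        "config_hash": config_hash(cfg),
        "config": cfg.model_dump(mode="json"),
        "master_seed": int(master_seed if master_seed is not None else cfg.master_seed),
        "software_version": __version__,
        "started": started.isoformat(),
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": list(outputs),
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2) + "\n")
    os.replace(tmp, path)
    return manifest
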