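"""Experiment orchestration: power grids, replication asymmetry, PRS transfer.

Every experiment simulates three cohorts per repetition under a shared
genetic architecture (same locus frequencies, causal loci, and weights):
the admixed cohort plus the two homogeneous source cohorts, represented
as the degenerate ancestry cases theta == 1 (Population 1) and
theta == 0 (Population 2).  Holding genetics fixed across cohorts makes
the cross-population power, replication, and portability comparisons
about ancestry composition only.

Randomness flows from one master seed through ``numpy.random.SeedSequence``
children keyed by (experiment, cell, repetition, population), so results
are bitwise reproducible and independent of execution order; repetitions
may run in parallel (joblib) and are re-ordered before reporting.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import optimize, special, stats

from ._regression import logistic_scan_stats
from .ancestry import AdmixtureSpec, constant_ancestry, sample_global_ancestry, sample_local_ancestry
from .assoc import AssocTable, assoc_scan, maf_filter, significant_mask
from .config import ExperimentGrid, RunConfig
from .genotype import GenotypeSet, LocusFrequencies, build_locus_frequencies, sample_genotypes
from .trait import (
    PhenotypeSet,
    TraitArchitecture,
    assemble_phenotype,
    assign_effects,
    compute_prs,
    draw_causal_indices,
    simulate_environment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "POPULATIONS",
    "SimulatedCohort",
    "RepetitionData",
    "child_seed_sequence",
    "simulate_repetition",
    "run_power_grid",
    "power_ratio_table",
    "ReplicationResult",
    "replication_experiment",
    "PRSAccuracy",
    "PRSTransferResult",
    "prs_transferability",
    "ancestry_trait_power_estimate",
]

POPULATIONS = ("admixed", "pop1", "pop2")
_POP_THETA = {"pop1": 1.0, "pop2": 0.0}


def child_seed_sequence(master_seed: int, *key: int | str) -> np.random.SeedSequence:
    """Deterministic child seed stream for a (experiment, cell, rep, ...) tuple.

    String key components are hashed with crc32 so the mapping is stable
    across runs and platforms.
    """
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=ints)


@dataclass
class SimulatedCohort:
    """One cohort's ancestry, genotypes, and phenotypes."""

    name: str
    theta: np.ndarray
    genotypes: GenotypeSet
    phenotypes: PhenotypeSet


@dataclass
class RepetitionData:
    """Shared frequencies/architecture plus the per-cohort simulations."""

    freqs: LocusFrequencies
    architecture: TraitArchitecture
    cohorts: dict[str, SimulatedCohort] = field(default_factory=dict)


def simulate_repetition(
    cfg: RunConfig,
    seed: np.random.SeedSequence | int,
    populations: tuple[str, ...] = POPULATIONS,
    n_individuals: int | None = None,
) -> RepetitionData:
    """Simulate one repetition: shared architecture, one cohort per population.

    By default (``trait.env_scale_reference == "admixed"``) the
    environmental variance is anchored to the admixed cohort's realized
    genetic variance and reused for the source cohorts, so all cohorts
    share one phenotypic scale; with ``"cohort"`` each cohort scales its
    own environment so the target heritability holds within every cohort.
    When the admixed cohort is not simulated, each cohort falls back to
    its own genetic variance.
    """
    unknown = set(populations) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown populations {sorted(unknown)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    streams = dict(zip(("shared",) + POPULATIONS, ss.spawn(1 + len(POPULATIONS))))
    rng_shared = np.random.default_rng(streams["shared"])
    n = n_individuals if n_individuals is not None else cfg.ancestry.n_individuals

    causal_idx = draw_causal_indices(cfg.loci.n_total, cfg.loci.n_causal, rng_shared)
    freqs = build_locus_frequencies(
        cfg.loci.n_total,
        causal_idx,
        rng_shared,
        fst_background=cfg.fst.background,
        delta=cfg.fst.delta,
        fst_fixed=cfg.fst.fixed,
    )
    weights = assign_effects(
        freqs, causal_idx, rng_shared, sign_mode=cfg.trait.sign_mode
    )
    arch = TraitArchitecture(
        causal_idx=causal_idx,
        weights=weights,
        h2=cfg.trait.h2,
        env_mode=cfg.trait.env_mode,
        env_anc_fraction=cfg.trait.env_anc_fraction,
        prevalence=cfg.trait.prevalence,
    )

    data = RepetitionData(freqs=freqs, architecture=arch)
    prs_by_pop: dict[str, np.ndarray] = {}
    geno_by_pop: dict[str, GenotypeSet] = {}
    theta_by_pop: dict[str, np.ndarray] = {}
    for pop in populations:
        rng = np.random.default_rng(streams[pop])
        if pop == "admixed":
            spec = AdmixtureSpec(cfg.ancestry.mean, cfg.ancestry.variance, n)
            theta = sample_global_ancestry(spec, rng)
        else:
            theta = constant_ancestry(_POP_THETA[pop], n)
        local = sample_local_ancestry(theta, cfg.loci.n_total, rng)
        geno = sample_genotypes(local, freqs, rng)
        theta_by_pop[pop] = theta
        geno_by_pop[pop] = geno
        prs_by_pop[pop] = compute_prs(geno, arch)

    env_var = None
    if (
        cfg.trait.env_scale_reference == "admixed"
        and "admixed" in populations
        and arch.h2 < 1.0
    ):
        v_g = float(np.var(prs_by_pop["admixed"]))
        if v_g <= 0.0:
            raise RuntimeError("admixed cohort has zero genetic variance")
        env_var = v_g * (1.0 - arch.h2) / arch.h2

    for pop in populations:
        rng_env = np.random.default_rng(streams[pop].spawn(1)[0])
        env = simulate_environment(
            theta_by_pop[pop], prs_by_pop[pop], arch, rng_env, env_var=env_var
        )
        pheno = assemble_phenotype(
            prs_by_pop[pop],
            env,
            trait_type=cfg.trait.type,
            prevalence=cfg.trait.prevalence,
        )
        data.cohorts[pop] = SimulatedCohort(
            name=pop, theta=theta_by_pop[pop], genotypes=geno_by_pop[pop], phenotypes=pheno
        )
    return data


def _scan_cohort(cohort: SimulatedCohort, cfg: RunConfig) -> AssocTable:
    """Scan one cohort: ancestry covariate in the admixed cohort only."""
    mode = "logistic" if cfg.trait.type == "dichotomous" else "linear"
    covar = cohort.theta if cohort.name == "admixed" else None
    mask = None
    if cfg.assoc.maf_threshold > 0.0:
        mask = maf_filter(cohort.genotypes, cfg.assoc.maf_threshold)
    return assoc_scan(cohort.genotypes, cohort.phenotypes, covar, mode, mask)


# ---------------------------------------------------------------------------
# power grid


def _power_grid_cell_rep(
    cfg_cell: RunConfig,
    cell_meta: dict,
    cell_index: int,
    rep: int,
    master_seed: int,
    alpha_levels: list[float],
) -> list[dict]:
    ss = child_seed_sequence(master_seed, "power_grid", cell_index, rep)
    sim = simulate_repetition(cfg_cell, ss)
    causal = sim.architecture.causal_idx
    noncausal = np.setdiff1d(np.arange(cfg_cell.loci.n_total), causal)
    rows = []
    for pop, cohort in sim.cohorts.items():
        table = _scan_cohort(cohort, cfg_cell)
        for alpha in alpha_levels:
            sig = significant_mask(table, alpha)
            row = {
                **cell_meta,
                "rep": rep,
                "population": pop,
                "alpha": alpha,
                "power": float(sig[causal].mean()),
                "fpr": float(sig[noncausal].mean()) if noncausal.size else np.nan,
            }
            rows.append(row)
    return rows


def run_power_grid(
    grid: ExperimentGrid,
    base: RunConfig | None = None,
    master_seed: int | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Power/FPR over the (sample size x F_ST x h2 x trait type) grid.

    Returns a long-format table with one row per grid cell, repetition,
    population, and significance level.  ``grid.fst_values`` set means the
    fixed-F_ST sweep at causal loci (background kept at ``base.fst.background``
    for the null loci); ``None`` means the flexible MAF-linked mode from
    ``base.fst``.
    """
    base = base if base is not None else RunConfig()
    master = master_seed if master_seed is not None else base.master_seed

    if grid.fst_values is None:
        fst_settings: list[tuple[str, float | None]] = [("flexible", None)]
    else:
        fst_settings = [("fixed", float(v)) for v in grid.fst_values]

    cells = list(
        itertools.product(
            grid.sample_sizes, fst_settings, grid.h2_values, grid.trait_types
        )
    )
    tasks = []
    for cell_index, (n, (fst_mode, fst_val), h2, trait_type) in enumerate(cells):
        cfg_cell = base.model_copy(deep=True)
        cfg_cell.ancestry.n_individuals = int(n)
        cfg_cell.trait.h2 = float(h2)
        cfg_cell.trait.type = trait_type
        if fst_mode == "fixed":
            cfg_cell.fst.delta = 0.0
            cfg_cell.fst.fixed = fst_val
        meta = {
            "sample_size": int(n),
            "fst_mode": fst_mode,
            "fst": fst_val if fst_val is not None else base.fst.background,
            "h2": float(h2),
            "trait_type": trait_type,
        }
        for rep in range(grid.n_reps):
            tasks.append((cfg_cell, meta, cell_index, rep))

    results = Parallel(n_jobs=n_jobs)(
        delayed(_power_grid_cell_rep)(
            cfg_cell, meta, cell_index, rep, master, list(grid.alpha_levels)
        )
        for cfg_cell, meta, cell_index, rep in tasks
    )
    rows = [row for chunk in results for row in chunk]
    return pd.DataFrame(rows)


def power_ratio_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell/repetition ratio of admixed power to mean ancestral power.

    Repetitions where both source cohorts have zero power are excluded
    (the ratio is undefined there); the excluded count is logged.
    """
    keys = ["sample_size", "fst_mode", "fst", "h2", "trait_type", "alpha", "rep"]
    wide = results.pivot_table(index=keys, columns="population", values="power")
    wide = wide.reset_index()
    wide["ancestral_mean_power"] = (wide["pop1"] + wide["pop2"]) / 2.0
    undefined = wide["ancestral_mean_power"] == 0.0
    if undefined.any():
        logger.info(
            "power_ratio_table: excluding %d repetition(s) with zero mean "
            "ancestral power",
            int(undefined.sum()),
        )
    wide = wide.loc[~undefined].copy()
    wide["power_ratio"] = wide["admixed"] / wide["ancestral_mean_power"]
    return wide


# ---------------------------------------------------------------------------
# replication asymmetry


@dataclass
class ReplicationResult:
    """Replication proportions per repetition and direction, plus the test.

    ``table`` has one row per repetition and direction
    (``admixed_to_pop1`` / ``pop1_to_admixed``) with the discovered and
    replicated counts; ``wilcoxon_p`` is the one-sided rank test of
    admixed-to-Pop1 replication exceeding the reverse direction.
    """

    table: pd.DataFrame
    wilcoxon_p: float
    n_skipped: int


def _replication_rep(
    cfg: RunConfig, rep: int, master_seed: int, alpha: float, causal_only: bool
) -> list[dict]:
    ss = child_seed_sequence(master_seed, "replication", rep)
    sim = simulate_repetition(cfg, ss, populations=("admixed", "pop1"))
    adx, p1 = sim.cohorts["admixed"], sim.cohorts["pop1"]
    thr = cfg.assoc.maf_threshold
    common = maf_filter(adx.genotypes, thr) & maf_filter(p1.genotypes, thr)
    mode = "logistic" if cfg.trait.type == "dichotomous" else "linear"
    t_adx = assoc_scan(adx.genotypes, adx.phenotypes, adx.theta, mode)
    t_p1 = assoc_scan(p1.genotypes, p1.phenotypes, None, mode)
    causal_mask = np.zeros(cfg.loci.n_total, dtype=bool)
    causal_mask[sim.architecture.causal_idx] = True

    rows = []
    for direction, t_a, t_b in (
        ("admixed_to_pop1", t_adx, t_p1),
        ("pop1_to_admixed", t_p1, t_adx),
    ):
        discovered = common & significant_mask(t_a, alpha)
        if causal_only:
            discovered &= causal_mask
        n_disc = int(discovered.sum())
        if n_disc == 0:
            rows.append(
                {
                    "rep": rep,
                    "direction": direction,
                    "n_discovered": 0,
                    "n_replicated": 0,
                    "proportion": np.nan,
                }
            )
            continue
        replicated = discovered & significant_mask(t_b, alpha)
        n_rep = int(replicated.sum())
        rows.append(
            {
                "rep": rep,
                "direction": direction,
                "n_discovered": n_disc,
                "n_replicated": n_rep,
                "proportion": n_rep / n_disc,
            }
        )
    return rows


def replication_experiment(
    cfg: RunConfig,
    n_reps: int = 20,
    alpha: float = 0.05,
    causal_only: bool = False,
    paired: bool = False,
    master_seed: int | None = None,
    n_jobs: int = 1,
) -> ReplicationResult:
    """Reciprocal replication between the admixed cohort and Population 1.

    Per repetition, loci common (sample MAF >= ``cfg.assoc.maf_threshold``)
    in both cohorts are scanned in each cohort; loci significant at
    ``alpha`` in the discovery cohort are re-looked-up in the other cohort
    at the same ``alpha``, and the replicated proportion is recorded for
    both directions.  The replication threshold equals the discovery
    threshold.  A one-sided Wilcoxon rank test across repetitions
    (rank-sum by default, signed-rank when ``paired=True``) compares the
    two directions.
    """
    master = master_seed if master_seed is not None else cfg.master_seed
    results = Parallel(n_jobs=n_jobs)(
        delayed(_replication_rep)(cfg, rep, master, alpha, causal_only)
        for rep in range(n_reps)
    )
    table = pd.DataFrame([row for chunk in results for row in chunk])
    n_skipped = int(table["proportion"].isna().sum())
    if n_skipped:
        logger.info(
            "replication_experiment: %d repetition-direction(s) had zero "
            "discoveries and contribute no proportion",
            n_skipped,
        )
    fwd = table.loc[table.direction == "admixed_to_pop1", ["rep", "proportion"]]
    rev = table.loc[table.direction == "pop1_to_admixed", ["rep", "proportion"]]
    if paired:
        merged = fwd.merge(rev, on="rep", suffixes=("_fwd", "_rev")).dropna()
        diffs = merged.proportion_fwd - merged.proportion_rev
        if (diffs != 0).sum() == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    else:
        x = fwd.proportion.dropna().to_numpy()
        y = rev.proportion.dropna().to_numpy()
        p = float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)
    return ReplicationResult(table=table, wilcoxon_p=p, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# PRS transferability


@dataclass
class PRSAccuracy:
    """Train x test matrix of mean PRS accuracy with bootstrap CIs.

    ``mean``, ``ci_low`` and ``ci_high`` are DataFrames indexed by training
    population with test populations as columns; accuracy is the Pearson
    correlation between estimated and true PRS in the held-out test
    individuals, averaged over repetitions, with a percentile bootstrap
    (default 1000 resamples) 95% CI of the mean.
    """

    mean: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    mode: str
    alpha: float
    n_reps: int


@dataclass
class PRSTransferResult:
    """Raw per-repetition accuracies for every train/test pair, mode, alpha."""

    table: pd.DataFrame
    n_boot: int
    master_seed: int

    def summarize(self, mode: str, alpha: float) -> PRSAccuracy:
        sub = self.table[(self.table["mode"] == mode) & (self.table["alpha"] == alpha)]
        if sub.empty:
            raise ValueError(f"no results for mode={mode!r}, alpha={alpha}")
        rng = np.random.default_rng(
            child_seed_sequence(self.master_seed, "prs_bootstrap")
        )
        pops = sorted(sub["train_pop"].unique())
        mean = pd.DataFrame(index=pops, columns=pops, dtype=float)
        lo = mean.copy()
        hi = mean.copy()
        for (tr, te), grp in sub.groupby(["train_pop", "test_pop"]):
            r = grp["r"].dropna().to_numpy()
            if r.size == 0:
                continue
            mean.loc[tr, te] = r.mean()
            draws = rng.choice(r, size=(self.n_boot, r.size), replace=True).mean(axis=1)
            lo.loc[tr, te] = np.quantile(draws, 0.025)
            hi.loc[tr, te] = np.quantile(draws, 0.975)
        n_reps = int(sub["rep"].nunique())
        return PRSAccuracy(mean=mean, ci_low=lo, ci_high=hi, mode=mode,
                           alpha=alpha, n_reps=n_reps)


def _prs_rep(
    cfg: RunConfig,
    rep: int,
    master_seed: int,
    n_train: int,
    n_test: int,
    alphas: tuple[float, ...],
    modes: tuple[str, ...],
    populations: tuple[str, ...],
) -> list[dict]:
    ss = child_seed_sequence(master_seed, "prs_transfer", rep)
    sim = simulate_repetition(
        cfg, ss, populations=populations, n_individuals=n_train + n_test
    )
    causal_mask = np.zeros(cfg.loci.n_total, dtype=bool)
    causal_mask[sim.architecture.causal_idx] = True
    mode_scan = "logistic" if cfg.trait.type == "dichotomous" else "linear"
    thr = cfg.assoc.maf_threshold

    rows = []
    trained: dict[str, tuple[AssocTable, np.ndarray]] = {}
    for pop in populations:
        cohort = sim.cohorts[pop]
        g_train = cohort.genotypes.dosages[:n_train]
        y_train = (
            cohort.phenotypes.y_binary[:n_train]
            if mode_scan == "logistic"
            else cohort.phenotypes.y_quant[:n_train]
        )
        covar = cohort.theta[:n_train] if pop == "admixed" else None
        mask = maf_filter(g_train, thr) if thr > 0 else None
        table = assoc_scan(g_train, y_train, covar, mode_scan, mask)
        trained[pop] = (table, causal_mask)

    for train_pop in populations:
        table, _ = trained[train_pop]
        for mode in modes:
            for alpha in alphas:
                selected = significant_mask(table, alpha)
                if mode == "true_positives":
                    selected = selected & causal_mask
                elif mode != "all_positives":
                    raise ValueError(
                        "mode must be 'true_positives' or 'all_positives'"
                    )
                sel_idx = np.flatnonzero(selected)
                for test_pop in populations:
                    cohort = sim.cohorts[test_pop]
                    g_test = cohort.genotypes.dosages[n_train:]
                    prs_true = cohort.phenotypes.prs_true[n_train:]
                    r = np.nan
                    if sel_idx.size:
                        est = g_test[:, sel_idx].astype(float) @ table.beta[sel_idx]
                        if np.std(est) > 0 and np.std(prs_true) > 0:
                            r = float(np.corrcoef(est, prs_true)[0, 1])
                    rows.append(
                        {
                            "rep": rep,
                            "train_pop": train_pop,
                            "test_pop": test_pop,
                            "mode": mode,
                            "alpha": alpha,
                            "n_selected": int(sel_idx.size),
                            "r": r,
                        }
                    )
    return rows


def prs_transferability(
    cfg: RunConfig,
    n_train: int = 10000,
    n_test: int = 1000,
    alphas: tuple[float, ...] = (0.05, 5e-4, 5e-6, 5e-8),
    modes: tuple[str, ...] = ("true_positives", "all_positives"),
    n_reps: int = 20,
    populations: tuple[str, ...] = POPULATIONS,
    master_seed: int | None = None,
    n_boot: int = 1000,
    n_jobs: int = 1,
) -> PRSTransferResult:
    """Cross-population polygenic-score portability matrix.

    Per repetition and training population, per-locus regression
    coefficients from a scan of ``n_train`` individuals (restricted to
    loci with training-sample MAF >= ``cfg.assoc.maf_threshold``) serve as
    estimated weights; scores for ``n_test`` held-out individuals of each
    test population are the weighted dosage sums over the selected loci,
    and accuracy is their Pearson correlation with the true PRS.
    ``true_positives`` selects significant loci that are truly causal;
    ``all_positives`` admits every significant locus.
    """
    master = master_seed if master_seed is not None else cfg.master_seed
    results = Parallel(n_jobs=n_jobs)(
        delayed(_prs_rep)(
            cfg, rep, master, n_train, n_test, tuple(alphas), tuple(modes),
            tuple(populations),
        )
        for rep in range(n_reps)
    )
    table = pd.DataFrame([row for chunk in results for row in chunk])
    return PRSTransferResult(table=table, n_boot=n_boot, master_seed=master)


# ---------------------------------------------------------------------------
# trait ~ global ancestry power (no genotypes)


def ancestry_trait_power_estimate(
    incidence: float,
    admixture_spec: AdmixtureSpec,
    ancestry_effect: float,
    n: int | None = None,
    n_reps: int = 200,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> float:
    """Power to detect a dichotomous trait ~ global ancestry correlation.

    Builds phenotypes from global ancestries alone, without genotypes: per
    repetition, theta is drawn from the admixture Beta distribution, case
    status follows a logistic model with slope ``ancestry_effect``
    (log-odds per unit theta) and an intercept solved numerically so the
    expected prevalence in the drawn cohort equals ``incidence``; the
    trait is then tested against theta by logistic regression.  Returns
    the proportion of repetitions significant at ``alpha`` — a design aid
    for judging whether a sample size can reveal a trait-ancestry
    correlation at a given incidence.
    """
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must lie in (0, 1)")
    n = n if n is not None else admixture_spec.n_individuals
    if incidence * n < 5:
        logger.warning(
            "ancestry_trait_power_estimate: expected cases %.1f < 5; logistic "
            "fits may be unstable",
            incidence * n,
        )
    spec = AdmixtureSpec(admixture_spec.mean, admixture_spec.variance, n)
    hits = 0
    used = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(
            child_seed_sequence(master_seed, "ancestry_trait_power", rep)
        )
        theta = sample_global_ancestry(spec, rng)

        def prevalence_gap(b0: float) -> float:
            return float(special.expit(b0 + ancestry_effect * theta).mean()) - incidence

        b0 = optimize.brentq(prevalence_gap, -60.0, 60.0)
        y = (rng.random(n) < special.expit(b0 + ancestry_effect * theta)).astype(float)
        if y.min() == y.max():  # all cases or all controls: no test possible
            continue
        s = logistic_scan_stats(theta[:, None], y)
        if not s.tested[0]:
            continue
        used += 1
        hits += int(s.p_value[0] <= alpha)
    if used == 0:
        raise RuntimeError("no repetition produced a testable cohort")
    return hits / used
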