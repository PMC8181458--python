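"""Experiment pipelines: reproducibility, monotonicity, degenerate thresholds."""

import logging

import numpy as np
import pandas as pd
import pytest

from admixpower import (
    AdmixtureSpec,
    ExperimentGrid,
    ancestry_trait_power_estimate,
    load_config,
    power_ratio_table,
    prs_transferability,
    replication_experiment,
    run_power_grid,
    simulate_repetition,
)


def _tiny_grid(**kw):
    defaults = dict(
        sample_sizes=[300],
        fst_values=[0.5],
        h2_values=[0.5],
        trait_types=["quantitative"],
        n_reps=2,
        alpha_levels=[0.05],
    )
    defaults.update(kw)
    return ExperimentGrid(**defaults)


class TestSimulateRepetition:
    def test_identical_seed_identical_cohorts(self, standard_cfg):
        a = simulate_repetition(standard_cfg, 11)
        b = simulate_repetition(standard_cfg, 11)
        for pop in a.cohorts:
            np.testing.assert_array_equal(
                a.cohorts[pop].genotypes.dosages, b.cohorts[pop].genotypes.dosages
            )
            np.testing.assert_array_equal(
                a.cohorts[pop].phenotypes.y_quant, b.cohorts[pop].phenotypes.y_quant
            )

    def test_architecture_shared_across_cohorts(self, standard_sim):
        # same frequencies object and causal weights for all three cohorts
        for c in standard_sim.cohorts.values():
            assert c.genotypes.freqs is standard_sim.freqs

    def test_source_cohorts_are_degenerate_ancestry(self, standard_sim):
        assert np.all(standard_sim.cohorts["pop1"].theta == 1.0)
        assert np.all(standard_sim.cohorts["pop2"].theta == 0.0)

    def test_shared_env_scale_puts_cohorts_on_one_scale(self, standard_sim):
        envs = {p: np.var(c.phenotypes.env_score) for p, c in standard_sim.cohorts.items()}
        assert envs["pop1"] == pytest.approx(envs["admixed"], rel=1e-6)
        assert envs["pop2"] == pytest.approx(envs["admixed"], rel=1e-6)

    def test_per_cohort_env_scale_enforces_h2_everywhere(self):
        cfg = load_config()
        cfg.trait.env_scale_reference = "cohort"
        sim = simulate_repetition(cfg, 13)
        for c in sim.cohorts.values():
            h2 = np.var(c.phenotypes.prs_true) / np.var(c.phenotypes.y_quant)
            assert h2 == pytest.approx(0.5, abs=0.05)

    def test_dichotomous_cohorts_have_exact_prevalence(self):
        cfg = load_config()
        cfg.trait.type = "dichotomous"
        sim = simulate_repetition(cfg, 14)
        for c in sim.cohorts.values():
            assert int(c.phenotypes.y_binary.sum()) == 50  # 5% of 1000


class TestPowerGrid:
    def test_bitwise_reproducible_under_master_seed(self, standard_cfg):
        grid = _tiny_grid()
        a = run_power_grid(grid, standard_cfg, master_seed=5)
        b = run_power_grid(grid, standard_cfg, master_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_parallel_matches_serial(self, standard_cfg):
        grid = _tiny_grid()
        a = run_power_grid(grid, standard_cfg, master_seed=5, n_jobs=1)
        b = run_power_grid(grid, standard_cfg, master_seed=5, n_jobs=2)
        pd.testing.assert_frame_equal(a, b)

    def test_power_nondecreasing_in_sample_size(self, standard_cfg):
        grid = _tiny_grid(sample_sizes=[500, 4000], fst_values=None, n_reps=5)
        df = run_power_grid(grid, standard_cfg, master_seed=6)
        mean_power = df.groupby("sample_size")["power"].mean()
        assert mean_power[4000] > mean_power[500]

    def test_ratio_table_excludes_zero_ancestral_power(self):
        rows = []
        for pop, power in (("admixed", 0.5), ("pop1", 0.0), ("pop2", 0.0)):
            rows.append(dict(sample_size=100, fst_mode="fixed", fst=0.5, h2=0.5,
                             trait_type="quantitative", alpha=0.05, rep=0,
                             population=pop, power=power, fpr=0.05))
        for pop, power in (("admixed", 0.5), ("pop1", 0.2), ("pop2", 0.3)):
            rows.append(dict(sample_size=100, fst_mode="fixed", fst=0.5, h2=0.5,
                             trait_type="quantitative", alpha=0.05, rep=1,
                             population=pop, power=power, fpr=0.05))
        ratios = power_ratio_table(pd.DataFrame(rows))
        assert len(ratios) == 1
        assert ratios["power_ratio"].iloc[0] == pytest.approx(0.5 / 0.25)


@pytest.fixture(scope="module")
def small_cfg():
    cfg = load_config()
    cfg.ancestry.n_individuals = 1500
    cfg.loci.n_total = 300
    cfg.loci.n_causal = 300
    cfg.fst.delta = 0.0
    cfg.fst.fixed = 0.5
    cfg.assoc.maf_threshold = 0.05
    return cfg


@pytest.fixture(scope="module")
def prs_result():
    cfg = load_config()
    cfg.loci.n_total = 100
    cfg.loci.n_causal = 100
    cfg.assoc.maf_threshold = 0.05
    return prs_transferability(
        cfg, n_train=3000, n_test=500, alphas=(1.0, 1e-300),
        modes=("true_positives",), n_reps=2,
        populations=("admixed", "pop1"), master_seed=31,
    )


class TestReplication:

    def test_replicated_never_exceeds_discovered(self, small_cfg):
        res = replication_experiment(small_cfg, n_reps=3, master_seed=21)
        assert (res.table["n_replicated"] <= res.table["n_discovered"]).all()
        ok = res.table["proportion"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_degenerate_alpha_replicates_everything(self, small_cfg):
        res = replication_experiment(small_cfg, n_reps=2, alpha=1.0, master_seed=22)
        valid = res.table.dropna(subset=["proportion"])
        assert (valid["proportion"] == 1.0).all()

    def test_paired_and_unpaired_tests_both_valid_pvalues(self, small_cfg):
        unpaired = replication_experiment(small_cfg, n_reps=3, master_seed=23)
        paired = replication_experiment(small_cfg, n_reps=3, master_seed=23, paired=True)
        for p in (unpaired.wilcoxon_p, paired.wilcoxon_p):
            assert 0.0 <= p <= 1.0


class TestPrsTransfer:
    def test_within_population_accuracy_near_one(self, prs_result):
        """All causal loci selected (alpha=1) with a large training set gives
        nearly perfect within-population score recovery."""
        t = prs_result.table
        same = t[(t.train_pop == t.test_pop) & (t.alpha == 1.0)]
        assert (same["r"] > 0.95).all()

    def test_empty_selection_yields_missing_accuracy(self, prs_result):
        t = prs_result.table
        none_sel = t[t.alpha == 1e-300]
        assert (none_sel["n_selected"] == 0).all()
        assert none_sel["r"].isna().all()

    def test_summary_matrix_bounded_with_cis(self, prs_result):
        acc = prs_result.summarize("true_positives", 1.0)
        vals = acc.mean.to_numpy(dtype=float)
        assert np.nanmax(np.abs(vals)) <= 1.0
        assert (acc.ci_low.to_numpy(dtype=float) <= acc.ci_high.to_numpy(dtype=float)).all()


class TestAncestryTraitPower:
    SPEC = AdmixtureSpec(0.75, 0.02, 1000)

    def test_power_increases_with_sample_size(self):
        small = ancestry_trait_power_estimate(0.1, self.SPEC, 1.5, n=200,
                                              n_reps=120, master_seed=41)
        large = ancestry_trait_power_estimate(0.1, self.SPEC, 1.5, n=3000,
                                              n_reps=120, master_seed=41)
        assert large > small

    def test_power_increases_with_effect_size(self):
        weak = ancestry_trait_power_estimate(0.1, self.SPEC, 0.5, n=1000,
                                             n_reps=120, master_seed=42)
        strong = ancestry_trait_power_estimate(0.1, self.SPEC, 3.0, n=1000,
                                               n_reps=120, master_seed=42)
        assert strong > weak

    def test_low_expected_case_count_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            ancestry_trait_power_estimate(0.01, self.SPEC, 1.0, n=100,
                                          n_reps=5, master_seed=43)
        assert any("unstable" in r.message for r in caplog.records)

    def test_invalid_incidence_rejected(self):
        with pytest.raises(ValueError):
            ancestry_trait_power_estimate(1.5, self.SPEC, 1.0, n=100, n_reps=2)
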