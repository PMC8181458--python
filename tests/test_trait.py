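"""Trait architecture: effect signs, PRS, environment scaling, liability cut."""

import numpy as np
import pytest

from admixpower import (
    LocusFrequencies,
    TraitArchitecture,
    assemble_phenotype,
    assign_effects,
    compute_prs,
    load_config,
    simulate_environment,
    simulate_repetition,
)


def _freqs(p1, p2):
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    return LocusFrequencies(
        p_anc=(p1 + p2) / 2, fst=np.full(p1.shape, 0.2), p1=p1, p2=p2
    )


def _arch(n_causal=1, h2=0.5, **kw):
    return TraitArchitecture(
        causal_idx=np.arange(n_causal),
        weights=np.ones(n_causal),
        h2=h2,
        **kw,
    )


class TestAssignEffects:
    def test_symmetric_frequencies_give_balanced_signs(self, rng):
        n = 4000
        freqs = _freqs(np.full(n, 0.4), np.full(n, 0.4))
        w = assign_effects(freqs, np.arange(n), rng)
        assert (w > 0).mean() == pytest.approx(0.5, abs=0.03)

    def test_pop1_frequent_alleles_get_positive_signs(self, rng):
        n = 4000
        freqs = _freqs(np.full(n, 0.99), np.full(n, 0.01))
        w = assign_effects(freqs, np.arange(n), rng)
        assert (w > 0).mean() == pytest.approx(0.99, abs=0.01)

    def test_ratio_capped_mode_saturates(self, rng):
        freqs = _freqs(np.full(500, 0.6), np.full(500, 0.3))
        w = assign_effects(freqs, np.arange(500), rng, sign_mode="ratio_capped")
        assert np.all(w > 0)  # p1/p2 = 2, capped at 1

    def test_magnitudes_are_half_normal(self, rng):
        freqs = _freqs(np.full(20_000, 0.5), np.full(20_000, 0.5))
        w = assign_effects(freqs, np.arange(20_000), rng)
        mags = np.abs(w)
        assert mags.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.02)

    def test_undefined_sign_probability_rejected(self, rng):
        freqs = _freqs([0.0], [0.0])
        with pytest.raises(ValueError):
            assign_effects(freqs, np.array([0]), rng)

    def test_prs_correlates_with_ancestry_under_divergence(self):
        """corr(prs_true, theta) > 0 in nearly all repetitions at F_ST 0.5."""
        cfg = load_config()
        cfg.ancestry.n_individuals = 5000
        cfg.fst.delta = 0.0
        cfg.fst.fixed = 0.5
        positive = 0
        n_reps = 50
        for rep in range(n_reps):
            sim = simulate_repetition(cfg, 1000 + rep, populations=("admixed",))
            c = sim.cohorts["admixed"]
            r = np.corrcoef(c.phenotypes.prs_true, c.theta)[0, 1]
            positive += int(r > 0)
        assert positive >= 45


class TestComputePrs:
    def test_linearity_single_locus(self):
        arch = TraitArchitecture(
            causal_idx=np.array([0]), weights=np.array([1.5]), h2=0.5
        )
        dosages = np.array([[0], [1], [2]])
        np.testing.assert_allclose(compute_prs(dosages, arch), [0.0, 1.5, 3.0])

    def test_zero_weights_zero_prs(self):
        arch = TraitArchitecture(
            causal_idx=np.arange(3), weights=np.zeros(3), h2=0.5
        )
        dosages = np.random.default_rng(0).integers(0, 3, (20, 5))
        assert np.all(compute_prs(dosages, arch) == 0)

    def test_permutation_equivariance(self):
        arch = TraitArchitecture(
            causal_idx=np.array([1, 3]), weights=np.array([0.5, -2.0]), h2=0.5
        )
        dosages = np.random.default_rng(1).integers(0, 3, (30, 5))
        perm = np.random.default_rng(2).permutation(30)
        np.testing.assert_allclose(
            compute_prs(dosages[perm], arch), compute_prs(dosages, arch)[perm]
        )


class TestEnvironment:
    def test_full_heritability_means_no_environment(self, rng):
        arch = _arch(h2=1.0)
        env = simulate_environment(np.full(100, 0.5), rng.standard_normal(100), arch, rng)
        assert np.all(env == 0)

    def test_zero_heritability_rejected(self):
        with pytest.raises(ValueError):
            _arch(h2=0.0)

    def test_variance_partition_matches_h2(self, rng):
        """Var(env)/Var(y) within 0.02 of 1 - h2 at N = 1e4."""
        arch = _arch(h2=0.5)
        theta = rng.uniform(0.4, 0.9, 10_000)
        prs = rng.standard_normal(10_000) * 2.0
        env = simulate_environment(theta, prs, arch, rng)
        y = prs + env
        assert np.var(env) / np.var(y) == pytest.approx(0.5, abs=0.02)

    def test_linear_anc_fraction_of_phenotypic_variance(self, rng):
        """The linear ancestry term explains env_anc_fraction of Var(y)."""
        arch = _arch(h2=0.5, env_mode="linear_anc", env_anc_fraction=0.10)
        theta = rng.beta(2, 2, 10_000)
        prs = rng.standard_normal(10_000)  # independent of theta by construction
        env = simulate_environment(theta, prs, arch, rng)
        y = prs + env
        # R^2 of y ~ theta is the lambda-term share when prs _|_ theta
        r2 = np.corrcoef(y, theta)[0, 1] ** 2
        assert r2 == pytest.approx(0.10, abs=0.02)

    def test_homogeneous_cohort_reduces_to_plain_noise(self, rng):
        arch = _arch(h2=0.5, env_mode="linear_anc", env_anc_fraction=0.10)
        theta = np.ones(5000)
        prs = rng.standard_normal(5000)
        env = simulate_environment(theta, prs, arch, rng, env_var=2.0)
        assert np.var(env) == pytest.approx(2.0, rel=1e-6)
        arch_g = _arch(h2=0.5)
        env_g = simulate_environment(theta, prs, arch_g, rng, env_var=2.0)
        assert np.var(env_g) == pytest.approx(2.0, rel=1e-6)


class TestAssemblePhenotype:
    def test_quantitative_is_direct_sum(self, rng):
        prs = rng.standard_normal(50)
        env = rng.standard_normal(50)
        ph = assemble_phenotype(prs, env, "quantitative")
        np.testing.assert_allclose(ph.y_quant, prs + env)
        assert ph.y_binary is None

    def test_exact_case_count_at_liability_threshold(self, rng):
        y = rng.standard_normal(1000)
        ph = assemble_phenotype(y, np.zeros(1000), "dichotomous", prevalence=0.05)
        assert int(ph.y_binary.sum()) == 50

    def test_half_prevalence_selects_upper_half(self):
        scores = np.arange(10, dtype=float)
        ph = assemble_phenotype(scores, np.zeros(10), "dichotomous", prevalence=0.5)
        np.testing.assert_array_equal(ph.y_binary, [0] * 5 + [1] * 5)

    def test_shift_invariance_of_case_assignment(self, rng):
        y = rng.standard_normal(400)
        a = assemble_phenotype(y, np.zeros(400), "dichotomous", prevalence=0.1)
        b = assemble_phenotype(y + 17.3, np.zeros(400), "dichotomous", prevalence=0.1)
        np.testing.assert_array_equal(a.y_binary, b.y_binary)

    def test_prevalence_required_for_dichotomous(self, rng):
        with pytest.raises(ValueError):
            assemble_phenotype(rng.standard_normal(10), np.zeros(10), "dichotomous",
                               prevalence=None)


class TestCrossCohortPatterns:
    def test_phenotype_ancestry_correlation_grows_with_fst(self):
        """Fig-2B-style mechanism: trait-ancestry correlation rises with F_ST."""
        mean_r = {}
        for fst in (0.2, 0.8):
            rs = []
            for rep in range(8):
                cfg = load_config()
                cfg.fst.delta = 0.0
                cfg.fst.fixed = fst
                sim = simulate_repetition(cfg, 500 + rep, populations=("admixed",))
                c = sim.cohorts["admixed"]
                rs.append(np.corrcoef(c.phenotypes.y_quant, c.theta)[0, 1])
            mean_r[fst] = np.mean(rs)
        assert mean_r[0.2] > 0
        assert mean_r[0.8] > mean_r[0.2]

    def test_source_population_phenotype_means_separate(self):
        """mean(y | Pop1) > mean(y | Pop2) when signs favor Pop1 alleles."""
        cfg = load_config()
        cfg.fst.delta = 0.0
        cfg.fst.fixed = 0.5
        wins = 0
        for rep in range(12):
            sim = simulate_repetition(cfg, 900 + rep)
            y1 = sim.cohorts["pop1"].phenotypes.y_quant.mean()
            y2 = sim.cohorts["pop2"].phenotypes.y_quant.mean()
            wins += int(y1 > y2)
        assert wins >= 11

    def test_realized_heritability_in_simulated_cohort(self):
        cfg = load_config()
        cfg.ancestry.n_individuals = 10_000
        sim = simulate_repetition(cfg, 77, populations=("admixed",))
        ph = sim.cohorts["admixed"].phenotypes
        h2 = np.var(ph.prs_true) / np.var(ph.y_quant)
        assert h2 == pytest.approx(0.5, abs=0.02)
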