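import numpy as np
import pytest

from stratclust.assoc import adjusted_rand_index
from stratclust.lca import lca_fit
from stratclust.simdata import (SimConfig, apply_missingness,
                                draw_population_freqs, estimate_fst,
                                inject_subgroup_effects, make_reference_panel,
                                simulate_cohort, simulate_genotypes,
                                simulate_subphenotypes)
from .conftest import make_genotypes


class TestPopulationFreqs:
    def test_zero_fst_means_no_drift(self, rng):
        p, freqs = draw_population_freqs(20, 3, 0.0, rng)
        for k in range(3):
            np.testing.assert_array_equal(freqs[k], p)

    def test_beta_mean_and_variance(self):
        rng = np.random.default_rng(7)
        m, p0, F = 10_000, 0.3, 0.2
        _, freqs = draw_population_freqs(m, 1, F, rng, ancestral_range=(p0, p0))
        draws = freqs[0]
        se_mean = np.sqrt(F * p0 * (1 - p0) / m)
        assert abs(draws.mean() - p0) < 3 * se_mean
        assert abs(draws.var() - F * p0 * (1 - p0)) < 0.1 * F * p0 * (1 - p0)

    def test_invalid_fst_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_population_freqs(5, 2, 1.0, rng)


class TestGenotypeSimulation:
    def test_fixed_frequency_boundaries(self, rng):
        freqs = np.array([[0.0, 1.0]])
        G, _ = simulate_genotypes(freqs, [10], rng)
        assert np.all(G.values[:, 0] == 0)
        assert np.all(G.values[:, 1] == 2)

    def test_hardy_weinberg_heterozygosity(self):
        rng = np.random.default_rng(8)
        p = 0.3
        G, _ = simulate_genotypes(np.array([[p]]), [10_000], rng)
        het = (G.values[:, 0] == 1).mean()
        target = 2 * p * (1 - p)
        assert abs(het - target) < 3 * np.sqrt(target * (1 - target) / 10_000)

    def test_population_labels_recorded(self, rng):
        freqs = np.tile(0.5, (2, 3))
        G, labels = simulate_genotypes(freqs, [4, 6], rng,
                                       pop_names=["A", "B"])
        assert (labels == "A").sum() == 4 and (labels == "B").sum() == 6


class TestSubgroupEffects:
    def test_null_effect_identical_output(self, rng):
        cfg = SimConfig(pop_sizes=(30, 10), pop_names=("A", "B"),
                        panel_sizes=(5, 5), n_subgroups=2,
                        affected_snps=(0, 1),
                        subgroup_deltas=((0.0, 0.0), (0.0, 0.0)))
        freqs = np.tile(0.4, (2, 10))
        r1 = np.random.default_rng(3)
        per1, sub1 = inject_subgroup_effects(freqs, (30, 10), cfg, r1)
        np.testing.assert_array_equal(per1, np.repeat(freqs, [30, 10], axis=0))

    def test_shifted_frequency_moment(self):
        rng = np.random.default_rng(9)
        cfg = SimConfig(pop_sizes=(4000,), pop_names=("A",), panel_sizes=(5,),
                        m_disease=5, n_subgroups=2,
                        subgroup_proportions=(0.5, 0.5),
                        affected_snps=(0,), subgroup_deltas=((0.3,), (-0.2,)))
        freqs = np.tile(0.4, (1, 5))
        per, sub = inject_subgroup_effects(freqs, (4000,), cfg, rng)
        g = rng.binomial(2, per).astype(float)
        for s, target in [(0, 0.7), (1, 0.2)]:
            est = g[sub == s, 0].mean() / 2
            n = (sub == s).sum()
            assert abs(est - target) < 3 * np.sqrt(target * (1 - target) / (2 * n))

    def test_lca_recovers_subgroups(self):
        rng = np.random.default_rng(10)
        cfg = SimConfig(pop_sizes=(500,), pop_names=("A",), panel_sizes=(5,),
                        m_disease=51, n_subgroups=2,
                        subgroup_proportions=(0.5, 0.5),
                        affected_snps=tuple(range(10)),
                        subgroup_deltas=(tuple([0.0] * 10),
                                         tuple([0.4] * 10)))
        freqs = np.tile(0.3, (1, 51))
        per, sub = inject_subgroup_effects(freqs, (500,), cfg, rng)
        G = make_genotypes(rng.binomial(2, per).astype(float))
        _, post = lca_fit(G, 2, n_restarts=5, seed=0)
        assert adjusted_rand_index(post.modal_label, sub) > 0.8

    def test_out_of_range_snp_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            SimConfig(pop_sizes=(10,), pop_names=("A",), panel_sizes=(5,),
                      m_disease=5, n_subgroups=2,
                      affected_snps=(7,), subgroup_deltas=((0.1,), (0.2,)))


class TestSubphenotypes:
    def test_degenerate_conditionals_deterministic(self, rng):
        cfg = SimConfig(pop_sizes=(20,), pop_names=("A",), panel_sizes=(5,),
                        n_subgroups=2, affected_snps=(),
                        subgroup_deltas=((), ()),
                        subphenotypes={"loc": (["ileum", "colon"],
                                               [[1.0, 0.0], [0.0, 1.0]])})
        sub = np.array([0, 1] * 10)
        table = simulate_subphenotypes(sub, cfg, rng)
        vals = table.frame["loc"].to_numpy()
        assert all(v == ("ileum" if s == 0 else "colon")
                   for v, s in zip(vals, sub))

    def test_conditional_frequencies_match(self):
        rng = np.random.default_rng(11)
        probs = [[0.7, 0.3], [0.2, 0.8]]
        cfg = SimConfig(pop_sizes=(2000,), pop_names=("A",), panel_sizes=(5,),
                        n_subgroups=2, affected_snps=(),
                        subgroup_deltas=((), ()),
                        subphenotypes={"beh": (["B1", "nonB1"], probs)})
        sub = rng.integers(0, 2, size=2000)
        table = simulate_subphenotypes(sub, cfg, rng)
        vals = table.frame["beh"].to_numpy()
        for s in (0, 1):
            frac = (vals[sub == s] == "B1").mean()
            p = probs[s][0]
            n = (sub == s).sum()
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestMissingness:
    def test_full_call_rate_no_missing(self, rng):
        G = make_genotypes(np.ones((20, 4)))
        out, rates = apply_missingness(G, (1.0, 1.0), rng)
        assert not np.isnan(out.values).any()
        np.testing.assert_array_equal(rates, 1.0)

    def test_realised_rate_matches(self):
        rng = np.random.default_rng(12)
        G = make_genotypes(np.ones((10_000, 1)))
        out, rates = apply_missingness(G, (0.5, 0.5), rng)
        assert abs(rates[0] - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_reproducible_given_seed(self):
        G = make_genotypes(np.ones((50, 8)))
        a, _ = apply_missingness(G, (0.6, 0.9), np.random.default_rng(5))
        b, _ = apply_missingness(G, (0.6, 0.9), np.random.default_rng(5))
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)

    def test_invalid_rate_rejected(self, rng):
        G = make_genotypes(np.ones((5, 2)))
        with pytest.raises(ValueError):
            apply_missingness(G, (0.0, 0.5), rng)


class TestFstEstimator:
    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(13)
        freqs = np.tile(rng.uniform(0.2, 0.8, 50), (2, 1))
        G, labels = simulate_genotypes(freqs, [1000, 1000], rng)
        _, mean_fst = estimate_fst(G, labels)
        assert abs(mean_fst) < 0.01

    def test_fixed_difference_is_one(self, rng):
        freqs = np.array([[0.0], [1.0]])
        G, labels = simulate_genotypes(freqs, [50, 50], rng)
        per_marker, _ = estimate_fst(G, labels)
        assert per_marker[0] == pytest.approx(1.0, abs=0.01)

    def test_round_trip_recovers_configured_fst(self):
        rng = np.random.default_rng(14)
        F = 0.15
        _, freqs = draw_population_freqs(100, 2, F, rng)
        G, labels = simulate_genotypes(freqs, [500, 500], rng)
        _, mean_fst = estimate_fst(G, labels)
        assert abs(mean_fst - F) < 0.03


class TestCohort:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(pop_sizes=(40, 10, 5), panel_sizes=(10, 10, 10))
        a = simulate_cohort(cfg, seed=21)
        b = simulate_cohort(cfg, seed=21)
        np.testing.assert_array_equal(a.disease.values, b.disease.values,
                                      strict=True)
        np.testing.assert_array_equal(a.aim.missing_mask, b.aim.missing_mask)
        np.testing.assert_array_equal(a.truth.subgroup, b.truth.subgroup)

    def test_study_shaped_defaults(self):
        cfg = SimConfig()
        c = simulate_cohort(cfg, seed=1)
        assert c.disease.n == 845 - 395  # the AIM-typed subset size
        assert c.disease.m == 51 and c.aim.m == 30
        assert (c.truth.population == "Europe").sum() == 430
        # disease-panel call rates span the configured profile
        rates = c.truth.call_rates["disease"]
        assert rates.min() < 0.6 and rates.max() > 0.85

    def test_reference_panel_fixture_is_assignable(self):
        rng = np.random.default_rng(15)
        cfg = SimConfig(pop_sizes=(40, 10, 5), panel_sizes=(20, 20, 20),
                        F_aim=0.5)
        _, pop_freqs = draw_population_freqs(cfg.m_aim, 3, cfg.F_aim, rng)
        panel, labels, _ = make_reference_panel(cfg, rng, pop_freqs=pop_freqs)
        from stratclust.adjust import assign_ancestry

        query, truth = simulate_genotypes(pop_freqs, cfg.pop_sizes, rng,
                                          pop_names=cfg.pop_names,
                                          marker_prefix="aim",
                                          sample_prefix="q")
        res = assign_ancestry(query, panel, labels)
        assert (res.labels.to_numpy() == truth).mean() > 0.9
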