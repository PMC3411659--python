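"""The generative screen model: stage-by-stage sampling behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from poolscreen.library import LibrarySpec, make_library
from poolscreen.simulate import (
    ScreenParams,
    StageCounts,
    simulate_cq_panel,
    simulate_gdna_aliquot,
    simulate_pcr,
    simulate_readout,
    simulate_screen,
    simulate_selection,
    simulate_transduction,
    substream,
)


class TestLibrary:
    def test_props_sum_to_one_and_ids_unique(self):
        lib = make_library(300, seed=0)
        assert lib.pool_size == 300
        assert lib.plasmid_props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LibrarySpec(["a", "a"], np.array([0.5, 0.5]))

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            LibrarySpec(["a", "b"], np.array([0.7, 0.7]))

    def test_sequences_distinct_and_dna(self):
        lib = make_library(100, with_sequences=True, seq_len=30, seed=2)
        assert len(set(lib.hairpin_seqs)) == 100
        assert all(set(s) <= set("ACGT") for s in lib.hairpin_seqs)


class TestTransduction:
    def test_total_is_pool_times_coverage(self, uniform_library):
        params = ScreenParams(fold_representation=100.0)
        t = simulate_transduction(uniform_library, params, rng=0)
        # 200 hairpins at 100-fold: 20 000 integrations, conserved exactly
        assert t.total == 20_000

    def test_paper_scale_total(self):
        lib = make_library(10_000, seed=0)
        t = simulate_transduction(lib, ScreenParams(fold_representation=100.0), rng=0)
        assert t.total == 1_000_000

    def test_poisson_moments_at_c100(self, uniform_library):
        params = ScreenParams(fold_representation=100.0)
        reps = np.array(
            [simulate_transduction(uniform_library, params, rng=s).counts for s in range(300)]
        )
        # per-hairpin mean 100, CV about 1/sqrt(100)
        assert reps.mean() == pytest.approx(100.0, rel=0.01)
        cv = reps.std(axis=0).mean() / reps.mean()
        assert cv == pytest.approx(0.1, rel=0.1)

    def test_large_c_converges_to_plasmid_props(self, skewed_library):
        params = ScreenParams(fold_representation=100_000.0)
        t = simulate_transduction(skewed_library, params, rng=0)
        np.testing.assert_allclose(t.proportions, skewed_library.plasmid_props, rtol=0.05)

    def test_vanishing_coverage_errors(self):
        lib = LibrarySpec(["a"], np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_transduction(lib, ScreenParams(fold_representation=1e-9))


class TestSelection:
    def test_neutral_deterministic_preserves_proportions(self):
        t0 = StageCounts("T0", np.array([100, 300, 600]))
        params = ScreenParams(fitness_effects=np.zeros(3))
        t1 = simulate_selection(t0, params, deterministic=True)
        np.testing.assert_allclose(t1.proportions, t0.proportions, atol=1e-3)

    def test_depletion_closed_form(self):
        # one hairpin at -0.3/day for 14 days: relative abundance falls e^-4.2
        n = 50
        t0 = StageCounts("T0", np.full(n, 10_000))
        fitness = np.zeros(n)
        fitness[0] = -0.3
        params = ScreenParams(fitness_effects=fitness, selection_days=14)
        t1 = simulate_selection(t0, params, deterministic=True)
        rel = (t1.counts[0] / t1.counts[1:].mean()) / (t0.counts[0] / t0.counts[1:].mean())
        assert rel == pytest.approx(math.exp(-4.2), rel=0.05)

    def test_enrichment_closed_form_stochastic(self):
        n = 400
        t0 = StageCounts("T0", np.full(n, 1_000))
        fitness = np.zeros(n)
        fitness[:20] = 0.1
        params = ScreenParams(fitness_effects=fitness, selection_days=14)
        rels = []
        for s in range(20):
            t1 = simulate_selection(t0, params, rng=s)
            rels.append(
                (t1.counts[:20].mean() / t1.counts[20:].mean())
                / (t0.counts[0] / t0.counts[-1])
            )
        # e^{0.1*14} = 4.055 relative enrichment
        assert np.mean(rels) == pytest.approx(math.exp(1.4), rel=0.1)

    def test_neutral_null_log_ratio_centered_at_zero(self, uniform_library):
        # log ratios of normalized abundances; |mean| bound allows the
        # second-order Jensen bias at ~100 copies per hairpin
        params = ScreenParams(fitness_effects=np.zeros(uniform_library.pool_size))
        means = []
        for s in range(100):
            t0 = simulate_transduction(uniform_library, params, rng=s)
            t1 = simulate_selection(t0, params, rng=1_000 + s)
            lr = np.log10(t1.proportions / t0.proportions)
            means.append(lr[np.isfinite(lr)].mean())
        assert abs(np.mean(means)) < 0.03


class TestAliquot:
    def test_draw_size_conserved(self, skewed_library):
        t = StageCounts("T1", np.full(500, 1_000))
        a = simulate_gdna_aliquot(t, template_copies=50, rng=0)
        assert a.total == 500 * 50

    def test_cv_scales_as_inverse_sqrt_template(self):
        t = StageCounts("T1", np.full(400, 100_000))
        cv = {}
        for copies in (50, 200):
            draws = np.array(
                [simulate_gdna_aliquot(t, copies, rng=s).counts for s in range(200)]
            )
            cv[copies] = (draws.std(axis=0) / draws.mean(axis=0)).mean()
        assert cv[50] / cv[200] == pytest.approx(2.0, rel=0.1)

    def test_zero_aliquot_errors(self):
        t = StageCounts("T1", np.full(10, 100))
        with pytest.raises(ValueError):
            simulate_gdna_aliquot(t, 0.0)


class TestPcr:
    def test_deterministic_perfect_doubling(self):
        a = StageCounts("gdna_aliquot", np.array([3, 5, 11]))
        out = simulate_pcr(a, cycles=4, e0=1.0, capacity=1e18, deterministic=True, rng=0)
        np.testing.assert_array_equal(out.counts, np.array([3, 5, 11]) * 16)

    def test_zero_cycles_is_identity(self):
        a = StageCounts("gdna_aliquot", np.array([3, 5, 11]))
        out = simulate_pcr(a, cycles=0, rng=0)
        np.testing.assert_array_equal(out.counts, a.counts)

    def test_invalid_efficiency(self):
        a = StageCounts("gdna_aliquot", np.array([3]))
        with pytest.raises(ValueError):
            simulate_pcr(a, cycles=1, e0=1.5)

    def test_branching_variance_scales_inverse_initial_copies(self):
        # Galton-Watson: relative variance of a clone's final share ~ 1/n0
        relvar = {}
        for n0 in (50, 150):
            a = StageCounts("gdna_aliquot", np.full(400, n0))
            finals = []
            for s in range(60):
                out = simulate_pcr(a, cycles=10, e0=0.5, capacity=1e15, rng=s)
                finals.append(out.counts / a.counts)
            finals = np.array(finals, dtype=float)
            relvar[n0] = (finals.var(axis=0) / finals.mean(axis=0) ** 2).mean()
        assert relvar[50] / relvar[150] == pytest.approx(3.0, rel=0.25)

    def test_saturation_slows_growth(self):
        a = StageCounts("gdna_aliquot", np.full(100, 1_000))
        free = simulate_pcr(a, cycles=10, e0=1.0, capacity=1e15, deterministic=True, rng=0)
        capped = simulate_pcr(a, cycles=10, e0=1.0, capacity=4e5, deterministic=True, rng=0)
        assert capped.total < free.total
        # step law: once past capacity, per-cycle gain is ~capacity*e0
        assert capped.total < 4e5 * 12

    def test_logistic_model_available(self):
        a = StageCounts("gdna_aliquot", np.full(100, 1_000))
        out = simulate_pcr(a, cycles=5, e0=1.0, capacity=4e5, saturation_model="logistic", rng=0)
        assert out.total > a.total


class TestReadout:
    def test_sequencing_depth_conserved(self, skewed_library):
        post = StageCounts("post_pcr", np.full(500, 10_000))
        params = ScreenParams(reads_per_sample=123_457)
        reads = simulate_readout(post, "sequencing", params, rng=0)
        assert reads.sum() == 123_457

    def test_uniform_depth_matches_lane_arithmetic(self):
        # 8 900 reads per shRNA on an even pool
        post = StageCounts("post_pcr", np.full(200, 5_000))
        params = ScreenParams(reads_per_sample=8_900 * 200)
        reads = simulate_readout(post, "sequencing", params, rng=0)
        assert reads.mean() == pytest.approx(8_900.0)

    def test_zero_depth_gives_all_zero(self):
        post = StageCounts("post_pcr", np.full(10, 100))
        reads = simulate_readout(post, "sequencing", ScreenParams(reads_per_sample=0), rng=0)
        assert (reads == 0).all()

    def test_noise_free_microarray_recovers_log_abundance(self):
        post = StageCounts("post_pcr", np.array([100, 200, 400, 800]))
        params = ScreenParams(array_noise_sd=0.0, array_background=0.0, array_probes_per_clone=2)
        inten = simulate_readout(post, "microarray", params, rng=0)
        lr = inten.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(np.diff(lr), 1.0)  # true doubling steps

    def test_unknown_mode(self):
        post = StageCounts("post_pcr", np.array([1]))
        with pytest.raises(ValueError):
            simulate_readout(post, "nanopore", ScreenParams())


class TestCqPanelGenerator:
    def test_noise_free_panel_unit_delta(self):
        panel = simulate_cq_panel(true_transition_cycle=10_000, noise_sd=0.0)
        from poolscreen.pcr_phase import corrected_delta_cq

        series = corrected_delta_cq(panel)
        assert np.allclose(series["delta_cq"], 1.0)

    def test_sybr_efficiency_affects_raw_not_corrected(self):
        from poolscreen.pcr_phase import corrected_delta_cq, efficiency_correction_factor

        panel = simulate_cq_panel(true_transition_cycle=10_000, sybr_efficiency_pct=65.0)
        series = corrected_delta_cq(panel, efficiency_pct=65.0)
        assert series["raw_delta_cq"].iloc[0] == pytest.approx(efficiency_correction_factor(65.0))
        assert np.allclose(series["delta_cq"], 1.0)

    def test_equal_seeds_identical_panels(self):
        p1 = simulate_cq_panel(noise_sd=0.1, rng=5)
        p2 = simulate_cq_panel(noise_sd=0.1, rng=5)
        pd.testing.assert_frame_equal(p1, p2)


class TestScreenOrchestration:
    def test_seeded_runs_bit_reproducible(self, skewed_library):
        params = ScreenParams(seed=9, reads_per_sample=100_000)
        r1 = simulate_screen(skewed_library, params, n_bio=2, n_tech=2)
        r2 = simulate_screen(skewed_library, params, n_bio=2, n_tech=2)
        pd.testing.assert_frame_equal(r1.counts, r2.counts)
        pd.testing.assert_frame_equal(r1.truth, r2.truth)

    def test_technical_replicates_share_biology(self, skewed_library):
        params = ScreenParams(seed=9, reads_per_sample=100_000)
        res = simulate_screen(skewed_library, params, n_bio=1, n_tech=2)
        # tech reps differ (new aliquot/PCR) but correlate strongly
        a, b = res.counts["T1_A_1"], res.counts["T1_A_2"]
        assert not a.equals(b)
        assert np.corrcoef(a, b)[0, 1] > 0.9

    def test_substreams_are_independent_and_stable(self):
        a = substream(1, "transduction", "A").normal(size=4)
        b = substream(1, "transduction", "B").normal(size=4)
        a2 = substream(1, "transduction", "A").normal(size=4)
        np.testing.assert_array_equal(a, a2)
        assert not np.allclose(a, b)

    def test_bottleneck_monotonicity_template_copies(self, skewed_library):
        """Technical-replicate correlation improves with template copies."""
        wins = 0
        runs = 12
        for s in range(runs):
            rs = {}
            for copies in (50, 150):
                params = ScreenParams(
                    seed=s,
                    template_copies=copies,
                    pcr_cycles=30,
                    reads_per_sample=200_000,
                    frac_affected=0.1,
                )
                res = simulate_screen(skewed_library, params, n_bio=1, n_tech=2)
                lr1 = np.log10((res.counts["T1_A_1"] + 0.5) / (res.counts["T0_A_1"] + 0.5))
                lr2 = np.log10((res.counts["T1_A_2"] + 0.5) / (res.counts["T0_A_2"] + 0.5))
                rs[copies] = np.corrcoef(lr1, lr2)[0, 1]
            wins += rs[150] > rs[50]
        assert wins >= runs - 2

    def test_representation_monotonicity_bio_replicates(self, skewed_library):
        """Biological-replicate correlation improves with fold representation."""
        wins = 0
        runs = 10
        for s in range(runs):
            rs = {}
            for c in (100, 500):
                params = ScreenParams(
                    seed=s,
                    fold_representation=c,
                    template_copies=c,
                    reads_per_sample=200_000,
                    frac_affected=0.1,
                    effect_sd=0.05,
                )
                res = simulate_screen(skewed_library, params, n_bio=2, n_tech=1)
                lra = np.log10((res.counts["T1_A_1"] + 0.5) / (res.counts["T0_A_1"] + 0.5))
                lrb = np.log10((res.counts["T1_B_1"] + 0.5) / (res.counts["T0_B_1"] + 0.5))
                rs[c] = np.corrcoef(lra, lrb)[0, 1]
            wins += rs[500] > rs[100]
        assert wins >= runs - 2
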