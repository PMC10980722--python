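"""Synthetic cohort generator: phenotypes, schedules, BOLD, behavior."""

import numpy as np
import pandas as pd
import pytest

from traitscan import CohortSpec, simulate_cohort
from traitscan.cohort import (
    RISK_ALLELES,
    SNP_IDS,
    _ball_voxels,
    build_event_schedule,
    calibrate_pattern_strength,
    score_asq,
    simulate_asq_responses,
    simulate_behavior,
    simulate_cohort_bold,
    simulate_genotypes,
    simulate_phenotypes,
    write_cohort,
)
from traitscan.glm import build_design_matrix, contrast_map, fit_glm
from traitscan.stats import hwe_test, rm_anova
from traitscan.task import CONDITIONS


class TestASQ:
    def test_scoring_extremes(self):
        assert score_asq(np.ones(50, dtype=int))[0] == 50
        assert score_asq(np.zeros(50, dtype=int))[0] == 0

    def test_scoring_validation(self):
        with pytest.raises(ValueError):
            score_asq(np.ones(49, dtype=int))
        with pytest.raises(ValueError):
            score_asq(np.full(50, 2))

    def test_total_equals_item_sum(self):
        df = simulate_asq_responses(50, seed=1)
        items = df[[c for c in df.columns if c.startswith("item_")]].to_numpy()
        assert (df["asq_total"].to_numpy() == items.sum(axis=1)).all()
        assert df["asq_total"].between(0, 50).all()

    def test_population_calibration(self):
        # population mean/SD of totals within 10% of 21.4 / 5.6 for large n
        df = simulate_asq_responses(2000, seed=3)
        assert df["asq_total"].mean() == pytest.approx(21.4, rel=0.10)
        assert df["asq_total"].std() == pytest.approx(5.6, rel=0.10)

    def test_latent_monotonicity(self):
        # subjects 2 SD apart in the latent trait keep their order in
        # expected totals (Monte Carlo over the item model)
        mu, sd = 21.4, 5.34
        low = simulate_asq_responses(10_000, (mu - 2 * sd, 0.0), seed=4)
        high = simulate_asq_responses(10_000, (mu + 2 * sd, 0.0), seed=5)
        assert high["asq_total"].mean() > low["asq_total"].mean() + 10

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_asq_responses(0)
        with pytest.raises(ValueError):
            simulate_asq_responses(5, (21.4, -1.0))


class TestGenotypes:
    def test_degenerate_frequency(self):
        g = simulate_genotypes(20, allele_freqs={s: 1.0 for s in SNP_IDS}, seed=0)
        for snp in SNP_IDS:
            risk = RISK_ALLELES[snp]
            assert (g[f"genotype_{snp}"] == risk * 2).all()
            assert (g[f"carrier_{snp}"] == 1).all()

    def test_frequency_validation(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, allele_freqs={"rs53576": 0.0})

    def test_heterozygote_fraction_half(self):
        g = simulate_genotypes(10_000, allele_freqs={"rs2254298": 0.5}, seed=1)
        het = (g["genotype_rs2254298"] == "AG").mean()
        # 2pq = 0.5; binomial 4-sigma band
        assert het == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / 10_000))

    def test_carrier_consistent_with_genotype(self):
        g = simulate_genotypes(500, seed=2)
        for snp in SNP_IDS:
            has_risk = g[f"genotype_{snp}"].str.contains(RISK_ALLELES[snp])
            assert (g[f"carrier_{snp}"] == has_risk.astype(int)).all()

    def test_hwe_pass_rate_under_null(self):
        # generated samples pass the package's own HWE test at the nominal rate
        rejections = 0
        n_trials = 800
        for seed in range(n_trials):
            g = simulate_genotypes(229, allele_freqs={"rs2268491": 0.3}, seed=seed)
            k = g["genotype_rs2268491"].str.count("T").to_numpy()
            counts = ((k == 0).sum(), (k == 1).sum(), (k == 2).sum())
            if hwe_test(counts)[1] < 0.05:
                rejections += 1
        rate = rejections / n_trials
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_trials))


class TestEventSchedule:
    def test_counts_and_balance(self):
        spec = CohortSpec(n_subjects=2, grid_shape=(16, 16, 16))
        sched = build_event_schedule(spec, seed=0)
        assert sched.n_runs == 2
        assert sched.n_events == 100
        for run in sched.runs:
            assert len(run) == 50
            counts = run["trial_type"].value_counts()
            assert all(counts[c] == 10 for c in CONDITIONS)
            assert run["stimulus_id"].is_unique
            assert (np.diff(run["onset"]) > 0).all()

    def test_determinism_and_run_difference(self):
        spec = CohortSpec(n_subjects=2, grid_shape=(16, 16, 16))
        a = build_event_schedule(spec, seed=3)
        b = build_event_schedule(spec, seed=3)
        pd.testing.assert_frame_equal(a.runs[0], b.runs[0])
        assert not a.runs[0]["stimulus_id"].equals(a.runs[1]["stimulus_id"])

    def test_run_too_short(self):
        spec = CohortSpec(n_subjects=2, grid_shape=(16, 16, 16), volumes_per_run=60)
        with pytest.raises(ValueError, match="too short"):
            build_event_schedule(spec, seed=0)

    def test_tsv_round_trip(self, tmp_path):
        spec = CohortSpec(n_subjects=2, grid_shape=(16, 16, 16))
        sched = build_event_schedule(spec, seed=1)
        paths = sched.to_tsv(tmp_path)
        from traitscan.task import EventSchedule

        back = EventSchedule.from_tsv(paths)
        pd.testing.assert_frame_equal(sched.runs[1], back.runs[1])


class TestBold:
    def test_determinism(self, small_cohort):
        spec = small_cohort.spec
        bold2, truth2 = simulate_cohort_bold(
            small_cohort.phenotypes, small_cohort.schedule, spec
        )
        np.testing.assert_array_equal(
            small_cohort.bold.subject(3), bold2.subject(3)
        )
        np.testing.assert_array_equal(
            small_cohort.truth.coupling_gains, truth2.coupling_gains
        )

    def test_noiseless_glm_recovers_injected_amplitudes(self, noiseless_cohort):
        sim = noiseless_cohort
        hrf = sim.spec.hrf()
        flat = sim.grid.flat_index_volume()
        pat = flat[tuple(sim.truth.regions["pattern"].T)]
        X = build_design_matrix(sim.schedule, sim.spec.volumes_per_run, hrf)
        w = X.condition_weights("angry", "neutral")
        for i in range(sim.spec.n_subjects):
            cmap = contrast_map(fit_glm(sim.bold.subject(i), X), w)
            np.testing.assert_allclose(
                cmap[pat], sim.truth.true_amplitude[i], atol=1e-8
            )

    def test_all_effects_off_gives_identical_contrasts(self):
        spec = CohortSpec(
            n_subjects=3, grid_shape=(16, 16, 16), noise_sd=0.0,
            pattern_strength=0.0, amplitude_shared_sd=0.0,
            amplitude_noise_sd=0.0, gain_noise_sd=0.0, seed_fluct_sd=0.0,
            coupling_base_gain=0.0,
            coupling_slopes={"noncarrier": 0.0, "carrier": 0.0}, rng_seed=9,
        )
        sim = simulate_cohort(spec)
        hrf = spec.hrf()
        X = build_design_matrix(sim.schedule, spec.volumes_per_run, hrf)
        w = X.condition_weights("angry", "neutral")
        maps = np.array(
            [contrast_map(fit_glm(sim.bold.subject(i), X), w) for i in range(3)]
        )
        np.testing.assert_allclose(maps[1:], np.tile(maps[0], (2, 1)), atol=1e-8)
        np.testing.assert_allclose(maps, np.zeros_like(maps), atol=1e-8)

    def test_trait_amplitude_calibration(self):
        # pattern strength calibrated for r ~ 0.5 between trait and the
        # regional mean of the true angry-neutral amplitudes
        spec = CohortSpec(n_subjects=200, grid_shape=(16, 16, 16), rng_seed=7)
        sim = simulate_cohort(spec)
        r = np.corrcoef(sim.truth.trait_z, sim.truth.true_amplitude.mean(1))[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)

    def test_region_validation(self):
        bad = CohortSpec(
            n_subjects=2, grid_shape=(16, 16, 16),
            pattern_region=_ball_voxels(np.array([8, 8, 8]), 3),
            coupling_target_region=_ball_voxels(np.array([9, 8, 8]), 2),
        )
        phen = simulate_phenotypes(2, seed=0)
        sched = build_event_schedule(bad, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_cohort_bold(phen, sched, bad)
        outside = CohortSpec(
            n_subjects=2, grid_shape=(16, 16, 16),
            pattern_region=np.array([[0, 0, 0]]),
        )
        with pytest.raises(ValueError, match="mask"):
            simulate_cohort_bold(phen, sched, outside)

    def test_calibration_closed_form_matches_unsmoothed_limit(self):
        region = _ball_voxels(np.array([8, 8, 8]), 2)
        s_smooth0 = calibrate_pattern_strength(0.5, 0.3, 0.5, region, 0.0)
        s_count = calibrate_pattern_strength(0.5, 0.3, 0.5, len(region))
        assert s_smooth0 == pytest.approx(s_count, rel=1e-12)


class TestBehavior:
    def test_support_constraints(self):
        phen = simulate_phenotypes(30, seed=1)
        beh = simulate_behavior(phen, seed=2)
        assert beh["accuracy"].between(0, 1).all()
        assert (beh["rt_s"] > 0).all()
        assert len(beh) == 30 * 5

    def test_null_effects_equal_means(self):
        phen = simulate_phenotypes(300, seed=3)
        null = {c: (0.0, 0.0) for c in CONDITIONS}
        beh = simulate_behavior(phen, effect_spec=null, seed=4)
        means = beh.groupby("condition")["accuracy"].mean()
        assert means.max() - means.min() < 0.02

    def test_invalid_accuracy_mean(self):
        phen = simulate_phenotypes(5, seed=0)
        with pytest.raises(ValueError, match="accuracy"):
            simulate_behavior(phen, effect_spec={"angry": (0.2, 0.0)})

    def test_rm_anova_detects_negative_emotion_decrement(self):
        # default -0.05 accuracy offset for negative faces; RM-ANOVA at
        # alpha=.01 should flag the condition effect in essentially every
        # cohort of 200
        hits = 0
        for seed in range(15):
            phen = simulate_phenotypes(200, seed=seed)
            beh = simulate_behavior(phen, seed=seed + 100)
            wide = beh.pivot_table(
                index="subject_id", columns="condition", values="accuracy"
            ).to_numpy()
            if rm_anova(wide).p < 0.01:
                hits += 1
        assert hits >= 14


class TestCohortExport:
    def test_write_cohort_tree(self, tmp_path):
        spec = CohortSpec(n_subjects=2, grid_shape=(12, 12, 14), rng_seed=3,
                          coupling_seed_region=np.array([[6, 6, 10]]),
                          pattern_region=_ball_voxels(np.array([5, 6, 7]), 2),
                          coupling_target_region=np.array([[9, 6, 7]]))
        sim = simulate_cohort(spec)
        write_cohort(tmp_path, spec, sim.phenotypes, sim.schedule, sim.bold,
                     sim.truth)
        assert (tmp_path / "participants.tsv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        assert len(list(tmp_path.glob("sub-*_run-*_bold.nii"))) == 4
        part = pd.read_csv(tmp_path / "participants.tsv", sep="\t")
        assert {"subject_id", "asq_total", "genotype_rs53576"} <= set(part.columns)
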