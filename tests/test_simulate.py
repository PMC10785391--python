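import numpy as np
import pandas as pd
import pytest

from cnvrpipe import QcThresholds, filter_samples
from cnvrpipe.io_qc import calls_to_frame
from cnvrpipe.pedigree import sort_pedigree
from cnvrpipe.simulate import (
    SimulationConfig,
    simulate_breeding_values,
    simulate_cnv_calls,
    simulate_cnv_landscape,
    simulate_feed_events,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_founders=1)
        with pytest.raises(ValueError):
            SimulationConfig(sigma2_u=-1)
        with pytest.raises(ValueError):
            SimulationConfig(carrier_freq_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(type_proportions=(0.5, 0.5, 0.5))


class TestPedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=2, n_generations=0))
        assert len(ped) == 2
        assert (ped["sire"] == "0").all() and (ped["dam"] == "0").all()

    def test_one_generation_parents_are_founders(self):
        cfg = SimulationConfig(n_founders=4, n_generations=1, offspring_per_mating=1)
        ped = simulate_pedigree(cfg)
        founders = set(ped.loc[ped["generation"] == 0, "animal"])
        offspring = ped[ped["generation"] == 1]
        assert len(offspring) >= 1
        assert set(offspring["sire"]) <= founders
        assert set(offspring["dam"]) <= founders

    def test_deterministic(self):
        cfg = SimulationConfig(seed=123, n_founders=20, n_generations=2)
        pd.testing.assert_frame_equal(simulate_pedigree(cfg), simulate_pedigree(cfg))

    def test_topologically_valid(self, small_cfg):
        ped = simulate_pedigree(small_cfg)
        # sorting succeeds (no cycles) and preserves the order already emitted
        ordered = sort_pedigree(ped[["animal", "sire", "dam"]])
        assert list(ordered["animal"]) == list(ped["animal"])


class TestLandscape:
    def test_single_region_fits_chromosome(self):
        cfg = SimulationConfig(
            chromosome_lengths={"1": 1_000_000}, n_regions=1, region_mean_length=50_000
        )
        land = simulate_cnv_landscape(cfg)
        assert len(land) == 1
        row = land.iloc[0]
        assert 1 <= row["start"] <= row["end"] <= 1_000_000

    def test_type_proportions_all_deletion(self):
        cfg = SimulationConfig(
            chromosome_lengths={"1": 50_000_000}, n_regions=25,
            type_proportions=(1.0, 0.0, 0.0),
        )
        land = simulate_cnv_landscape(cfg)
        assert (land["type"] == "deletion").all()

    def test_regions_non_overlapping(self, small_cfg):
        land = simulate_cnv_landscape(small_cfg)
        for chrom, grp in land.groupby("chromosome"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()

    def test_genome_scale_coverage(self):
        # 500 regions of mean 170 kb on the 2.5 Gb autosomal genome:
        # expected total ~ 85 Mb, i.e. 3-4% of the genome
        land = simulate_cnv_landscape(SimulationConfig(seed=77))
        total = (land["end"] - land["start"] + 1).sum()
        genome = sum(SimulationConfig().chromosome_lengths.values())
        assert 0.02 < total / genome < 0.05

    def test_infeasible_count_rejected(self):
        cfg = SimulationConfig(chromosome_lengths={"1": 1_000_000}, n_regions=50)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cnv_landscape(cfg)


class TestCalls:
    def test_single_carrier_single_call(self, rng):
        cfg = SimulationConfig(
            n_founders=2, n_generations=0, chromosome_lengths={"1": 1_000_000},
            n_regions=1, region_mean_length=50_000, qc_fail_fraction=0.0,
        )
        ped = simulate_pedigree(cfg)
        land = simulate_cnv_landscape(cfg)
        geno = pd.DataFrame(
            [[-1], [0]], index=pd.Index(ped["animal"], name="sample_id"),
            columns=land["region_id"],
        )
        calls, qc = simulate_cnv_calls(ped, land, geno, cfg, rng)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end) == (int(land.iloc[0]["start"]), int(land.iloc[0]["end"]))
        assert c.copy_state == 1

    def test_fragmentation_produces_mergeable_pieces(self, rng):
        cfg = SimulationConfig(
            n_founders=2, n_generations=0, chromosome_lengths={"1": 1_000_000},
            n_regions=1, region_mean_length=50_000, fragmentation=1.0, qc_fail_fraction=0.0,
        )
        ped = simulate_pedigree(cfg)
        land = simulate_cnv_landscape(cfg)
        geno = pd.DataFrame(
            [[1], [0]], index=pd.Index(ped["animal"], name="sample_id"),
            columns=land["region_id"],
        )
        calls, _ = simulate_cnv_calls(ped, land, geno, cfg, rng)
        assert len(calls) == 2
        a, b = sorted(calls, key=lambda c: c.start)
        assert a.end == b.start  # shared breakpoint base
        assert (a.start, b.end) == (int(land.iloc[0]["start"]), int(land.iloc[0]["end"]))

    def test_qc_failure_fraction(self):
        cfg = SimulationConfig(
            n_founders=200, n_generations=0, chromosome_lengths={"1": 10_000_000},
            n_regions=2, region_mean_length=50_000, qc_fail_fraction=0.1, seed=3,
        )
        ped = simulate_pedigree(cfg)
        land = simulate_cnv_landscape(cfg)
        geno = simulate_genotypes(ped, land, np.random.default_rng(1))
        _, qc = simulate_cnv_calls(ped, land, geno, cfg)
        passing, _ = filter_samples(qc, QcThresholds())
        n_fail = 200 - len(passing)
        # binomial(200, 0.1): mean 20, sd ~4.2; allow 4 sd
        assert 3 <= n_fail <= 37


class TestPhenotypes:
    def make(self, cfg, rng=None):
        ped = simulate_pedigree(cfg)
        land = simulate_cnv_landscape(cfg)
        geno = simulate_genotypes(ped, land, np.random.default_rng(2))
        return ped, land, geno

    def test_deterministic_phenotypes(self, small_cfg):
        s1 = simulate_study(small_cfg)
        s2 = simulate_study(small_cfg)
        pd.testing.assert_frame_equal(s1.phenotypes, s2.phenotypes)
        assert calls_to_frame(s1.calls).equals(calls_to_frame(s2.calls))

    def test_no_variance_no_effects_constant(self):
        cfg = SimulationConfig(
            n_founders=10, n_generations=1, chromosome_lengths={"1": 10_000_000},
            n_regions=1, region_mean_length=50_000, sigma2_u=0.0, sigma2_e=0.0,
            group_effect_sd=0.0, n_groups=1, mu=7.5,
        )
        ped, land, geno = self.make(cfg)
        geno.iloc[:, :] = 0
        records, _ = simulate_phenotypes(ped, land, geno, cfg)
        np.testing.assert_allclose(records["y"], 7.5)

    def test_noise_free_effect_spacing(self):
        cfg = SimulationConfig(
            n_founders=12, n_generations=0, chromosome_lengths={"1": 10_000_000},
            n_regions=1, region_mean_length=50_000, sigma2_u=0.0, sigma2_e=0.0,
            group_effect_sd=0.0, n_groups=1, effect_sizes={"TR1": 2.0},
        )
        ped, land, geno = self.make(cfg)
        codes = np.array([-1, 0, 1] * 4, dtype=np.int8)
        geno.iloc[:, 0] = codes
        records, _ = simulate_phenotypes(ped, land, geno, cfg)
        y = records["y"].to_numpy()
        assert np.ptp(y[codes == 0]) == 0
        assert y[codes == 1][0] - y[codes == 0][0] == pytest.approx(2.0)
        assert y[codes == 0][0] - y[codes == -1][0] == pytest.approx(2.0)

    def test_founder_breeding_value_variance(self):
        # founders draw u ~ N(0, sigma2_u); 10,000 independent founders
        ped = simulate_pedigree(SimulationConfig(n_founders=10_000, n_generations=0))
        u = simulate_breeding_values(ped, 2.0, np.random.default_rng(4))
        var = u.var(ddof=1)
        se = 2.0 * np.sqrt(2.0 / 10_000)  # SE of a variance estimate
        assert abs(var - 2.0) < 3 * se

    def test_mendelian_sampling_variance(self):
        # non-inbred parents: offspring u has variance sigma2_u given a
        # large full-sib family (var of sibs around parent mean = 0.5 su2)
        ped = pd.DataFrame(
            {"animal": ["S", "D"] + [f"O{i}" for i in range(8000)],
             "sire": ["0", "0"] + ["S"] * 8000,
             "dam": ["0", "0"] + ["D"] * 8000}
        )
        u = simulate_breeding_values(ped, 1.0, np.random.default_rng(5))
        sibs = u.iloc[2:]
        dev = sibs - 0.5 * (u["S"] + u["D"])
        assert abs(dev.var(ddof=1) - 0.5) < 3 * 0.5 * np.sqrt(2 / 8000)

    def test_variance_decomposition(self):
        # with no CNVR effects and one fixed level, Var(y) ~ su2 + se2
        cfg = SimulationConfig(
            n_founders=4000, n_generations=0, chromosome_lengths={"1": 10_000_000},
            n_regions=1, region_mean_length=50_000, sigma2_u=1.0, sigma2_e=2.0,
            group_effect_sd=0.0, n_groups=1, seed=6,
        )
        ped, land, geno = self.make(cfg)
        geno.iloc[:, :] = 0
        records, truth = simulate_phenotypes(ped, land, geno, cfg)
        var = records["y"].var(ddof=1)
        se = 3.0 * np.sqrt(2.0 / 4000)
        assert abs(var - 3.0) < 3 * se


class TestFeedEvents:
    def test_one_meal_per_day_truth(self, rng):
        _, truth = simulate_feed_events(["A"], n_days=10, rng=rng, meals_per_day=1)
        assert truth.iloc[0]["FF"] == pytest.approx(1.0)

    def test_cadence_within_scan_interval(self, rng):
        stream, _ = simulate_feed_events(["A"], n_days=1, rng=rng)
        per_animal = stream[stream["animal_id"] == "A"]["timestamp_s"].to_numpy()
        gaps = np.diff(per_animal)
        within = gaps[gaps <= 300.0]
        assert within.min() >= 1.0 and within.max() <= 6.3

    def test_meals_separated_by_more_than_300s(self, rng):
        stream, truth = simulate_feed_events(["A"], n_days=3, rng=rng, meals_per_day=2)
        from cnvrpipe.phenotypes import derive_meal_events
        events = derive_meal_events(stream)
        assert len(events) == int(truth.iloc[0]["FF"] * 3)

    def test_no_events_lost_to_discard_filter(self, rng):
        from cnvrpipe.phenotypes import derive_meal_events, filter_meal_events
        stream, _ = simulate_feed_events(["A", "B"], n_days=5, rng=rng)
        events = derive_meal_events(stream)
        assert filter_meal_events(events) == events

    def test_gap_must_exceed_criterion(self, rng):
        with pytest.raises(ValueError):
            simulate_feed_events(["A"], 1, rng, inter_meal_gap_s=(200.0, 400.0))


class TestStudyDeterminism:
    def test_byte_identical_outputs(self, small_cfg):
        s1 = simulate_study(small_cfg)
        s2 = simulate_study(small_cfg)
        assert s1.pedigree.to_csv() == s2.pedigree.to_csv()
        assert s1.landscape.to_csv() == s2.landscape.to_csv()
        assert s1.genotypes.to_csv() == s2.genotypes.to_csv()
        assert calls_to_frame(s1.calls).to_csv() == calls_to_frame(s2.calls).to_csv()
        assert s1.phenotypes.to_csv() == s2.phenotypes.to_csv()
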