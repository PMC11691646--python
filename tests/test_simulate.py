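import dataclasses
import math

import numpy as np
import pytest

from censat.io import read_bed, read_features, read_trf_dat
from censat.simulate import (
    SimulationConfig,
    TruthSet,
    generate_genome,
    simulate_coverage,
    simulate_reads,
    write_truth,
)
from censat.windows import compute_windows, ThresholdConfig


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_config):
        g1, t1 = generate_genome(small_config)
        g2, t2 = generate_genome(small_config)
        assert g1 == g2
        assert t1.planted_arrays == t2.planted_arrays
        assert t1.feature_partition == t2.feature_partition
        c1 = simulate_coverage(g1, t1, small_config)
        c2 = simulate_coverage(g2, t2, small_config)
        assert c1[0].intervals == c2[0].intervals
        r1 = simulate_reads(g1, t1, small_config)
        r2 = simulate_reads(g2, t2, small_config)
        assert r1 == r2

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        g1, _ = generate_genome(small_config)
        g2, _ = generate_genome(other)
        assert g1 != g2


class TestGenomeStructure:
    def test_zero_divergence_plants_exact_generator_copies(self):
        cfg = SimulationConfig(
            seed=3, n_scaffolds=2, scaffold_length=60_000,
            centromere_length=20_000, n_families=2, motif_lengths=(5, 63),
            arrays_per_family=2, divergence=0.0, noise_model="none",
        )
        genome, truth = generate_genome(cfg)
        seqs = {r.id: r.seq for r in genome}
        generators = {f.family_id: f.generator_motif for f in truth.planted_families}
        for arr, fid in zip(truth.planted_arrays, truth.array_families):
            gen = generators[fid]
            assert arr.motif == gen
            planted = seqs[arr.scaffold][arr.start : arr.end]
            assert planted == gen * (len(planted) // len(gen))

    def test_array_bookkeeping(self, small_config):
        _, truth = generate_genome(small_config)
        expected = small_config.n_families * small_config.arrays_per_family
        assert len(truth.planted_arrays) == expected
        assert len(truth.array_families) == expected

    def test_arrays_confined_to_centromere_regions(self, small_config):
        _, truth = generate_genome(small_config)
        regions = {
            scaffold: (start, end)
            for scaffold, start, end in truth.centromere_regions
        }
        for arr in truth.planted_arrays:
            start, end = regions[arr.scaffold]
            assert start <= arr.start < arr.end <= end

    def test_shared_and_specific_family_structure(self, noise_free_sim):
        truth = noise_free_sim.truth
        scaffolds_of = {}
        for arr, fid in zip(truth.planted_arrays, truth.array_families):
            scaffolds_of.setdefault(fid, set()).add(arr.scaffold)
        spans = sorted(len(s) for s in scaffolds_of.values())
        assert spans[-1] >= 3   # one family shared across several scaffolds
        assert spans[0] == 1    # one scaffold-specific family

    def test_feature_partition_tiles_and_matches_arrays(self, small_config):
        _, truth = generate_genome(small_config)
        per_scaffold = {}
        for a in truth.feature_partition:
            per_scaffold.setdefault(a.scaffold, []).append(a)
        for scaffold, feats in per_scaffold.items():
            feats.sort(key=lambda a: a.start)
            assert feats[0].start == 0
            assert feats[-1].end == truth.scaffold_lengths[scaffold]
            for prev, nxt in zip(feats, feats[1:]):
                assert prev.end == nxt.start  # no gaps, no overlaps
        tandem = sorted(
            (a.scaffold, a.start, a.end)
            for a in truth.feature_partition
            if a.category == "tandem_repeat"
        )
        assert tandem == sorted(
            (a.scaffold, a.start, a.end) for a in truth.planted_arrays
        )

    def test_oversized_arrays_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_genome(
                SimulationConfig(
                    seed=1, n_scaffolds=2, scaffold_length=30_000,
                    centromere_length=10_000, n_families=2,
                    motif_lengths=(150,), arrays_per_family=8,
                    array_copy_number=40,
                )
            )


class TestCoverage:
    def test_fold16_no_noise_gives_exact_log2_of_4(self, noise_free_sim):
        sim = noise_free_sim
        windows = compute_windows(
            sim.chip, sim.control, sim.truth.scaffold_lengths,
            ThresholdConfig(pseudocount=0.0),
        )
        truth_windows = sim.truth.centromere_windows(sim.config.window_size)
        for w in windows:
            expected = 4.0 if (w.scaffold, w.start, w.end) in truth_windows else 0.0
            assert w.log2_ratio == pytest.approx(expected)

    def test_fold_1_gives_identical_tracks(self, small_config):
        cfg = dataclasses.replace(small_config, centromere_fold_enrichment=1.0)
        genome, truth = generate_genome(cfg)
        chip, ctrl = simulate_coverage(genome, truth, cfg)
        chip_depth = {(s, a, b): d for s, a, b, d in chip.intervals}
        ctrl_depth = {(s, a, b): d for s, a, b, d in ctrl.intervals}
        for key, depth in chip_depth.items():
            covered = sum(
                d * (min(b, key[2]) - max(a, key[1]))
                for s, a, b, d in ctrl.intervals
                if s == key[0] and a < key[2] and b > key[1]
            )
            assert covered == pytest.approx(depth * (key[2] - key[1]))

    def test_poisson_window_mean_within_3_se(self):
        cfg = SimulationConfig(
            seed=9, n_scaffolds=1, scaffold_length=100_000,
            centromere_length=20_000, n_families=1, motif_lengths=(63,),
            arrays_per_family=1, background_depth=50.0, noise_model="poisson",
        )
        genome, truth = generate_genome(cfg)
        _, ctrl = simulate_coverage(genome, truth, cfg)
        from censat.windows import window_means

        means = window_means(ctrl, 10_000, truth.scaffold_lengths)["scaffold_1"]
        n_bins = 100_000 // cfg.coverage_bin
        se = math.sqrt(cfg.background_depth / n_bins)
        assert abs(float(np.mean(means)) - 50.0) < 3 * se

    def test_x_mode_scaffold_enriched_chromosome_wide(self):
        cfg = SimulationConfig(
            seed=4, n_scaffolds=3, scaffold_length=60_000,
            centromere_length=20_000, n_families=2, motif_lengths=(5, 63),
            arrays_per_family=2, x_mode=True, noise_model="none",
        )
        genome, truth = generate_genome(cfg)
        assert truth.x_scaffold == "scaffold_3"
        assert all(r[0] != truth.x_scaffold for r in truth.centromere_regions)
        chip, ctrl = simulate_coverage(genome, truth, cfg)
        windows = compute_windows(chip, ctrl, truth.scaffold_lengths)
        x_wins = [w for w in windows if w.scaffold == truth.x_scaffold]
        assert all(w.is_centromere for w in x_wins)
        # terminal window carries the extra boost
        assert x_wins[0].log2_ratio > x_wins[1].log2_ratio


class TestReads:
    def test_zero_reads_gives_empty_set(self, small_config):
        cfg = dataclasses.replace(small_config, n_reads_chip=0)
        genome, truth = generate_genome(cfg)
        chip_reads, input_reads = simulate_reads(genome, truth, cfg)
        assert chip_reads == []
        assert len(input_reads) == cfg.n_reads_input

    def test_chip_centromere_fraction_matches_analytic_sampling(self):
        cfg = SimulationConfig(
            seed=6, n_scaffolds=3, scaffold_length=100_000,
            centromere_length=20_000, n_families=2, motif_lengths=(5, 63),
            arrays_per_family=2, centromere_fold_enrichment=10.0,
            noise_model="none", n_reads_chip=20_000, n_reads_input=0,
        )
        genome, truth = generate_genome(cfg)
        chip_reads, _ = simulate_reads(genome, truth, cfg)
        regions = {
            scaffold: (start, end)
            for scaffold, start, end in truth.centromere_regions
        }
        inside = 0
        for read in chip_reads:
            _, scaffold, start, _ = read.id.split("|")
            mid = int(start) + cfg.read_length // 2
            lo, hi = regions[scaffold]
            inside += lo <= mid < hi
        total_bp = sum(truth.scaffold_lengths.values())
        cen_bp = sum(hi - lo for lo, hi in regions.values())
        c = cen_bp / total_bp
        f = cfg.centromere_fold_enrichment
        expected = f * c / (f * c + (1 - c))
        se = math.sqrt(expected * (1 - expected) / len(chip_reads))
        # half-read clipping at region edges adds a sub-se bias allowance
        assert abs(inside / len(chip_reads) - expected) < 3 * se + 0.01

    def test_read_length_validation(self, small_config):
        with pytest.raises(ValueError, match="read_length"):
            dataclasses.replace(small_config, read_length=70_000)


class TestTruthSerialization:
    def test_round_trip_through_io_readers(self, small_config, tmp_path):
        _, truth = generate_genome(small_config)
        paths = write_truth(truth, tmp_path)
        arrays = read_trf_dat(paths["arrays"])
        assert arrays == sorted(
            truth.planted_arrays, key=lambda a: (a.scaffold, a.start)
        )
        assert read_bed(paths["centromeres"]) == sorted(truth.centromere_regions)
        feats = read_features(paths["features"])
        assert sorted(feats, key=lambda f: (f.scaffold, f.start)) == sorted(
            truth.feature_partition, key=lambda f: (f.scaffold, f.start)
        )

    def test_empty_truth_writes_valid_files(self, tmp_path):
        truth = TruthSet(
            planted_families=[], planted_arrays=[], array_families=[],
            centromere_regions=[], feature_partition=[],
            scaffold_lengths={"s": 1_000},
        )
        paths = write_truth(truth, tmp_path)
        assert read_trf_dat(paths["arrays"]) == []
        assert read_bed(paths["centromeres"]) == []
        assert read_features(paths["features"]) == []
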