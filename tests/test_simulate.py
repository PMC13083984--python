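"""Truth profiles, admixture counts, dilution ladders, BAM fixtures."""

import numpy as np
import pytest

import cnfer as cf
from cnfer import SimulationError
from cnfer.simulate import downsample_counts


class TestTruthProfile:
    def test_zero_instability_is_all_diploid(self, sim_grid):
        truth = cf.make_truth_profile(sim_grid, gi_level=0.0, seed=0)
        assert (truth.copy_number == 2).all()
        assert truth.altered_fraction == 0.0

    def test_altered_fraction_matches_target(self, sim_grid):
        truth = cf.make_truth_profile(sim_grid, gi_level=0.3, seed=0)
        assert 0.25 <= truth.altered_fraction <= 0.35
        states = set(np.unique(truth.copy_number)) - {2}
        assert states <= {0, 1, 3, 4, 6}

    def test_deterministic_for_fixed_seed(self, sim_grid):
        t1 = cf.make_truth_profile(sim_grid, gi_level=0.3, seed=7)
        t2 = cf.make_truth_profile(sim_grid, gi_level=0.3, seed=7)
        assert (t1.copy_number == t2.copy_number).all()
        assert t1.events == t2.events

    def test_contains_a_focal_event(self, sim_grid):
        truth = cf.make_truth_profile(sim_grid, gi_level=0.3, seed=7)
        assert any(last - first + 1 < 30 for _, first, last, _
                   in truth.events)

    def test_unreachable_gi_level_is_an_error(self, sim_grid):
        with pytest.raises(SimulationError, match="unreachable"):
            cf.make_truth_profile(sim_grid, gi_level=0.8, n_events=2, seed=0)

    def test_gi_level_out_of_range(self, sim_grid):
        with pytest.raises(SimulationError):
            cf.make_truth_profile(sim_grid, gi_level=0.9, seed=0)


class TestBinCounts:
    def test_tumor_free_counts_flat_at_expected_depth(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.0, depth_equivalent=1.0)
        raw = cf.simulate_bin_counts(truth, spec, sim_grid,
                                     rng=np.random.default_rng(0))
        expected = spec.reads_per_bin(sim_grid.bin_width)   # 1000 at 1x
        assert expected == 1000
        assert abs(raw.raw_counts.mean() / expected - 1) < 0.01

    def test_pure_tumor_double_gain_doubles_coverage(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=1.0)
        raw = cf.simulate_bin_counts(truth, spec, sim_grid,
                                     rng=np.random.default_rng(1))
        c4 = raw.raw_counts[truth.copy_number == 4].mean()
        c2 = raw.raw_counts[truth.copy_number == 2].mean()
        assert c4 / c2 == pytest.approx(2.0, rel=0.02)

    def test_low_tf_deviation_after_centering(self, sim_grid, truth):
        # t = 0.01, c = 3 -> expected deviation t(c-2)/2 = +0.005
        spec = cf.AdmixtureSpec(tumor_fraction=0.01)
        raw = cf.simulate_bin_counts(truth, spec, sim_grid,
                                     rng=np.random.default_rng(2))
        prof = cf.profile_from_counts(raw.raw_counts, sim_grid, correct=False)
        c3 = prof.deviation[truth.copy_number == 3].mean()
        assert c3 == pytest.approx(0.005, abs=0.002)

    def test_gc_bias_multiplier_applied(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.0,
                                gc_bias=np.array([2.0, 1.0]))  # 1 + 2(gc-.5)
        raw = cf.simulate_bin_counts(truth, spec, sim_grid,
                                     rng=np.random.default_rng(3))
        gc = sim_grid.bins["gc"].to_numpy()
        hi = raw.raw_counts[gc > 0.55].mean()
        lo = raw.raw_counts[gc < 0.45].mean()
        assert hi > lo * 1.1

    def test_downsampling_preserves_rates(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.0, depth_equivalent=2.0)
        raw = cf.simulate_bin_counts(truth, spec, sim_grid,
                                     rng=np.random.default_rng(4))
        thin = downsample_counts(raw.raw_counts, 0.25,
                                 np.random.default_rng(5))
        assert (thin <= raw.raw_counts).all()
        assert thin.mean() / raw.raw_counts.mean() == pytest.approx(0.25,
                                                                    rel=0.02)


class TestDilutionSeries:
    def test_manifest_accounting(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.0, n_replicates=3, seed=9)
        profiles, manifest = cf.simulate_dilution_series(
            truth, [0.0, 0.002, 0.02], spec, sim_grid, correct=False)
        assert len(manifest) == 10          # 9 queries + 1 reference
        assert len(profiles) == 10
        assert (manifest["role"] == "reference").sum() == 1

    def test_same_master_seed_identical_manifest(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.0, n_replicates=2, seed=9)
        _, m1 = cf.simulate_dilution_series(truth, [0.0, 0.01], spec,
                                            sim_grid, correct=False)
        _, m2 = cf.simulate_dilution_series(truth, [0.0, 0.01], spec,
                                            sim_grid, correct=False)
        assert m1.to_csv(sep="\t", index=False) == m2.to_csv(sep="\t",
                                                             index=False)

    def test_generators_are_pure_functions_of_seed(self, sim_grid, truth):
        spec = cf.AdmixtureSpec(tumor_fraction=0.05, seed=3)
        r1 = cf.simulate_bin_counts(truth, spec, sim_grid)
        r2 = cf.simulate_bin_counts(truth, spec, sim_grid)
        assert (r1.raw_counts == r2.raw_counts).all()


@pytest.fixture(scope="module")
def small_grid():
    import pandas as pd
    bins = pd.DataFrame({
        "chrom": "chr1", "start": np.arange(40) * 100_000,
        "end": (np.arange(40) + 1) * 100_000,
        "gc": 0.5, "mappability": 1.0, "reptiming": 0.0})
    return cf.BinGrid(bins=bins, bin_width=100_000, step=100_000,
                      chrom_sizes={"chr1": 4_000_000})


class TestFixtureBam:
    def test_flat_bam_counts_near_poisson(self, small_grid, tmp_path):
        truth = cf.TruthProfile(copy_number=np.full(40, 2), gi_level=0.0,
                                seed=0)
        bam = cf.make_fixture_bam(tmp_path / "flat.bam", small_grid, truth,
                                  t=0.0, n_reads=20_000, seed=1)
        prof = cf.count_reads(bam, small_grid)
        counts = prof.raw_counts
        # two records per fragment -> ~1000 per bin; CV consistent w/ Poisson
        assert counts.mean() == pytest.approx(1000, rel=0.05)
        cv = counts.std() / counts.mean()
        assert cv < 2.5 / np.sqrt(counts.mean())

    def test_low_mapq_reads_are_invisible(self, small_grid, tmp_path):
        truth = cf.TruthProfile(copy_number=np.full(40, 2), gi_level=0.0,
                                seed=0)
        bam = cf.make_fixture_bam(tmp_path / "q20.bam", small_grid, truth,
                                  t=0.0, n_reads=500, seed=1, mapq=20)
        with pytest.raises(cf.CoverageError, match="zero usable"):
            cf.count_reads(bam, small_grid, mapq_min=30)
        assert cf.count_reads(bam, small_grid, mapq_min=20).raw_counts.sum() > 0

    def test_tumor_density_tracks_copy_number(self, small_grid, tmp_path):
        c = np.full(40, 2, dtype=np.int64)
        c[10:20] = 6
        truth = cf.TruthProfile(copy_number=c, gi_level=0.25, seed=0)
        bam = cf.make_fixture_bam(tmp_path / "gain.bam", small_grid, truth,
                                  t=1.0, n_reads=20_000, seed=2)
        prof = cf.count_reads(bam, small_grid)
        ratio = prof.raw_counts[10:20].mean() / prof.raw_counts[:10].mean()
        assert ratio == pytest.approx(3.0, rel=0.1)
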