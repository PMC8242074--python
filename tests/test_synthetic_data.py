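import numpy as np
import pytest

from minibulkcna import (
    CNAEvent,
    SimSpec,
    compute_mapd,
    gc_normalize,
    make_genome,
    simulate_cohort,
    simulate_sample,
)
from minibulkcna.synthetic_data import (
    SimulationError,
    baseline_cn,
    calibrate_dispersion,
    true_cn_vector,
)


class TestMakeGenome:
    def test_full_scale_bin_count(self, full_genome):
        assert len(set(full_genome.chrom)) == 24
        assert 2700 <= full_genome.n_bins <= 3100

    def test_deterministic_under_seed(self):
        assert make_genome(scale=0.25, seed=7) == make_genome(scale=0.25, seed=7)

    def test_gc_confined(self, full_genome):
        assert np.all(full_genome.gc >= 0.3) and np.all(full_genome.gc <= 0.6)

    def test_too_small_scale_rejected(self):
        with pytest.raises(SimulationError, match="< 10 bins"):
            make_genome(scale=0.05)


class TestTruth:
    def test_sex_baselines(self, small_genome):
        male = baseline_cn(small_genome, "male")
        female = baseline_cn(small_genome, "female")
        slx = small_genome.chrom_slices()["X"]
        sly = small_genome.chrom_slices()["Y"]
        assert np.all(male[slx] == 1) and np.all(male[sly] == 1)
        assert np.all(female[slx] == 2) and np.all(female[sly] == 0)
        assert np.all(male[small_genome.is_autosome] == 2)

    def test_event_on_absent_chromosome_rejected(self, small_genome):
        spec = SimSpec(bins=small_genome, sex="female", events=[CNAEvent("Y", 0, 5, 1.0)])
        with pytest.raises(SimulationError, match="absent for sex"):
            true_cn_vector(spec)

    def test_overlapping_events_rejected(self, small_genome):
        with pytest.raises(SimulationError, match="overlapping"):
            SimSpec(
                bins=small_genome,
                events=[CNAEvent("7", 0, 10, 3.0), CNAEvent("7", 5, 15, 1.0)],
            )


class TestSimulateSample:
    def test_flat_diploid_mean_count(self, full_genome):
        # no GC bias, no events: expected count per autosomal-equivalent bin
        # is depth / n_bins for a female minus her zero-copy Y block
        spec = SimSpec(
            bins=full_genome, sex="female", depth=1e6, gc_bias=(1.0, 0.0, 0.0), seed=5
        )
        bc, truth = simulate_sample(spec)
        ny = full_genome.chrom_slices()["Y"].stop - full_genome.chrom_slices()["Y"].start
        expected = 1e6 / (full_genome.n_bins - ny)
        observed = bc.counts[truth.true_cn == 2].mean()
        assert abs(observed - expected) < 5

    def test_total_count_matches_depth(self, full_genome):
        spec = SimSpec(bins=full_genome, depth=1e6, seed=2)
        bc, _ = simulate_sample(spec)
        # Poisson sum around 1e6: 5 sd is 5000
        assert abs(bc.total_mapped - 1e6) < 5000

    def test_event_region_mean_ratio(self, full_genome):
        spec = SimSpec(
            bins=full_genome,
            depth=1e6,
            gc_bias=(1.0, 0.0, 0.0),
            events=[CNAEvent("5", 10, 60, 3.0)],
            seed=9,
        )
        bc, truth = simulate_sample(spec)
        in_event = bc.counts[truth.true_cn == 3].mean()
        baseline = np.median(bc.counts[truth.true_cn == 2])
        assert abs(in_event / baseline - 1.5) < 0.075  # 5% of the 1.5 ratio

    def test_dispersion_raises_mapd(self, small_genome):
        mapds = {0.0: [], 0.05: []}
        for d in mapds:
            rng = np.random.default_rng(11)
            for _ in range(20):
                spec = SimSpec(bins=small_genome, depth=3e5, dispersion=d)
                bc, _ = simulate_sample(spec, rng=rng)
                mapds[d].append(compute_mapd(gc_normalize(bc, small_genome)))
        assert np.median(mapds[0.05]) > np.median(mapds[0.0])

    def test_determinism_and_seed_sensitivity(self, small_genome):
        spec = SimSpec(bins=small_genome, depth=2e5, seed=13)
        a, _ = simulate_sample(spec)
        b, _ = simulate_sample(spec)
        c, _ = simulate_sample(SimSpec(bins=small_genome, depth=2e5, seed=14))
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_noiseless_profile_matches_truth(self, small_genome):
        # dispersion 0 at high depth: normalized profile within 2% of true CN
        spec = SimSpec(
            bins=small_genome,
            sex="female",
            depth=5e7,
            dispersion=0.0,
            events=[CNAEvent("3", 5, 25, 3.0)],
            seed=3,
        )
        bc, truth = simulate_sample(spec)
        prof = gc_normalize(bc, small_genome)
        ok = prof.mask & (truth.true_cn > 0)
        rel = np.abs(prof.x[ok] - truth.true_cn[ok]) / truth.true_cn[ok]
        assert np.max(rel) < 0.02


class TestCalibration:
    def test_target_below_poisson_floor_rejected(self, small_genome):
        spec = SimSpec(bins=small_genome, depth=1e6, seed=1)
        with pytest.raises(SimulationError, match="floor"):
            calibrate_dispersion(0.01, spec)

    def test_calibration_hits_target(self, small_genome):
        # fast variant on the small genome; the full-depth check lives in
        # the acceptance suite
        spec = SimSpec(bins=small_genome, depth=2e5, seed=21)
        d = calibrate_dispersion(0.25, spec, n_reps=10)
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(10):
            bc, _ = simulate_sample(
                SimSpec(bins=small_genome, depth=2e5, dispersion=d), rng=rng
            )
            vals.append(compute_mapd(gc_normalize(bc, small_genome)))
        assert abs(np.median(vals) - 0.25) <= 0.025


class TestCohort:
    def test_fd_patients_event_free(self, small_genome):
        counts, truths, sheet = simulate_cohort(
            small_genome, groups={"FD": 5}, depth=5e4, seed=4
        )
        assert all(len(t.events) == 0 for t in truths.values())
        baselines = {
            sid: baseline_cn(small_genome, sheet.sex_of(sid)) for sid in truths
        }
        assert all(np.array_equal(truths[s].true_cn, baselines[s]) for s in truths)

    def test_lesional_samples_share_truth_normals_clean(self, small_genome):
        counts, truths, sheet = simulate_cohort(
            small_genome, groups={"OF": 3}, depth=5e4, seed=8
        )
        for pid, sids in sheet.patients().items():
            lesional = [s for s in sids if sheet.is_lesional(s)]
            normals = [s for s in sids if not sheet.is_lesional(s)]
            ref = truths[lesional[0]].events
            for s in lesional[1:]:
                assert truths[s].events == ref
            for s in normals:
                assert truths[s].events == []

    def test_os_patients_hit_many_chromosomes(self, small_genome):
        counts, truths, sheet = simulate_cohort(
            small_genome, groups={"OS": 3}, depth=5e4, seed=15
        )
        for sid, t in truths.items():
            if sheet.is_lesional(sid):
                assert len({e.chrom for e in t.events}) >= 8

    def test_cohort_deterministic(self, small_genome):
        a, _, _ = simulate_cohort(small_genome, groups={"OF": 1, "FD": 1}, depth=5e4, seed=6)
        b, _, _ = simulate_cohort(small_genome, groups={"OF": 1, "FD": 1}, depth=5e4, seed=6)
        assert set(a) == set(b)
        assert all(np.array_equal(a[s].counts, b[s].counts) for s in a)
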