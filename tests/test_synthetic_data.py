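"""Simulator ground truth: landscape geometry, conservation, closed forms."""

import filecmp

import numpy as np
import pytest

import scarline as sl
from scarline import synthetic_data as sd


class TestLandscape:
    def test_single_zone_fork_direction(self):
        layout = sl.GenomeLayout.from_dict({"chr1": 100_000})
        land = sd.ReplicationLandscape(
            layout=layout,
            zones=sd.pd.DataFrame(
                {"chrom": ["chr1"], "start": [45_000], "end": [55_000], "efficiency": [1.0]}
            ),
        )
        fd = land.fork_direction("chr1", [10_000, 50_000, 90_000])
        assert fd.tolist() == [-1.0, 0.0, 1.0]

    def test_two_zone_termination_midpoint(self):
        layout = sl.GenomeLayout.from_dict({"chr1": 100_000})
        land = sd.ReplicationLandscape(
            layout=layout,
            zones=sd.pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [18_000, 58_000],
                    "end": [22_000, 62_000],
                    "efficiency": [1.0, 1.0],
                }
            ),
        )
        assert land.termination_midpoints("chr1").tolist() == [40_000.0]
        fd = land.fork_direction("chr1", [30_000, 40_000, 50_000])
        assert fd.tolist() == [1.0, 0.0, -1.0]

    def test_rfd_equals_fork_direction_at_full_efficiency(self, landscape, grid1kb):
        track = landscape.rfd_track(grid1kb)
        centers = grid1kb.centers()
        fd = landscape.fork_direction("chr1", centers)
        np.testing.assert_allclose(track.values, fd)

    def test_rfd_matches_monte_carlo_firing(self, rng):
        layout = sl.GenomeLayout.from_dict({"chr1": 500_000})
        land = sd.simulate_landscape(
            layout, n_zones=5, efficiency=(0.3, 0.9), zone_width=2_000, seed=3
        )
        centers = ((land.zones["start"] + land.zones["end"]) // 2).to_numpy(float)
        eff = land.zones["efficiency"].to_numpy()
        positions = np.linspace(10_000, 490_000, 25)
        analytic = land.rfd("chr1", positions)
        n_mc = 4_000
        fired = rng.random((n_mc, len(eff))) < eff
        mc = np.zeros((n_mc, len(positions)))
        for i in range(n_mc):
            on = centers[fired[i]]
            if on.size == 0:
                continue
            for j, x in enumerate(positions):
                d = np.abs(x - on)
                m = d.min()
                winners = on[d == m]
                signs = np.sign(x - winners)
                mc[i, j] = signs[0] if np.all(signs == signs[0]) else 0.0
        mc_mean = mc.mean(axis=0)
        mc_se = mc.std(axis=0, ddof=1) / np.sqrt(n_mc)
        assert np.all(np.abs(analytic - mc_mean) < 3 * np.maximum(mc_se, 1e-3))

    def test_zone_density_guard(self):
        layout = sl.GenomeLayout.from_dict({"chr1": 50_000})
        with pytest.raises(ValueError, match="denser"):
            sd.simulate_landscape(layout, n_zones=20, zone_width=5_000, seed=0)


class TestRecycling:
    def test_parental_mass_conserved_exactly(self, rng):
        for bias in (-1.0, -0.3, 0.0, 0.7, 1.0):
            n = rng.integers(0, 50, size=1_000)
            lead, lag = sd.replicate_nucleosomes(n, bias, rng)
            assert np.array_equal(lead + lag, n)
            assert (lead >= 0).all() and (lag >= 0).all()

    def test_bias_out_of_range(self, rng):
        with pytest.raises(ValueError):
            sd.replicate_nucleosomes(10, 1.5, rng)
        with pytest.raises(ValueError):
            sd.RecyclingModel(bias=-1.2)

    def test_symmetric_recycling_gives_equal_strand_means(self, landscape, grid1kb, rfd):
        model = sd.RecyclingModel(bias=0.0, noise="poisson")
        sc = sd.simulate_scarseq_counts(
            landscape, model, "H3K27me3", 0.0, grid1kb, rfd=rfd, seed=10
        )
        diff = sc.forward.astype(float) - sc.reverse.astype(float)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_parental_only_mark_partition_matches_bias(self, landscape, grid1kb, rfd):
        """At rho = 0 the oriented partition of a parental mark equals b."""
        model = sd.RecyclingModel(
            bias=0.8,
            marks={"M": sd.MarkKinetics(parental_prob=1.0, restoration_rate=0.0)},
            noise="poisson",
        )
        sc = sd.simulate_scarseq_counts(landscape, model, "M", 8.0, grid1kb, rfd=rfd, seed=11)
        part = sl.compute_partition(sc)
        right = rfd.values > 0.99
        ok = right & np.isfinite(part.values)
        m = part.values[ok].mean()
        se = part.values[ok].std(ddof=1) / np.sqrt(ok.sum())
        assert abs(m - 0.8) < 3 * se

    def test_new_histone_wave_mark_has_opposite_sign(self, landscape, grid1kb, rfd):
        """A mark carried mostly on new histones partitions toward the lagging strand."""
        model = sd.RecyclingModel(bias=0.7, noise="poisson")
        right = rfd.values > 0.99
        parental = sd.simulate_scarseq_counts(
            landscape, model, "H3K27me3", 0.0, grid1kb, rfd=rfd, seed=12
        )
        wave = sd.simulate_scarseq_counts(
            landscape, model, "H3K27ac", 0.0, grid1kb, rfd=rfd, seed=13
        )
        p_par = sl.compute_partition(parental).values
        p_wave = sl.compute_partition(wave).values
        assert np.nanmean(p_par[right]) > 0.2
        assert np.nanmean(p_wave[right]) < -0.05

    def test_asymmetry_decays_monotonically_for_restoring_mark(self, landscape, grid1kb, rfd):
        model = sd.RecyclingModel(bias=0.7, noise="poisson")
        amps = []
        for i, t in enumerate((0.0, 1.0, 3.0, 8.0)):
            sc = sd.simulate_scarseq_counts(
                landscape, model, "H3K27me3", t, grid1kb, rfd=rfd, seed=20 + i
            )
            part = sl.compute_partition(sc)
            prof = sl.orient_partition(part, landscape.zones, rfd, flank=40_000)
            amps.append(sl.asymmetry_amplitude(prof)["amplitude"])
        assert all(b < a + 0.02 for a, b in zip(amps, amps[1:]))
        assert amps[-1] < amps[0]

    def test_same_seed_identical_counts(self, landscape, grid1kb, rfd):
        model = sd.RecyclingModel(bias=0.3)
        a = sd.simulate_scarseq_counts(landscape, model, "H3K4me3", 1.0, grid1kb, rfd=rfd, seed=5)
        b = sd.simulate_scarseq_counts(landscape, model, "H3K4me3", 1.0, grid1kb, rfd=rfd, seed=5)
        assert np.array_equal(a.forward, b.forward) and np.array_equal(a.reverse, b.reverse)


def test_experiment_outputs_byte_identical(tmp_path):
    kw = dict(
        scenario="MCM2-2A",
        marks=("H3K27me3",),
        times=(0.0, 3.0),
        chrom_length=500_000,
        n_zones=4,
        seed=9,
    )
    sd.simulate_experiment(tmp_path / "a", **kw)
    sd.simulate_experiment(tmp_path / "b", **kw)
    names = [p.name for p in sorted((tmp_path / "a").iterdir())]
    match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
    assert not mismatch and not errors and len(match) == len(names) >= 4


class TestQChipSim:
    def test_planted_global_gain_recoverable_via_spike(self):
        sim = sd.simulate_qchip_counts(
            n_bins=2_000, global_scale={"WT": 1.0, "MUT": 1.3}, seed=3
        )
        from scarline import qchip_do as q

        fac = q.spikein_scale_factors(sim.spike_totals)
        norm = q.normalize_signal(sim.counts, fac).normalized
        wt = [c for c in norm if c.startswith("WT")]
        mut = [c for c in norm if c.startswith("MUT")]
        ratio = norm[mut].to_numpy().mean() / norm[wt].to_numpy().mean()
        assert abs(ratio - 1.3) < 0.065  # within 5 %

    def test_planted_bin_bookkeeping(self):
        sim = sd.simulate_qchip_counts(
            n_bins=1_000, local_changes={"MUT": (0.05, 2.0)}, seed=4
        )
        bins = sim.truth["local"]["MUT"]["bins"]
        assert len(bins) == 50 and len(set(bins)) == 50
        assert sim.truth["local"]["MUT"]["fold"] == 2.0

    def test_parameter_guards(self):
        with pytest.raises(ValueError):
            sd.simulate_qchip_counts(spike_fraction=0.5)
        with pytest.warns(UserWarning, match="replicates"):
            sd.simulate_qchip_counts(n_bins=10, replicates=1, seed=0)


class TestRepeatSim:
    def test_zero_multimapping_rate(self):
        sim = sd.simulate_repeat_counts(
            n_subfamilies=20, multimapping_rate=(0.0, 0.0), seed=1
        )
        assert (sim.multi_counts.to_numpy() == 0).all()

    def test_multimapping_fraction_matches_rate_at_depth(self):
        sim = sd.simulate_repeat_counts(
            n_subfamilies=50,
            multimapping_rate=(0.5, 0.5),
            mean_reads_per_subfamily=2_000,
            nonrepeat_reads=0.0,
            seed=2,
        )
        frac = sim.multi_counts.sum().sum() / sim.ptm_counts.sum().sum()
        assert abs(frac - 0.5) < 0.02

    def test_read_level_generator_alignment_counts(self, rng):
        copies = sd.pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "start": [0, 1_000, 2_000, 3_000, 4_000, 5_000],
                "end": [500, 1_500, 2_500, 3_500, 4_500, 5_500],
                "subfamily": ["A", "A", "A", "B", "B", "B"],
            }
        )
        reads = sd.simulate_repeat_reads(copies, n_reads=200, multimapping_rate=0.4, seed=3)
        per_read = reads.groupby("read_id").size()
        assert per_read.min() == 1 and per_read.max() <= 4
        assert per_read.size == 200
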