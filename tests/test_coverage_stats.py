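import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from covsex.coverage_stats import (
    ChromCoverageSummary,
    coverage_ratio_matrix,
    density_modes,
    genome_wide_mean_depth,
    normalized_per_base,
    read_coverage_summary,
    sex_mean_normalized_depth,
    window_sex_means,
    write_coverage_summary,
)
from covsex.io_formats import (
    PerBaseDepthTrack,
    SampleRecord,
    SampleSheet,
    WindowCountTable,
)


def summary_of(depths: dict, lengths: dict) -> ChromCoverageSummary:
    return ChromCoverageSummary(pd.DataFrame(depths).T, lengths)


class TestGenomeWideMean:
    def test_equal_lengths_plain_average(self):
        s = summary_of({"s1": {"c1": 4.0, "c2": 6.0}}, {"c1": 100, "c2": 100})
        assert genome_wide_mean_depth(s, "s1") == pytest.approx(5.0)

    def test_length_weighting(self):
        # hand-computed: (4*300 + 8*100) / 400
        s = summary_of({"s1": {"c1": 4.0, "c2": 8.0}}, {"c1": 300, "c2": 100})
        assert genome_wide_mean_depth(s, "s1") == pytest.approx(5.0)

    def test_single_chromosome_identity(self):
        s = summary_of({"s1": {"c1": 4.4}}, {"c1": 1000})
        assert genome_wide_mean_depth(s, "s1") == pytest.approx(4.4)

    def test_exclusion_option(self):
        s = summary_of({"s1": {"c1": 4.0, "c2": 8.0}}, {"c1": 100, "c2": 100})
        assert genome_wide_mean_depth(s, "s1", exclude={"c2"}) == pytest.approx(4.0)


class TestCoverageRatios:
    def test_ratio_one_and_half(self):
        s = summary_of({"s1": {"c1": 4.4, "c2": 2.2}},
                       {"c1": 1_000_000, "c2": 10})
        rm = coverage_ratio_matrix(s)
        assert rm.ratios.loc["s1", "c1"] == pytest.approx(1.0, abs=1e-4)
        assert rm.ratios.loc["s1", "c2"] == pytest.approx(0.5, rel=1e-4)

    def test_zero_depth_sample_excluded(self):
        s = summary_of({"s1": {"c1": 4.0}, "s2": {"c1": 0.0}}, {"c1": 100})
        rm = coverage_ratio_matrix(s)
        assert rm.excluded_samples == ["s2"]
        assert "s2" not in rm.ratios.index

    @given(st.lists(st.floats(0.1, 20), min_size=2, max_size=6),
           st.lists(st.integers(10, 10_000), min_size=2, max_size=6))
    def test_weighted_mean_of_ratios_is_one(self, means, lengths):
        k = min(len(means), len(lengths))
        chroms = [f"c{i}" for i in range(k)]
        s = summary_of({"s1": dict(zip(chroms, means[:k]))},
                       dict(zip(chroms, lengths[:k])))
        rm = coverage_ratio_matrix(s)
        w = np.array(lengths[:k], dtype=float)
        weighted = float((rm.ratios.loc["s1"].to_numpy() * w).sum() / w.sum())
        assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_summary_tsv_roundtrip(self, tmp_path):
        s = summary_of({"s1": {"c1": 4.125, "c2": 2.5}},
                       {"c1": 300, "c2": 100})
        path = tmp_path / "summary.tsv"
        write_coverage_summary(s, path)
        back = read_coverage_summary(path)
        assert back.lengths == s.lengths
        pd.testing.assert_frame_equal(back.mean_depth, s.mean_depth,
                                      check_names=False)


class TestNormalizedPerBase:
    def track(self, depths):
        depths = np.asarray(depths)
        return PerBaseDepthTrack("c1", np.arange(1, len(depths) + 1),
                                 depths.reshape(-1, 1), ["s1"],
                                 chrom_length=len(depths))

    def test_simple_normalization(self):
        out = normalized_per_base(self.track([0, 2, 4]), "s1", 2.0)
        assert out.tolist() == [0.0, 1.0, 2.0]

    def test_all_zero_chromosome(self):
        out = normalized_per_base(self.track([0, 0, 0]), "s1", 2.0)
        assert not out.any()

    def test_conservation(self):
        raw = [3, 0, 7, 1]
        out = normalized_per_base(self.track(raw), "s1", 4.4)
        assert out.sum() * 4.4 == pytest.approx(sum(raw))

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            normalized_per_base(self.track([1]), "s1", 0.0)

    def test_absent_positions_count_as_zero(self):
        track = PerBaseDepthTrack("c1", np.array([2]), np.array([[4]]),
                                  ["s1"], chrom_length=4)
        out = normalized_per_base(track, "s1", 2.0)
        assert out.tolist() == [0.0, 2.0, 0.0, 0.0]


class TestDensityModes:
    def test_zero_one_point_masses(self):
        values = np.array([0.0] * 500 + [1.0] * 500)
        nd = density_modes(values)
        assert len(nd.modes) == 2
        assert nd.mode_locations[0] == pytest.approx(0.0, abs=0.03)
        assert nd.mode_locations[1] == pytest.approx(1.0, abs=0.03)

    def test_single_point_mass(self):
        nd = density_modes(np.full(100, 1.0))
        assert len(nd.modes) == 1
        assert nd.mode_locations[0] == pytest.approx(1.0, abs=0.03)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            density_modes(np.array([]))

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        nd = density_modes(rng.uniform(0, 2, 5000))
        assert nd.density.sum() * nd.binwidth == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(1.0, 0.1, 2000).clip(0)
        a = density_modes(values)
        b = density_modes(rng.permutation(values))
        assert a.mode_locations == b.mode_locations

    def test_scaling_halves_mode_locations(self):
        rng = np.random.default_rng(2)
        values = rng.normal(1.0, 0.06, 5000).clip(0)
        full = density_modes(values)
        halved = density_modes(values / 2)  # doubled genome mean
        assert halved.mode_locations[0] == pytest.approx(
            full.mode_locations[0] / 2, abs=0.03)

    def test_mixture_modes_and_height_order(self):
        # dosage mixture: hemizygous bases dominate -> the 0.5 mode is higher
        rng = np.random.default_rng(3)
        values = np.concatenate([
            rng.normal(0.5, 0.05, 6000),
            rng.normal(1.0, 0.05, 4000),
        ]).clip(0)
        nd = density_modes(values)
        assert len(nd.modes) == 2
        locs = nd.mode_locations
        assert locs[0] == pytest.approx(0.5, abs=0.05)
        assert locs[1] == pytest.approx(1.0, abs=0.05)
        assert nd.modes[0][1] > nd.modes[1][1]


class TestWindowSexMeans:
    def table(self, counts, sample_ids):
        counts = np.asarray(counts)
        n = counts.shape[0]
        starts = np.arange(n) * 10
        return WindowCountTable("c1", starts, starts + 10, counts, sample_ids)

    def sheet(self, labels):
        return SampleSheet([SampleRecord(f"s{i + 1}", lab)
                            for i, lab in enumerate(labels)])

    def test_basic_means(self):
        t = self.table([[10, 20, 0, 0]], ["s1", "s2", "s3", "s4"])
        wsm = window_sex_means(t, self.sheet(["male", "male", "female", "female"]))
        assert wsm.male_mean[0] == 15.0
        assert wsm.female_mean[0] == 0.0

    def test_equal_counts_equal_means(self):
        t = self.table([[7, 7, 7]], ["s1", "s2", "s3"])
        wsm = window_sex_means(t, self.sheet(["male", "female", "female"]))
        assert wsm.male_mean[0] == wsm.female_mean[0] == 7.0

    def test_unknowns_excluded(self):
        t = self.table([[10, 0, 1000]], ["s1", "s2", "s3"])
        wsm = window_sex_means(t, self.sheet(["male", "female", "unknown"]))
        assert wsm.male_mean[0] == 10.0

    def test_missing_sex_errors(self):
        t = self.table([[10, 20]], ["s1", "s2"])
        with pytest.raises(ValueError, match="female"):
            window_sex_means(t, self.sheet(["male", "male"]))

    def test_conservation_against_column_sums(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 100, size=(6, 5))
        ids = [f"s{i + 1}" for i in range(5)]
        labels = ["male", "male", "male", "female", "female"]
        wsm = window_sex_means(self.table(counts, ids), self.sheet(labels))
        assert (wsm.male_mean * 3).sum() == pytest.approx(counts[:, :3].sum())
        assert (wsm.female_mean * 2).sum() == pytest.approx(counts[:, 3:].sum())

    def test_means_bounded_by_member_extremes(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(8, 4))
        ids = [f"s{i + 1}" for i in range(4)]
        wsm = window_sex_means(self.table(counts, ids),
                               self.sheet(["male", "male", "female", "female"]))
        assert np.all(wsm.male_mean >= counts[:, :2].min(axis=1))
        assert np.all(wsm.male_mean <= counts[:, :2].max(axis=1))


def test_sex_mean_normalized_depth_averages_dosage(xy_sim):
    """Cross-sample averaging keeps PAR bases near 1 and hemizygous male
    bases near 0.5 in normalized units."""
    from covsex.coverage_stats import coverage_ratio_matrix

    rm = coverage_ratio_matrix(xy_sim.summary, xy_sim.sheet)
    vals = sex_mean_normalized_depth(xy_sim.track, xy_sim.sheet,
                                     rm.genome_means, "male")
    labels = xy_sim.plan.base_labels()
    assert vals[labels == 1].mean() == pytest.approx(0.5, abs=0.02)
    assert vals[labels == 0].mean() == pytest.approx(1.0, abs=0.02)
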