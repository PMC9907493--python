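import numpy as np
import pandas as pd
import pytest

from covsex.coverage_stats import (
    CoverageRatioMatrix,
    WindowSexMeans,
    coverage_ratio_matrix,
    window_sex_means,
)
from covsex.io_formats import SampleRecord, SampleSheet, WindowCountTable
from covsex.sex_inference import (
    AMBIGUOUS,
    SEX_SPECIFIC,
    SHARED,
    InferenceConfig,
    assign_unknowns,
    call_system,
    chromosome_scan,
    detect_candidates,
    segment_windows,
)
from covsex.stat_tests import welch_t
from covsex.synthetic_data import SimConfig, simulate_cohort


def ratio_matrix(values: dict, chrom="chr12") -> CoverageRatioMatrix:
    df = pd.DataFrame({chrom: pd.Series(values)})
    return CoverageRatioMatrix(df, pd.Series({s: 4.4 for s in values}))


def sheet_from(labels: dict) -> SampleSheet:
    return SampleSheet([SampleRecord(s, lab) for s, lab in labels.items()])


class TestDetectCandidates:
    def test_planted_chromosome_is_sole_candidate(self, xy_sim):
        rm = coverage_ratio_matrix(xy_sim.summary, xy_sim.sheet)
        cands = detect_candidates(rm, xy_sim.sheet)
        assert [c.chromosome for c in cands] == [xy_sim.truth.sex_chromosome]
        assert cands[0].direction == "female_lower"

    def test_identical_sexes_no_candidate(self):
        # zero variance in both groups, equal means -> degenerate Welch path
        values = {f"s{i}": 1.0 for i in range(8)}
        labels = {f"s{i}": ("male" if i < 4 else "female") for i in range(8)}
        cands = detect_candidates(ratio_matrix(values), sheet_from(labels))
        assert cands == []

    def test_requires_two_per_sex(self):
        values = {"a": 1.0, "b": 0.9, "c": 1.1}
        labels = {"a": "male", "b": "female", "c": "female"}
        with pytest.raises(ValueError):
            detect_candidates(ratio_matrix(values), sheet_from(labels))

    def test_adjusted_p_at_least_raw(self, xy_sim):
        rm = coverage_ratio_matrix(xy_sim.summary, xy_sim.sheet)
        for ev in chromosome_scan(rm, xy_sim.sheet):
            assert ev.p_adj >= ev.welch.p - 1e-15


class TestSegmentWindows:
    def wsm(self, male, female):
        male, female = np.asarray(male, float), np.asarray(female, float)
        n = len(male)
        starts = np.arange(n) * 10
        return WindowSexMeans("chr12", starts, starts + 10, male, female,
                              male, female)

    def test_sex_specific_window(self):
        track = segment_windows(self.wsm([1000, 1000], [0, 990]))
        assert track.labels[0] == SEX_SPECIFIC
        assert track.lacking[0] == "female"
        assert track.labels[1] == SHARED

    def test_all_zero_chromosome_ambiguous(self):
        track = segment_windows(self.wsm([0, 0], [0, 0]))
        assert track.labels == [AMBIGUOUS, AMBIGUOUS]

    def test_intermediate_ratio_ambiguous(self):
        track = segment_windows(self.wsm([1000, 1000], [500, 1000]))
        assert track.labels[0] == AMBIGUOUS

    def test_recovers_planted_hemizygous_fraction(self, xy_sim):
        rm = coverage_ratio_matrix(xy_sim.summary, xy_sim.sheet)
        wsm = window_sex_means(xy_sim.windows, xy_sim.sheet, rm.genome_means)
        track = segment_windows(wsm)
        recovered = sum(1 for lab in track.labels if lab == SEX_SPECIFIC)
        planted = sum(1 for lab in xy_sim.truth.window_labels
                      if lab == "hemizygous")
        assert abs(recovered - planted) <= 1
        # and they are the right windows
        planted_set = {
            (s, e) for s, e, lab in zip(xy_sim.truth.window_starts,
                                        xy_sim.truth.window_ends,
                                        xy_sim.truth.window_labels)
            if lab == "hemizygous"
        }
        recovered_set = set(track.sex_specific_windows("female"))
        assert len(planted_set ^ recovered_set) <= 1


class TestAssignUnknowns:
    def build(self, unknown_ratio, unknown_counts):
        """Two known clusters (f=0.70, m=0.85) and one unknown; two
        sex-specific windows and one shared window."""
        labels = {"f1": "female", "f2": "female", "m1": "male", "m2": "male",
                  "u1": "unknown"}
        sheet = sheet_from(labels)
        values = {"f1": 0.70, "f2": 0.70, "m1": 0.85, "m2": 0.85,
                  "u1": unknown_ratio}
        rm = ratio_matrix(values)
        counts = np.array([
            [0, 0, 300, 300, unknown_counts[0]],
            [0, 0, 300, 300, unknown_counts[1]],
            [300, 300, 300, 300, 300],
        ])
        table = WindowCountTable("chr12", np.array([0, 10, 20]),
                                 np.array([10, 20, 30]), counts,
                                 list(labels))
        wsm = window_sex_means(table, sheet, rm.genome_means)
        track = segment_windows(wsm)
        return rm, track, table, sheet

    def test_clear_female(self):
        rm, track, table, sheet = self.build(0.70, (0, 0))
        [a] = assign_unknowns(rm, track, table, sheet)
        assert a.assigned_sex == "female"
        assert a.zero_fraction == 1.0

    def test_midpoint_unassigned(self):
        rm, track, table, sheet = self.build(0.775, (0, 0))
        [a] = assign_unknowns(rm, track, table, sheet)
        assert a.assigned_sex == "unassigned"

    def test_disagreeing_axes_never_assign(self):
        # female-like ratio but male-like mapping signal
        rm, track, table, sheet = self.build(0.70, (300, 300))
        [a] = assign_unknowns(rm, track, table, sheet)
        assert a.assigned_sex == "unassigned"
        assert not a.axes_agree

    def test_ratio_only_fallback_flagged(self):
        rm, track, table, sheet = self.build(0.70, (0, 0))
        [a] = assign_unknowns(rm, None, table, sheet)
        assert a.assigned_sex == "female"
        assert a.fallback_ratio_only

    def test_recovers_planted_unknown_sexes(self, xy_sim, xy_report):
        truth = xy_sim.truth.true_sex
        assert len(xy_report.assignments) == 8
        for a in xy_report.assignments:
            assert a["assigned_sex"] == truth[a["sample_id"]]


class TestCallSystem:
    def evidence(self, direction="female_lower", t=-10.0):
        from covsex.sex_inference import CandidateEvidence
        from covsex.stat_tests import WelchResult

        w = WelchResult(t, 10.0, 1e-8, 7, 20, 0.7, 0.85)
        return CandidateEvidence("chr12", w, 1e-7, direction, -0.15,
                                 modes_female=[0.0, 1.0],
                                 modes_male=[0.5, 1.0])

    def test_xy_pattern(self):
        het = welch_t([10, 11, 12], [30, 31, 32])  # males elevated
        call = call_system(self.evidence(), het=het, het_n_sites=100)
        assert call.verdict == "XY"
        assert call.heterogametic_sex == "male"
        assert call.axes["modes"]["status"] == "agree"
        assert call.axes["het"]["status"] == "agree"

    def test_mirrored_pattern_is_zw(self):
        ev = self.evidence(direction="male_lower", t=10.0)
        ev.modes_female, ev.modes_male = ev.modes_male, ev.modes_female
        het = welch_t([30, 31, 32], [10, 11, 12])  # females elevated
        call = call_system(ev, het=het, het_n_sites=100)
        assert call.verdict == "ZW"
        assert call.heterogametic_sex == "female"

    def test_no_candidate_undetermined(self):
        call = call_system(None)
        assert call.verdict == "undetermined"
        assert call.reason == "no_candidate"

    def test_contradicting_het_withholds_verdict(self):
        het = welch_t([30, 31, 32], [10, 11, 12])  # females elevated: anti-XY
        call = call_system(self.evidence(), het=het, het_n_sites=100)
        assert call.verdict == "undetermined"
        assert call.reason == "het_contradicts_coverage"

    def test_few_het_sites_skips_axis(self):
        het = welch_t([30, 31, 32], [10, 11, 12])
        call = call_system(self.evidence(), het=het, het_n_sites=10)
        assert call.verdict == "XY"
        assert call.axes["het"]["status"] == "skipped"


def test_label_swap_symmetry(xy_sim):
    """Swapping male/female labels maps the verdict XY -> ZW with identical
    |t| statistics."""
    from covsex import analyze_cohort

    swapped = xy_sim.sheet.relabelled({"male": "female", "female": "male"})
    rep_xy = analyze_cohort(xy_sim.summary, xy_sim.sheet, xy_sim.windows)
    rep_zw = analyze_cohort(xy_sim.summary, swapped, xy_sim.windows)
    assert rep_xy.verdict == "XY"
    assert rep_zw.verdict == "ZW"
    t_xy = {ev["chromosome"]: ev["welch"]["t"] for ev in rep_xy.chromosome_scan}
    t_zw = {ev["chromosome"]: ev["welch"]["t"] for ev in rep_zw.chromosome_scan}
    for chrom in t_xy:
        assert abs(t_xy[chrom]) == pytest.approx(abs(t_zw[chrom]), abs=1e-9)


def test_null_simulations_rarely_yield_candidates():
    hits = 0
    for seed in range(20):
        sim = simulate_cohort(SimConfig(sex_system="none", seed=300 + seed,
                                        per_base_track=False, genotypes=False))
        rm = coverage_ratio_matrix(sim.summary, sim.sheet)
        hits += bool(detect_candidates(rm, sim.sheet))
    assert hits <= 2
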