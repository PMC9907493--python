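"""Sex-linked chromosome detection, region segmentation, unknown-sex
assignment and the XY/ZW system call.

The evidentiary hierarchy follows the differential-coverage logic: the
male/female coverage contrast on a chromosome is the primary axis; density
modes of normalized per-base coverage and the heterozygosity contrast only
corroborate (they can withhold a verdict but never create one on their own).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .coverage_stats import CoverageRatioMatrix, WindowSexMeans
from .io_formats import SampleSheet, WindowCountTable
from .stat_tests import WelchResult, bonferroni, welch_t

logger = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    """All inference thresholds in one block (echoed into reports)."""

    alpha: float = 0.05                  # family-wise, Bonferroni across chromosomes
    min_effect: float = 0.05             # minimum |mean ratio difference|
    zero_fraction_threshold: float = 0.05  # "near zero" = <= this x the other sex
    min_signal_frac: float = 0.10        # vs chromosome-wide mean of the present sex
    shared_delta: float = 0.20           # shared band on the f/m normalized ratio
    assign_margin: float = 0.10          # fraction of between-cluster distance
    min_het_sites: int = 50              # het axis needs this many filtered sites
    mode_tolerance: float = 0.15         # matching dosage modes to {0, 0.5, 1}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CandidateEvidence:
    """Per-chromosome coverage contrast evidence."""

    chromosome: str
    welch: WelchResult
    p_adj: float
    direction: str  # female_lower | male_lower | none
    mean_diff: float  # mean female ratio - mean male ratio
    modes_female: list[float] = field(default_factory=list)
    modes_male: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "welch": self.welch.to_dict(),
            "p_adj": self.p_adj,
            "direction": self.direction,
            "mean_diff": self.mean_diff,
            "modes_female": self.modes_female,
            "modes_male": self.modes_male,
        }


def chromosome_scan(ratios: CoverageRatioMatrix, sheet: SampleSheet
                    ) -> list[CandidateEvidence]:
    """Welch's t (females vs males) on coverage ratios for every chromosome,
    Bonferroni-adjusted across chromosomes."""
    females = [s for s in sheet.females if s in ratios.ratios.index]
    males = [s for s in sheet.males if s in ratios.ratios.index]
    if len(females) < 2 or len(males) < 2:
        raise ValueError("need at least 2 known samples of each sex")
    results = []
    for chrom in ratios.ratios.columns:
        f_vals = ratios.ratios.loc[females, chrom].to_numpy()
        m_vals = ratios.ratios.loc[males, chrom].to_numpy()
        results.append((chrom, welch_t(f_vals, m_vals)))
    p_adj = bonferroni([w.p for _, w in results])
    scan = []
    for (chrom, w), pa in zip(results, p_adj):
        diff = w.mean1 - w.mean2
        if w.t < 0:
            direction = "female_lower"
        elif w.t > 0:
            direction = "male_lower"
        else:
            direction = "none"
        scan.append(CandidateEvidence(chrom, w, float(pa), direction, float(diff)))
    return scan


def detect_candidates(
    ratios: CoverageRatioMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    min_effect: float = 0.05,
) -> list[CandidateEvidence]:
    """Chromosomes whose male/female ratio contrast is both significant
    (Bonferroni-adjusted p < alpha) and material (|mean diff| >= min_effect),
    sorted by adjusted p then |effect|."""
    scan = chromosome_scan(ratios, sheet)
    candidates = [
        ev for ev in scan
        if ev.p_adj < alpha and abs(ev.mean_diff) >= min_effect
        and ev.direction != "none"
    ]
    candidates.sort(key=lambda ev: (ev.p_adj, -abs(ev.mean_diff)))
    return candidates


# ---------------------------------------------------------------------------
# window segmentation
# ---------------------------------------------------------------------------

SEX_SPECIFIC = "sex_specific"
SHARED = "shared"
AMBIGUOUS = "ambiguous"


@dataclass
class RegionLabelTrack:
    """Per-window region labels on the candidate chromosome."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    labels: list[str]           # sex_specific | shared | ambiguous
    lacking: list[str | None]   # the sex lacking coverage, for sex_specific

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    def sex_specific_windows(self, lacking: str | None = None
                             ) -> list[tuple[int, int]]:
        return [
            (int(s), int(e))
            for s, e, lab, lk in zip(self.starts, self.ends, self.labels,
                                     self.lacking)
            if lab == SEX_SPECIFIC and (lacking is None or lk == lacking)
        ]

    def shared_windows(self) -> list[tuple[int, int]]:
        return [
            (int(s), int(e))
            for s, e, lab in zip(self.starts, self.ends, self.labels)
            if lab == SHARED
        ]

    def to_records(self) -> list[dict]:
        return [
            {"chromosome": self.chromosome, "start": int(s), "end": int(e),
             "label": lab, "lacking": lk}
            for s, e, lab, lk in zip(self.starts, self.ends, self.labels,
                                     self.lacking)
        ]


def segment_windows(wsm: WindowSexMeans,
                    config: InferenceConfig | None = None) -> RegionLabelTrack:
    """Label each window sex-specific / shared / ambiguous.

    A window is sex-specific (lacking sex X) when X's mean is at most
    ``zero_fraction_threshold`` times the other sex's mean and the other
    sex's mean is at least ``min_signal_frac`` of its chromosome-wide mean;
    shared when the depth-normalized female/male ratio lies within
    1 +- ``shared_delta``; otherwise ambiguous.
    """
    config = config or InferenceConfig()
    m = wsm.male_norm if wsm.male_norm is not None else wsm.male_mean
    f = wsm.female_norm if wsm.female_norm is not None else wsm.female_mean
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    m_chrom, f_chrom = m.mean(), f.mean()
    if m_chrom == 0 and f_chrom == 0:
        logger.warning("%s: no coverage in either sex; all windows ambiguous",
                       wsm.chromosome)
        n = wsm.n_windows
        return RegionLabelTrack(wsm.chromosome, wsm.starts.copy(),
                                wsm.ends.copy(), [AMBIGUOUS] * n, [None] * n)
    zft = config.zero_fraction_threshold
    labels: list[str] = []
    lacking: list[str | None] = []
    for mi, fi in zip(m, f):
        if fi <= zft * mi and mi >= config.min_signal_frac * m_chrom and mi > 0:
            labels.append(SEX_SPECIFIC)
            lacking.append("female")
        elif mi <= zft * fi and fi >= config.min_signal_frac * f_chrom and fi > 0:
            labels.append(SEX_SPECIFIC)
            lacking.append("male")
        elif mi > 0 and (1 - config.shared_delta) <= fi / mi <= (1 + config.shared_delta):
            labels.append(SHARED)
            lacking.append(None)
        else:
            labels.append(AMBIGUOUS)
            lacking.append(None)
    return RegionLabelTrack(wsm.chromosome, wsm.starts.copy(), wsm.ends.copy(),
                            labels, lacking)


# ---------------------------------------------------------------------------
# unknown-sex assignment
# ---------------------------------------------------------------------------

@dataclass
class SexAssignment:
    sample_id: str
    assigned_sex: str  # male | female | unassigned
    ratio: float
    cluster_female: float
    cluster_male: float
    zero_fraction: float | None  # fraction of sex-specific windows near zero
    axes_agree: bool
    fallback_ratio_only: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def assign_unknowns(
    ratios: CoverageRatioMatrix,
    track: RegionLabelTrack | None,
    window_table: WindowCountTable,
    sheet: SampleSheet,
    config: InferenceConfig | None = None,
) -> list[SexAssignment]:
    """Assign unknown-sex individuals from two evidence axes.

    Axis (i): the sample's candidate-chromosome coverage ratio versus the
    known-sex cluster means — assign to the nearest cluster, but only when
    the ratio sits more than ``assign_margin`` x the between-cluster distance
    away from the midpoint. Axis (ii): the fraction of sex-specific windows
    where the sample has near-zero depth-normalized coverage (the "mapping
    signal"); known members of the lacking sex sit near 1, the other sex
    near 0. A sample is assigned only when both axes agree; with no
    sex-specific windows the ratio axis alone is used, flagged.
    """
    config = config or InferenceConfig()
    chrom = window_table.chromosome
    females = [s for s in sheet.females if s in ratios.ratios.index]
    males = [s for s in sheet.males if s in ratios.ratios.index]
    if not females or not males:
        raise ValueError("need at least one known sample of each sex")
    c_f = float(ratios.ratios.loc[females, chrom].mean())
    c_m = float(ratios.ratios.loc[males, chrom].mean())
    midpoint = (c_f + c_m) / 2
    spread = abs(c_f - c_m)

    ss_windows = track.sex_specific_windows() if track is not None else []
    lacking_sexes = {lk for lk in (track.lacking if track else []) if lk}
    lacking_sex = lacking_sexes.pop() if len(lacking_sexes) == 1 else None
    use_zero_axis = bool(ss_windows) and lacking_sex is not None
    if not use_zero_axis:
        logger.warning("no sex-specific windows; assigning on coverage ratio only")

    present_sex = "male" if lacking_sex == "female" else "female"
    zero_ref = None
    win_index = {(int(s), int(e)): i
                 for i, (s, e) in enumerate(zip(window_table.starts,
                                                window_table.ends))}
    if use_zero_axis:
        ss_idx = [win_index[w] for w in ss_windows if w in win_index]
        present_ids = sheet.by_sex(present_sex)
        ref_rows = []
        for s in present_ids:
            if s in ratios.genome_means.index and s in window_table.sample_ids:
                col = window_table.sample_column(s).astype(float)
                ref_rows.append(col[ss_idx] / float(ratios.genome_means[s]))
        zero_ref = np.mean(ref_rows, axis=0) if ref_rows else None
        use_zero_axis = zero_ref is not None

    out = []
    for sample in sheet.unknowns:
        if sample not in ratios.ratios.index:
            continue
        r = float(ratios.ratios.loc[sample, chrom])
        near_f = abs(r - c_f) < abs(r - c_m)
        clear = abs(r - midpoint) > config.assign_margin * spread
        axis1 = ("female" if near_f else "male") if clear else None

        zero_frac = None
        axis2 = None
        if use_zero_axis and sample in window_table.sample_ids:
            col = window_table.sample_column(sample).astype(float)
            g = float(ratios.genome_means.get(sample, np.nan))
            if np.isfinite(g) and g > 0:
                vals = col[ss_idx] / g
                near_zero = vals <= config.zero_fraction_threshold * zero_ref
                zero_frac = float(near_zero.mean())
                if zero_frac > 0.5:
                    axis2 = lacking_sex
                elif zero_frac < 0.5:
                    axis2 = present_sex

        if axis1 is None:
            assigned, agree = "unassigned", axis2 is not None
        elif not use_zero_axis:
            assigned, agree = axis1, True
        elif axis2 is None or axis2 != axis1:
            assigned, agree = "unassigned", False
        else:
            assigned, agree = axis1, True
        out.append(SexAssignment(
            sample, assigned, r, c_f, c_m, zero_frac, agree,
            fallback_ratio_only=not use_zero_axis,
        ))
    return out


# ---------------------------------------------------------------------------
# the system call
# ---------------------------------------------------------------------------

@dataclass
class SexSystemCall:
    verdict: str  # XY | ZW | undetermined
    candidate_chromosome: str | None
    heterogametic_sex: str | None
    reason: str | None
    axes: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _modes_match(modes: list[float], targets: list[float], tol: float) -> bool:
    return all(any(abs(m - t) <= tol for m in modes) for t in targets)


def call_system(
    evidence: CandidateEvidence | None,
    track: RegionLabelTrack | None = None,
    het: WelchResult | None = None,
    het_n_sites: int = 0,
    config: InferenceConfig | None = None,
) -> SexSystemCall:
    """Combine the evidence axes into an XY / ZW / undetermined verdict.

    The coverage direction decides the putative system: reduced female
    coverage on the candidate (the reference carrying Y-specific sequence)
    means XY; the mirror means ZW. Density modes (heterogametic sex near
    {0.5, 1}, homogametic near {0, 1}) and a heterogametic-elevated
    heterozygosity contrast corroborate; an actively contradicting
    corroboration axis withholds the verdict.
    """
    config = config or InferenceConfig()
    axes: dict = {}
    if evidence is None:
        return SexSystemCall("undetermined", None, None, "no_candidate", axes)
    if evidence.direction == "none":
        return SexSystemCall("undetermined", evidence.chromosome, None,
                             "no_coverage_direction", axes)
    putative = "XY" if evidence.direction == "female_lower" else "ZW"
    het_sex = "male" if putative == "XY" else "female"
    hom_sex = "female" if putative == "XY" else "male"
    axes["coverage"] = {
        "status": "primary", "direction": evidence.direction,
        "t": evidence.welch.t, "p_adj": evidence.p_adj,
    }

    # density-mode corroboration
    mode_sets = {"male": evidence.modes_male, "female": evidence.modes_female}
    if mode_sets["male"] and mode_sets["female"]:
        tol = config.mode_tolerance
        ok = (_modes_match(mode_sets[het_sex], [0.5, 1.0], tol)
              and _modes_match(mode_sets[hom_sex], [0.0, 1.0], tol))
        axes["modes"] = {"status": "agree" if ok else "neutral",
                         "male": mode_sets["male"], "female": mode_sets["female"]}
    else:
        axes["modes"] = {"status": "skipped"}

    # heterozygosity corroboration (t is females - males)
    contradiction = None
    if het is not None and het_n_sites >= config.min_het_sites:
        het_higher_in = "female" if het.t > 0 else ("male" if het.t < 0 else None)
        if het_higher_in == het_sex:
            status = "agree"
        elif het_higher_in is None or het.p >= config.alpha:
            status = "neutral"
        else:
            status = "contradict"
            contradiction = "het_contradicts_coverage"
        axes["het"] = {"status": status, "t": het.t, "p": het.p,
                       "n_sites": het_n_sites}
    else:
        axes["het"] = {"status": "skipped",
                       "n_sites": het_n_sites if het is not None else 0}

    if contradiction:
        return SexSystemCall("undetermined", evidence.chromosome, None,
                             contradiction, axes)
    return SexSystemCall(putative, evidence.chromosome, het_sex, None, axes)
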