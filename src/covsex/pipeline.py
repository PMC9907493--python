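"""End-to-end orchestration: coverage ratios -> candidate detection ->
window segmentation -> unknown sexing -> heterozygosity contrast -> verdict.

`analyze_cohort` is the in-memory core; `run_pipeline` wraps it with file
I/O so that the result of one full run equals composing the standalone
subcommands on the same inputs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import yaml

from . import __version__
from .coverage_stats import (
    ChromCoverageSummary,
    CoverageRatioMatrix,
    coverage_ratio_matrix,
    density_modes,
    read_coverage_summary,
    sex_mean_normalized_depth,
    window_sex_means,
)
from .io_formats import (
    GenotypeMatrix,
    PerBaseDepthTrack,
    SampleSheet,
    SexReport,
    WindowCountTable,
    read_depth_track,
    read_sample_sheet,
    read_vcf_genotypes,
    read_window_counts,
    write_report,
)
from .sex_inference import (
    CandidateEvidence,
    InferenceConfig,
    assign_unknowns,
    call_system,
    detect_candidates,
    segment_windows,
)
from .stat_tests import HetFilterParams, filter_genotypes, het_counts, welch_t

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File locations plus every tunable threshold, echoed into the report."""

    sample_sheet: str
    coverage_summary: str
    window_counts: str | None = None
    depth_track: str | None = None
    vcf: str | None = None
    vcf_region: str | None = None
    output_dir: str = "covsex_out"
    window_size: int = 150_000
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    het_filters: HetFilterParams = field(default_factory=HetFilterParams)
    all_candidates: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inf = InferenceConfig(**raw.pop("inference", {}))
        het = HetFilterParams(**raw.pop("het_filters", {}))
        return cls(inference=inf, het_filters=het, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def validate(self) -> None:
        for name in ("sample_sheet", "coverage_summary", "window_counts",
                     "depth_track", "vcf"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path} does not exist")


def analyze_cohort(
    summary: ChromCoverageSummary,
    sheet: SampleSheet,
    window_table: WindowCountTable | None = None,
    track: PerBaseDepthTrack | None = None,
    genotypes: GenotypeMatrix | None = None,
    inference: InferenceConfig | None = None,
    het_filters: HetFilterParams | None = None,
    config_echo: dict | None = None,
) -> SexReport:
    """Run the full differential-coverage analysis on in-memory inputs."""
    inference = inference or InferenceConfig()
    het_filters = het_filters or HetFilterParams()
    report = SexReport()
    report.config = dict(config_echo or {},
                         inference=inference.to_dict(),
                         het_filters=asdict(het_filters),
                         covsex_version=__version__)

    # stage 1: coverage ratios and candidate chromosomes
    ratios = coverage_ratio_matrix(summary, sheet)
    from .sex_inference import chromosome_scan
    scan = chromosome_scan(ratios, sheet)
    report.chromosome_scan = [ev.to_dict() for ev in scan]
    candidates = detect_candidates(ratios, sheet, inference.alpha,
                                   inference.min_effect)
    report.stage_counts["chromosomes_tested"] = len(scan)
    report.stage_counts["candidates"] = len(candidates)
    if not candidates:
        call = call_system(None, config=inference)
        report.verdict, report.reason = call.verdict, call.reason
        report.axes = call.axes
        return report
    top = candidates[0]
    report.candidate_chromosome = top.chromosome

    # stage 2: window segmentation on the top candidate
    seg = None
    if window_table is not None and window_table.chromosome == top.chromosome:
        wsm = window_sex_means(window_table, sheet, ratios.genome_means)
        seg = segment_windows(wsm, inference)
        report.window_labels = seg.to_records()
        report.stage_counts["windows"] = seg.n_windows
        report.stage_counts["sex_specific_windows"] = len(
            seg.sex_specific_windows())
    elif window_table is not None:
        logger.warning("window table is for %s, candidate is %s; skipping "
                       "segmentation", window_table.chromosome, top.chromosome)

    # stage 3: unknown-sex assignment
    if window_table is not None and sheet.unknowns:
        assignments = assign_unknowns(ratios, seg, window_table, sheet,
                                      inference)
        report.assignments = [a.to_dict() for a in assignments]

    # stage 4: density modes of sex-averaged normalized per-base coverage
    if track is not None and track.chromosome == top.chromosome:
        length = track.chrom_length or int(track.positions.max())
        for sex in ("female", "male"):
            vals = sex_mean_normalized_depth(track, sheet, ratios.genome_means,
                                             sex, length)
            nd = density_modes(vals)
            if sex == "female":
                top.modes_female = nd.mode_locations
            else:
                top.modes_male = nd.mode_locations
        report.density_modes = {"female": top.modes_female,
                                "male": top.modes_male}

    # stage 5: heterozygosity contrast in shared regions
    het_result = None
    het_n_sites = 0
    if genotypes is not None and seg is not None and seg.shared_windows():
        filtered = filter_genotypes(genotypes, het_filters)
        report.stage_counts["het_filter_drops"] = filtered.drops
        shared = seg.shared_windows()
        hc = het_counts(filtered.matrix, shared)
        het_n_sites = hc.n_sites_evaluated
        females = sheet.females
        males = sheet.males
        if len(females) >= 2 and len(males) >= 2 and het_n_sites > 0:
            het_result = welch_t([hc.counts[s] for s in females],
                                 [hc.counts[s] for s in males])
            report.het_contrast = {
                "welch": het_result.to_dict(),
                "n_sites": het_n_sites,
                "counts": hc.counts,
                "rates": hc.rates,
            }

    call = call_system(top, seg, het_result, het_n_sites, inference)
    report.verdict = call.verdict
    report.reason = call.reason
    report.heterogametic_sex = call.heterogametic_sex
    report.axes = call.axes
    report.chromosome_scan = [ev.to_dict() for ev in scan]  # modes now filled
    return report


def run_pipeline(config: PipelineConfig) -> SexReport:
    """File-based end-to-end run; writes report.json plus stage tables."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    sheet = read_sample_sheet(config.sample_sheet)
    summary = read_coverage_summary(config.coverage_summary)
    window_table = None
    if config.window_counts:
        window_table = read_window_counts(config.window_counts,
                                          sheet.sample_ids,
                                          window_size=None)
    track = None
    if config.depth_track:
        track = read_depth_track(config.depth_track, sheet.sample_ids)
        chrom = track.chromosome
        track.chrom_length = summary.lengths.get(chrom, None)
    genotypes = None
    if config.vcf:
        genotypes = read_vcf_genotypes(config.vcf, config.vcf_region)
    try:
        report = analyze_cohort(
            summary, sheet, window_table, track, genotypes,
            config.inference, config.het_filters,
            config_echo={"pipeline": config.to_dict()},
        )
    except Exception:
        marker = os.path.join(config.output_dir, "FAILED")
        with open(marker, "w") as fh:
            fh.write("pipeline run failed; see logs\n")
        raise
    write_report(report, os.path.join(config.output_dir, "report.json"), "json")
    if report.window_labels:
        write_report(report, os.path.join(config.output_dir, "regions.tsv"),
                     "tsv")
    _write_stage_tables(report, config.output_dir)
    return report


def _write_stage_tables(report: SexReport, outdir: str) -> None:
    import pandas as pd

    if report.chromosome_scan:
        rows = [
            {"chromosome": ev["chromosome"], "t": ev["welch"]["t"],
             "p": ev["welch"]["p"], "p_adj": ev["p_adj"],
             "mean_diff": ev["mean_diff"], "direction": ev["direction"]}
            for ev in report.chromosome_scan
        ]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "chromosome_scan.tsv"),
                                  sep="\t", index=False)
    if report.assignments:
        pd.DataFrame(report.assignments).to_csv(
            os.path.join(outdir, "assignments.tsv"), sep="\t", index=False)
    if report.het_contrast:
        rows = [{"sample_id": s, "het_count": c,
                 "het_rate": report.het_contrast["rates"][s]}
                for s, c in report.het_contrast["counts"].items()]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "het.tsv"),
                                  sep="\t", index=False)
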