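#!/usr/bin/env python
"""Per-chromosome coverage ratios and the male/female contrast scan.

Reads the cohort written by 01_simulate_cohort.py, computes each sample's
ratio of per-chromosome depth to genome-wide depth, runs Welch's t
(females vs males) on every chromosome with Bonferroni correction, and
writes results/ratios.tsv, results/chromosome_scan.tsv and a ratio figure.
"""

import os
import sys

import pandas as pd

from covsex.coverage_stats import coverage_ratio_matrix, read_coverage_summary
from covsex.io_formats import read_sample_sheet
from covsex.plotting import plot_coverage_ratios
from covsex.sex_inference import chromosome_scan, detect_candidates


def main() -> None:
    sheet = read_sample_sheet("results/cohort/samples.tsv")
    summary = read_coverage_summary("results/cohort/coverage_summary.tsv")
    ratios = coverage_ratio_matrix(summary, sheet)
    ratios.ratios.rename_axis("sample_id").to_csv(
        "results/ratios.tsv", sep="\t", float_format="%.6g")

    scan = chromosome_scan(ratios, sheet)
    pd.DataFrame([
        {"chromosome": ev.chromosome, "t": ev.welch.t, "p": ev.welch.p,
         "p_adj": ev.p_adj, "mean_diff": ev.mean_diff,
         "direction": ev.direction}
        for ev in scan
    ]).to_csv("results/chromosome_scan.tsv", sep="\t", index=False,
              float_format="%.6g")

    candidates = detect_candidates(ratios, sheet)
    print(f"tested {len(scan)} chromosomes; "
          f"{len(candidates)} candidate(s) pass alpha=0.05 + effect filter")
    for ev in candidates:
        print(f"  {ev.chromosome}: Welch t = {ev.welch.t:.1f}, "
              f"adjusted p = {ev.p_adj:.3g}, "
              f"mean ratio difference (F-M) = {ev.mean_diff:.3f}")

    os.makedirs("results/figures", exist_ok=True)
    plot_coverage_ratios(ratios, sheet, "results/figures/coverage_ratios.png")
    print("wrote results/ratios.tsv, results/chromosome_scan.tsv, "
          "results/figures/coverage_ratios.png")


if __name__ == "__main__":
    sys.exit(main())
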