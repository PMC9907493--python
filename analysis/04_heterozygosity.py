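#!/usr/bin/env python
"""Heterozygosity contrast between sexes in shared regions.

Filters the cohort VCF with the standard site/genotype rules (per-genotype
depth 1-50, site presence >= 95%), counts heterozygous sites per individual
inside the shared (present-in-both-sexes) windows from 03_segment_and_sex.py,
and tests the female-male difference with Welch's t. Writes results/het.tsv
and the per-sex het figure.
"""

import os
import sys

import pandas as pd

from covsex.io_formats import read_sample_sheet, read_vcf_genotypes
from covsex.plotting import plot_het_counts
from covsex.stat_tests import filter_genotypes, het_counts, welch_t


def main() -> None:
    sheet = read_sample_sheet("results/cohort/samples.tsv")
    gm = read_vcf_genotypes("results/cohort/variants.vcf")
    filtered = filter_genotypes(gm)
    print(f"{gm.n_sites} sites in VCF; filter drops: {filtered.drops}; "
          f"{filtered.matrix.n_sites} sites retained")

    shared = []
    with open("results/regions.bed") as fh:
        for line in fh:
            chrom, start, end, label = line.split()
            if label == "shared":
                shared.append((int(start), int(end)))
    hc = het_counts(filtered.matrix, shared)
    pd.DataFrame([
        {"sample_id": s, "sex": sheet.sex_of(s), "het_count": c,
         "het_rate": hc.rates[s]}
        for s, c in hc.counts.items()
    ]).to_csv("results/het.tsv", sep="\t", index=False, float_format="%.4g")

    res = welch_t([hc.counts[s] for s in sheet.females],
                  [hc.counts[s] for s in sheet.males])
    print(f"{hc.n_sites_evaluated} filtered sites in shared regions")
    print(f"mean het sites: females {res.mean1:.1f}, males {res.mean2:.1f}")
    print(f"Welch's t (females - males) = {res.t:.2f}, p = {res.p:.3g}")

    os.makedirs("results/figures", exist_ok=True)
    plot_het_counts(hc.counts, sheet, "results/figures/het_counts.png")
    print("wrote results/het.tsv, results/figures/het_counts.png")


if __name__ == "__main__":
    sys.exit(main())
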