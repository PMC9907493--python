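"""Figure writers mirroring the standard differential-coverage panels:
per-chromosome ratio bars, windowed per-sex alignment means, normalized
per-base coverage densities, and the heterozygosity contrast."""

from __future__ import annotations

import numpy as np

from .coverage_stats import CoverageRatioMatrix, NormalizedDensity, WindowSexMeans
from .io_formats import SampleSheet

SEX_COLORS = {"male": "#1f77b4", "female": "#d62728", "unknown": "#999999"}


def _ax(figsize=(7, 3)):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_coverage_ratios(ratios: CoverageRatioMatrix, sheet: SampleSheet,
                         path: str, chromosomes: list[str] | None = None) -> None:
    """Bar panel: per-sample ratio of chromosome depth to genome-wide depth."""
    fig, ax = _ax((10, 3))
    chroms = chromosomes or list(ratios.ratios.columns)
    samples = [s for s in sheet.sample_ids if s in ratios.ratios.index]
    n_s = len(samples)
    width = 0.9 / n_s
    for k, s in enumerate(samples):
        x = np.arange(len(chroms)) + k * width
        ax.bar(x, ratios.ratios.loc[s, chroms], width=width,
               color=SEX_COLORS[sheet.sex_of(s)])
    ax.set_xticks(np.arange(len(chroms)) + 0.45)
    ax.set_xticklabels(chroms, rotation=90, fontsize=7)
    ax.axhline(1.0, color="k", lw=0.5, ls="--")
    ax.set_ylabel("depth ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_window_means(wsm: WindowSexMeans, path: str,
                      y_cap: float = 15_000) -> None:
    """Per-sex mean alignment counts along the chromosome (y capped)."""
    fig, ax = _ax()
    mid = (wsm.starts + wsm.ends) / 2
    ax.plot(mid, np.minimum(wsm.male_mean, y_cap), color=SEX_COLORS["male"],
            label="males")
    ax.plot(mid, np.minimum(wsm.female_mean, y_cap), color=SEX_COLORS["female"],
            label="females")
    ax.set_ylim(0, y_cap)
    ax.set_xlabel(f"position on {wsm.chromosome} (bp)")
    ax.set_ylabel("mean alignments / window")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_density(densities: dict[str, NormalizedDensity], path: str,
                 cap: float = 2.0) -> None:
    """Normalized per-base coverage densities per sex (x and y capped)."""
    fig, ax = _ax()
    for sex, nd in densities.items():
        ax.plot(nd.x, nd.density, color=SEX_COLORS[sex], label=f"{sex}s")
        for loc, height in nd.modes:
            ax.plot([loc], [min(height, cap)], "v", color=SEX_COLORS[sex])
    ax.set_xlim(0, cap)
    ax.set_ylim(0, cap * 4)
    ax.set_xlabel("normalized per-base coverage")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_het_counts(counts: dict[str, int], sheet: SampleSheet, path: str) -> None:
    """Per-individual heterozygous-site counts, grouped by sex."""
    fig, ax = _ax((4, 3))
    for i, sex in enumerate(("male", "female")):
        vals = [counts[s] for s in sheet.by_sex(sex) if s in counts]
        x = np.full(len(vals), i) + np.linspace(-0.15, 0.15, max(len(vals), 1))
        ax.plot(x, vals, "o", color=SEX_COLORS[sex])
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["males", "females"])
    ax.set_ylabel("heterozygous sites")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
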