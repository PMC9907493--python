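"""Normalized coverage statistics.

Everything here works in units of the *genome-wide mean depth* of a sample:
dividing per-chromosome or per-base depth by that mean makes individuals
sequenced to different effort directly comparable and turns copy number into
a dosage signal (diploid ~1, haploid ~0.5, absent ~0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_formats import PerBaseDepthTrack, SampleSheet, WindowCountTable

logger = logging.getLogger(__name__)


@dataclass
class ChromCoverageSummary:
    """Per (sample, chromosome) mean depth plus chromosome lengths.

    ``mean_depth`` is a DataFrame indexed by sample_id with one column per
    chromosome; ``lengths`` maps chromosome -> bp.
    """

    mean_depth: pd.DataFrame
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(self.mean_depth.columns) - set(self.lengths)
        if missing:
            raise ValueError(f"no length for chromosome(s): {sorted(missing)}")
        if (self.mean_depth.values < 0).any():
            raise ValueError("mean depths must be >= 0")
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.mean_depth.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mean_depth.index)


def read_coverage_summary(path) -> ChromCoverageSummary:
    """Read a long-format TSV: sample_id, chromosome, length, mean_depth."""
    df = pd.read_csv(path, sep="\t")
    lengths = (
        df.drop_duplicates("chromosome").set_index("chromosome")["length"].to_dict()
    )
    wide = df.pivot(index="sample_id", columns="chromosome", values="mean_depth")
    # preserve first-appearance chromosome order
    order = list(dict.fromkeys(df["chromosome"]))
    return ChromCoverageSummary(wide[order], {c: int(lengths[c]) for c in order})


def write_coverage_summary(summary: ChromCoverageSummary, path) -> None:
    rows = []
    for sample in summary.sample_ids:
        for chrom in summary.chromosomes:
            rows.append(
                (sample, chrom, summary.lengths[chrom],
                 summary.mean_depth.at[sample, chrom])
            )
    pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "length", "mean_depth"]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def genome_wide_mean_depth(
    summary: ChromCoverageSummary, sample_id: str, exclude: set[str] | None = None
) -> float:
    """Chromosome-length-weighted mean depth for one sample.

    ``exclude`` optionally removes chromosomes (e.g. a sex-linked candidate)
    from the average; by default the whole genome is used.
    """
    chroms = [c for c in summary.chromosomes if not (exclude and c in exclude)]
    lengths = np.array([summary.lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("zero total chromosome length")
    means = summary.mean_depth.loc[sample_id, chroms].to_numpy(dtype=float)
    return float((means * lengths).sum() / total)


@dataclass
class CoverageRatioMatrix:
    """Per-sample per-chromosome depth ratios relative to the genome-wide mean."""

    ratios: pd.DataFrame  # samples x chromosomes
    genome_means: pd.Series  # per sample, the normalizer actually used
    excluded_samples: list[str] = field(default_factory=list)


def coverage_ratio_matrix(
    summary: ChromCoverageSummary,
    sheet: SampleSheet | None = None,
    exclude_from_genome_mean: set[str] | None = None,
) -> CoverageRatioMatrix:
    """Chromosome mean depth over genome-wide mean depth, per sample.

    Samples with zero genome-wide depth are excluded with a warning. For a
    complete summary (no exclusions) the length-weighted mean of each
    sample's ratios is exactly 1.
    """
    sample_ids = sheet.sample_ids if sheet is not None else summary.sample_ids
    gmeans, rows, kept, excluded = {}, [], [], []
    for sample in sample_ids:
        g = genome_wide_mean_depth(summary, sample, exclude_from_genome_mean)
        if g <= 0:
            logger.warning("sample %s has zero genome-wide depth; excluded", sample)
            excluded.append(sample)
            continue
        gmeans[sample] = g
        rows.append(summary.mean_depth.loc[sample].to_numpy(dtype=float) / g)
        kept.append(sample)
    ratios = pd.DataFrame(rows, index=kept, columns=summary.chromosomes)
    return CoverageRatioMatrix(ratios, pd.Series(gmeans), excluded)


def normalized_per_base(
    track: PerBaseDepthTrack,
    sample_id: str,
    genome_mean: float,
    chrom_length: int | None = None,
    include_absent: bool = True,
) -> np.ndarray:
    """Per-base depth divided by the sample's genome-wide mean.

    With ``include_absent`` (the default) positions missing from the track are
    included as zeros, which requires the chromosome length.
    """
    if genome_mean <= 0:
        raise ValueError("genome_mean must be positive")
    if include_absent:
        length = chrom_length or track.chrom_length
        if length is None:
            raise ValueError("chromosome length required when include_absent=True")
        depths = np.zeros(length, dtype=float)
        depths[track.positions - 1] = track.sample_column(sample_id)
    else:
        depths = track.sample_column(sample_id).astype(float)
    return depths / genome_mean


def sex_mean_normalized_depth(
    track: PerBaseDepthTrack,
    sheet: SampleSheet,
    genome_means: pd.Series,
    sex: str,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Per-base average, across one sex, of each sample's normalized depth.

    This is the quantity whose density shows the dosage modes: averaging n
    samples raises the effective depth n-fold, so haploid (0.5x) and diploid
    (1x) bases separate even at modest per-sample coverage.
    """
    samples = [s for s in sheet.by_sex(sex) if s in genome_means.index]
    if not samples:
        raise ValueError(f"no {sex} samples with a usable genome-wide mean")
    acc = None
    for s in samples:
        v = normalized_per_base(track, s, float(genome_means[s]), chrom_length)
        acc = v if acc is None else acc + v
    return acc / len(samples)


@dataclass
class NormalizedDensity:
    """Histogram density of normalized coverage plus its detected modes."""

    x: np.ndarray           # bin centers
    density: np.ndarray     # integrates to ~1 over the support
    modes: list[tuple[float, float]]  # (location, height), sorted by location
    support_limit: float
    binwidth: float

    @property
    def mode_locations(self) -> list[float]:
        return [m[0] for m in self.modes]


def density_modes(
    values: np.ndarray,
    support_limit: float = 2.0,
    binwidth: float = 0.02,
    prominence_frac: float = 0.05,
    smooth_sigma_bins: float = 2.0,
) -> NormalizedDensity:
    """Histogram density on [0, support_limit] with local-maximum modes.

    The histogram (binwidth 0.02 by default, support capped at 2 like the
    usual normalized-coverage plots) is lightly smoothed with a fixed
    Gaussian kernel before peak finding, so that the discreteness of
    integer-depth data does not fragment a dosage mode into several bins.
    Modes are local maxima with prominence >= ``prominence_frac`` of the
    global maximum, sorted by location; ties break toward smaller location.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if np.any(values < 0):
        raise ValueError("normalized coverage must be >= 0")
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    capped = values[values <= support_limit]
    if capped.size == 0:
        raise ValueError("no values within the support limit")
    n_bins = int(np.ceil(support_limit / binwidth))
    edges = np.arange(n_bins + 1) * binwidth
    counts, _ = np.histogram(capped, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), smooth_sigma_bins,
                                 mode="nearest")
    density = smoothed / (smoothed.sum() * binwidth)
    # pad so maxima at the support edges (e.g. the zero-coverage spike) count
    padded = np.concatenate(([-1.0], density, [-1.0]))
    threshold = prominence_frac * density.max()
    peaks, _ = find_peaks(padded, prominence=threshold)
    centers = (edges[:-1] + edges[1:]) / 2
    modes = sorted((float(centers[p - 1]), float(density[p - 1])) for p in peaks)
    return NormalizedDensity(centers, density, modes, support_limit, binwidth)


@dataclass
class WindowSexMeans:
    """Per-window mean alignment counts for males and females.

    ``male_mean``/``female_mean`` are raw multicov-style count averages (as
    plotted in coverage scans); the ``*_norm`` variants divide each sample's
    count by its genome-wide mean depth and the window width, which removes
    sequencing-effort and tail-window artifacts before ratio comparisons.
    """

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    male_mean: np.ndarray
    female_mean: np.ndarray
    male_norm: np.ndarray | None = None
    female_norm: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def window_sex_means(
    table: WindowCountTable,
    sheet: SampleSheet,
    genome_means: pd.Series | None = None,
) -> WindowSexMeans:
    """Arithmetic mean of per-window counts within each known sex.

    Unknown-sex samples never contribute. Raises if either sex has no known
    samples in the table.
    """
    def _cols(sex: str) -> list[int]:
        idx = [table.sample_ids.index(s) for s in sheet.by_sex(sex)
               if s in table.sample_ids]
        if not idx:
            raise ValueError(f"no known {sex} samples in window table")
        return idx

    m_idx, f_idx = _cols("male"), _cols("female")
    counts = table.counts.astype(float)
    male_mean = counts[:, m_idx].mean(axis=1)
    female_mean = counts[:, f_idx].mean(axis=1)
    male_norm = female_norm = None
    if genome_means is not None:
        widths = table.widths.astype(float)
        def _norm(idx: list[int]) -> np.ndarray:
            acc = np.zeros(table.n_windows)
            for i in idx:
                g = float(genome_means[table.sample_ids[i]])
                acc += counts[:, i] / (g * widths)
            return acc / len(idx)
        male_norm = _norm(m_idx)
        female_norm = _norm(f_idx)
    return WindowSexMeans(
        table.chromosome, table.starts.copy(), table.ends.copy(),
        male_mean, female_mean, male_norm, female_norm,
    )
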