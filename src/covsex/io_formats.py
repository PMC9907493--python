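"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions, applied consistently at module boundaries:

* per-base depth tracks (``samtools depth`` dialect) are **1-based**; positions
  absent from a file are interpreted as depth 0 (the default, ``-a``-less,
  behaviour of ``samtools depth``);
* window tables (``bedtools multicov`` dialect) are **0-based half-open** BED
  intervals that tile a chromosome without overlap;
* VCF positions are 1-based, as in the format itself.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_TOKENS = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "u": "unknown",
    "unknown": "unknown",
}

REPORT_SCHEMA_VERSION = 1

# integer genotype codes used throughout
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One individual: identifier, sex label, and (optionally) its mean depth."""

    sample_id: str
    sex_label: str  # 'male' | 'female' | 'unknown'
    genome_wide_depth: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be nonempty")
        if self.sex_label not in ("male", "female", "unknown"):
            raise FormatError(f"invalid sex label {self.sex_label!r}")
        if self.genome_wide_depth is not None and self.genome_wide_depth < 0:
            raise FormatError("genome_wide_depth must be >= 0")


@dataclass
class SampleSheet:
    """Validated cohort description (unique sample ids, known sex vocabulary)."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise FormatError(f"duplicate sample_id(s): {', '.join(dupes)}")
        if not self.records:
            raise FormatError("no samples")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def by_sex(self, sex: str) -> list[str]:
        return [r.sample_id for r in self.records if r.sex_label == sex]

    @property
    def males(self) -> list[str]:
        return self.by_sex("male")

    @property
    def females(self) -> list[str]:
        return self.by_sex("female")

    @property
    def unknowns(self) -> list[str]:
        return self.by_sex("unknown")

    def sex_of(self, sample_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.sex_label
        raise KeyError(sample_id)

    def relabelled(self, mapping: dict[str, str]) -> "SampleSheet":
        """Return a sheet with sex labels permuted (e.g. male<->female)."""
        return SampleSheet(
            [
                SampleRecord(r.sample_id, mapping.get(r.sex_label, r.sex_label),
                             r.genome_wide_depth)
                for r in self.records
            ]
        )


def read_sample_sheet(path: str | os.PathLike | io.TextIOBase) -> SampleSheet:
    """Read a TSV sample sheet with header columns ``sample_id`` and ``sex``.

    Sex tokens M/F/U and male/female/unknown are accepted case-insensitively.
    """
    close = False
    if isinstance(path, io.TextIOBase):
        fh = path
    else:
        fh = open(path)
        close = True
    try:
        header = fh.readline()
        if not header.strip():
            raise FormatError("no samples")
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        try:
            i_id = cols.index("sample_id")
            i_sex = cols.index("sex")
        except ValueError as exc:
            raise FormatError(
                "sample sheet must have 'sample_id' and 'sex' columns"
            ) from exc
        i_depth = cols.index("genome_wide_depth") if "genome_wide_depth" in cols else None
        records = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            token = parts[i_sex].strip().lower()
            if token not in SEX_TOKENS:
                raise FormatError(
                    f"unrecognized sex token {parts[i_sex]!r} on line {ln}"
                )
            depth = None
            if i_depth is not None and len(parts) > i_depth and parts[i_depth].strip():
                depth = float(parts[i_depth])
            records.append(SampleRecord(parts[i_id].strip(), SEX_TOKENS[token], depth))
        if not records:
            raise FormatError("no samples")
        return SampleSheet(records)
    finally:
        if close:
            fh.close()


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\tgenome_wide_depth\n")
        for r in sheet.records:
            d = "" if r.genome_wide_depth is None else f"{r.genome_wide_depth:.6g}"
            fh.write(f"{r.sample_id}\t{r.sex_label}\t{d}\n")


# ---------------------------------------------------------------------------
# per-base depth tracks
# ---------------------------------------------------------------------------

@dataclass
class PerBaseDepthTrack:
    """Per-base read depth on one chromosome for a set of samples.

    ``positions`` are 1-based and strictly increasing; positions not listed
    are depth 0. ``depths`` has shape (n_positions, n_samples).
    """

    chromosome: str
    positions: np.ndarray
    depths: np.ndarray
    sample_ids: list[str]
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depths = np.atleast_2d(np.asarray(self.depths))
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise FormatError(
                f"positions not strictly increasing on {self.chromosome}"
            )
        if np.any(self.depths < 0):
            raise FormatError("negative depth")
        if self.depths.shape != (self.positions.size, len(self.sample_ids)):
            raise FormatError("depth matrix shape inconsistent with positions/samples")

    def dense(self, length: int | None = None) -> np.ndarray:
        """(length, n_samples) depth matrix with absent positions as 0."""
        length = length or self.chrom_length
        if length is None:
            raise ValueError("chromosome length required to densify")
        out = np.zeros((length, len(self.sample_ids)), dtype=self.depths.dtype)
        out[self.positions - 1] = self.depths
        return out

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.depths[:, self.sample_ids.index(sample_id)]


def read_depth_tracks(
    stream: str | os.PathLike | io.TextIOBase, sample_ids: Sequence[str]
) -> dict[str, PerBaseDepthTrack]:
    """Parse a samtools-depth TSV into one track per chromosome.

    Order across chromosomes is free; within a chromosome positions must be
    strictly increasing.
    """
    close = False
    if isinstance(stream, io.TextIOBase):
        fh = stream
    else:
        fh = open(stream)
        close = True
    n = len(sample_ids)
    per_chrom: dict[str, tuple[list[int], list[list[int]]]] = {}
    try:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 + n:
                raise FormatError(
                    f"line {ln}: expected {2 + n} columns, got {len(parts)}"
                )
            chrom, pos = parts[0], int(parts[1])
            depths = [int(x) for x in parts[2:]]
            if any(d < 0 for d in depths):
                raise FormatError(f"line {ln}: negative depth")
            positions, rows = per_chrom.setdefault(chrom, ([], []))
            if positions and pos <= positions[-1]:
                raise FormatError(
                    f"line {ln}: non-monotone position {pos} on {chrom}"
                )
            positions.append(pos)
            rows.append(depths)
    finally:
        if close:
            fh.close()
    return {
        chrom: PerBaseDepthTrack(
            chrom,
            np.array(positions, dtype=np.int64),
            np.array(rows, dtype=np.int32).reshape(len(positions), n),
            list(sample_ids),
        )
        for chrom, (positions, rows) in per_chrom.items()
    }


def read_depth_track(
    stream: str | os.PathLike | io.TextIOBase,
    sample_ids: Sequence[str],
    chromosome: str | None = None,
) -> PerBaseDepthTrack:
    """Single-chromosome convenience wrapper around :func:`read_depth_tracks`."""
    tracks = read_depth_tracks(stream, sample_ids)
    if chromosome is not None:
        if chromosome not in tracks:
            raise FormatError(f"chromosome {chromosome!r} not in depth file")
        return tracks[chromosome]
    if len(tracks) != 1:
        raise FormatError(
            f"depth file contains {len(tracks)} chromosomes; pass chromosome="
        )
    return next(iter(tracks.values()))


def write_depth_track(track: PerBaseDepthTrack, path: str | os.PathLike,
                      omit_zero_rows: bool = True) -> None:
    """Write samtools-depth dialect; all-zero rows omitted by default."""
    with open(path, "w") as fh:
        for i, pos in enumerate(track.positions):
            row = track.depths[i]
            if omit_zero_rows and not row.any():
                continue
            fh.write(track.chromosome + "\t" + str(int(pos)) + "\t"
                     + "\t".join(str(int(d)) for d in row) + "\n")


# ---------------------------------------------------------------------------
# window count tables
# ---------------------------------------------------------------------------

@dataclass
class WindowCountTable:
    """Per-window alignment counts (bedtools multicov dialect, BED half-open)."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray  # (n_windows, n_samples)
    sample_ids: list[str]
    window_size: int | None = None
    has_partial_tail: bool = False

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.ends <= self.starts):
            raise FormatError("window end must exceed start")
        order = np.argsort(self.starts)
        if not np.array_equal(order, np.arange(len(order))):
            raise FormatError("windows not sorted")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise FormatError("overlapping windows")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise FormatError("windows do not tile the chromosome (gaps)")
        if np.any(self.counts < 0):
            raise FormatError("negative alignment count")
        widths = self.widths
        if self.window_size is None and len(widths):
            self.window_size = int(np.bincount(widths).argmax()) if len(widths) > 1 \
                else int(widths[0])
        if self.window_size is not None and len(widths):
            bad = np.nonzero(widths[:-1] != self.window_size)[0]
            if bad.size:
                raise FormatError(
                    f"non-terminal window(s) with width != {self.window_size}: "
                    f"indices {bad.tolist()}"
                )
            if widths[-1] != self.window_size:
                self.has_partial_tail = True
                logger.warning(
                    "%s: final window [%d, %d) shorter than %d bp; retained",
                    self.chromosome, self.starts[-1], self.ends[-1], self.window_size,
                )

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]


def read_window_counts(
    stream: str | os.PathLike | io.TextIOBase,
    sample_ids: Sequence[str],
    window_size: int | None = None,
) -> WindowCountTable:
    """Parse a bedtools-multicov TSV (chrom, start, end, count-per-sample)."""
    close = False
    if isinstance(stream, io.TextIOBase):
        fh = stream
    else:
        fh = open(stream)
        close = True
    n = len(sample_ids)
    chrom = None
    starts, ends, rows = [], [], []
    try:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3 + n:
                raise FormatError(
                    f"line {ln}: expected {3 + n} columns, got {len(parts)}"
                )
            if chrom is None:
                chrom = parts[0]
            elif parts[0] != chrom:
                raise FormatError("window table must cover a single chromosome")
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            rows.append([int(x) for x in parts[3:]])
    finally:
        if close:
            fh.close()
    if chrom is None:
        raise FormatError("empty window table")
    return WindowCountTable(
        chrom,
        np.array(starts), np.array(ends),
        np.array(rows, dtype=np.int64),
        list(sample_ids),
        window_size=window_size,
    )


def write_window_counts(table: WindowCountTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i in range(table.n_windows):
            fh.write(
                f"{table.chromosome}\t{int(table.starts[i])}\t{int(table.ends[i])}\t"
                + "\t".join(str(int(c)) for c in table.counts[i]) + "\n"
            )


# ---------------------------------------------------------------------------
# genotype matrices (VCF)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic-SNV genotypes plus per-genotype depth.

    ``genotypes`` uses the GT_* codes (missing = -1); shape (n_sites, n_samples).
    """

    sites: pd.DataFrame  # columns: chromosome, position (1-based), ref, alt
    genotypes: np.ndarray
    depth: np.ndarray
    sample_ids: list[str]
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=np.int8))
        self.depth = np.atleast_2d(np.asarray(self.depth, dtype=np.int32))
        n_sites = len(self.sites)
        if self.genotypes.shape != (n_sites, len(self.sample_ids)):
            raise FormatError("genotype matrix shape mismatch")
        if self.depth.shape != self.genotypes.shape:
            raise FormatError("depth matrix shape mismatch")
        if np.any(self.depth < 0):
            raise FormatError("negative genotype depth")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sites.copy(), self.genotypes.copy(), self.depth.copy(),
            list(self.sample_ids), dict(self.dropped),
        )


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    lo, hi = span.split("-")
    return chrom, int(lo), int(hi)


def read_vcf_genotypes(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Load biallelic SNVs with GT and per-sample DP from a VCF.

    Multiallelic and non-SNV records are dropped (counted in ``dropped``);
    missing GT or DP==0 genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        vcf.get_header_type("DP")
    except KeyError as exc:
        raise FormatError(
            "VCF lacks a DP FORMAT field; re-export genotypes with per-sample DP"
        ) from exc
    sample_ids = list(vcf.samples)
    want = _parse_region(region) if region else None
    rows, gts, dps = [], [], []
    dropped = {"multiallelic": 0, "non_snv": 0, "no_depth": 0}
    for v in vcf:
        if want is not None:
            chrom, lo, hi = want
            if v.CHROM != chrom:
                continue
            if lo is not None and not (lo <= v.POS <= hi):
                continue
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped["non_snv"] += 1
            continue
        dp = v.format("DP")
        if dp is None:
            dropped["no_depth"] += 1
            continue
        # cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
        code = np.array(v.gt_types, dtype=np.int8)
        gt = np.where(code == 0, GT_HOM_REF,
                      np.where(code == 1, GT_HET,
                               np.where(code == 3, GT_HOM_ALT, GT_MISSING)))
        dpv = np.asarray(dp).reshape(-1).astype(np.int64)
        dpv = np.where(dpv < 0, 0, dpv)  # cyvcf2 encodes missing DP as negative
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gts.append(gt)
        dps.append(dpv)
    for rule, count in dropped.items():
        if count:
            logger.info("read_vcf_genotypes: dropped %d records (%s)", count, rule)
    sites = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt"])
    n = len(sample_ids)
    return GenotypeMatrix(
        sites,
        np.array(gts, dtype=np.int8).reshape(len(rows), n),
        np.array(dps, dtype=np.int32).reshape(len(rows), n),
        sample_ids,
        dropped,
    )


_GT_STRINGS = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT:DP, suitable for cyvcf2 round-trips."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i, site in enumerate(gm.sites.itertuples(index=False)):
            cells = [
                f"{_GT_STRINGS[int(g)]}:{int(d)}"
                for g, d in zip(gm.genotypes[i], gm.depth[i])
            ]
            fh.write(
                f"{site.chromosome}\t{site.position}\t.\t{site.ref}\t{site.alt}"
                "\t.\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class SexReport:
    """Full pipeline result, serializable to JSON (lossless) and TSV (labels)."""

    verdict: str = "undetermined"  # XY | ZW | undetermined
    reason: str | None = None
    heterogametic_sex: str | None = None
    candidate_chromosome: str | None = None
    chromosome_scan: list[dict] = field(default_factory=list)
    window_labels: list[dict] = field(default_factory=list)
    assignments: list[dict] = field(default_factory=list)
    het_contrast: dict | None = None
    density_modes: dict | None = None
    axes: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = REPORT_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SexReport":
        d = dict(d)
        d.pop("schema_version", None)
        return cls(**d)


def write_report(report: SexReport, path: str | os.PathLike, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("chromosome\tstart\tend\tlabel\tlacking_sex\n")
            for w in report.window_labels:
                fh.write(
                    f"{w['chromosome']}\t{w['start']}\t{w['end']}\t{w['label']}\t"
                    f"{w.get('lacking') or '.'}\n"
                )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | os.PathLike) -> SexReport:
    with open(path) as fh:
        return SexReport.from_dict(json.load(fh))
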