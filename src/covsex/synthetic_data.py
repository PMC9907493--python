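"""Synthetic resequencing cohorts with a planted sex-determination system.

The generator emulates the statistical structure that the differential
coverage analysis consumes, at desk scale:

* a multi-chromosome genome (17 chromosomes by default, lengths following a
  descending power law — a macro/microchromosome karyotype in miniature);
* a cohort of known males, known females and unknown-sex individuals, each
  with its own genome-wide mean depth (log-uniform on 1.3-11.8x by default,
  matching the spread and ~4.4x mean typical of population resequencing);
* one sex-linked reference chromosome partitioned into pseudo-autosomal
  (PAR), hemizygous (sex-specific) and diverged-gametolog segments.

Expected per-base depth is ``sample_mean * dosage_factor`` where the dosage
factor encodes copy number relative to diploid: 1 in PARs and autosomes,
0.5 / 0 in hemizygous regions for the heterogametic / homogametic sex, and
(1+lambda)/2 / lambda in diverged regions (the heterogametic sex has one
perfectly-mapping copy plus one diverged copy that maps with efficiency
lambda; the homogametic sex has two diverged copies). Depth noise is Poisson
(negative binomial optionally); window "alignment counts" are per-window
depth sums divided by a nominal 150 bp read length. Fixed gametolog
differences render the heterogametic sex heterozygous in diverged regions,
on top of background polymorphism shared by both sexes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coverage_stats import ChromCoverageSummary, write_coverage_summary
from .io_formats import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GenotypeMatrix,
    PerBaseDepthTrack,
    SampleRecord,
    SampleSheet,
    SexReport,
    WindowCountTable,
    write_depth_track,
    write_sample_sheet,
    write_vcf,
    write_window_counts,
)

PAR = "par"
HEMIZYGOUS = "hemizygous"
DIVERGED = "diverged"


@dataclass
class SimConfig:
    """Generative parameters; the defaults are the package's study conditions."""

    n_males: int = 20
    n_females: int = 7
    n_unknowns: int = 8
    n_chromosomes: int = 17
    genome_length: int = 10_000_000
    length_exponent: float = 0.7
    sex_system: str = "XY"  # XY | ZW | none
    sex_chrom_rank: int = 12
    par_fraction: float = 0.55
    hemizygous_fraction: float = 0.30
    diverged_fraction: float = 0.15
    divergence: float = 1e-3          # fixed X/Y differences per bp, diverged regions
    mappability_leak: float = 0.9     # lambda: mapping efficiency of diverged copies
    depth_fixed: float | None = None  # fix every sample's mean depth (x)
    depth_range: tuple[float, float] = (1.3, 11.8)  # log-uniform draw otherwise
    noise: str = "poisson"            # poisson | nb
    nb_theta: float = 10.0
    window_size: int = 10_000
    read_length: int = 150
    snv_rate: float = 1e-3            # background SNVs per bp on the sex chromosome
    per_base_track: bool = True
    genotypes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.par_fraction + self.hemizygous_fraction + self.diverged_fraction
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1")
        if self.sex_system not in ("XY", "ZW", "none"):
            raise ValueError("sex_system must be XY, ZW or none")
        if not (0.0 <= self.mappability_leak <= 1.0):
            raise ValueError("mappability_leak must lie in [0, 1]")
        for name in ("divergence", "snv_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.sex_chrom_rank <= self.n_chromosomes):
            raise ValueError("sex_chrom_rank out of range")

    @property
    def heterogametic_sex(self) -> str | None:
        return {"XY": "male", "ZW": "female", "none": None}[self.sex_system]

    def chromosome_lengths(self) -> dict[str, int]:
        i = np.arange(1, self.n_chromosomes + 1, dtype=float)
        w = i ** (-self.length_exponent)
        lengths = np.round(self.genome_length * w / w.sum()).astype(int)
        return {f"chr{k + 1}": int(lengths[k]) for k in range(self.n_chromosomes)}

    @property
    def sex_chromosome(self) -> str:
        return f"chr{self.sex_chrom_rank}"


@dataclass
class RegionPlan:
    """Window-aligned partition of the sex chromosome into region classes."""

    chromosome: str
    chrom_length: int
    window_size: int
    starts: np.ndarray
    ends: np.ndarray
    window_labels: list[str]  # PAR / HEMIZYGOUS / DIVERGED per window

    def base_labels(self) -> np.ndarray:
        """Per-base integer class codes (0=par, 1=hemizygous, 2=diverged)."""
        codes = {PAR: 0, HEMIZYGOUS: 1, DIVERGED: 2}
        out = np.empty(self.chrom_length, dtype=np.int8)
        for s, e, lab in zip(self.starts, self.ends, self.window_labels):
            out[s:e] = codes[lab]
        return out

    def realized_fraction(self, label: str) -> float:
        widths = self.ends - self.starts
        total = widths.sum()
        sel = sum(int(w) for w, lab in zip(widths, self.window_labels) if lab == label)
        return sel / total

    def segments(self, label: str) -> list[tuple[int, int]]:
        """Merged 0-based half-open intervals carrying ``label``."""
        out: list[tuple[int, int]] = []
        for s, e, lab in zip(self.starts, self.ends, self.window_labels):
            if lab != label:
                continue
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], int(e))
            else:
                out.append((int(s), int(e)))
        return out


def plan_regions(config: SimConfig, rng: np.random.Generator) -> RegionPlan:
    """Lay out contiguous PAR / hemizygous / diverged blocks on the sex
    chromosome, snapped to the window grid, in a seeded random block order.

    Autosomes are implicitly entirely shared. With ``sex_system='none'`` the
    whole chromosome is PAR-like.
    """
    length = config.chromosome_lengths()[config.sex_chromosome]
    ws = config.window_size
    if length < ws:
        raise ValueError("sex chromosome shorter than one window")
    starts = np.arange(0, length, ws)
    ends = np.minimum(starts + ws, length)
    n = len(starts)
    if config.sex_system == "none":
        labels = [PAR] * n
    else:
        k_hemi = int(round(config.hemizygous_fraction * n))
        k_div = int(round(config.diverged_fraction * n))
        k_par = n - k_hemi - k_div
        if k_par < 0:
            raise ValueError("window grid too coarse for the requested fractions")
        block_order = [PAR, HEMIZYGOUS, DIVERGED]
        rng.shuffle(block_order)
        counts = {PAR: k_par, HEMIZYGOUS: k_hemi, DIVERGED: k_div}
        labels = []
        for lab in block_order:
            labels.extend([lab] * counts[lab])
    return RegionPlan(config.sex_chromosome, length, ws, starts, ends, labels)


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring pipeline output."""

    system: str
    heterogametic_sex: str | None
    sex_chromosome: str
    true_sex: dict[str, str]
    window_labels: list[str]
    window_starts: list[int]
    window_ends: list[int]
    realized_fractions: dict[str, float]
    divergence: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    config: SimConfig
    sheet: SampleSheet
    summary: ChromCoverageSummary
    track: PerBaseDepthTrack | None
    windows: WindowCountTable
    genotypes: GenotypeMatrix | None
    truth: SyntheticTruth
    plan: RegionPlan


def _dosage_factors(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-region-class dosage factor for each role (index: par, hemi, div)."""
    lam = config.mappability_leak
    return {
        "het": np.array([1.0, 0.5, (1.0 + lam) / 2.0]),
        "hom": np.array([1.0, 0.0, lam]),
    }


def _draw_total(rng: np.random.Generator, lam_total: float, n_bases: int,
                config: SimConfig) -> int:
    """Total depth over a block of bases under the configured noise law."""
    if lam_total <= 0:
        return 0
    if config.noise == "poisson":
        return int(rng.poisson(lam_total))
    theta = config.nb_theta * n_bases
    p = theta / (theta + lam_total)
    return int(rng.negative_binomial(theta, p))


def _draw_per_base(rng: np.random.Generator, lam: np.ndarray,
                   config: SimConfig) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(lam)
    p = config.nb_theta / (config.nb_theta + lam)
    return rng.negative_binomial(config.nb_theta, np.where(lam > 0, p, 1.0))


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a full cohort: coverage summary, per-base track and window
    counts on the sex chromosome, a genotype matrix, sample sheet and truth.

    Deterministic for a given config (seed included): identical configs give
    bit-identical outputs. An XY configuration and the ZW configuration with
    male/female counts swapped are exact mirror images under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    lengths = config.chromosome_lengths()
    chroms = list(lengths)
    sex_chrom = config.sex_chromosome
    het_sex = config.heterogametic_sex

    # --- cohort roles (heterogametic / homogametic), label-free draws -----
    if het_sex == "male":
        n_het, n_hom = config.n_males, config.n_females
    elif het_sex == "female":
        n_het, n_hom = config.n_females, config.n_males
    else:
        n_het, n_hom = config.n_males, config.n_females  # roles inert
    n_known = n_het + n_hom
    n_total = n_known + config.n_unknowns
    roles = ["het"] * n_het + ["hom"] * n_hom
    unknown_roles = ["hom"] * (config.n_unknowns // 2) \
        + ["het"] * (config.n_unknowns - config.n_unknowns // 2)
    unknown_roles = [unknown_roles[i] for i in rng.permutation(config.n_unknowns)]
    roles += unknown_roles
    width = len(str(n_total))
    sample_ids = [f"ind{i + 1:0{width}d}" for i in range(n_total)]

    role_to_sex = {"het": het_sex or "male",
                   "hom": ("female" if (het_sex or "male") == "male" else "male")}
    true_sex = {s: role_to_sex[r] for s, r in zip(sample_ids, roles)}
    labels = [true_sex[s] if i < n_known else "unknown"
              for i, s in enumerate(sample_ids)]
    sheet = SampleSheet([SampleRecord(s, lab) for s, lab in zip(sample_ids, labels)])

    # --- per-sample mean depths ------------------------------------------
    if config.depth_fixed is not None:
        mu = np.full(n_total, float(config.depth_fixed))
    else:
        lo, hi = config.depth_range
        mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_total))

    # --- region plan and dosage ------------------------------------------
    plan = plan_regions(config, rng)
    base_class = plan.base_labels()
    factors = _dosage_factors(config)
    if config.sex_system == "none":
        factors = {"het": np.ones(3), "hom": np.ones(3)}

    # --- coverage summary (autosomes by aggregate draws) ------------------
    depth_rows = np.zeros((n_total, len(chroms)))
    for j, chrom in enumerate(chroms):
        if chrom == sex_chrom:
            continue
        L = lengths[chrom]
        for i in range(n_total):
            depth_rows[i, j] = _draw_total(rng, mu[i] * L, L, config) / L

    j_sex = chroms.index(sex_chrom)
    L_sex = lengths[sex_chrom]
    class_lengths = np.bincount(base_class, minlength=3)

    track: PerBaseDepthTrack | None = None
    if config.per_base_track:
        depth_mat = np.empty((L_sex, n_total), dtype=np.int32)
        for i in range(n_total):
            lam = mu[i] * factors[roles[i]][base_class]
            depth_mat[:, i] = _draw_per_base(rng, lam, config)
        track = PerBaseDepthTrack(
            sex_chrom, np.arange(1, L_sex + 1), depth_mat, sample_ids,
            chrom_length=L_sex,
        )
        depth_rows[:, j_sex] = depth_mat.sum(axis=0, dtype=np.int64) / L_sex
        window_totals = np.add.reduceat(depth_mat, plan.starts, axis=0,
                                        dtype=np.int64)
    else:
        window_totals = np.zeros((plan.starts.size, n_total), dtype=np.int64)
        for w, (s, e) in enumerate(zip(plan.starts, plan.ends)):
            seg_class = base_class[s:e]
            seg_counts = np.bincount(seg_class, minlength=3)
            for i in range(n_total):
                lam_total = mu[i] * float(factors[roles[i]] @ seg_counts)
                window_totals[w, i] = _draw_total(rng, lam_total, e - s, config)
        depth_rows[:, j_sex] = window_totals.sum(axis=0) / L_sex

    summary = ChromCoverageSummary(
        pd.DataFrame(depth_rows, index=sample_ids, columns=chroms), dict(lengths)
    )
    windows = WindowCountTable(
        sex_chrom, plan.starts.copy(), plan.ends.copy(),
        np.rint(window_totals / config.read_length).astype(np.int64),
        sample_ids, window_size=config.window_size,
    )

    # --- genotypes on the sex chromosome ----------------------------------
    gm: GenotypeMatrix | None = None
    if config.genotypes:
        gm = _simulate_genotypes(config, rng, plan, base_class, class_lengths,
                                 roles, mu, sample_ids, factors)

    truth = SyntheticTruth(
        system=config.sex_system,
        heterogametic_sex=het_sex,
        sex_chromosome=sex_chrom,
        true_sex=true_sex,
        window_labels=list(plan.window_labels),
        window_starts=[int(x) for x in plan.starts],
        window_ends=[int(x) for x in plan.ends],
        realized_fractions={lab: plan.realized_fraction(lab)
                            for lab in (PAR, HEMIZYGOUS, DIVERGED)},
        divergence=config.divergence,
    )
    return SimResult(config, sheet, summary, track, windows, gm, truth, plan)


def _simulate_genotypes(config, rng, plan, base_class, class_lengths, roles,
                        mu, sample_ids, factors) -> GenotypeMatrix:
    L = plan.chrom_length
    n = len(sample_ids)
    # background SNVs anywhere on the chromosome
    n_bg = rng.poisson(config.snv_rate * L)
    bg_pos = np.sort(rng.choice(L, size=min(n_bg, L), replace=False)) + 1
    # fixed gametolog differences within diverged bases
    div_bases = np.flatnonzero(base_class == 2)
    n_div = rng.poisson(config.divergence * div_bases.size) if div_bases.size else 0
    div_pos = np.sort(rng.choice(div_bases, size=min(n_div, div_bases.size),
                                 replace=False)) + 1 if n_div else np.array([], int)
    div_pos = np.setdiff1d(div_pos, bg_pos)
    pos = np.concatenate([bg_pos, div_pos])
    is_fixed_diff = np.concatenate(
        [np.zeros(bg_pos.size, bool), np.ones(div_pos.size, bool)]
    )
    order = np.argsort(pos, kind="stable")
    pos, is_fixed_diff = pos[order], is_fixed_diff[order]
    site_class = base_class[pos - 1]

    gts = np.full((pos.size, n), GT_HOM_REF, dtype=np.int8)
    mafs = rng.uniform(0.1, 0.5, size=pos.size)
    role_is_het = np.array([r == "het" for r in roles])
    for k in range(pos.size):
        if is_fixed_diff[k]:
            gts[k, role_is_het] = GT_HET
            gts[k, ~role_is_het] = GT_HOM_REF
        elif site_class[k] == 1 and config.sex_system != "none":
            # hemizygous: heterogametic sex is haploid here, never het
            alt = rng.random(n) < mafs[k]
            gts[k] = np.where(alt, GT_HOM_ALT, GT_HOM_REF)
        else:
            g = rng.binomial(2, mafs[k], size=n)
            gts[k] = g.astype(np.int8)  # 0/1/2 == hom_ref/het/hom_alt codes

    lam = mu[None, :] * np.stack(
        [factors[r][site_class] for r in roles], axis=1
    )
    dp = rng.poisson(lam).astype(np.int32)
    gts[dp == 0] = GT_MISSING

    sites = pd.DataFrame({
        "chromosome": plan.chromosome,
        "position": pos.astype(int),
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(sites, gts, dp, list(sample_ids))


# ---------------------------------------------------------------------------
# disk round trip and truth scoring
# ---------------------------------------------------------------------------

def write_cohort(sim: SimResult, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the cohort in its standard on-disk formats (all via io_formats)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sheet": os.path.join(outdir, "samples.tsv"),
        "summary": os.path.join(outdir, "coverage_summary.tsv"),
        "windows": os.path.join(outdir, "windows.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_sample_sheet(sim.sheet, paths["sheet"])
    write_coverage_summary(sim.summary, paths["summary"])
    write_window_counts(sim.windows, paths["windows"])
    if sim.track is not None:
        paths["depth"] = os.path.join(outdir, "depth.tsv")
        write_depth_track(sim.track, paths["depth"])
    if sim.genotypes is not None:
        paths["vcf"] = os.path.join(outdir, "variants.vcf")
        write_vcf(sim.genotypes, paths["vcf"],
                  {sim.plan.chromosome: sim.plan.chrom_length})
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def truth_check(report: SexReport, truth: SyntheticTruth) -> dict:
    """Score a pipeline report against the planted truth."""
    report_samples = {a["sample_id"] for a in report.assignments}
    unknown_truth = {s: t for s, t in truth.true_sex.items()
                     if s in report_samples}
    if report.assignments and not report_samples <= set(truth.true_sex):
        raise ValueError("report samples not in the simulated cohort")
    verdict_score = float(report.verdict == truth.system)
    candidate_score = float(report.candidate_chromosome == truth.sex_chromosome) \
        if truth.system != "none" else float(report.candidate_chromosome is None)
    correct = sum(
        1 for a in report.assignments
        if a["assigned_sex"] == unknown_truth.get(a["sample_id"])
    )
    n_unknown = len(report.assignments)

    # window-label confusion: true class -> predicted label counts
    expected = {PAR: "shared", HEMIZYGOUS: "sex_specific", DIVERGED: "shared"}
    confusion: dict[str, dict[str, int]] = {}
    if report.window_labels:
        pred = {(w["start"], w["end"]): w["label"] for w in report.window_labels}
        for s, e, lab in zip(truth.window_starts, truth.window_ends,
                             truth.window_labels):
            row = confusion.setdefault(lab, {})
            p = pred.get((s, e), "absent")
            row[p] = row.get(p, 0) + 1
    window_acc = None
    if confusion:
        tot = sum(sum(r.values()) for r in confusion.values())
        good = sum(r.get(expected[lab], 0) for lab, r in confusion.items())
        window_acc = good / tot
    return {
        "verdict_correct": verdict_score,
        "candidate_correct": candidate_score,
        "unknown_accuracy": (correct / n_unknown) if n_unknown else None,
        "n_unknowns_scored": n_unknown,
        "window_confusion": confusion,
        "window_accuracy": window_acc,
    }
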