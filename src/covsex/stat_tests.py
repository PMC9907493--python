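"""Self-implemented statistics: Welch's t-test, Bonferroni adjustment,
genotype filters, and per-individual heterozygosity counts.

The Welch statistic, its Welch-Satterthwaite degrees of freedom and the
two-sided p-value are computed from the closed forms here (only the Student-t
tail probability comes from scipy). Group order is fixed as (females, males)
throughout the package so that a negative t always means "males larger".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import t as student_t

from .io_formats import (
    GT_HET,
    GT_MISSING,
    GenotypeMatrix,
)


@dataclass
class WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    ``t`` is (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2); swapping the groups
    negates t and leaves p unchanged. When both variances are zero the test
    degenerates: equal means give t=0, p=1; unequal means give signed
    infinity with p=0 and ``degenerate`` set.
    """

    t: float
    df: float
    p: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "n1": self.n1, "n2": self.n2,
            "mean1": self.mean1, "mean2": self.mean2,
            "degenerate": self.degenerate,
        }


def welch_t(group1: Sequence[float], group2: Sequence[float]) -> WelchResult:
    """Welch's t-test of group1 vs group2 (two-sided).

    Group 1 is conventionally the females and group 2 the males, so that a
    male-elevated quantity yields a negative t.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, n1, n2, m1, m2,
                               degenerate=True)
        t_val = np.inf if m1 > m2 else -np.inf
        return WelchResult(float(t_val), float(n1 + n2 - 2), 0.0, n1, n2, m1, m2,
                           degenerate=True)
    t_val = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(student_t.sf(abs(t_val), df))
    return WelchResult(float(t_val), float(df), min(p, 1.0), n1, n2,
                       float(m1), float(m2))


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p*m), order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    return np.minimum(1.0, p * m)


@dataclass
class HetFilterParams:
    """Genotype/site filters mirroring standard VCFtools usage.

    Genotypes with depth outside [min_genotype_depth, max_genotype_depth]
    are set to missing first; sites present (non-missing) in fewer than
    ``min_presence_fraction`` of individuals are then dropped. The presence
    rule is inclusive: a site at exactly the threshold passes.
    """

    min_genotype_depth: int = 1
    max_genotype_depth: int = 50
    min_presence_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.min_genotype_depth <= self.max_genotype_depth):
            raise ValueError("need 0 < min depth <= max depth")
        if not (0 < self.min_presence_fraction <= 1):
            raise ValueError("presence fraction must be in (0, 1]")


@dataclass
class FilteredGenotypes:
    matrix: GenotypeMatrix
    drops: dict[str, int] = field(default_factory=dict)


def filter_genotypes(gm: GenotypeMatrix, params: HetFilterParams | None = None
                     ) -> FilteredGenotypes:
    """Apply the depth-window and presence filters; report per-rule drops.

    Idempotent on the matrix: re-filtering a filtered matrix is a no-op.
    Drop counts: ``genotypes_low_depth`` / ``genotypes_high_depth`` are
    genotype cells newly set to missing; ``sites_low_presence`` is sites
    removed by the presence rule.
    """
    params = params or HetFilterParams()
    out = gm.copy()
    present = out.genotypes != GT_MISSING
    low = present & (out.depth < params.min_genotype_depth)
    high = present & (out.depth > params.max_genotype_depth)
    out.genotypes[low | high] = GT_MISSING
    presence = (out.genotypes != GT_MISSING).mean(axis=1)
    keep = presence >= params.min_presence_fraction
    drops = {
        "genotypes_low_depth": int(low.sum()),
        "genotypes_high_depth": int(high.sum()),
        "sites_low_presence": int((~keep).sum()),
    }
    out = GenotypeMatrix(
        out.sites.loc[keep].reset_index(drop=True),
        out.genotypes[keep],
        out.depth[keep],
        list(out.sample_ids),
        dict(out.dropped),
    )
    return FilteredGenotypes(out, drops)


@dataclass
class HetCounts:
    """Per-sample heterozygous-site counts over a stated region set."""

    counts: dict[str, int]
    n_sites_evaluated: int
    rates: dict[str, float] = field(default_factory=dict)  # per evaluated site


def het_counts(gm: GenotypeMatrix,
               regions: Sequence[tuple[int, int]]) -> HetCounts:
    """Count het genotypes per sample at sites inside ``regions``.

    Regions are 0-based half-open intervals on the matrix's chromosome;
    a 1-based site position p falls in [start, end) iff start < p <= end.
    Missing genotypes are never counted. Additive over disjoint regions.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    pos = gm.sites["position"].to_numpy()
    mask = np.zeros(len(pos), dtype=bool)
    for start, end in regions:
        mask |= (pos > start) & (pos <= end)
    sub = gm.genotypes[mask]
    n_sites = int(mask.sum())
    counts = {
        s: int((sub[:, j] == GT_HET).sum())
        for j, s in enumerate(gm.sample_ids)
    }
    evaluated = {
        s: int((sub[:, j] != GT_MISSING).sum())
        for j, s in enumerate(gm.sample_ids)
    }
    rates = {
        s: (counts[s] / evaluated[s] if evaluated[s] else 0.0)
        for s in gm.sample_ids
    }
    return HetCounts(counts, n_sites, rates)
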