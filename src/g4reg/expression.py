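"""TMM/CPM normalization, Wilcoxon differential expression, and
G4-status expression comparisons.

The DE route follows the large-cohort recipe: TMM between-sample
normalization, CPM transformation, a per-gene two-sided Wilcoxon rank-sum
test between conditions, Benjamini-Hochberg FDR, and calls at FDR < 0.01
with a >=4-fold change (|log2FC| >= 2). The rank test is preferred over
parametric fits because at hundreds of samples per group its FDR control
is solid without distributional assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genes import GeneModel
from .intervals import GenomicInterval, count_overlaps
from .stats import (
    ContingencyTable2x2,
    TestResult,
    bh_adjust,
    fisher_exact_two_sided,
    wilcoxon_rank_sum,
)

__all__ = [
    "CountMatrix",
    "DEResult",
    "tmm_factors",
    "cpm_matrix",
    "wilcoxon_de",
    "g4_status_groups",
    "expression_by_group",
    "deg_g4_enrichment",
]


@dataclass
class CountMatrix:
    """Genes x samples raw counts with per-sample condition labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples), non-negative ints
    condition: dict[str, str]  # sample -> tumor | nat | normal

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def samples_with(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition.get(s) == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p: float
    fdr: float
    status: str  # up | down | ns


def _quantile_type7(x: np.ndarray, p: float) -> float:
    # R's default quantile (type 7) == numpy linear interpolation
    return float(np.quantile(x, p, method="linear"))


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions. For each sample vs reference,
    genes zero in either are dropped, M = log2 ratio of library-size-scaled
    counts and A = average log abundance are trimmed two-sidedly (30% of M,
    5% of A, by average ranks), and the factor is 2**(weighted mean of the
    kept M values) with inverse asymptotic (delta-method) variances as
    weights.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >=2 samples")
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs positive total counts")
    f75 = np.array([_quantile_type7(mat[:, j], 0.75) for j in range(mat.shape[1])]) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    xr, nr = mat[:, ref], lib[ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        xs, ns = mat[:, j], lib[j]
        keep = (xs > 0) & (xr > 0)
        x, r = xs[keep], xr[keep]
        if x.size == 0:
            continue
        m = np.log2((x / ns) / (r / nr))
        a = 0.5 * np.log2((x / ns) * (r / nr))
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_l = np.floor(n * log_ratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * abs_expr_trim) + 1
        hi_s = n + 1 - lo_s
        rm, ra = rankdata(m), rankdata(a)
        kept = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        w = (ns - x) / (ns * x) + (nr - r) / (nr * r)
        with np.errstate(divide="ignore"):
            f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
        factors[j] = 2.0**f
    return factors / np.exp(np.mean(np.log(factors)))


def cpm_matrix(
    counts: CountMatrix | np.ndarray,
    factors: np.ndarray | None = None,
    log: bool = False,
    prior: float = 1.0,
) -> np.ndarray:
    """Counts per million over effective library sizes (library x factor)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    lib = mat.sum(axis=0)
    if factors is None:
        factors = np.ones(mat.shape[1])
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    cpm = mat / (lib * factors) * 1e6
    if log:
        return np.log2(cpm + prior)
    return cpm


def wilcoxon_de(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_cut: float = 0.01,
    lfc_cut: float = 2.0,
    prior: float = 1.0,
) -> list[DEResult]:
    """Per-gene Wilcoxon DE between two sample groups on TMM-CPM values.

    Genes are pre-filtered to those with CPM > 1 in at least
    ``min(|a|, |b|)`` samples; log2FC = log2((mean CPM_a + prior) /
    (mean CPM_b + prior)); status 'up' means higher in group_a.
    """
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need >=2 samples")
    col = {s: i for i, s in enumerate(counts.sample_ids)}
    ia = [col[s] for s in ga]
    ib = [col[s] for s in gb]
    factors = tmm_factors(counts)
    cpm = cpm_matrix(counts, factors)
    sub = cpm[:, ia + ib]
    keep = (sub > 1.0).sum(axis=1) >= min(len(ia), len(ib))
    tested = np.flatnonzero(keep)
    pvals = np.empty(tested.size)
    lfc = np.empty(tested.size)
    for k, gi in enumerate(tested):
        a, b = cpm[gi, ia], cpm[gi, ib]
        pvals[k] = wilcoxon_rank_sum(a, b, "two_sided").p_value
        lfc[k] = np.log2((a.mean() + prior) / (b.mean() + prior))
    fdr = bh_adjust(pvals)
    out: list[DEResult] = []
    for k, gi in enumerate(tested):
        if fdr[k] < fdr_cut and lfc[k] >= lfc_cut:
            status = "up"
        elif fdr[k] < fdr_cut and lfc[k] <= -lfc_cut:
            status = "down"
        else:
            status = "ns"
        out.append(DEResult(counts.gene_ids[gi], float(lfc[k]), float(pvals[k]), float(fdr[k]), status))
    return out


def g4_status_groups(
    genes: Sequence[GeneModel], peaks: Sequence[GenomicInterval]
) -> tuple[dict[str, str], dict[str, str]]:
    """Classify genes by where G4 peaks fall (any-overlap, >=1 bp).

    Returns two maps: gene -> {both, promoter_only, intron_only, neither}
    and gene -> {intron1_g4, other_intron_g4, no_intron_g4}.
    """
    promoters = [g.promoter for g in genes]
    prom_hit = count_overlaps(promoters, peaks, "any_overlap") > 0
    combined: dict[str, str] = {}
    intron_split: dict[str, str] = {}
    for i, g in enumerate(genes):
        introns = g.introns
        hits = count_overlaps(introns, peaks, "any_overlap") if introns else np.array([], dtype=int)
        any_intron = bool((hits > 0).any())
        intron1 = bool(hits.size and hits[0] > 0)
        if prom_hit[i] and any_intron:
            combined[g.gene_id] = "both"
        elif prom_hit[i]:
            combined[g.gene_id] = "promoter_only"
        elif any_intron:
            combined[g.gene_id] = "intron_only"
        else:
            combined[g.gene_id] = "neither"
        if intron1:
            intron_split[g.gene_id] = "intron1_g4"
        elif any_intron:
            intron_split[g.gene_id] = "other_intron_g4"
        else:
            intron_split[g.gene_id] = "no_intron_g4"
    return combined, intron_split


def expression_by_group(
    log_cpm: np.ndarray,
    gene_ids: Sequence[str],
    groups: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], TestResult]:
    """Two-sided rank-sum tests on per-gene mean log-CPM between groups."""
    means = np.asarray(log_cpm).mean(axis=1)
    by_label: dict[str, list[float]] = {}
    for gid, mu in zip(gene_ids, means):
        lab = groups.get(gid)
        if lab is not None:
            by_label.setdefault(lab, []).append(float(mu))
    out: dict[tuple[str, str], TestResult] = {}
    for la, lb in pairs:
        xa, xb = by_label.get(la, []), by_label.get(lb, [])
        if len(xa) < 3 or len(xb) < 3:
            warnings.warn(f"group pair ({la}, {lb}) too small; skipped", stacklevel=2)
            continue
        out[(la, lb)] = wilcoxon_rank_sum(xa, xb, "two_sided")
    return out


def deg_g4_enrichment(
    de: Sequence[DEResult],
    groups: Mapping[str, str],
    region: str = "promoter",
) -> TestResult:
    """Fisher test of region-G4 presence among up- vs down-regulated genes.

    ``region='promoter'`` counts {both, promoter_only} as G4-positive;
    ``region='intron1'`` counts the intron1_g4 label.
    """
    if region == "promoter":
        positive = {"both", "promoter_only"}
    elif region == "intron1":
        positive = {"intron1_g4"}
    else:
        raise ValueError(f"unknown region {region!r}")
    a = b = c = d = 0
    for r in de:
        if r.status not in ("up", "down"):
            continue
        has = groups.get(r.gene_id) in positive
        if r.status == "up":
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        warnings.warn("degenerate DEG/G4 table; p = 1", stacklevel=2)
        return TestResult(float("nan"), 1.0, "fisher_exact_two_sided", a + b + c + d)
    return fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
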