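"""Transcription-factor binding on G4 regions.

A TF "binds" a G4 region when the midpoint of one of its ChIP peaks falls
inside the region (the midpoint binding-site rule). On top of that rule
this module builds: per-gene promoter / first-intron TF assignments and
their complementarity statistics, permutation-control TF enrichment, and
multi-TF co-localization sites (bedtools-multiinter semantics) with a
two-tailed Fisher enrichment of co-bound sites inside G4 regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genes import GeneModel
from .intervals import GenomicInterval, count_overlaps, shuffle_intervals
from .stats import (
    ContingencyTable2x2,
    TestResult,
    fisher_exact_two_sided,
    spearman_correlation,
    wilcoxon_rank_sum,
)

__all__ = [
    "TFPeakSet",
    "G4TFAssignment",
    "EnrichmentResult",
    "ColocalizationSite",
    "assign_tf_binding",
    "interaction_summary",
    "tf_enrichment",
    "promoter_intron_complementarity",
    "multi_tf_colocalization",
    "colocalization_enrichment",
]

REGION_CLASSES = ("promoter", "intron_1", "intron_2plus")


@dataclass
class TFPeakSet:
    tf_name: str
    peaks: list[GenomicInterval]


@dataclass
class G4TFAssignment:
    """TF sets per G4 region and per (gene, region class)."""

    region_tfs: list[tuple[GenomicInterval, str | None, str | None, set[str]]]
    # (region, gene_id, region_class, tf set)
    gene_class_tfs: dict[tuple[str, str], set[str]] = field(default_factory=dict)


def _classify_region(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, str | None]:
    """Owning gene and region class by any-overlap, promoter > intron_1 >
    intron_2plus; ties resolve to the smallest gene_id."""
    best: tuple[int, str, str] | None = None
    rank = {c: i for i, c in enumerate(REGION_CLASSES)}
    for g in genes:
        if g.chrom != region.chrom:
            continue
        cls = None
        if region.overlaps(g.promoter):
            cls = "promoter"
        else:
            for idx, intr in enumerate(g.introns, start=1):
                if region.overlaps(intr):
                    cls = "intron_1" if idx == 1 else "intron_2plus"
                    if cls == "intron_1":
                        break
        if cls is None:
            continue
        key = (rank[cls], g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (rank[cls], g.gene_id, cls)
    if best is None:
        return None, None
    return best[1], best[2]


def assign_tf_binding(
    g4_regions: Sequence[GenomicInterval],
    tf_sets: Sequence[TFPeakSet],
    genes: Sequence[GeneModel],
) -> G4TFAssignment:
    """Midpoint-rule TF assignment to G4 regions, with region classes."""
    region_tfs: list[tuple[GenomicInterval, str | None, str | None, set[str]]] = []
    per_tf_counts = {
        ts.tf_name: count_overlaps(g4_regions, ts.peaks, "midpoint_in")
        for ts in tf_sets
    }
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_class: dict[tuple[str, str], set[str]] = {}
    for i, region in enumerate(g4_regions):
        tfs = {name for name, cnt in per_tf_counts.items() if cnt[i] > 0}
        gene_id, cls = _classify_region(region, by_chrom.get(region.chrom, ()))
        region_tfs.append((region, gene_id, cls, tfs))
        if gene_id is not None and cls is not None:
            gene_class.setdefault((gene_id, cls), set()).update(tfs)
    return G4TFAssignment(region_tfs, gene_class)


def interaction_summary(assignment: G4TFAssignment):
    """Per region class: mean TF count per G4 region, SEM, and pairwise
    rank-sum comparisons between classes."""
    counts: dict[str, list[int]] = {}
    for _region, _gene, cls, tfs in assignment.region_tfs:
        if cls is not None:
            counts.setdefault(cls, []).append(len(tfs))
    summary: dict[str, tuple[float, float, int]] = {}
    for cls, vals in counts.items():
        arr = np.asarray(vals, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        summary[cls] = (float(arr.mean()), sem, int(arr.size))
    tests: dict[tuple[str, str], TestResult] = {}
    present = [c for c in REGION_CLASSES if c in counts]
    for i, ca in enumerate(present):
        for cb in present[i + 1 :]:
            tests[(ca, cb)] = wilcoxon_rank_sum(counts[ca], counts[cb], "two_sided")
    for cls in REGION_CLASSES:
        if cls not in counts:
            warnings.warn(f"no G4 regions in class {cls}", stacklevel=2)
    return summary, tests


@dataclass(frozen=True)
class EnrichmentResult:
    set_label: str
    n_query: int
    overlaps_query: int
    overlaps_control: float
    fold_enrichment: float
    log_p: float
    p_value: float


def tf_enrichment(
    query: Sequence[GenomicInterval],
    tf_set: TFPeakSet,
    universe: Sequence[GenomicInterval],
    n_perm: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of TF-peak midpoints in query regions vs shuffled controls.

    The control count is the number of shuffled query regions containing a
    TF-peak midpoint, averaged over ``n_perm`` length-preserving shuffles of
    the query over the universe. The Fisher test compares the observed
    count with the rounded mean control out of ``n_query`` each.
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    n = len(query)
    if not tf_set.peaks or n == 0:
        return EnrichmentResult(tf_set.tf_name, n, 0, 0.0, 0.0, 0.0, 1.0)
    observed = int((count_overlaps(query, tf_set.peaks, "midpoint_in") > 0).sum())
    rng = np.random.default_rng(seed)
    control_counts = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_intervals(query, universe, rng)
        control_counts[i] = (count_overlaps(shuffled, tf_set.peaks, "midpoint_in") > 0).sum()
    mean_control = float(control_counts.mean())
    if mean_control > 0:
        fold = observed / mean_control
    else:
        fold = float(n) if observed > 0 else 0.0
    ctrl = int(round(mean_control))
    if observed == 0 and ctrl == 0:
        return EnrichmentResult(tf_set.tf_name, n, 0, mean_control, 0.0, 0.0, 1.0)
    res = fisher_exact_two_sided(
        ContingencyTable2x2(observed, n - observed, ctrl, n - ctrl)
    )
    log_p = math.log10(res.p_value) if res.p_value > 0 else -math.inf
    return EnrichmentResult(tf_set.tf_name, n, observed, mean_control, fold, log_p, res.p_value)


def promoter_intron_complementarity(
    assignment: G4TFAssignment, bins: int = 10
):
    """Complementarity of promoter vs first-intron TF repertoires per gene.

    For genes with both a promoter G4 and a first-intron G4, correlates the
    per-gene TF counts (Spearman). For those additionally having >=1
    first-intron TF, shared_fraction = |promoter ∩ intron1| / |intron1|;
    the histogram reports the fraction of genes at exactly 0 plus binned
    nonzero fractions.
    """
    gene_ids = sorted(
        {g for (g, cls) in assignment.gene_class_tfs if cls == "promoter"}
        & {g for (g, cls) in assignment.gene_class_tfs if cls == "intron_1"}
    )
    records = []
    shared_fractions = []
    n_prom, n_int = [], []
    for gid in gene_ids:
        prom = assignment.gene_class_tfs[(gid, "promoter")]
        intr = assignment.gene_class_tfs[(gid, "intron_1")]
        n_prom.append(len(prom))
        n_int.append(len(intr))
        rec = {"gene_id": gid, "n_promoter_tfs": len(prom), "n_intron1_tfs": len(intr)}
        if intr:
            frac = len(prom & intr) / len(intr)
            rec["shared_fraction"] = frac
            shared_fractions.append(frac)
        else:
            rec["shared_fraction"] = float("nan")
        records.append(rec)
    if not gene_ids:
        warnings.warn("no gene has both promoter and first-intron G4s", stacklevel=2)
        return records, None, {}
    corr = spearman_correlation(n_prom, n_int) if len(gene_ids) >= 3 else None
    hist: dict[str, float] = {}
    if shared_fractions:
        arr = np.asarray(shared_fractions)
        hist["zero_fraction"] = float((arr == 0).mean())
        edges = np.linspace(0, 1, bins + 1)
        counts, _ = np.histogram(arr[arr > 0], bins=edges)
        hist["nonzero_bins"] = counts.tolist()
        hist["bin_edges"] = edges.tolist()
    return records, corr, hist


@dataclass(frozen=True)
class ColocalizationSite:
    interval: GenomicInterval
    n_proteins: int
    proteins: frozenset[str]


def multi_tf_colocalization(tf_sets: Sequence[TFPeakSet]) -> list[ColocalizationSite]:
    """Maximal segments covered by >=2 distinct TFs' peaks.

    The genome is partitioned at every peak boundary (multiinter
    semantics); adjacent segments with identical protein sets merge into
    one maximal site. Output is independent of TF-set input order.
    """
    if len(tf_sets) < 2:
        raise ValueError("need >=2 TF peak sets")
    events: dict[str, list[tuple[int, int, str]]] = {}
    for ts in tf_sets:
        for p in ts.peaks:
            events.setdefault(p.chrom, []).append((p.start, 1, ts.tf_name))
            events.setdefault(p.chrom, []).append((p.end, -1, ts.tf_name))
    sites: list[ColocalizationSite] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom], key=lambda e: e[0])
        cover: dict[str, int] = {}
        pending: tuple[int, frozenset[str]] | None = None  # (start, proteins)
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                _, delta, name = evs[i]
                cover[name] = cover.get(name, 0) + delta
                if cover[name] == 0:
                    del cover[name]
                i += 1
            current = frozenset(cover) if len(cover) >= 2 else None
            if pending is not None and current != pending[1]:
                sites.append(
                    ColocalizationSite(
                        GenomicInterval(chrom, pending[0], pos),
                        len(pending[1]),
                        pending[1],
                    )
                )
                pending = None
            if current is not None and pending is None:
                pending = (pos, current)
        # coverage always returns to zero at the last event
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return sites


def colocalization_enrichment(
    sites: Sequence[ColocalizationSite],
    g4_regions: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    k: int = 2,
    seed: int = 0,
) -> EnrichmentResult:
    """Fisher enrichment of class->=k co-localized sites in G4 regions.

    ``overlaps`` counts G4 regions containing >=1 midpoint of a site with
    ``n_proteins >= k``; the control is the same count on a single seeded
    length-preserving shuffle of the G4 regions over the universe.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    if not g4_regions:
        raise ValueError("g4_regions must be non-empty")
    class_sites = [s.interval for s in sites if s.n_proteins >= k]
    n = len(g4_regions)
    observed = int((count_overlaps(g4_regions, class_sites, "midpoint_in") > 0).sum())
    control_regions = shuffle_intervals(g4_regions, universe, seed)
    control = int((count_overlaps(control_regions, class_sites, "midpoint_in") > 0).sum())
    res = fisher_exact_two_sided(
        ContingencyTable2x2(observed, n - observed, control, n - control)
    )
    fold = observed / control if control > 0 else (float(n) if observed else 0.0)
    log_p = math.log10(res.p_value) if res.p_value > 0 else -math.inf
    return EnrichmentResult(f">={k}", n, observed, float(control), fold, log_p, res.p_value)
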