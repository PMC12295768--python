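"""Gene models, strand-aware feature derivation and midpoint annotation.

A :class:`GeneModel` carries one transcript per gene (when several exist the
longest is used, maximizing intron coverage). Introns are the gaps between
consecutive exons, numbered 1..n in *transcription* direction, so intron 1
is the TSS-proximal gap — the genomically last gap for a ``-`` strand gene.
The promoter is ``promoter_window`` bases immediately upstream of the TSS,
strand-aware, clipped at chromosome edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "FeatureAnnotation",
    "annotate_interval",
    "read_gene_models_tsv",
    "write_gene_models_tsv",
    "read_gene_models_gtf",
    "DEFAULT_PRIORITY",
]

DEFAULT_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[GenomicInterval]  # genomic order, sorted, non-overlapping
    promoter_window: int = 1000
    utr5: list[GenomicInterval] | None = None
    utr3: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def promoter(self) -> GenomicInterval:
        """``promoter_window`` bases immediately upstream of the TSS."""
        if self.strand == "+":
            start = max(0, self.start - self.promoter_window)
            end = self.start
            if end <= start:  # TSS at chromosome edge
                end = start + 1
        else:
            start = self.end
            end = self.end + self.promoter_window
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, ordered in transcription direction."""
        gaps = [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]
        if self.strand == "-":
            gaps.reverse()
        return gaps

    def intron(self, index: int) -> GenomicInterval:
        """1-based intron in transcription direction."""
        return self.introns[index - 1]


@dataclass(frozen=True)
class FeatureAnnotation:
    interval: GenomicInterval
    feature: str  # promoter | utr5 | utr3 | exon | intron | intergenic
    intron_index: int | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if (self.feature == "intron") != (self.intron_index is not None):
            raise ValueError("intron_index present iff feature == 'intron'")


def _candidate_features(pos: int, gene: GeneModel):
    if gene.promoter.contains(pos):
        yield "promoter", None
    for ivs, label in ((gene.utr5, "utr5"), (gene.utr3, "utr3")):
        if ivs:
            for iv in ivs:
                if iv.contains(pos):
                    yield label, None
    for ex in gene.exons:
        if ex.contains(pos):
            yield "exon", None
    for idx, intr in enumerate(gene.introns, start=1):
        if intr.contains(pos):
            yield "intron", idx


def annotate_interval(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> FeatureAnnotation:
    """Single-label annotation of an interval by its midpoint.

    When the midpoint hits features of several genes (or several features of
    one gene), the first feature in ``priority`` wins; ties on the same
    feature resolve to the lexicographically smallest gene_id for
    determinism. Intergenic is the fallback.
    """
    pos = interval.midpoint
    rank = {f: i for i, f in enumerate(priority)}
    best: tuple[int, str, str, int | None] | None = None
    for gene in genes:
        if gene.chrom != interval.chrom:
            continue
        for feature, idx in _candidate_features(pos, gene):
            key = (rank.get(feature, len(rank)), gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (key[0], gene.gene_id, feature, idx)
    if best is None:
        return FeatureAnnotation(interval, "intergenic")
    return FeatureAnnotation(interval, best[2], best[3], best[1])


# ---------------------------------------------------------------------------
# I/O: simplified gene-model TSV and minimal GTF


def write_gene_models_tsv(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texon_starts\texon_ends\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                f"{','.join(str(e.start) for e in g.exons)}\t"
                f"{','.join(str(e.end) for e in g.exons)}\n"
            )


def read_gene_models_tsv(path, promoter_window: int = 1000) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or not f[0]:
                continue
            starts = [int(x) for x in f[idx["exon_starts"]].split(",") if x]
            ends = [int(x) for x in f[idx["exon_ends"]].split(",") if x]
            chrom, strand = f[idx["chrom"]], f[idx["strand"]]
            exons = [GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)]
            genes.append(
                GeneModel(f[idx["gene_id"]], chrom, strand, exons, promoter_window)
            )
    return genes


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models_gtf(path, promoter_window: int = 1000) -> list[GeneModel]:
    """Minimal GTF reader: exon lines only, longest transcript per gene.

    GTF is 1-based inclusive; converted to 0-based half-open on read. Only
    the ``gene_id`` and ``transcript_id`` attributes are consulted.
    """
    transcripts: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id", gid)
            if gid is None:
                continue
            rec = transcripts.setdefault(
                (gid, tid), {"chrom": f[0], "strand": f[6], "exons": []}
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    by_gene: dict[str, dict] = {}
    for (gid, _tid), rec in transcripts.items():
        span = sum(e - s for s, e in rec["exons"])
        cur = by_gene.get(gid)
        if cur is None or span > cur["span"]:
            by_gene[gid] = {**rec, "span": span}
    genes = []
    for gid in sorted(by_gene):
        rec = by_gene[gid]
        exons = [
            GenomicInterval(rec["chrom"], s, e, rec["strand"])
            for s, e in sorted(rec["exons"])
        ]
        genes.append(GeneModel(gid, rec["chrom"], rec["strand"], exons, promoter_window))
    return genes
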