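"""Genomic-interval primitives and bedtools-style operations.

All coordinates are 0-based half-open (BED convention). The operations here
pin down the exact semantics the downstream analyses rely on: ``merge``
joins overlapping *or abutting* intervals (bedtools-merge default),
``count_overlaps`` offers both any-overlap and midpoint-containment modes,
and ``shuffle_intervals`` re-places intervals uniformly over a universe of
segments with probability proportional to the number of legal start
positions (bedtools-shuffle semantics, overlaps among outputs allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "count_overlaps",
    "shuffle_intervals",
    "normalized_5prime_position",
    "midpoint",
]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def midpoint(interval: GenomicInterval) -> int:
    """Midpoint ``floor((start+end)/2)`` — the binding-site convention."""
    return interval.midpoint


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving input order.

    Columns 4-6 (name, score, strand), when present, are mapped onto the
    optional fields; a ``.`` score is treated as missing.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6; round-trips bit-exactly with :func:`read_bed`."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name if iv.name is not None else ".",
                        _fmt_score(iv.score),
                        iv.strand,
                    ]
                )
                + "\n"
            )


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, strand-agnostic, abutting intervals join.

    Matches ``bedtools merge`` defaults (distance 0 joins). Name/score/strand
    are dropped in the output.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _by_chrom_arrays(ivs: Sequence[GenomicInterval]):
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def count_overlaps(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    mode: str = "any_overlap",
) -> np.ndarray:
    """Per-query count of subject intervals hitting it.

    ``any_overlap`` counts subjects sharing >=1 base; ``midpoint_in`` counts
    subjects whose midpoint ``floor((start+end)/2)`` lies inside the query.
    """
    if mode not in {"any_overlap", "midpoint_in"}:
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.zeros(len(query), dtype=np.int64)
    if not query or not subject:
        return counts
    if mode == "midpoint_in":
        mids: dict[str, np.ndarray] = {}
        tmp: dict[str, list[int]] = {}
        for iv in subject:
            tmp.setdefault(iv.chrom, []).append(iv.midpoint)
        for chrom, m in tmp.items():
            mids[chrom] = np.sort(np.asarray(m, dtype=np.int64))
        for qi, q in enumerate(query):
            m = mids.get(q.chrom)
            if m is None:
                continue
            counts[qi] = np.searchsorted(m, q.end - 1, side="right") - np.searchsorted(
                m, q.start, side="left"
            )
        return counts
    subj = _by_chrom_arrays(subject)
    for qi, q in enumerate(query):
        arrs = subj.get(q.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        counts[qi] = int(np.count_nonzero((starts < q.end) & (ends > q.start)))
    return counts


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    seed: int | np.random.Generator,
) -> list[GenomicInterval]:
    """Length-preserving uniform re-placement over universe segments.

    Each interval keeps its length; its new start is uniform over all legal
    start positions across all universe segments (segment weight
    ``max(seg_len - L + 1, 0)``). Outputs may overlap each other.
    Deterministic for a given integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not universe:
        raise ValueError("empty universe")
    seg_chrom = [u.chrom for u in universe]
    seg_start = np.asarray([u.start for u in universe], dtype=np.int64)
    seg_len = np.asarray([len(u) for u in universe], dtype=np.int64)

    lengths = np.asarray([len(iv) for iv in intervals], dtype=np.int64)
    out: list[GenomicInterval] = []
    # group identical lengths so the weight vector is built once per length
    order = np.argsort(lengths, kind="stable")
    placed_seg = np.empty(len(intervals), dtype=np.int64)
    placed_start = np.empty(len(intervals), dtype=np.int64)
    i = 0
    while i < len(order):
        j = i
        L = lengths[order[i]]
        while j < len(order) and lengths[order[j]] == L:
            j += 1
        weights = np.maximum(seg_len - L + 1, 0)
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"interval of length {L} longer than every universe segment")
        idxs = order[i:j]
        cum = np.cumsum(weights)
        # choose a legal start uniformly over the concatenated start space
        draws = rng.integers(0, total, size=len(idxs))
        segs = np.searchsorted(cum, draws, side="right")
        offsets = draws - np.concatenate(([0], cum[:-1]))[segs]
        placed_seg[idxs] = segs
        placed_start[idxs] = seg_start[segs] + offsets
        i = j
    for k, iv in enumerate(intervals):
        s = int(placed_start[k])
        out.append(replace(iv, chrom=seg_chrom[placed_seg[k]], start=s, end=s + len(iv)))
    return out


def normalized_5prime_position(
    interval: GenomicInterval, feature: GenomicInterval
) -> float:
    """Midpoint position within ``feature`` scaled to [0, 1] from its 5' end.

    For a ``+`` feature the 5' end is ``start``; for ``-`` it is ``end - 1``.
    """
    mid = interval.midpoint
    if interval.chrom != feature.chrom or not feature.contains(mid):
        raise ValueError("interval midpoint lies outside the feature")
    if feature.strand == "-":
        dist = (feature.end - 1) - mid
    else:
        dist = mid - feature.start
    return dist / len(feature)
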