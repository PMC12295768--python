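"""Canonical pG4 scanning and SNV effects on G4 motifs.

The canonical putative-quadruplex motif is four G-tracts of length >=
``min_tract`` (default 3) separated by three loops of 1..``max_loop``
(default 7) arbitrary bases: ``G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+``. The
scanner emits non-overlapping motifs per strand, taking at each position
the leftmost match with minimal loops and maximal G-tracts, then resuming
after the emitted motif. The minus strand is scanned on the reverse
complement and coordinates are mapped back. ``N`` bases never match.

SNVs inside a motif are classified as G-tract or loop hits; substitution
types are expressed on the G-rich (motif) strand so that e.g. a genomic
C>T under a minus-strand motif aggregates as G>A. A built-in G-run scorer
(G4Hunter-style: each base in a G-run of length L contributes +min(L, 4),
in a C-run -min(L, 4), averaged over the window; higher = more stable)
provides stability deltas; any external scorer obeying the
higher-is-more-stable contract can be plugged in (folding engines adapt by
negating their minimum free energy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .stats import ContingencyTable2x2, TestResult, fisher_exact_two_sided

__all__ = [
    "PQSMotif",
    "SNVRecord",
    "SNVG4Effect",
    "EnrichmentScoreInput",
    "scan_pg4",
    "classify_snv",
    "snv_spectrum",
    "g_run_stability",
    "stability_delta",
    "detect_gain_loss",
    "region_enrichment_score",
    "reverse_complement",
    "SUBSTITUTION_TYPES",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

BASES = ("A", "C", "G", "T")
SUBSTITUTION_TYPES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PQSMotif:
    """A canonical pG4 with its G-tract/loop map (genomic coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    tracts: tuple[tuple[int, int], ...]  # 4 half-open genomic intervals
    loops: tuple[tuple[int, int], ...]  # 3 half-open genomic intervals

    def __post_init__(self) -> None:
        if len(self.tracts) != 4 or len(self.loops) != 3:
            raise ValueError("a pG4 has exactly 4 tracts and 3 loops")
        parts = sorted(self.tracts + self.loops)
        if parts[0][0] != self.start or parts[-1][1] != self.end:
            raise ValueError("tracts/loops must tile the motif span")
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            if e1 != s2:
                raise ValueError("tracts/loops must tile the motif span")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def region_of(self, pos: int) -> str | None:
        """'g_tract' / 'loop' for a genomic position inside the motif."""
        for s, e in self.tracts:
            if s <= pos < e:
                return "g_tract"
        for s, e in self.loops:
            if s <= pos < e:
                return "loop"
        return None


def _pattern(min_tract: int, max_loop: int) -> re.Pattern:
    tract = f"(G{{{min_tract},}})"
    loop = f"([ACGT]{{1,{max_loop}}}?)"
    return re.compile(tract + loop + tract + loop + tract + loop + tract)


def _scan_one_strand(seq: str, min_tract: int, max_loop: int):
    """Yield (start, [part lengths 7]) for non-overlapping motifs."""
    pat = _pattern(min_tract, max_loop)
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return
        yield m.start(), [len(g) for g in m.groups()]
        pos = m.end()


def scan_pg4(
    sequence: str,
    chrom: str = "chr",
    chrom_offset: int = 0,
    min_tract: int = 3,
    max_loop: int = 7,
    both_strands: bool = True,
) -> list[PQSMotif]:
    """Scan a sequence for canonical pG4 motifs on one or both strands."""
    seq = sequence.upper()
    motifs: list[PQSMotif] = []

    def build(start: int, part_lens: list[int], strand: str, seqlen: int) -> PQSMotif:
        # part boundaries on the scanned strand
        bounds = np.cumsum([start] + part_lens)
        parts = list(zip(bounds[:-1], bounds[1:]))
        if strand == "-":
            parts = [(seqlen - e, seqlen - s) for s, e in parts]
        parts = [(chrom_offset + int(s), chrom_offset + int(e)) for s, e in parts]
        if strand == "-":
            parts.reverse()
        tracts = tuple(parts[0::2])
        loops = tuple(parts[1::2])
        lo = min(s for s, _ in parts)
        hi = max(e for _, e in parts)
        return PQSMotif(chrom, lo, hi, strand, tracts, loops)

    for start, lens in _scan_one_strand(seq, min_tract, max_loop):
        motifs.append(build(start, lens, "+", len(seq)))
    if both_strands:
        rc = reverse_complement(seq)
        for start, lens in _scan_one_strand(rc, min_tract, max_loop):
            motifs.append(build(start, lens, "-", len(seq)))
    motifs.sort(key=lambda m: (m.start, m.end, m.strand))
    return motifs


@dataclass(frozen=True)
class SNVRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class SNVG4Effect:
    snv: SNVRecord
    motif: PQSMotif | None
    region: str  # g_tract | loop | outside
    snv_type: str  # ref>alt on the motif strand ('' when outside)
    stability_ref: float
    stability_alt: float
    delta: float
    call: str  # destabilizing | stabilizing | neutral
    gained_motif: bool
    lost_motif: bool


def classify_snv(
    snv: SNVRecord, motifs: Sequence[PQSMotif]
) -> tuple[str, PQSMotif | None]:
    """Region of an SNV among motifs: g_tract beats loop across overlaps."""
    best: tuple[str, PQSMotif] | None = None
    for m in motifs:
        if m.chrom != snv.chrom:
            continue
        region = m.region_of(snv.pos)
        if region == "g_tract":
            return "g_tract", m
        if region == "loop" and best is None:
            best = ("loop", m)
    return best if best is not None else ("outside", None)


def motif_strand_type(snv: SNVRecord, strand: str) -> str:
    """Substitution expressed on the motif (G-rich) strand."""
    if strand == "-":
        return f"{snv.ref.translate(_COMP)}>{snv.alt.translate(_COMP)}"
    return f"{snv.ref}>{snv.alt}"


def snv_spectrum(effects: Sequence[SNVG4Effect]):
    """12 substitution types x {g_tract, loop} count table (pandas)."""
    import pandas as pd

    table = pd.DataFrame(
        0, index=list(SUBSTITUTION_TYPES), columns=["g_tract", "loop"], dtype=int
    )
    for eff in effects:
        if eff.region in ("g_tract", "loop") and eff.snv_type:
            table.loc[eff.snv_type, eff.region] += 1
    return table


def g_run_stability(seq: str) -> float:
    """Built-in G4 stability score: mean per-base G-run(+)/C-run(-) score.

    Each base inside a run of k identical G (C) contributes +min(k, 4)
    (-min(k, 4)); other bases contribute 0. Higher = more stable on the
    forward strand.
    """
    seq = seq.upper()
    total = 0.0
    i = 0
    n = len(seq)
    while i < n:
        b = seq[i]
        j = i
        while j < n and seq[j] == b:
            j += 1
        run = j - i
        if b == "G":
            total += run * min(run, 4)
        elif b == "C":
            total -= run * min(run, 4)
        i = j
    return total / n if n else 0.0


StabilityScorer = Callable[[str], float]


def stability_delta(
    motif_window_ref: str,
    motif_window_alt: str,
    scorer: StabilityScorer = g_run_stability,
    tol: float = 0.0,
) -> tuple[float, float, float, str]:
    """Score REF/ALT windows; delta = alt - ref (higher = more stable)."""
    if len(motif_window_ref) != len(motif_window_alt):
        raise ValueError("windows must have equal length")
    ndiff = sum(a != b for a, b in zip(motif_window_ref, motif_window_alt))
    if ndiff != 1:
        raise ValueError(f"windows must differ at exactly one position (got {ndiff})")
    s_ref = scorer(motif_window_ref)
    s_alt = scorer(motif_window_alt)
    delta = s_alt - s_ref
    if delta < -tol:
        call = "destabilizing"
    elif delta > tol:
        call = "stabilizing"
    else:
        call = "neutral"
    return s_ref, s_alt, delta, call


def detect_gain_loss(
    snv: SNVRecord,
    genome: Mapping[str, str],
    flank: int = 30,
    min_tract: int = 3,
    max_loop: int = 7,
):
    """Compare pG4 motifs in the +-``flank`` nt window around an SNV.

    Returns ``(gained, lost, motifs_ref, motifs_alt)`` where gained means a
    motif (keyed by coordinates + strand) present with ALT but not REF.
    """
    seq = str(genome[snv.chrom])
    lo = max(0, snv.pos - flank)
    hi = min(len(seq), snv.pos + flank + 1)
    window = seq[lo:hi].upper()
    offset = snv.pos - lo
    if window[offset] != snv.ref:
        raise ValueError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: genome has "
            f"{window[offset]}, SNV says {snv.ref}"
        )
    alt_window = window[:offset] + snv.alt + window[offset + 1 :]
    motifs_ref = scan_pg4(window, snv.chrom, lo, min_tract, max_loop, True)
    motifs_alt = scan_pg4(alt_window, snv.chrom, lo, min_tract, max_loop, True)
    key = lambda m: (m.start, m.end, m.strand)
    ref_keys = {key(m) for m in motifs_ref}
    alt_keys = {key(m) for m in motifs_alt}
    gained = bool(alt_keys - ref_keys)
    lost = bool(ref_keys - alt_keys)
    return gained, lost, motifs_ref, motifs_alt


@dataclass(frozen=True)
class EnrichmentScoreInput:
    n_g4_region: int
    n_g4_total: int
    n_bc_region: int
    n_bc_total: int

    def __post_init__(self) -> None:
        if min(self.n_g4_region, self.n_g4_total, self.n_bc_region, self.n_bc_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_g4_region > self.n_g4_total or self.n_bc_region > self.n_bc_total:
            raise ValueError("region counts cannot exceed totals")
        if self.n_g4_total == 0 or self.n_bc_total == 0:
            raise ValueError("totals must be positive")


def region_enrichment_score(inp: EnrichmentScoreInput) -> tuple[float, TestResult]:
    """Ratio of region proportions (G4-linked vs background SNVs) + Fisher p.

    score = (n_g4_region / n_g4_total) / (n_bc_region / n_bc_total);
    values > 1 flag over-representation of G4-linked SNVs in the region.
    """
    if inp.n_bc_region == 0:
        score = float("nan")
    else:
        score = (inp.n_g4_region / inp.n_g4_total) / (inp.n_bc_region / inp.n_bc_total)
    test = fisher_exact_two_sided(
        ContingencyTable2x2(
            inp.n_g4_region,
            inp.n_g4_total - inp.n_g4_region,
            inp.n_bc_region,
            inp.n_bc_total - inp.n_bc_region,
        )
    )
    return score, test


def evaluate_snvs(
    snvs: Sequence[SNVRecord],
    genome: Mapping[str, str],
    motifs: Sequence[PQSMotif],
    flank: int = 30,
    scorer: StabilityScorer = g_run_stability,
    tol: float = 0.0,
) -> list[SNVG4Effect]:
    """Full per-SNV evaluation: region, type, stability delta, gain/loss."""
    from bisect import bisect_left, bisect_right

    by_chrom: dict[str, list[PQSMotif]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda m: (m.start, m.end))
        starts[chrom] = [m.start for m in ms]
        max_len[chrom] = max(m.end - m.start for m in ms)

    def candidates(snv: SNVRecord) -> list[PQSMotif]:
        ms = by_chrom.get(snv.chrom)
        if not ms:
            return []
        st = starts[snv.chrom]
        lo = bisect_left(st, snv.pos - max_len[snv.chrom])
        hi = bisect_right(st, snv.pos)
        return ms[lo:hi]

    out: list[SNVG4Effect] = []
    for snv in snvs:
        region, motif = classify_snv(snv, candidates(snv))
        gained, lost, _, _ = detect_gain_loss(snv, genome, flank)
        seq = str(genome[snv.chrom])
        if motif is not None:
            w_ref = seq[motif.start : motif.end].upper()
            off = snv.pos - motif.start
            w_alt = w_ref[:off] + snv.alt + w_ref[off + 1 :]
            if motif.strand == "-":
                w_ref, w_alt = reverse_complement(w_ref), reverse_complement(w_alt)
            s_ref, s_alt, delta, call = stability_delta(w_ref, w_alt, scorer, tol)
            stype = motif_strand_type(snv, motif.strand)
        else:
            s_ref = s_alt = delta = 0.0
            call = "neutral"
            stype = ""
        out.append(
            SNVG4Effect(snv, motif, region, stype, s_ref, s_alt, delta, call, gained, lost)
        )
    return out
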