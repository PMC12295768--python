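"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a small genome
with gene models, G4 peak files, negative-binomial count matrices with a
G4-linked expression effect, TF ChIP peak sets with tunable
promoter/first-intron complementarity, and SNV tables with a tunable
G-tract bias. All generators are pure functions of (config, seed): a
single integer seed feeds a named substream per generator, so adding a
generator never perturbs the others, and text outputs are byte-identical
across runs.

What the generator emulates (and what it does not): gene transcripts
average ~7.6 introns with first introns drawn markedly longer than
downstream ones; canonical pG4 motifs are embedded at feature-specific
rates with a 5'-biased Beta position inside first introns; expression is
negative-binomial with a mean shift in tumor samples for genes carrying a
promoter or first-intron G4. It does not attempt realistic human chromatin,
mutational signatures beyond a single G>A dial, or real cohort library-size
distributions.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .expression import CountMatrix
from .genes import GeneModel, write_gene_models_tsv
from .intervals import GenomicInterval, write_bed
from .tf import TFPeakSet
from .variants import SNVRecord, reverse_complement, scan_pg4

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "synth_genome_and_genes",
    "synth_g4_peaks",
    "synth_counts",
    "synth_tf_peaks",
    "synth_snvs",
    "write_outputs",
]

# substream ids: appending new generators must not renumber existing ones
_STREAMS = {
    "genome": 0,
    "genes": 1,
    "g4": 2,
    "peaks": 3,
    "counts": 4,
    "tf": 5,
    "snv": 6,
    "baseline": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class ExpressionConfig:
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    g4_log2_effect: float = 1.0
    n_per_group: int = 30


@dataclass
class TFConfig:
    n_tfs: int = 20
    base_rate: float = 0.08  # binding prob to downstream-intron G4s
    p_low: float = 0.05  # per-gene binding prob range for promoter/intron1
    p_high: float = 0.6
    complementarity_rho: float = -0.5  # rank correlation of (p_prom, p_int)
    peak_halfwidth: int = 75
    background_peaks_per_tf: int = 50


@dataclass
class SNVConfig:
    n_snvs: int = 5000
    tract_fraction: float = 0.5
    loop_fraction: float = 0.35  # remainder after tract+loop is background
    g_to_a_bias: float = 0.6
    n_gain: int = 30
    n_loss: int = 30


@dataclass
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    mean_introns: float = 7.6
    promoter_window: int = 1000
    gc_content: float = 0.41
    # expected embedded-motif counts per feature (Poisson); the first-intron
    # rate is set for a ~3x per-base motif density over downstream introns
    # (first introns are drawn ~3x longer, so the per-feature rate is 9x)
    g4_rates: dict = field(
        default_factory=lambda: {"promoter": 0.6, "intron_1": 1.35, "intron_other": 0.15}
    )
    intron1_5prime_beta: tuple[float, float] = (1.0, 4.0)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    tf: TFConfig = field(default_factory=TFConfig)
    snv: SNVConfig = field(default_factory=SNVConfig)


@dataclass
class G4Placement:
    gene_id: str | None
    feature: str  # promoter | intron_1 | intron_other
    chrom: str
    start: int
    end: int
    strand: str  # strand whose sequence is G-rich


@dataclass
class SynthTruth:
    config: SynthConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    g4_placements: list[G4Placement]
    gain_loss_sites: list[dict]
    gene_baseline: dict[str, float] = field(default_factory=dict)
    gene_g4_linked: dict[str, bool] = field(default_factory=dict)
    tf_propensities: dict[str, tuple[float, float]] = field(default_factory=dict)
    snv_truth: list[dict] = field(default_factory=list)

    def placements_for(self, gene_id: str, feature: str) -> list[G4Placement]:
        return [
            p for p in self.g4_placements if p.gene_id == gene_id and p.feature == feature
        ]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _motif_sequence(rng: np.random.Generator) -> tuple[str, list[int]]:
    """Canonical pG4 with tract lengths 3-4 and loops 1-7 over {A,C,T}."""
    tracts = rng.integers(3, 5, size=4)
    loops = rng.integers(1, 8, size=3)
    loop_bases = np.array(list("ACT"))
    parts: list[str] = []
    lens: list[int] = []
    for i in range(4):
        parts.append("G" * int(tracts[i]))
        lens.append(int(tracts[i]))
        if i < 3:
            loop = "".join(rng.choice(loop_bases, size=int(loops[i])))
            parts.append(loop)
            lens.append(int(loops[i]))
    return "".join(parts), lens


def _write_seq(genome: np.ndarray, start: int, seq: str) -> None:
    genome[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")


def synth_genome_and_genes(config: SynthConfig) -> SynthTruth:
    """Generate the genome, gene models, embedded G4s and gain/loss sites."""
    rng_genome = _rng(config.seed, "genome")
    rng_genes = _rng(config.seed, "genes")
    rng_g4 = _rng(config.seed, "g4")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {
        c: _random_sequence(rng_genome, config.chrom_length, config.gc_content)
        for c in chrom_names
    }

    genes: list[GeneModel] = []
    per_chrom = int(math.ceil(config.n_genes / config.n_chroms))
    gi = 0
    p_intron = 1.0 / config.mean_introns
    for chrom in chrom_names:
        cursor = config.promoter_window + 500
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            n_introns = int(rng_genes.geometric(p_intron))
            n_exons = n_introns + 1
            exon_lens = np.maximum(
                rng_genes.lognormal(math.log(150), 0.4, size=n_exons).astype(int), 30
            )
            intron_lens = np.maximum(
                rng_genes.lognormal(math.log(400), 0.6, size=n_introns).astype(int), 80
            )
            strand = "+" if rng_genes.random() < 0.5 else "-"
            # first intron (transcription direction) drawn longer: 3x median
            if n_introns > 0:
                first_idx = 0 if strand == "+" else n_introns - 1
                intron_lens[first_idx] = max(
                    int(rng_genes.lognormal(math.log(1200), 0.6)), 200
                )
            span = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng_genes.integers(800, 3000))
            start = cursor + config.promoter_window
            if start + span + config.promoter_window + 500 > config.chrom_length:
                raise ValueError(
                    f"genes overflow {chrom}: increase chrom_length or reduce n_genes"
                )
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
                )
                pos += int(exon_lens[k])
                if k < n_introns:
                    pos += int(intron_lens[k])
            gene = GeneModel(f"G{gi + 1:04d}", chrom, strand, exons, config.promoter_window)
            genes.append(gene)
            cursor = pos + gap
            gi += 1

    # embed G4 motifs: Poisson counts per feature at the configured rates,
    # skipping placements that would overwrite an already-planted motif
    placements: list[G4Placement] = []
    alpha, beta = config.intron1_5prime_beta
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def _collides(chrom: str, start: int, end: int) -> bool:
        from bisect import bisect_left

        occ = occupied[chrom]
        i = bisect_left(occ, (start, start))
        for s, e in occ[max(0, i - 1) : i + 1]:
            if s < end + 1 and start - 1 < e:
                return True
        return False

    for gene in genes:
        arr = arrays[gene.chrom]

        def embed(feature: str, region: GenomicInterval, biased: bool) -> None:
            seq, _lens = _motif_sequence(rng_g4)
            if len(region) < len(seq) + 2:
                return
            for _attempt in range(4):
                if biased:
                    off = int(
                        round(float(rng_g4.beta(alpha, beta)) * (len(region) - len(seq)))
                    )
                else:
                    off = int(rng_g4.integers(0, len(region) - len(seq) + 1))
                # offset measured from the feature's 5' end
                if region.strand == "-":
                    start = region.end - off - len(seq)
                else:
                    start = region.start + off
                if not _collides(gene.chrom, start, start + len(seq)):
                    break
            else:
                return
            motif_strand = "+" if rng_g4.random() < 0.5 else "-"
            written = seq if motif_strand == "+" else reverse_complement(seq)
            _write_seq(arr, start, written)
            from bisect import insort

            insort(occupied[gene.chrom], (start, start + len(seq)))
            placements.append(
                G4Placement(gene.gene_id, feature, gene.chrom, start, start + len(seq), motif_strand)
            )

        for _ in range(int(rng_g4.poisson(config.g4_rates.get("promoter", 0.0)))):
            embed("promoter", gene.promoter, False)
        introns = gene.introns
        if introns:
            for _ in range(int(rng_g4.poisson(config.g4_rates.get("intron_1", 0.0)))):
                embed("intron_1", introns[0], True)
            for intr in introns[1:]:
                for _ in range(int(rng_g4.poisson(config.g4_rates.get("intron_other", 0.0)))):
                    embed("intron_other", intr, False)

    # plant gain/loss constructs in intergenic space after the last gene
    gain_loss: list[dict] = []
    snv_cfg = config.snv
    pad = "T" * 8  # isolates constructs: no loop (<=7 nt) can bridge them
    n_gain_pc = int(math.ceil(snv_cfg.n_gain / config.n_chroms))
    n_loss_pc = int(math.ceil(snv_cfg.n_loss / config.n_chroms))
    for chrom in chrom_names:
        arr = arrays[chrom]
        last_gene_end = max(
            (g.end for g in genes if g.chrom == chrom), default=0
        )
        cursor = last_gene_end + 2 * config.promoter_window
        for kind, count in (("gain", n_gain_pc), ("loss", n_loss_pc)):
            for _ in range(count):
                seq, _lens = _motif_sequence(rng_g4)
                if kind == "gain":
                    # plant the motif with its 4th tract broken at the middle
                    # G; the SNV restores it (ref A -> alt G)
                    run_end = len(seq)
                    run_start = run_end
                    while run_start > 0 and seq[run_start - 1] == "G":
                        run_start -= 1
                    mid = (run_start + run_end) // 2
                    construct = pad + seq[:mid] + "A" + seq[mid + 1 :] + pad
                    snv_off = len(pad) + mid
                    ref, alt = "A", "G"
                else:
                    # full motif planted; the SNV breaks tract 2's middle G
                    s2, e2 = _g_runs(seq)[1]
                    mid = (s2 + e2) // 2
                    construct = pad + seq + pad
                    snv_off = len(pad) + mid
                    ref, alt = "G", "A"
                if cursor + len(construct) > config.chrom_length - 100:
                    raise ValueError(f"gain/loss constructs overflow {chrom}")
                _write_seq(arr, cursor, construct)
                gain_loss.append(
                    {
                        "kind": kind,
                        "chrom": chrom,
                        "pos": cursor + snv_off,
                        "ref": ref,
                        "alt": alt,
                    }
                )
                cursor += len(construct) + int(rng_g4.integers(20, 40))

    genome = {c: arrays[c].tobytes().decode() for c in chrom_names}
    truth = SynthTruth(config, genome, genes, placements, gain_loss)

    rng_baseline = _rng(config.seed, "baseline")
    for gene in genes:
        truth.gene_baseline[gene.gene_id] = float(
            rng_baseline.lognormal(math.log(config.expression.baseline_mean), 1.0)
        )
        truth.gene_g4_linked[gene.gene_id] = bool(
            truth.placements_for(gene.gene_id, "promoter")
            or truth.placements_for(gene.gene_id, "intron_1")
        )
    return truth


def _g_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def synth_g4_peaks(
    truth: SynthTruth, jitter: int = 10, decoy_rate: float = 0.1
) -> list[GenomicInterval]:
    """One peak per embedded motif (boundaries jittered) plus decoy peaks.

    Peak names record provenance: ``m<i>`` for planted motifs, ``decoy<i>``
    for decoys.
    """
    rng = _rng(truth.config.seed, "peaks")
    peaks: list[GenomicInterval] = []
    for i, pl in enumerate(truth.g4_placements):
        if jitter > 0:
            ds = int(rng.integers(-jitter, jitter + 1))
            de = int(rng.integers(-jitter, jitter + 1))
        else:
            ds = de = 0
        start = max(0, pl.start + ds)
        end = min(truth.config.chrom_length, pl.end + de)
        if end <= start:
            start, end = pl.start, pl.end
        peaks.append(GenomicInterval(pl.chrom, start, end, ".", f"m{i}"))
    n_decoys = int(round(decoy_rate * len(truth.g4_placements)))
    chroms = sorted(truth.genome)
    for i in range(n_decoys):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        width = int(rng.integers(20, 40))
        start = int(rng.integers(0, truth.config.chrom_length - width))
        peaks.append(GenomicInterval(chrom, start, start + width, ".", f"decoy{i}"))
    return peaks


def synth_counts(truth: SynthTruth, config: SynthConfig | None = None) -> CountMatrix:
    """Negative-binomial counts: tumor vs NAT, G4-linked genes shifted up.

    Genes carrying a promoter or first-intron G4 get a ``g4_log2_effect``
    mean shift in tumor samples; library sizes vary +-30%.
    """
    config = config or truth.config
    expr = config.expression
    if expr.n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    rng = _rng(config.seed, "counts")
    gene_ids = [g.gene_id for g in truth.genes]
    n = expr.n_per_group
    sample_ids = [f"tumor{i + 1}" for i in range(n)] + [f"nat{i + 1}" for i in range(n)]
    condition = {s: ("tumor" if s.startswith("tumor") else "nat") for s in sample_ids}
    lib_factor = rng.uniform(0.7, 1.3, size=2 * n)
    r = 1.0 / expr.dispersion
    counts = np.zeros((len(gene_ids), 2 * n), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        mu = truth.gene_baseline[gid]
        effect = 2.0**expr.g4_log2_effect if truth.gene_g4_linked[gid] else 1.0
        mus = np.where(np.arange(2 * n) < n, mu * effect, mu) * lib_factor
        p = r / (r + mus)
        counts[i] = rng.negative_binomial(r, p)
    return CountMatrix(gene_ids, sample_ids, counts, condition)


def synth_tf_peaks(
    truth: SynthTruth, config: SynthConfig | None = None
) -> list[TFPeakSet]:
    """TF peak sets whose promoter/intron-1 binding propensities are
    rank-correlated ``complementarity_rho`` per gene (Gaussian copula)."""
    config = config or truth.config
    tfc = config.tf
    if tfc.n_tfs < 2:
        raise ValueError("need n_tfs >= 2")
    rng = _rng(config.seed, "tf")
    rho = tfc.complementarity_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    from scipy.stats import norm

    tf_names = [f"TF{i + 1:02d}" for i in range(tfc.n_tfs)]
    peaks: dict[str, list[GenomicInterval]] = {t: [] for t in tf_names}
    hw = tfc.peak_halfwidth

    def add_peak(tf: str, g4: G4Placement) -> None:
        mid = int(rng.integers(g4.start, g4.end))
        start = max(0, mid - hw)
        peaks[tf].append(GenomicInterval(g4.chrom, start, mid + hw + 1, ".", tf))

    for gene in truth.genes:
        z = chol @ rng.standard_normal(2)
        u = norm.cdf(z)
        p_prom = tfc.p_low + (tfc.p_high - tfc.p_low) * float(u[0])
        p_int = tfc.p_low + (tfc.p_high - tfc.p_low) * float(u[1])
        truth.tf_propensities[gene.gene_id] = (p_prom, p_int)
        proms = truth.placements_for(gene.gene_id, "promoter")
        ints = truth.placements_for(gene.gene_id, "intron_1")
        others = truth.placements_for(gene.gene_id, "intron_other")
        # binding decided at the gene level (per-gene TF counts are then
        # Binomial(n_tfs, p) as designed); the peak lands in one randomly
        # chosen G4 of that class so every region sees coverage
        for tf in tf_names:
            if proms and rng.random() < p_prom:
                add_peak(tf, proms[int(rng.integers(len(proms)))])
            if ints and rng.random() < p_int:
                add_peak(tf, ints[int(rng.integers(len(ints)))])
            for other in others:
                if rng.random() < tfc.base_rate:
                    add_peak(tf, other)
    chroms = sorted(truth.genome)
    for tf in tf_names:
        for _ in range(tfc.background_peaks_per_tf):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            mid = int(rng.integers(hw, config.chrom_length - hw - 1))
            peaks[tf].append(GenomicInterval(chrom, mid - hw, mid + hw + 1, ".", tf))
    return [TFPeakSet(t, peaks[t]) for t in tf_names]


def synth_snvs(
    truth: SynthTruth, config: SynthConfig | None = None
) -> list[SNVRecord]:
    """SNVs with a G-tract placement bias and a G>A substitution bias.

    Truth labels (g_tract / loop / background, the planted substitution on
    the motif strand, and planted gain/loss flags) are recorded in
    ``truth.snv_truth``. Region labels are defined against motifs scanned
    from the realized genome, so downstream classification can recover them
    exactly; loop positions are restricted to A/T reference bases so no
    opposite-strand G-tract can own them.
    """
    config = config or truth.config
    cfg = config.snv
    rng = _rng(config.seed, "snv")
    motifs = []
    for chrom in sorted(truth.genome):
        motifs.extend(scan_pg4(truth.genome[chrom], chrom, 0))
    tract_positions: list[tuple[str, int, str]] = []  # (chrom, pos, motif_strand)
    loop_positions: list[tuple[str, int, str]] = []
    for m in motifs:
        seq = truth.genome[m.chrom]
        for s, e in m.tracts:
            for pos in range(s, e):
                tract_positions.append((m.chrom, pos, m.strand))
        for s, e in m.loops:
            for pos in range(s, e):
                if seq[pos] in "AT":
                    loop_positions.append((m.chrom, pos, m.strand))

    n_gl = len(truth.gain_loss_sites)
    n_free = max(cfg.n_snvs - n_gl, 0)
    n_tract = int(round(cfg.tract_fraction * n_free))
    n_loop = int(round(cfg.loop_fraction * n_free))
    n_bg = n_free - n_tract - n_loop

    records: list[SNVRecord] = []
    truth.snv_truth = []

    def motif_strand_base(chrom: str, pos: int, strand: str) -> str:
        b = truth.genome[chrom][pos]
        return b if strand == "+" else b.translate(str.maketrans("ACGT", "TGCA"))

    idx = rng.choice(len(tract_positions), size=min(n_tract, len(tract_positions)), replace=False)
    for i in idx:
        chrom, pos, strand = tract_positions[int(i)]
        alt_m = "A" if rng.random() < cfg.g_to_a_bias else ("C" if rng.random() < 0.5 else "T")
        ref_g = truth.genome[chrom][pos]  # G on + motifs, C on - motifs
        alt_g = alt_m if strand == "+" else alt_m.translate(str.maketrans("ACGT", "TGCA"))
        records.append(SNVRecord(chrom, pos, ref_g, alt_g))
        truth.snv_truth.append(
            {"region": "g_tract", "type": f"G>{alt_m}", "gain": None, "loss": None}
        )
    idx = rng.choice(len(loop_positions), size=min(n_loop, len(loop_positions)), replace=False)
    for i in idx:
        chrom, pos, strand = loop_positions[int(i)]
        ref_g = truth.genome[chrom][pos]
        alt_g = str(rng.choice([b for b in "ACGT" if b != ref_g]))
        ref_m = motif_strand_base(chrom, pos, strand)
        alt_m = alt_g if strand == "+" else alt_g.translate(str.maketrans("ACGT", "TGCA"))
        records.append(SNVRecord(chrom, pos, ref_g, alt_g))
        truth.snv_truth.append(
            {"region": "loop", "type": f"{ref_m}>{alt_m}", "gain": None, "loss": None}
        )
    # background SNVs outside any motif
    motif_spans: dict[str, list[tuple[int, int]]] = {}
    for m in motifs:
        motif_spans.setdefault(m.chrom, []).append((m.start, m.end))
    chroms = sorted(truth.genome)
    placed = 0
    while placed < n_bg:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, config.chrom_length))
        if any(s <= pos < e for s, e in motif_spans.get(chrom, ())):
            continue
        ref = truth.genome[chrom][pos]
        if ref not in "ACGT":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        records.append(SNVRecord(chrom, pos, ref, alt))
        truth.snv_truth.append({"region": "background", "type": f"{ref}>{alt}", "gain": None, "loss": None})
        placed += 1
    for site in truth.gain_loss_sites:
        records.append(SNVRecord(site["chrom"], site["pos"], site["ref"], site["alt"]))
        truth.snv_truth.append(
            {
                "region": "background" if site["kind"] == "gain" else "g_tract",
                "type": None,
                "gain": site["kind"] == "gain",
                "loss": site["kind"] == "loss",
            }
        )
    return records


def synth_de_matrix(
    seed: int,
    n_genes: int = 2000,
    n_planted: int = 100,
    log2_effect: float = 3.0,
    n_per_group: int = 30,
    dispersion: float = 0.2,
    baseline_mean: float = 100.0,
) -> tuple[CountMatrix, set[str]]:
    """Plain negative-binomial DE calibration matrix with planted genes.

    The first ``n_planted`` genes get a ``log2_effect`` mean shift in the
    tumor group; library sizes vary +-30%. Returns the matrix and the set
    of planted gene ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
    gene_ids = [f"D{i + 1:05d}" for i in range(n_genes)]
    planted = set(gene_ids[:n_planted])
    n = n_per_group
    sample_ids = [f"tumor{i + 1}" for i in range(n)] + [f"nat{i + 1}" for i in range(n)]
    condition = {s: ("tumor" if s.startswith("tumor") else "nat") for s in sample_ids}
    base = rng.lognormal(math.log(baseline_mean), 1.0, size=n_genes)
    lib = rng.uniform(0.7, 1.3, size=2 * n)
    effect = np.ones(n_genes)
    effect[:n_planted] = 2.0**log2_effect
    mus = base[:, None] * lib[None, :]
    mus[:, :n] *= effect[:, None]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mus))
    return CountMatrix(gene_ids, sample_ids, counts, condition), planted


# ---------------------------------------------------------------------------
# serialization


def write_outputs(truth: SynthTruth, outdir: str) -> dict[str, str]:
    """Write FASTA, gene models, peaks, counts, TF BEDs, SNVs and truth.json."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    fasta = os.path.join(outdir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom in sorted(truth.genome):
            fh.write(f">{chrom}\n")
            seq = truth.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["fasta"] = fasta

    genes_tsv = os.path.join(outdir, "genes.tsv")
    write_gene_models_tsv(truth.genes, genes_tsv)
    paths["genes"] = genes_tsv

    peaks = synth_g4_peaks(truth)
    peaks_bed = os.path.join(outdir, "g4_peaks.bed")
    write_bed(peaks, peaks_bed)
    paths["peaks"] = peaks_bed

    cm = synth_counts(truth)
    counts_tsv = os.path.join(outdir, "counts.tsv")
    cm.to_frame().to_csv(counts_tsv, sep="\t")
    samples_tsv = os.path.join(outdir, "samples.tsv")
    with open(samples_tsv, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in cm.sample_ids:
            fh.write(f"{s}\t{cm.condition[s]}\n")
    paths["counts"], paths["samples"] = counts_tsv, samples_tsv

    tf_dir = os.path.join(outdir, "tf_peaks")
    os.makedirs(tf_dir, exist_ok=True)
    for ts in synth_tf_peaks(truth):
        write_bed(ts.peaks, os.path.join(tf_dir, f"{ts.tf_name}.bed"))
    paths["tf_dir"] = tf_dir

    snvs = synth_snvs(truth)
    snv_tsv = os.path.join(outdir, "snvs.tsv")
    with open(snv_tsv, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for s in snvs:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")
    paths["snvs"] = snv_tsv

    truth_json = os.path.join(outdir, "truth.json")
    payload = {
        "config": asdict(truth.config),
        "g4_placements": [asdict(p) for p in truth.g4_placements],
        "gain_loss_sites": truth.gain_loss_sites,
        "gene_g4_linked": truth.gene_g4_linked,
        "gene_baseline": truth.gene_baseline,
        "tf_propensities": truth.tf_propensities,
        "snv_truth": truth.snv_truth,
    }
    with open(truth_json, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_json
    return paths
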