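"""pG4 scanning, SNV classification, stability deltas, gain/loss."""

import numpy as np
import pytest

from g4reg.stats import TestResult as StatsTestResult
from g4reg.variants import (
    EnrichmentScoreInput,
    PQSMotif,
    SNVRecord,
    classify_snv,
    detect_gain_loss,
    evaluate_snvs,
    g_run_stability,
    region_enrichment_score,
    reverse_complement,
    scan_pg4,
    snv_spectrum,
    stability_delta,
)


def scan_oracle(seq, min_tract=3, max_loop=7):
    """Independent scanner: leftmost start, greedy tracts, lazy loops,
    explicit backtracking, resume after each emitted motif. Returns
    (start, end) spans on the scanned strand."""

    def g_run_len(pos):
        n = 0
        while pos + n < len(seq) and seq[pos + n] == "G":
            n += 1
        return n

    def match_from(pos, part):
        # part 0,2,4,6 are tracts; 1,3,5 loops; returns end or None
        if part == 7:
            return pos
        if part % 2 == 0:
            run = g_run_len(pos)
            if run < min_tract:
                return None
            for take in range(run, min_tract - 1, -1):  # greedy
                end = match_from(pos + take, part + 1)
                if end is not None:
                    return end
            return None
        for take in range(1, max_loop + 1):  # lazy
            if pos + take > len(seq):
                return None
            if any(b not in "ACGT" for b in seq[pos : pos + take]):
                return None
            end = match_from(pos + take, part + 1)
            if end is not None:
                return end
        return None

    spans = []
    pos = 0
    while pos < len(seq):
        end = match_from(pos, 0)
        if end is not None:
            spans.append((pos, end))
            pos = end
        else:
            pos += 1
    return spans


def random_seq(rng, n, gc=0.45):
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )


class TestScan:
    def test_minimal_canonical_motif(self):
        [m] = scan_pg4("GGGAGGGTGGGAGGG", both_strands=False)
        assert (m.start, m.end, m.strand) == (0, 15, "+")
        assert [e - s for s, e in m.tracts] == [3, 3, 3, 3]
        assert [e - s for s, e in m.loops] == [1, 1, 1]

    def test_short_fourth_tract_no_match(self):
        assert scan_pg4("GGGAGGGTGGGAGG", both_strands=False) == []

    def test_c_rich_sequence_matches_minus_strand_only(self):
        motifs = scan_pg4("CCCACCCTCCCACCC")
        assert [m.strand for m in motifs] == ["-"]
        assert (motifs[0].start, motifs[0].end) == (0, 15)

    def test_n_bases_never_match(self):
        assert scan_pg4("GGGNGGGTGGGAGGG", both_strands=False) == []

    def test_matches_backtracking_oracle_on_random_sequences(self, rng):
        for _ in range(15):
            seq = random_seq(rng, 3000, gc=0.55)
            got = [(m.start, m.end) for m in scan_pg4(seq, both_strands=False)]
            assert got == scan_oracle(seq)

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 2000, gc=0.55)
            fwd = scan_pg4(seq)
            rc = scan_pg4(reverse_complement(seq))
            n = len(seq)
            mapped = sorted(
                (n - m.end, n - m.start, "-" if m.strand == "+" else "+") for m in rc
            )
            assert sorted((m.start, m.end, m.strand) for m in fwd) == mapped

    def test_tract_loop_tiling_invariant(self, rng):
        seq = random_seq(rng, 5000, gc=0.6)
        for m in scan_pg4(seq):
            parts = sorted(m.tracts + m.loops)
            assert parts[0][0] == m.start and parts[-1][1] == m.end
            for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
                assert e1 == s2

    def test_genomic_offset_applied(self):
        [m] = scan_pg4("GGGAGGGTGGGAGGG", chrom="chr9", chrom_offset=1000, both_strands=False)
        assert (m.chrom, m.start, m.end) == ("chr9", 1000, 1015)


class TestClassify:
    @staticmethod
    def motif():
        [m] = scan_pg4("GGGAGGGTGGGAGGG", both_strands=False)
        return m

    def test_tract_position(self):
        assert classify_snv(SNVRecord("chr", 5, "G", "A"), [self.motif()])[0] == "g_tract"

    def test_loop_position(self):
        assert classify_snv(SNVRecord("chr", 3, "A", "T"), [self.motif()])[0] == "loop"

    def test_outside_motif(self):
        assert classify_snv(SNVRecord("chr", 15, "A", "T"), [self.motif()])[0] == "outside"

    def test_tract_preferred_over_loop_across_overlapping_motifs(self):
        m1 = self.motif()
        # a second motif shifted so that position 3 (loop of m1) is a tract
        shifted = PQSMotif(
            "chr",
            3,
            18,
            "+",
            tuple((s + 3, e + 3) for s, e in m1.tracts),
            tuple((s + 3, e + 3) for s, e in m1.loops),
        )
        region, owner = classify_snv(SNVRecord("chr", 3, "A", "G"), [m1, shifted])
        assert region == "g_tract" and owner is shifted


class TestSpectrum:
    def test_single_tract_hit(self):
        genome = {"chr": "GGGAGGGTGGGAGGGTTTTT" + "A" * 40}
        motifs = scan_pg4(genome["chr"], "chr")
        effects = evaluate_snvs([SNVRecord("chr", 1, "G", "A")], genome, motifs)
        table = snv_spectrum(effects)
        assert table.loc["G>A", "g_tract"] == 1
        assert table.to_numpy().sum() == 1

    def test_empty_input_all_zero(self):
        assert snv_spectrum([]).to_numpy().sum() == 0

    def test_minus_strand_types_normalized_to_motif_strand(self):
        # C-rich plus strand: motif lives on the minus strand; a genomic
        # C>T inside a tract is a G>A on the motif strand
        genome = {"chr": "CCCACCCTCCCACCC" + "T" * 46}
        motifs = scan_pg4(genome["chr"], "chr")
        effects = evaluate_snvs([SNVRecord("chr", 1, "C", "T")], genome, motifs)
        assert effects[0].region == "g_tract"
        assert effects[0].snv_type == "G>A"
        table = snv_spectrum(effects)
        assert table.loc["G>A", "g_tract"] == 1


class TestStability:
    def test_tract_break_destabilizes(self):
        ref = "GGGAGGGTGGGAGGG"
        alt = ref[:5] + "A" + ref[6:]
        s_ref, s_alt, delta, call = stability_delta(ref, alt)
        assert delta < 0 and call == "destabilizing"

    def test_loop_swap_neutral(self):
        ref = "GGGAGGGTGGGAGGG"
        alt = ref[:3] + "T" + ref[4:]
        *_, delta, call = stability_delta(ref, alt)
        assert delta == 0 and call == "neutral"

    def test_tract_extension_stabilizes(self):
        ref = "GGGAGGGTGGGAGGG"
        alt = ref[:3] + "G" + ref[4:]
        *_, delta, call = stability_delta(ref, alt)
        assert delta > 0 and call == "stabilizing"

    def test_any_tract_g_loss_nonpositive(self, rng):
        ref = "TTGGGGAGGGTGGGAGGGTT"
        for i, b in enumerate(ref):
            if b != "G":
                continue
            for alt_base in "ACT":
                alt = ref[:i] + alt_base + ref[i + 1 :]
                *_, delta, _ = stability_delta(ref, alt)
                assert delta <= 0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            stability_delta("GGGA", "GGG")
        with pytest.raises(ValueError):
            stability_delta("GGGA", "GCCA")

    def test_c_runs_score_negative(self):
        assert g_run_stability("CCCC") < 0 < g_run_stability("GGGG")


class TestGainLoss:
    def test_completing_fourth_tract_gains(self):
        seq = "T" * 10 + "GGGAGGGTGGGAGAG" + "T" * 10
        genome = {"c": seq}
        pos = 23  # the middle A of the trailing G-A-G; A>G completes tract 4
        snv = SNVRecord("c", pos, "A", "G")
        gained, lost, _, _ = detect_gain_loss(snv, genome)
        assert gained and not lost

    def test_breaking_tract_loses(self):
        seq = "T" * 10 + "GGGAGGGTGGGAGGG" + "T" * 10
        genome = {"c": seq}
        snv = SNVRecord("c", 11, "G", "A")
        gained, lost, _, _ = detect_gain_loss(snv, genome)
        assert lost and not gained

    def test_loop_substitution_changes_nothing(self):
        seq = "T" * 10 + "GGGAGGGTGGGAGGG" + "T" * 10
        snv = SNVRecord("c", 13, "A", "T")  # loop 1
        gained, lost, _, _ = detect_gain_loss(snv, {"c": seq})
        assert not gained and not lost

    def test_ref_alt_swap_swaps_flags(self):
        seq = "T" * 10 + "GGGAGGGTGGGAGAG" + "T" * 10
        pos = 23
        snv = SNVRecord("c", pos, "A", "G")
        gained, lost, _, _ = detect_gain_loss(snv, {"c": seq})
        mutated = seq[:pos] + "G" + seq[pos + 1 :]
        back = SNVRecord("c", pos, "G", "A")
        gained2, lost2, _, _ = detect_gain_loss(back, {"c": mutated})
        assert (gained, lost) == (gained2, lost2)[::-1] == (True, False)

    def test_reference_mismatch_named_position(self):
        with pytest.raises(ValueError, match="7"):
            detect_gain_loss(SNVRecord("c", 7, "G", "A"), {"c": "A" * 40})


class TestEnrichmentScore:
    def test_proportional_counts_score_one(self):
        score, _ = region_enrichment_score(EnrichmentScoreInput(5, 100, 50, 1000))
        assert score == pytest.approx(1.0)

    def test_tenfold(self):
        score, _ = region_enrichment_score(EnrichmentScoreInput(10, 100, 10, 1000))
        assert score == pytest.approx(10.0)

    def test_random_fixtures_equal_direct_formula(self, rng):
        for _ in range(25):
            g4t = int(rng.integers(10, 500))
            bct = int(rng.integers(500, 5000))
            g4r = int(rng.integers(0, g4t + 1))
            bcr = int(rng.integers(1, bct + 1))
            score, test = region_enrichment_score(EnrichmentScoreInput(g4r, g4t, bcr, bct))
            assert score == pytest.approx((g4r / g4t) / (bcr / bct))
            assert isinstance(test, StatsTestResult) and 0 <= test.p_value <= 1

    def test_zero_background_region_flagged(self):
        score, _ = region_enrichment_score(EnrichmentScoreInput(5, 100, 0, 1000))
        assert np.isnan(score)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentScoreInput(5, 4, 1, 10)


class TestSNVRecord:
    def test_identical_ref_alt_rejected(self):
        with pytest.raises(ValueError):
            SNVRecord("c", 0, "G", "G")

    def test_non_base_rejected(self):
        with pytest.raises(ValueError):
            SNVRecord("c", 0, "G", "N")
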