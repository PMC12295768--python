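"""TMM/CPM normalization and Wilcoxon differential expression."""

import numpy as np
import pytest

from g4reg import synth as sy
from g4reg.expression import (
    CountMatrix,
    cpm_matrix,
    deg_g4_enrichment,
    expression_by_group,
    g4_status_groups,
    tmm_factors,
    wilcoxon_de,
)
from g4reg.intervals import GenomicInterval, count_overlaps


def tmm_oracle(mat):
    """Clean-room TMM straight from the definition (loops, no vectorizing)."""
    import math

    n_genes, n_samples = len(mat), len(mat[0])
    lib = [sum(mat[g][s] for g in range(n_genes)) for s in range(n_samples)]

    def quantile07(values, p):
        xs = sorted(values)
        h = (len(xs) - 1) * p
        lo = int(math.floor(h))
        if lo + 1 >= len(xs):
            return float(xs[lo])
        return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])

    f75 = [quantile07([mat[g][s] for g in range(n_genes)], 0.75) / lib[s] for s in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean75))

    def avg_rank(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(values):
            j = i
            while j < len(values) and values[order[j]] == values[order[i]]:
                j += 1
            for k in range(i, j):
                ranks[order[k]] = (i + j + 1) / 2
            i = j
        return ranks

    log_factors = []
    for s in range(n_samples):
        if s == ref:
            log_factors.append(0.0)
            continue
        ms, aa, ws = [], [], []
        for g in range(n_genes):
            x, r = mat[g][s], mat[g][ref]
            if x > 0 and r > 0:
                ms.append(math.log2((x / lib[s]) / (r / lib[ref])))
                aa.append(0.5 * math.log2((x / lib[s]) * (r / lib[ref])))
                ws.append((lib[s] - x) / (lib[s] * x) + (lib[ref] - r) / (lib[ref] * r))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            log_factors.append(0.0)
            continue
        n = len(ms)
        lo_l, lo_s = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rm, ra = avg_rank(ms), avg_rank(aa)
        num = den = 0.0
        for k in range(n):
            if lo_l <= rm[k] <= hi_l and lo_s <= ra[k] <= hi_s:
                num += ms[k] / ws[k]
                den += 1.0 / ws[k]
        log_factors.append(num / den if den else 0.0)
    mean_log = sum(log_factors) / n_samples
    return [2.0 ** (f - mean_log) for f in log_factors]


class TestTMM:
    def test_identical_columns_unit_factors(self):
        mat = np.tile(np.arange(1, 101)[:, None], (1, 4))
        assert tmm_factors(mat) == pytest.approx(np.ones(4))

    def test_library_size_scaling_cancels(self, rng):
        col = rng.integers(1, 500, size=200)
        mat = np.column_stack([col, 2 * col])
        assert tmm_factors(mat) == pytest.approx(np.ones(2))

    def test_matches_clean_room_oracle(self, rng):
        for _ in range(10):
            mat = rng.negative_binomial(5, 0.05, size=(150, 4)).astype(float)
            mat[rng.uniform(size=mat.shape) < 0.1] = 0
            mat = mat[mat.sum(axis=1) > 0]
            got = tmm_factors(mat)
            want = tmm_oracle(mat.tolist())
            assert got == pytest.approx(want, abs=1e-10)

    def test_geometric_mean_one(self, rng):
        mat = rng.negative_binomial(5, 0.02, size=(300, 6)).astype(float)
        f = tmm_factors(mat)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        mat = np.ones((10, 3))
        mat[:, 1] = 0
        with pytest.raises(ValueError):
            tmm_factors(mat)


class TestCPM:
    def test_simple_scaling(self):
        mat = np.array([[10.0]])
        # library of 10 scaled to a million
        assert cpm_matrix(mat)[0, 0] == pytest.approx(1e6)

    def test_doubling_counts_leaves_cpm_unchanged(self, rng):
        mat = rng.integers(1, 100, size=(50, 3)).astype(float)
        doubled = mat.copy()
        doubled[:, 0] *= 2
        assert cpm_matrix(doubled)[:, 0] == pytest.approx(cpm_matrix(mat)[:, 0])

    def test_unit_factor_columns_sum_to_million(self, rng):
        mat = rng.integers(0, 100, size=(80, 4)).astype(float)
        assert cpm_matrix(mat).sum(axis=0) == pytest.approx(np.full(4, 1e6))


def _null_matrix(rng, n_genes=300, n=10):
    cm, _ = sy.synth_de_matrix(
        seed=int(rng.integers(2**31)), n_genes=n_genes, n_planted=0, n_per_group=n
    )
    return cm


class TestWilcoxonDE:
    def test_identical_groups_no_calls(self, rng):
        cm = _null_matrix(rng)
        res = wilcoxon_de(cm, cm.samples_with("tumor"), cm.samples_with("nat"))
        assert all(r.status == "ns" for r in res)

    def test_overlapping_groups_rejected(self, rng):
        cm = _null_matrix(rng)
        with pytest.raises(ValueError):
            wilcoxon_de(cm, cm.sample_ids[:5], cm.sample_ids[4:9])

    def test_planted_eightfold_genes_detected(self):
        cm, planted = sy.synth_de_matrix(seed=42, n_genes=600, n_planted=60)
        res = wilcoxon_de(cm, cm.samples_with("tumor"), cm.samples_with("nat"))
        up = {r.gene_id for r in res if r.status == "up"}
        assert len(up & planted) >= 0.9 * len(planted)
        # false calls kept rare by the fold filter + FDR cut
        assert len(up - planted) <= max(1, 0.05 * len(up))

    def test_effect_size_recovery(self):
        """Planted log2 shifts are recovered by group mean differences."""
        for delta in (0.0, 0.5, 1.0):
            cm, planted = sy.synth_de_matrix(
                seed=7, n_genes=600, n_planted=300, log2_effect=delta
            )
            f = tmm_factors(cm)
            lcpm = cpm_matrix(cm, f, log=True)
            n = len(cm.samples_with("tumor"))
            planted_rows = [i for i, g in enumerate(cm.gene_ids) if g in planted]
            others = [i for i, g in enumerate(cm.gene_ids) if g not in planted]
            diff = lcpm[:, :n].mean(axis=1) - lcpm[:, n:].mean(axis=1)
            est = diff[planted_rows].mean() - diff[others].mean()
            assert abs(est - delta) < 0.15


class TestG4StatusGroups:
    def test_promoter_only_and_both(self, default_truth):
        gene = next(g for g in default_truth.genes if g.introns)
        prom, intr = gene.promoter, gene.intron(1)
        peaks_p = [GenomicInterval(prom.chrom, prom.start + 5, prom.start + 25)]
        combined, _ = g4_status_groups([gene], peaks_p)
        assert combined[gene.gene_id] == "promoter_only"
        # one peak spanning promoter..first intron counts for both
        span = [GenomicInterval(prom.chrom, prom.end - 10, intr.start + 10)]
        combined, isplit = g4_status_groups([gene], span)
        if gene.strand == "+":
            assert combined[gene.gene_id] == "both"
            assert isplit[gene.gene_id] == "intron1_g4"

    def test_matches_brute_force_overlap_oracle(self, default_truth, default_peaks):
        genes = default_truth.genes[:80]
        combined, isplit = g4_status_groups(genes, default_peaks)
        for g in genes:
            prom = any(p.overlaps(g.promoter) for p in default_peaks)
            intr_hits = [
                any(p.overlaps(i) for p in default_peaks) for i in g.introns
            ]
            any_i = any(intr_hits)
            want = (
                "both" if prom and any_i else "promoter_only" if prom else "intron_only" if any_i else "neither"
            )
            assert combined[g.gene_id] == want
            want_i = (
                "intron1_g4" if intr_hits and intr_hits[0] else "other_intron_g4" if any_i else "no_intron_g4"
            )
            assert isplit[g.gene_id] == want_i


class TestExpressionByGroup:
    def test_identical_groups_p_one(self, rng):
        lcpm = rng.normal(5, 1, size=(40, 6))
        ids = [f"g{i}" for i in range(40)]
        groups = {f"g{i}": ("a" if i < 20 else "b") for i in range(40)}
        groups_b = {f"g{i}": ("b" if i < 20 else "a") for i in range(40)}
        res = expression_by_group(lcpm, ids, groups, [("a", "b")])
        swapped = expression_by_group(lcpm, ids, groups_b, [("a", "b")])
        assert res[("a", "b")].p_value == pytest.approx(swapped[("a", "b")].p_value)

    def test_planted_shift_detected(self, rng):
        lcpm = rng.normal(5, 1, size=(400, 6))
        lcpm[:200] += 1.0  # +1 log2 unit for group 'g4'
        ids = [f"g{i}" for i in range(400)]
        groups = {f"g{i}": ("g4" if i < 200 else "none") for i in range(400)}
        res = expression_by_group(lcpm, ids, groups, [("g4", "none")])
        assert res[("g4", "none")].p_value < 0.01

    def test_small_group_skipped_with_warning(self, rng):
        lcpm = rng.normal(size=(5, 4))
        groups = {"g0": "a", "g1": "a", "g2": "a", "g3": "b", "g4": "b"}
        with pytest.warns(UserWarning):
            res = expression_by_group(lcpm, list(groups), groups, [("a", "b")])
        assert res == {}


class TestDEGEnrichment:
    def test_reported_promoter_table(self):
        """Up/down DEG counts with promoter G4s give a very small Fisher p."""
        from g4reg.stats import ContingencyTable2x2, fisher_exact_two_sided

        res = fisher_exact_two_sided(ContingencyTable2x2(303, 755, 78, 502))
        assert res.p_value == pytest.approx(8.992e-13, rel=1e-3)
        assert res.p_value < 1e-10

    def test_equal_proportions_p_one(self):
        from g4reg.expression import DEResult

        de = [
            DEResult("a", 3, 1e-5, 1e-4, "up"),
            DEResult("b", 3, 1e-5, 1e-4, "up"),
            DEResult("c", -3, 1e-5, 1e-4, "down"),
            DEResult("d", -3, 1e-5, 1e-4, "down"),
        ]
        groups = {"a": "promoter_only", "b": "neither", "c": "both", "d": "neither"}
        assert deg_g4_enrichment(de, groups, "promoter").p_value == 1.0

    def test_hand_built_table(self):
        from g4reg.expression import DEResult
        from g4reg.stats import ContingencyTable2x2, fisher_exact_two_sided

        de, groups = [], {}
        spec = [("up", True, 8), ("up", False, 2), ("down", True, 1), ("down", False, 9)]
        i = 0
        for status, has_g4, count in spec:
            for _ in range(count):
                gid = f"g{i}"
                de.append(DEResult(gid, 3 if status == "up" else -3, 0.001, 0.001, status))
                groups[gid] = "promoter_only" if has_g4 else "neither"
                i += 1
        got = deg_g4_enrichment(de, groups, "promoter")
        want = fisher_exact_two_sided(ContingencyTable2x2(8, 2, 1, 9))
        assert got.p_value == pytest.approx(want.p_value)
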