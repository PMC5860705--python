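"""Consequence classification, depletion chi-square, transcript
correlation and the hotspot scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svcohort.annotate import (CLASS_PRECEDENCE, GeneIndex, classify_sv,
                               annotate_callset, consequence_summary,
                               conserved_gene_test, gene_sv_table,
                               hotspot_scan, sv_class_summary,
                               transcript_correlation, window_counts)
from svcohort.popmerge import PopulationSv
from svcohort.sv_io import Gene, GeneSet, Transcript


def make_gene(gene_id="g1", chrom="1", strand="+", start=10_000, end=20_000,
              exons=((10_000, 12_000), (15_000, 17_000), (19_000, 20_000)),
              utr5=(10_000, 10_500), utr3=(19_500, 20_000), conserved=False):
    cds = []
    for s, e in exons:
        cs, ce = max(s, utr5[1]), min(e, utr3[0])
        if ce > cs:
            cds.append((cs, ce))
    t = Transcript(f"{gene_id}.t1", tuple(exons), tuple(cds), (utr5, utr3))
    return Gene(gene_id, gene_id, "protein_coding", chrom, strand, start, end,
                (t,), conserved)


def sv(sv_id, chrom, start, end, sv_type="DEL"):
    length = end - start if sv_type != "INS" else 100
    return PopulationSv(sv_id, chrom, start, end, sv_type, length,
                        frozenset({"a", "b"}))


GENES = GeneSet({"g1": make_gene()})


class TestClassifySv:
    @pytest.mark.parametrize("interval,expected,lof", [
        ((12_500, 12_700), "intronic", False),   # wholly inside intron 1
        ((11_000, 11_300), "exonic", True),      # inside CDS of exon 1
        ((10_100, 10_400), "utr", True),         # inside the 5' UTR
        ((7_000, 7_400), "upstream", False),     # within 5 kb before (+)
        ((22_000, 22_300), "downstream", False), # within 5 kb after (+)
        ((40_000, 40_500), "intergenic", False), # far from everything
    ])
    def test_constructed_gene_model(self, interval, expected, lof):
        (c,) = classify_sv(sv("v1", "1", *interval), GENES)
        assert c.consequence == expected
        assert c.lof is lof
        assert (c.gene_id == "") == (expected == "intergenic")

    def test_strand_flips_flank_sense(self):
        minus = GeneSet({"g1": make_gene(strand="-")})
        (c,) = classify_sv(sv("v1", "1", 7_000, 7_400), minus)
        assert c.consequence == "downstream"

    def test_insertion_breakpoint_inside_intron(self):
        (c,) = classify_sv(sv("v1", "1", 13_000, 13_000, "INS"), GENES)
        assert c.consequence == "intronic"

    def test_multi_gene_overlap_yields_one_record_per_gene(self):
        genes = GeneSet({"g1": make_gene(),
                         "g2": make_gene("g2", start=19_900, end=30_000,
                                         exons=((19_900, 21_000),
                                                (25_000, 30_000)),
                                         utr5=(19_900, 20_000),
                                         utr3=(29_500, 30_000))})
        recs = classify_sv(sv("v1", "1", 19_950, 20_100), genes)
        assert {r.gene_id for r in recs} == {"g1", "g2"}

    def test_matches_per_base_brute_force(self, rng, toy_genes):
        """Random SVs vs a literal per-base feature lookup."""
        index = GeneIndex(toy_genes, flank_bp=5000)
        genes = list(toy_genes)
        for _ in range(300):
            start = int(rng.integers(0, 9_990_000))
            length = int(rng.integers(50, 500))
            record = sv("v", "1", start, start + length)
            got = {(c.gene_id, c.consequence)
                   for c in classify_sv(record, index)}
            expected = set()
            for g in genes:
                if g.chrom != "1":
                    continue
                if min(g.end, record.end) > max(g.start, start):
                    cls = "intronic"
                    positions = range(max(g.start, start),
                                      min(g.end, record.end))
                    in_cds = any(any(s <= p < e for s, e in t.cds)
                                 for t in g.transcripts for p in positions)
                    in_utr = any(any(s <= p < e for s, e in t.utrs)
                                 for t in g.transcripts for p in positions)
                    if in_cds:
                        cls = "exonic"
                    elif in_utr:
                        cls = "utr"
                    expected.add((g.gene_id, cls))
            if expected:
                assert got == expected
            else:
                # no gene-body overlap: only flank or intergenic records
                assert {cls for _, cls in got} <= \
                    {"upstream", "downstream", "intergenic"}


class TestConsequenceSummary:
    def test_half_intergenic_half_intronic(self):
        svs = [sv("v1", "1", 12_500, 12_700), sv("v2", "1", 12_600, 12_800),
               sv("v3", "1", 40_000, 40_200), sv("v4", "1", 50_000, 50_200)]
        summary = consequence_summary(annotate_callset(svs, GENES))
        assert summary.loc["intronic", "fraction"] == pytest.approx(0.5)
        assert summary.loc["intergenic", "fraction"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, rng, toy_genes):
        svs = [sv(f"v{i}", "1", int(p), int(p) + 200)
               for i, p in enumerate(rng.integers(0, 9_000_000, 150))]
        summary = consequence_summary(annotate_callset(svs, toy_genes))
        assert summary["fraction"].sum() == pytest.approx(1.0)
        assert summary["count"].sum() == 150

    def test_most_severe_class_wins(self):
        # one SV spanning CDS and intron: counted once, as exonic
        recs = annotate_callset([sv("v1", "1", 11_500, 12_500)], GENES)
        assert sv_class_summary(recs).loc["v1"] == "exonic"


class TestConservedGeneTest:
    def test_identical_proportions_give_zero(self):
        res = conserved_gene_test(10, 100, 100, 1000)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_margins_preserved(self):
        res = conserved_gene_test(112, 437, 7881, 25880)
        assert np.allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))
        assert np.allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        assert res.df == 1

    def test_transpose_symmetry(self):
        res = conserved_gene_test(112, 437, 7881, 25880)
        flipped = stats.chi2_contingency(res.observed.T, correction=False)
        assert res.statistic == pytest.approx(flipped.statistic)

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            n_total = int(rng.integers(200, 5000))
            n_cons = int(rng.integers(20, n_total // 2))
            n_with = int(rng.integers(10, n_total - 10))
            n_cons_with = int(rng.integers(1, min(n_cons, n_with)))
            if n_with - n_cons_with > n_total - n_cons:
                continue
            res = conserved_gene_test(n_cons_with, n_cons, n_with, n_total)
            O = res.observed
            rows, cols, N = O.sum(1), O.sum(0), O.sum()
            E = np.outer(rows, cols) / N
            if (E == 0).any():
                continue
            assert res.statistic == pytest.approx(((O - E) ** 2 / E).sum(),
                                                  abs=1e-9)

    def test_inconsistent_marginals_fatal(self):
        with pytest.raises(ValueError):
            conserved_gene_test(500, 437, 7881, 25880)


class TestTranscriptCorrelation:
    def _table(self, pairs):
        return pd.DataFrame(
            [{"gene_id": f"g{i}", "sv_count": x, "transcript_count": y,
              "conserved": False} for i, (x, y) in enumerate(pairs)]
        ).set_index("gene_id")

    def test_perfectly_monotone(self):
        rho, _ = transcript_correlation(self._table([(1, 1), (2, 2), (3, 3)]))
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = transcript_correlation(self._table([(1, 3), (2, 2), (3, 1)]))
        assert rho == pytest.approx(-1.0)

    def test_zero_variance_returns_nan(self):
        rho, p = transcript_correlation(self._table([(2, 1), (2, 5), (2, 3)]))
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_rank_formula_with_ties(self, rng):
        # Pearson correlation of average ranks == Spearman with tie correction
        x = rng.integers(0, 6, size=200).astype(float)
        y = rng.integers(1, 5, size=200).astype(float)
        rho, _ = transcript_correlation(self._table(list(zip(x, y))))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = (np.corrcoef(rx, ry)[0, 1])
        assert rho == pytest.approx(expected, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x = rng.integers(0, 30, size=50).astype(float)
        y = rng.integers(1, 11, size=50).astype(float)
        base, _ = transcript_correlation(self._table(list(zip(x, y))))
        warped, _ = transcript_correlation(
            self._table(list(zip(np.exp(x / 10), y ** 3))))
        assert warped == pytest.approx(base, abs=1e-12)


CHROM_LENGTHS = {"1": 10_000_000, "2": 10_000_000,
                 "3": 10_000_000, "x": 10_000_000}


def uniform_callset(rng, n):
    chroms = list(CHROM_LENGTHS)
    out = []
    for i in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, CHROM_LENGTHS[c] - 500))
        out.append(sv(f"SV{i:05d}", c, s, s + 300))
    return out


class TestHotspotScan:
    def test_empty_callset(self):
        assert hotspot_scan([], CHROM_LENGTHS) == []

    def test_invalid_window_geometry_fatal(self):
        with pytest.raises(ValueError):
            window_counts([], CHROM_LENGTHS, window_bp=100, step_bp=200)

    def test_missing_chrom_length_fatal(self):
        with pytest.raises(ValueError):
            hotspot_scan([sv("v", "17", 0, 300)], CHROM_LENGTHS)

    def test_window_counts_tile_and_tally(self, rng):
        calls = uniform_callset(rng, 200)
        wins = window_counts(calls, CHROM_LENGTHS)
        # every SV start falls in exactly two half-overlapping windows,
        # except within the first and last half-windows of a chromosome
        per_chrom = wins.groupby("chrom").sv_count.sum()
        for chrom, grp in per_chrom.items():
            n = sum(1 for c in calls if c.chrom == chrom)
            n_single = sum(1 for c in calls if c.chrom == chrom
                           and (c.start < 500_000 or c.start >= 9_500_000))
            assert grp == 2 * n - n_single

    def test_null_produces_no_hotspots_in_most_seeds(self):
        zero = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            if not hotspot_scan(uniform_callset(rng, 1500), CHROM_LENGTHS):
                zero += 1
        assert zero >= int(0.95 * n_seeds)

    def test_planted_enrichment_recovered(self):
        region = (2_500_000, 7_500_000)  # 5 Mb at 10x density on chrX
        covered = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            calls = uniform_callset(rng, 1500)
            n_extra = rng.poisson(9 * 1500 * 5 / 40)
            for k in range(n_extra):
                s = int(rng.integers(region[0], region[1] - 500))
                calls.append(sv(f"H{k}", "x", s, s + 300))
            hits = hotspot_scan(calls, CHROM_LENGTHS)
            cov = sum(max(0, min(h.end, region[1]) - max(h.start, region[0]))
                      for h in hits if h.chrom == "x")
            covered.append(cov / (region[1] - region[0]))
        assert all(c >= 0.8 for c in covered)

    def test_hot_windows_merge_into_one_interval(self):
        rng = np.random.default_rng(3)
        calls = uniform_callset(rng, 1000)
        for k in range(600):
            s = int(rng.integers(4_000_000, 6_000_000))
            calls.append(sv(f"H{k}", "2", s, s + 300))
        hits = hotspot_scan(calls, CHROM_LENGTHS)
        on_2 = [h for h in hits if h.chrom == "2"]
        assert len(on_2) == 1
        assert on_2[0].start <= 4_000_000 and on_2[0].end >= 6_000_000
        assert on_2[0].sv_count >= 600


class TestGeneSvTable:
    def test_counts_sv_once_per_gene(self, toy_genes):
        gene = next(iter(toy_genes))
        svs = [sv("v1", gene.chrom, gene.start, gene.start + 100),
               sv("v2", gene.chrom, gene.start + 50, gene.start + 200)]
        table = gene_sv_table(annotate_callset(svs, toy_genes), toy_genes)
        assert table.loc[gene.gene_id, "sv_count"] == 2
        assert (table.transcript_count >= 1).all()
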