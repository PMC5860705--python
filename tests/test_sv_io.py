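"""Format round trips, record validation and deterministic ordering."""

import numpy as np
import pytest

from svcohort import sv_io
from svcohort.popmerge import PopulationSv
from svcohort.sv_io import SvCall, chrom_sort_key, normalize_chrom

from conftest import random_call, random_population_sv


class TestChromNames:
    @pytest.mark.parametrize("raw,expected", [
        ("chr1", "1"), ("Chr1", "1"), ("1", "1"), ("chrX", "x"), ("X", "x"),
    ])
    def test_normalization(self, raw, expected):
        assert normalize_chrom(raw) == expected

    def test_sort_order_numeric_then_x_then_rest(self):
        chroms = ["x", "10", "2", "1", "mt", "11"]
        assert sorted(chroms, key=chrom_sort_key) == \
            ["1", "2", "10", "11", "x", "mt"]


class TestReadSvCalls:
    def _write(self, tmp_path, rows):
        p = tmp_path / "calls.tsv"
        body = "\n".join("\t".join(map(str, r)) for r in rows)
        p.write_text("chrom\tstart\tend\ttype\tsupport\n" + body + "\n")
        return p

    def test_tsv_field_mapping(self, tmp_path):
        p = self._write(tmp_path, [("chr1", 100, 200, "DEL", 5)])
        res = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        (call,) = res.calls
        assert call == SvCall("s1", "cA", "1", 100, 200, "DEL", 100, 5)

    def test_translocation_rejected_with_reason(self, tmp_path):
        p = self._write(tmp_path, [("chr1", 100, 200, "TRA", 5)])
        res = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        assert res.calls == []
        assert res.rejections["unsupported type"] == 1

    def test_negative_coordinate_rejected(self, tmp_path):
        p = self._write(tmp_path, [("chr1", -5, 200, "DEL", 5)])
        res = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        assert res.calls == []
        assert res.rejections["negative coordinate"] == 1

    def test_short_record_rejected(self, tmp_path):
        p = self._write(tmp_path, [("chr1", 100, 130, "DEL", 5)])
        res = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        assert res.rejections["below minimum length"] == 1

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sv_io.read_sv_calls(tmp_path / "nope.tsv", "tsv", "s1", "cA")

    def test_undeclared_dialect_is_fatal(self, tmp_path):
        p = self._write(tmp_path, [("chr1", 100, 200, "DEL", 5)])
        with pytest.raises(ValueError):
            sv_io.read_sv_calls(p, "guess", "s1", "cA")

    def test_ingest_deterministic(self, tmp_path, rng):
        rows = [("chr%d" % rng.integers(1, 4), s, s + 100, t, 4)
                for s, t in zip(rng.integers(0, 10000, 30),
                                ["DEL", "TRA", "DUP"] * 10)]
        p = self._write(tmp_path, rows)
        a = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        b = sv_io.read_sv_calls(p, "tsv", "s1", "cA")
        assert a.calls == b.calls and a.rejections == b.rejections


class TestRoundTrips:
    def test_call_tsv_round_trip(self, tmp_path, rng):
        calls = [random_call(rng, sample_id="s9", caller_id="cB")
                 for _ in range(100)]
        path = tmp_path / "rt.tsv"
        sv_io.write_sv_calls(calls, path)
        back = sv_io.read_sv_calls(path, "tsv", "s9", "cB")
        assert not back.rejections
        assert sorted(back.calls, key=sv_io.sv_sort_key) == \
            sorted(calls, key=sv_io.sv_sort_key)

    @pytest.mark.parametrize("fmt", ["tsv", "vcf"])
    def test_population_callset_round_trip(self, tmp_path, rng, fmt):
        callset = [random_population_sv(rng, f"SV{i + 1:05d}")
                   for i in range(200)]
        path = tmp_path / f"callset.{fmt}"
        sv_io.write_population_callset(callset, path, fmt)
        back = sv_io.read_population_callset(path, fmt)
        key = lambda s: s.sv_id
        for orig, rt in zip(sorted(callset, key=key), sorted(back, key=key)):
            assert (orig.chrom, orig.start, orig.end, orig.sv_type,
                    orig.length, orig.carriers) == \
                   (rt.chrom, rt.start, rt.end, rt.sv_type, rt.length,
                    rt.carriers)

    def test_empty_callset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        sv_io.write_population_callset([], path, "tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("sv_id")

    def test_callset_sorted_by_chrom_then_start(self, tmp_path):
        svs = [PopulationSv("A", "2", 50, 150, "DEL", 100, frozenset({"s"})),
               PopulationSv("B", "1", 500, 700, "DEL", 200, frozenset({"s"})),
               PopulationSv("C", "1", 100, 300, "DUP", 200, frozenset({"s"}))]
        path = tmp_path / "sorted.tsv"
        sv_io.write_population_callset(svs, path, "tsv")
        ids = [l.split("\t")[0] for l in path.read_text().splitlines()[1:]]
        assert ids == ["C", "B", "A"]

    def test_duplicate_ids_fatal(self, tmp_path):
        svs = [PopulationSv("A", "1", 0, 100, "DEL", 100, frozenset({"s"}))] * 2
        with pytest.raises(ValueError):
            sv_io.write_population_callset(svs, tmp_path / "dup.tsv", "tsv")


class TestGeneModels:
    def test_toy_gff_transcript_count(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text("\n".join([
            "##gff-version 3",
            "1\ttoy\tgene\t1001\t5000\t.\t+\t.\tID=g1;Name=G1",
            "1\ttoy\tmRNA\t1001\t5000\t.\t+\t.\tID=t1;Parent=g1",
            "1\ttoy\texon\t1001\t2000\t.\t+\t.\tID=e1;Parent=t1",
            "1\ttoy\tCDS\t1101\t2000\t.\t+\t0\tID=c1;Parent=t1",
            "1\ttoy\tmRNA\t1001\t5000\t.\t+\t.\tID=t2;Parent=g1",
            "1\ttoy\texon\t1001\t5000\t.\t+\t.\tID=e2;Parent=t2",
        ]) + "\n")
        gs = sv_io.read_gene_models(gff, conserved_ids={"g1", "absent"})
        assert len(gs) == 1
        gene = gs.genes["g1"]
        assert gene.transcript_count == 2
        assert gene.conserved
        assert gs.n_conserved == 1  # absent IDs don't inflate the count
        assert gene.start == 1000 and gene.end == 5000  # 0-based half-open

    def test_empty_gene_set_is_fatal(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        with pytest.raises(ValueError):
            sv_io.read_gene_models(gff)

    def test_gene_models_round_trip(self, tmp_path, small_config, toy_genes):
        path = tmp_path / "genes.gff3"
        sv_io.write_gene_models(toy_genes, path)
        back = sv_io.read_gene_models(path)
        assert set(back.genes) == set(toy_genes.genes)
        for gid, orig in toy_genes.genes.items():
            rt = back.genes[gid]
            assert (rt.chrom, rt.strand, rt.start, rt.end) == \
                (orig.chrom, orig.strand, orig.start, orig.end)
            orig_t = sorted(orig.transcripts, key=lambda t: t.transcript_id)
            rt_t = sorted(rt.transcripts, key=lambda t: t.transcript_id)
            assert len(orig_t) == len(rt_t)
            for a, b in zip(orig_t, rt_t):
                assert a.exons == b.exons
                assert a.cds == b.cds
                assert tuple(sorted(a.utrs)) == tuple(sorted(b.utrs))


class TestGenotypeTable:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        gt = sv_io.GenotypeTable(pd.DataFrame([
            {"locus_id": "L1", "population_id": "XP",
             "n_II": 3, "n_ID": 10, "n_DD": 35},
        ]))
        path = tmp_path / "gt.csv"
        sv_io.write_genotype_table(gt, path)
        back = sv_io.read_genotype_table(path)
        assert back.counts("L1", "XP") == {"II": 3, "ID": 10, "DD": 35}

    def test_all_zero_row_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            sv_io.GenotypeTable(pd.DataFrame([
                {"locus_id": "L1", "population_id": "XP",
                 "n_II": 0, "n_ID": 0, "n_DD": 0}]))
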