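"""File readers/writers: normalization, accounting, determinism."""
from __future__ import annotations

import random

import pytest

from vea import (
    ConfigError,
    ContingencyTable2x2,
    FileFormatError,
    PathwayEnrichmentResult,
    VariantKey,
    read_background_counts,
    read_deg_list,
    read_expression_table,
    read_gmt,
    read_variant_table,
    write_report,
)
from vea.formats_io import read_report

TSV_HEADER = (
    "Chr\tStart\tEnd\tRef\tAlt\tGene.refGene\tExonicFunc.refGene\t"
    "SIFT_pred\tPolyphen2_HDIV_pred\tFATHMM_pred\tCADD_phred"
)


def _tsv(tmp_path, rows, name="sample.tsv"):
    p = tmp_path / name
    p.write_text("\n".join([TSV_HEADER, *rows]) + "\n")
    return p


class TestVariantKey:
    def test_chr_prefix_and_case_insensitive_identity(self):
        a = VariantKey.from_raw("chr1", 100, "a", "g")
        b = VariantKey.from_raw("1", 100, "A", "G")
        assert a == b

    def test_shared_suffix_and_prefix_trimmed(self):
        # CAG>CTG shares prefix C and suffix G -> A>T at pos+1
        k = VariantKey.from_raw("2", 50, "CAG", "CTG")
        assert (k.pos, k.ref, k.alt) == (51, "A", "T")

    @pytest.mark.parametrize(
        "pos,ref,alt", [(0, "A", "G"), (5, "A", "A"), (5, "A", "X")]
    )
    def test_invalid_keys_rejected(self, pos, ref, alt):
        with pytest.raises(ValueError):
            VariantKey(chrom="1", pos=pos, ref=ref, alt=alt)


class TestVariantTable:
    def test_direct_field_mapping(self, tmp_path):
        p = _tsv(tmp_path, ["chr1\t12345\t12345\tA\tG\tNOD2\tstopgain\tD\tB\tT\t25.1"])
        (v,) = read_variant_table(p)
        assert v.key == VariantKey("1", 12345, "A", "G")
        assert v.genes == {"NOD2"}
        assert v.func_class == "stopgain"
        assert v.predictor_calls["SIFT"] == "damaging"
        assert v.predictor_calls["PolyPhen2"] == "tolerated"
        assert v.predictor_scores["CADD"] == pytest.approx(25.1)

    def test_empty_gene_rows_dropped_and_accounted(self, tmp_path):
        rows = [
            f"chr1\t{100 + i}\t{100 + i}\tA\tG\tG{i}\tsynonymous SNV\tT\tT\tT\t1.0"
            for i in range(97)
        ] + [f"chr1\t{500 + i}\t{500 + i}\tA\tG\t.\tsynonymous SNV\tT\tT\tT\t1.0" for i in range(3)]
        variants, summary = read_variant_table(_tsv(tmp_path, rows), return_summary=True)
        assert len(variants) == 97
        assert summary.dropped == {"no_gene": 3}
        assert summary.n_records == summary.n_kept + summary.n_dropped == 100

    def test_order_insensitive(self, tmp_path):
        rows = [
            f"chr{c}\t{p}\t{p}\tA\tG\tGENE{p}\tnonsynonymous SNV\tD\t.\tT\t{s}"
            for c, p, s in [(1, 10, 5.0), (2, 20, 30.0), (3, 30, 1.0), ("X", 44, 9.9)]
        ]
        shuffled = rows[:]
        random.Random(3).shuffle(shuffled)
        a = read_variant_table(_tsv(tmp_path, rows, "a.tsv"))
        b = read_variant_table(_tsv(tmp_path, shuffled, "b.tsv"))
        assert sorted((v.key for v in a), key=str) == sorted((v.key for v in b), key=str)

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Chr\tStart\tRef\tAlt\tGene.refGene\n")
        with pytest.raises(ConfigError, match="ExonicFunc.refGene"):
            read_variant_table(p)

    def test_too_many_bad_coordinates_rejects_file(self, tmp_path):
        rows = [
            f"chr1\t{100 + i}\t.\tA\tG\tG{i}\tsynonymous SNV\tT\tT\tT\t1.0"
            for i in range(50)
        ] + ["chr1\tnotanumber\t.\tA\tG\tGX\tsynonymous SNV\tT\tT\tT\t1.0"]
        with pytest.raises(FileFormatError, match="failed to parse"):
            read_variant_table(_tsv(tmp_path, rows))

    def test_vcf_multiallelic_split_and_filter(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=FUNC,Number=1,Type=String,Description="f">\n'
            '##INFO=<ID=SIFT,Number=1,Type=String,Description="s">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t12345\t.\tA\tG,T\t.\tPASS\tGENE=NOD2;FUNC=nonsynonymous_SNV;SIFT=D\n"
            "chr1\t99999\t.\tC\tT\t.\tLowQual\tGENE=TNF;FUNC=stopgain\n"
        )
        variants, summary = read_variant_table(p, dialect="vcf", return_summary=True)
        assert {(v.key.pos, v.key.alt) for v in variants} == {(12345, "G"), (12345, "T")}
        assert all(v.genes == {"NOD2"} for v in variants)
        assert summary.dropped == {"filtered": 1}


class TestGmt:
    def test_parse_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text(
            "R-HSA-1462054\talpha-defensins\tDEFA1\tDEFA3\tDEFA4\n"
            "R-HSA-9\trepeat\tIL1B\tIL1B\n"
        )
        db = read_gmt(p)
        assert db.pathways["R-HSA-1462054"] == {"DEFA1", "DEFA3", "DEFA4"}
        assert db.pathways["R-HSA-9"] == {"IL1B"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("R-1\ta\tG1\nR-1\tb\tG2\n")
        with pytest.raises(FileFormatError, match="duplicate"):
            read_gmt(p)

    def test_empty_gene_list_skipped(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("R-1\tno genes here\nR-2\tok\tG1\n")
        db = read_gmt(p)
        assert set(db.pathways) == {"R-2"}


class TestBackground:
    def test_counts_and_metadata(self, tmp_path):
        p = tmp_path / "bg.tsv"
        p.write_text("# ancestry=nfe\n# af_threshold=0.01\nGENE1\t10\nGENE2\t0\n")
        bg = read_background_counts(p)
        assert bg.per_gene == {"GENE1": 10, "GENE2": 0}
        assert bg.total == 10
        assert bg.meta["ancestry"] == "nfe"

    def test_duplicate_gene_rows_summed(self, tmp_path):
        p = tmp_path / "bg.tsv"
        p.write_text("G\t3\nG\t4\n")
        assert read_background_counts(p).per_gene == {"G": 7}

    @pytest.mark.parametrize("row", ["G\t-1", "G\tx"])
    def test_bad_count_rejected(self, tmp_path, row):
        p = tmp_path / "bg.tsv"
        p.write_text(row + "\n")
        with pytest.raises(FileFormatError):
            read_background_counts(p)


class TestExpressionTable:
    HEADER = "gene\ttissue\trna_value\tprotein_level"

    def test_or_rule(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text(
            f"{self.HEADER}\n"
            "A\tskin\t5.0\tNot detected\n"   # RNA only
            "B\tskin\t0.0\tMedium\n"          # protein only
            "C\tskin\t0.0\tNot detected\n"    # neither
        )
        expr = read_expression_table(p, tissue="skin")
        assert expr.is_expressed("A") and expr.is_expressed("B")
        assert not expr.is_expressed("C")
        assert not expr.is_expressed("ABSENT")  # no evidence -> not expressed

    def test_missing_tissue_lists_available(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text(f"{self.HEADER}\nA\tliver\t5.0\tHigh\n")
        with pytest.raises(ConfigError, match="liver"):
            read_expression_table(p, tissue="skin")


class TestReport:
    @staticmethod
    def _results():
        mk = lambda pid, fdr: PathwayEnrichmentResult(
            pathway_id=pid, name=f"name {pid}",
            table=ContingencyTable2x2(3, 7, 5, 95),
            odds_ratio=8.142857142857142, p_value=0.01, fdr=fdr,
            n_important_var=2, important_var_genes={"NOD2": 2},
            genes=("NOD2",), epr=0.5, enriched=fdr < 0.05,
        )
        return [mk("C", 0.04), mk("A", 0.01), mk("B", 0.04)]

    def test_sorted_by_fdr_then_id(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_report(self._results(), out, "tsv")
        ids = [line.split("\t")[0] for line in out.read_text().splitlines()[1:]]
        assert ids == ["A", "B", "C"]

    def test_write_is_deterministic(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(self._results(), a, "tsv")
        write_report(list(reversed(self._results())), b, "tsv")
        assert a.read_bytes() == b.read_bytes()

    def test_json_roundtrip_lossless(self, tmp_path):
        out = tmp_path / "r.json"
        write_report(self._results(), out, "json")
        back = read_report(out, "json")
        again = tmp_path / "r2.json"
        write_report(back, again, "json")
        assert out.read_bytes() == again.read_bytes()
        assert back[0].odds_ratio == 8.142857142857142
        assert back[0].important_var_genes == {"NOD2": 2}

    def test_empty_results(self, tmp_path):
        out = tmp_path / "e.tsv"
        write_report([], out, "tsv")
        assert len(out.read_text().splitlines()) == 1


def test_deg_list_comments_and_case(tmp_path):
    p = tmp_path / "deg.txt"
    p.write_text("# a comment\nIl1b\nTNF # trailing\n\nTNF\n")
    assert read_deg_list(p) == {"IL1B", "TNF"}
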