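"""Domain-type invariants and format round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import svsweep.io as svio
from svsweep import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ConsensusSV,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    SVCall,
    SVFormatError,
    read_population_map,
    read_sv_vcf,
    write_sv_vcf,
)
from svsweep.model import merge_intervals


class TestSVCall:
    def test_spanning_svlen_is_canonicalised(self):
        call = SVCall("chr1", 1001, 2000, "DEL", 0, "delly")
        assert call.svlen == 1000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", start=0, end=10, svtype="DEL", svlen=0, caller="x"),
            dict(chrom="chr1", start=10, end=5, svtype="DEL", svlen=0, caller="x"),
            dict(chrom="chr1", start=10, end=10, svtype="XXX", svlen=1, caller="x"),
            dict(chrom="chr1", start=10, end=10, svtype="INS", svlen=0, caller="x"),
            dict(chrom="chr1", start=10, end=11, svtype="INS", svlen=5, caller="x"),
            dict(chrom="chr1", start=10, end=10, svtype="TRA", svlen=0, caller="x"),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SVCall(**kwargs)


class TestVcf:
    def _write_raw(self, tmp_path, body_lines):
        path = tmp_path / "in.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        )
        path.write_text(header + "".join(line + "\n" for line in body_lines))
        return path

    def test_pos_end_mapping(self, tmp_path):
        path = self._write_raw(
            tmp_path, ["chr1\t1001\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\tGT\t0/1\t1/1"]
        )
        (call,) = read_sv_vcf(path, caller="delly")
        assert (call.start, call.end, call.svlen) == (1001, 2000, 1000)

    def test_end_derived_from_svlen_when_absent(self, tmp_path):
        path = self._write_raw(
            tmp_path, ["chr1\t500\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-100\tGT\t0/0\t0/0"]
        )
        (call,) = read_sv_vcf(path, caller="delly")
        assert call.end == 599 and call.svlen == 100

    def test_missing_genotype_and_gt_mapping(self, tmp_path):
        path = self._write_raw(
            tmp_path, ["chr1\t100\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=400\tGT\t./.\t1/0"]
        )
        (call,) = read_sv_vcf(path, caller="delly")
        assert call.genotypes == {"s1": MISSING, "s2": HET}

    def test_multiallelic_rejected(self, tmp_path):
        path = self._write_raw(
            tmp_path, ["chr1\t100\t.\tN\t<DEL>,<DUP>\t.\tPASS\tSVTYPE=DEL;END=400\tGT\t0/1\t0/2"]
        )
        with pytest.raises(SVFormatError, match="multi-allelic"):
            read_sv_vcf(path, caller="delly")

    def test_unknown_svtype_skipped_with_warning(self, tmp_path, caplog):
        path = self._write_raw(
            tmp_path,
            [
                "chr1\t100\t.\tN\t<CNV>\t.\tPASS\tSVTYPE=CNV;END=400\tGT\t0/1\t0/0",
                "chr1\t500\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=900\tGT\t0/1\t0/0",
            ],
        )
        with caplog.at_level("WARNING", logger="svsweep.io"):
            calls = read_sv_vcf(path, caller="delly")
        assert len(calls) == 1 and calls[0].svtype == "DEL"
        assert any("CNV" in rec.message for rec in caplog.records)

    def test_round_trip_identity(self, tmp_path):
        calls = [
            SVCall("chr1", 100, 599, "DEL", 500, "delly",
                   genotypes={"s1": HOM_REF, "s2": HOM_ALT}),
            SVCall("chr1", 700, 700, "INS", 321, "delly",
                   genotypes={"s1": HET, "s2": MISSING}),
            SVCall("chr2", 50, 50, "TRA", 0, "delly", mate_chrom="chr1", mate_pos=9000,
                   genotypes={"s1": MISSING, "s2": MISSING}),
        ]
        path = tmp_path / "out.vcf"
        write_sv_vcf(calls, path, samples=["s1", "s2"])
        back = read_sv_vcf(path, caller="delly")
        assert back == calls
        assert [dict(c.genotypes) for c in back] == [dict(c.genotypes) for c in calls]

    def test_consensus_round_trip_keeps_callers(self, tmp_path):
        svs = [
            ConsensusSV("chr1", 100, 599, "DEL", 500, ("manta", "delly")),
            ConsensusSV("chr1", 900, 1400, "DUP", 501, ("delly", "cnvnator", "manta")),
        ]
        path = tmp_path / "cons.vcf"
        write_sv_vcf(svs, path)
        assert "SUPP_CALLERS=delly,manta;" in path.read_text()
        assert svio.read_consensus_vcf(path) == svs

    def test_empty_call_list_gives_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_sv_vcf([], path)
        assert read_sv_vcf(path, caller="x") == []

    def test_unsorted_input_rejected(self, tmp_path):
        calls = [
            SVCall("chr1", 500, 900, "DEL", 0, "d"),
            SVCall("chr1", 100, 400, "DEL", 0, "d"),
        ]
        with pytest.raises(ValueError, match="not sorted"):
            write_sv_vcf(calls, tmp_path / "x.vcf")


class TestPopulationMap:
    def test_read_valid_map(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text(
            "sample\tpopulation\n"
            "a\tMS\nb\tMS\nc\tDU\nd\tDU\ne\tTB\nf\tTB\n"
        )
        pm = read_population_map(path, focal="MS")
        assert pm.focal == "MS" and pm.references == ("DU", "TB")
        assert pm.samples_in("TB") == ["e", "f"]

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("a\tMS\na\tDU\nb\tTB\n")
        with pytest.raises(SVFormatError, match="duplicate"):
            read_population_map(path, focal="MS")

    def test_absent_focal_rejected(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("a\tDU\nb\tTB\n")
        with pytest.raises(SVFormatError, match="focal"):
            read_population_map(path, focal="MS")

    def test_focal_cannot_be_reference(self):
        with pytest.raises(ValueError):
            PopulationMap({"a": "MS", "b": "DU"}, focal="MS", references=("MS",))


class TestGeneModels:
    def test_bed_converted_to_1_based(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chr1\t999\t2000\tgeneA\n")
        (gene,) = svio.read_gene_models(path)
        assert (gene.start, gene.end) == (1000, 2000)
        assert gene.exons == ((1000, 2000),)

    def test_gff3_kept_1_based_with_exons(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA;biotype=protein_coding\n"
            "chr1\tsrc\texon\t1000\t1200\t.\t+\t.\tID=geneA.e1;Parent=geneA\n"
            "chr1\tsrc\texon\t1800\t2000\t.\t+\t.\tID=geneA.e2;Parent=geneA\n"
        )
        (gene,) = svio.read_gene_models(path)
        assert (gene.start, gene.end) == (1000, 2000)
        assert gene.exons == ((1000, 1200), (1800, 2000))

    def test_overlapping_exons_merged(self):
        gene = GeneModel("g", "chr1", 50, 400, "+", exons=((100, 200), (150, 250)))
        assert gene.exons == ((100, 250),)

    def test_bed12_blocks_become_exons(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text(
            "chr1\t999\t2000\tgeneA\t0\t-\t999\t2000\t0\t2\t100,200,\t0,801,\n"
        )
        (gene,) = svio.read_gene_models(path)
        assert gene.strand == "-"
        assert gene.exons == ((1000, 1099), (1801, 2000))

    def test_malformed_bed_names_line(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chr1\t10\t20\tok\nchr1\tnope\t30\tbad\n")
        with pytest.raises(SVFormatError, match="line 2"):
            svio.read_gene_models(path)

    def test_bed_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", "chr1", 1000, 5000, "+", exons=((1000, 1500), (4000, 5000))),
            GeneModel("g2", "chr2", 200, 900, "-", exons=((200, 900),)),
        ]
        path = tmp_path / "genes.bed"
        svio.write_gene_models_bed(genes, path)
        assert svio.read_gene_models(path) == genes


@given(
    st.lists(
        st.tuples(st.integers(1, 300), st.integers(0, 50)).map(lambda t: (t[0], t[0] + t[1])),
        max_size=12,
    )
)
def test_merge_intervals_is_a_disjoint_cover(intervals):
    merged = merge_intervals(intervals)
    covered = set()
    for lo, hi in intervals:
        covered.update(range(lo, hi + 1))
    merged_cover = set()
    for lo, hi in merged:
        assert hi >= lo
        assert not merged_cover & set(range(lo, hi + 1))
        merged_cover.update(range(lo, hi + 1))
    assert merged_cover == covered


def test_genotype_matrix_tsv_round_trip(tmp_path):
    sites = [
        SVCall("chr1", 100, 599, "DEL", 0, "t"),
        SVCall("chr1", 900, 1200, "DUP", 0, "t"),
    ]
    codes = np.array([[HOM_REF, HET, HOM_ALT], [MISSING, HOM_REF, HET]], dtype=np.int8)
    matrix = GenotypeMatrix(sites, ["s1", "s2", "s3"], codes)
    path = tmp_path / "gm.tsv"
    svio.write_genotype_matrix(matrix, path)
    assert svio.read_genotype_matrix(path) == matrix


def test_genotype_matrix_rejects_bad_codes():
    with pytest.raises(ValueError):
        GenotypeMatrix(["a"], ["s1"], np.array([[5]], dtype=np.int8))
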