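"""Annotation I/O: parsing, TSS derivation, filtering, CpG classification."""

import numpy as np
import pytest

from chromtx.annotation import (
    TranscriptRecord,
    TssSite,
    cpg_score_from_sequence,
    derive_tss_sites,
    filter_by_length,
    normalized_cpg_score,
    read_transcript_annotation,
    select_representative,
)

GTF = """\
chr1\tsrc\ttranscript\t101\t500\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\tsrc\ttranscript\t101\t900\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\tsrc\ttranscript\t2001\t9000\t.\t-\t.\tgene_id "gB"; transcript_id "tB1"; tag "cds_start_NF";
"""


@pytest.fixture
def gtf_file(tmp_path):
    p = tmp_path / "test.gtf"
    p.write_text(GTF)
    return p


class TestReadAnnotation:
    def test_gtf_records_and_coordinates(self, gtf_file):
        recs = read_transcript_annotation(gtf_file)
        assert len(recs) == 3
        a1 = recs[0]
        # GTF is 1-based inclusive; internal is 0-based half-open
        assert (a1.start, a1.end, a1.length) == (100, 500, 400)
        assert a1.tss == 100 and a1.tts == 500

    def test_minus_strand_tss_is_end(self, gtf_file):
        b1 = [r for r in read_transcript_annotation(gtf_file) if r.strand == "-"][0]
        assert b1.tss == b1.end == 9000
        assert b1.tts == b1.start == 2000

    def test_incompleteness_tag_captured(self, gtf_file):
        recs = {r.transcript_id: r for r in read_transcript_annotation(gtf_file)}
        assert recs["tB1"].cds_incomplete_5p
        assert not recs["tA1"].cds_incomplete_5p

    def test_invalid_strand_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ts\ttranscript\t1\t10\t.\t.\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(ValueError, match="line 1"):
            read_transcript_annotation(p)

    def test_bed12_roundtrip(self, tmp_path):
        from chromtx.simulate import simulate_genes, write_bed12

        genes = simulate_genes(5, seed=1)
        p = tmp_path / "genes.bed"
        write_bed12(genes, p)
        recs = read_transcript_annotation(p)
        assert [(r.chrom, r.start, r.end, r.strand) for r in recs] == [
            (g.chrom, g.start, g.end, g.strand) for g in genes
        ]


class TestTssSites:
    def test_shared_position_grouped(self):
        txs = [
            TranscriptRecord("t1", "g", "chr1", 100, 5000, "+"),
            TranscriptRecord("t2", "g", "chr1", 100, 8000, "+"),
        ]
        sites = derive_tss_sites(txs)
        assert len(sites) == 1
        assert sites[0].member_transcripts == frozenset({"t1", "t2"})

    def test_incomplete_5p_excluded(self):
        txs = [TranscriptRecord("t1", "g", "chr1", 100, 5000, "+", cds_incomplete_5p=True)]
        assert derive_tss_sites(txs) == []

    def test_distinct_positions_distinct_sites(self):
        txs = [
            TranscriptRecord(f"t{i}", "g", "chr1", 100 * (i + 1), 100 * (i + 1) + 5000, "+")
            for i in range(3)
        ]
        assert len(derive_tss_sites(txs)) == 3

    def test_empty_input_empty_output(self):
        assert derive_tss_sites([]) == []

    def test_site_count_never_exceeds_transcripts(self, small_dataset):
        genes = small_dataset.genes
        assert len(derive_tss_sites(genes)) <= len(genes)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept", [(4100, False), (4101, True), (4099, False)]
    )
    def test_strict_boundary(self, length, kept):
        tx = TranscriptRecord("t", "g", "chr1", 0, length, "+")
        assert (filter_by_length([tx]) == [tx]) is kept

    def test_empty(self):
        assert filter_by_length([]) == []


class TestRepresentative:
    txs = [
        TranscriptRecord("tA", "g", "chr1", 0, 5000, "+"),
        TranscriptRecord("tB", "g", "chr1", 0, 6000, "+"),
    ]

    def test_strongest_expression_wins(self):
        rep = select_representative(self.txs, {"tA": 5.0, "tB": 10.0})
        assert rep.transcript_id == "tB"

    def test_single_transcript_identity(self):
        assert select_representative(self.txs[:1], {"tA": 0.0}).transcript_id == "tA"

    def test_tie_breaks_to_smaller_id(self):
        assert select_representative(self.txs, {"tA": 3.0, "tB": 3.0}).transcript_id == "tA"

    def test_missing_expression_errors(self):
        with pytest.raises(KeyError, match="tB"):
            select_representative(self.txs, {"tA": 1.0})


class TestCpG:
    def test_observed_expected_oracle(self):
        # 3 CG dinucleotides, 3 C, 3 G, length 6 -> 3*6/(3*3) = 2.0
        assert cpg_score_from_sequence("CGCGCG") == pytest.approx(2.0)

    def test_no_cg_scores_zero(self):
        assert cpg_score_from_sequence("AATTAA") == 0.0

    def test_case_insensitive(self):
        assert cpg_score_from_sequence("cgcgcg") == cpg_score_from_sequence("CGCGCG")

    def test_reverse_complement_invariant(self):
        rng = np.random.default_rng(0)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            rc = seq.translate(comp)[::-1]
            assert cpg_score_from_sequence(seq) == pytest.approx(
                cpg_score_from_sequence(rc)
            )

    def test_threshold_04_is_lcp(self):
        # a score exactly at the threshold is low-CpG, not high-CpG
        genome = {"chr1": "AT" * 3000}
        site = TssSite("chr1", 3000, "+", frozenset({"t"}))
        pc = normalized_cpg_score(genome, site)
        assert pc.cpg_score <= 0.4 and pc.label == "LCP"

    def test_truncation_warns(self):
        genome = {"chr1": "ACGT" * 500}
        site = TssSite("chr1", 10, "+", frozenset({"t"}))
        with pytest.warns(UserWarning, match="truncated"):
            normalized_cpg_score(genome, site)

    def test_hcp_label_above_threshold(self):
        genome = {"chr1": "CG" * 3000}
        site = TssSite("chr1", 3000, "+", frozenset({"t"}))
        assert normalized_cpg_score(genome, site).label == "HCP"
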