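"""Structure extraction, isoform sampling, filter cascade, IpE assembly."""

import numpy as np
import pytest

from genearch.gene_model import (
    TranscriptModel,
    apply_filters,
    build_ipe_units,
    extract_structure,
    flag_nested_genes,
    parse_annotation,
    select_isoform,
    select_isoforms,
)
from genearch.genome import GenomeSequence, parse_genome, reverse_complement, write_fasta
from genearch.pipeline import extract_survey


class TestParseGenome:
    def test_reads_and_normalizes(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgtRYacgt\n>chr2\nGGGG\n")
        g = parse_genome(p)
        assert g.fetch("chr1", 0, 10) == "ACGTNNACGT"
        assert g.fetch("chr2", 0, 4) == "GGGG"

    def test_gzip_roundtrip(self, tmp_path):
        import gzip

        p = tmp_path / "g.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">c\nACGTACGT\n")
        assert parse_genome(p).fetch("c", 2, 6) == "GTAC"

    def test_missing_chromosome_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        g = parse_genome(p)
        with pytest.raises(KeyError):
            g.fetch("chrX", 0, 1)

    def test_out_of_bounds_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        with pytest.raises(ValueError):
            parse_genome(p).fetch("chr1", 0, 5)

    def test_duplicate_record_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nAAAA\n>c\nCCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_genome(p)

    def test_missing_file_is_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_genome(tmp_path / "absent.fa")


class TestSelectIsoform:
    def _gene(self, n):
        return [
            TranscriptModel(f"g", f"t{i}", "c", "+", ((0, 10),)) for i in range(n)
        ]

    def test_single_isoform_forced(self):
        txs = self._gene(1)
        assert select_isoform(txs, np.random.default_rng(5)) is txs[0]

    def test_deterministic_under_seed(self):
        txs = self._gene(3)
        picks = [
            select_isoform(txs, np.random.default_rng(42)).transcript_id
            for _ in range(2)
        ]
        assert picks[0] == picks[1]

    def test_uniform_over_two_isoforms(self):
        # 10,000 seeded draws: each isoform chosen ~5,000; 4-sigma binomial
        # band is +/- 200.
        txs = self._gene(2)
        rng = np.random.default_rng(123)
        counts = {"t0": 0, "t1": 0}
        for _ in range(10_000):
            counts[select_isoform(txs, rng).transcript_id] += 1
        assert abs(counts["t0"] - 5000) < 200

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_isoform([], np.random.default_rng(0))


def _plus_layout():
    """Exon(10) + intron GTAAGTCCCCCCAG(wait) layout used by strand tests."""
    exon1 = "A" * 10
    intron = "GT" + "C" * 26 + "AG"  # 30 nt
    exon2 = "G" * 10
    return exon1, intron, exon2


class TestExtractStructure:
    def test_plus_strand_intron_construction(self):
        exon1, intron, exon2 = _plus_layout()
        genome = GenomeSequence({"c": exon1 + intron + exon2})
        tx = TranscriptModel("g", "t", "c", "+", ((0, 10), (40, 50)))
        exons, introns = extract_structure(tx, genome)
        assert len(introns) == 1
        rec = introns[0]
        assert rec.sequence == intron
        assert rec.length == 30
        assert rec.donor_dinuc == "GT" and rec.acceptor_dinuc == "AG"
        assert rec.donor_window == exon1[-3:] + intron[:6]
        assert rec.acceptor_window == intron[-20:] + exon2[:3]
        assert [e.sequence for e in exons] == [exon1, exon2]

    def test_minus_strand_mirror_yields_identical_records(self):
        # Strand oracle: the reverse-complement layout on the minus strand
        # must produce byte-identical transcript-orientation records.
        exon1, intron, exon2 = _plus_layout()
        seq = exon1 + intron + exon2
        genome_plus = GenomeSequence({"c": seq})
        genome_minus = GenomeSequence({"c": reverse_complement(seq)})
        tx_plus = TranscriptModel("g", "t", "c", "+", ((0, 10), (40, 50)))
        tx_minus = TranscriptModel("g", "t", "c", "-", ((40, 50), (0, 10)))
        ex_p, in_p = extract_structure(tx_plus, genome_plus)
        ex_m, in_m = extract_structure(tx_minus, genome_minus)
        for a, b in zip(in_p, in_m):
            assert a.sequence == b.sequence
            assert a.donor_window == b.donor_window
            assert a.acceptor_window == b.acceptor_window
            assert a.length == b.length
        assert [e.sequence for e in ex_p] == [e.sequence for e in ex_m]

    def test_three_exons_give_first_and_last_intron(self):
        e, i, _ = _plus_layout()
        seq = e + i + e + i + e
        genome = GenomeSequence({"c": seq})
        tx = TranscriptModel(
            "g", "t", "c", "+", ((0, 10), (40, 50), (80, 90))
        )
        exons, introns = extract_structure(tx, genome)
        assert [r.pos_class for r in introns] == ["first", "last"]
        assert [r.ordinal for r in introns] == [1, 2]
        assert [e.pos_class for e in exons] == ["first", "second", "last"]

    def test_exon_classes_with_four_exons(self):
        e, i, _ = _plus_layout()
        seq = (e + i) * 3 + e
        genome = GenomeSequence({"c": seq})
        tx = TranscriptModel(
            "g", "t", "c", "+", tuple((40 * j, 40 * j + 10) for j in range(4))
        )
        exons, introns = extract_structure(tx, genome)
        assert [x.pos_class for x in exons] == ["first", "second", "internal", "last"]
        assert [x.pos_class for x in introns] == ["first", "internal", "last"]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel("g", "t", "c", "+", ((0, 10), (5, 20)))

    def test_zero_length_intron_rejected(self):
        genome = GenomeSequence({"c": "A" * 40})
        tx = TranscriptModel("g", "t", "c", "+", ((0, 10), (10, 20)))
        with pytest.raises(ValueError, match="zero-length"):
            extract_structure(tx, genome)

    def test_short_flank_marks_window_unavailable(self):
        # 2-nt first exon cannot supply the 3 exonic donor-window bases.
        intron = "GT" + "C" * 26 + "AG"
        genome = GenomeSequence({"c": "AA" + intron + "G" * 10})
        tx = TranscriptModel("g", "t", "c", "+", ((0, 2), (32, 42)))
        _, introns = extract_structure(tx, genome)
        assert introns[0].donor_window is None
        assert introns[0].acceptor_window is not None


class TestFilters:
    def test_filter_cascade_on_toy_genes(self, toy_dataset):
        genome = parse_genome(toy_dataset.fasta)
        by_gene, spans = parse_annotation(toy_dataset.gtf)
        chosen = select_isoforms(by_gene, 0)
        all_introns = []
        for gid in sorted(chosen):
            _, introns = extract_structure(chosen[gid], genome)
            all_introns.extend(introns)
        surveyed = apply_filters(all_introns, spans)
        got = {}
        for i in surveyed:
            got[i.gene_id] = got.get(i.gene_id, 0) + 1
        assert got == toy_dataset.expected_survivors

    def test_length_threshold_is_inclusive(self):
        genome = GenomeSequence({"c": "A" * 3 + "GT" + "C" * 28 + "AG" + "G" * 3})
        tx = TranscriptModel("g", "t", "c", "+", ((0, 3), (35, 38)))
        _, (intron,) = extract_structure(tx, genome)
        assert intron.length == 32
        assert intron.min_size_ok and intron.canonical

    def test_nested_mode_containment_vs_overlap(self):
        genome = GenomeSequence({"c": "A" * 200})
        intron_like = TranscriptModel("g1", "t1", "c", "+", ((0, 10), (110, 120)))
        _, introns = [], None
        # build a fake intron record spanning [10, 110)
        from genearch.gene_model import IntronRecord

        rec = IntronRecord(
            gene_id="g1", transcript_id="t1", ordinal=1, pos_class="first",
            length=100, sequence="GT" + "A" * 96 + "AG", donor_dinuc="GT",
            acceptor_dinuc="AG", donor_window=None, acceptor_window=None,
            chrom="c", start=10, end=110, strand="+",
        )
        spans_contained = {"g1": ("c", 0, 120), "g2": ("c", 30, 60)}
        spans_straddle = {"g1": ("c", 0, 120), "g2": ("c", 100, 150)}
        flag_nested_genes([rec], spans_contained, mode="containment")
        assert rec.nested_gene_overlap
        flag_nested_genes([rec], spans_straddle, mode="containment")
        assert not rec.nested_gene_overlap
        flag_nested_genes([rec], spans_straddle, mode="overlap")
        assert rec.nested_gene_overlap


class TestIpEUnits:
    def _records(self, first_exon_len):
        genome_seq = (
            "A" * first_exon_len
            + "GT" + "C" * 96 + "AG"
            + "G" * 200
            + "GT" + "C" * 46 + "AG"
            + "T" * 30
        )
        genome = GenomeSequence({"c": genome_seq})
        e1 = (0, first_exon_len)
        i1 = (first_exon_len, first_exon_len + 100)
        e2 = (i1[1], i1[1] + 200)
        i2 = (e2[1], e2[1] + 50)
        e3 = (i2[1], i2[1] + 30)
        tx = TranscriptModel("g", "t", "c", "+", (e1, e2, e3))
        return extract_structure(tx, genome)

    def test_size_is_intron_plus_next_exon(self):
        exons, introns = self._records(100)
        units = build_ipe_units(exons, introns)
        assert [u.size for u in units] == [100 + 200, 50 + 30]

    @pytest.mark.parametrize(
        "first_exon_len,expected", [(250, "first_cap_proximal"), (251, "first_cap_distal")]
    )
    def test_cap_boundary_is_inclusive(self, first_exon_len, expected):
        exons, introns = self._records(first_exon_len)
        units = build_ipe_units(exons, introns)
        assert units[0].pos_class == expected

    def test_unit_count_equals_intron_count(self, small_survey):
        assert len(small_survey.units) == len(small_survey.introns)

    def test_count_conservation(self, small_survey):
        # first == last == number of surveyed genes; internal = rest
        by_class = {}
        for i in small_survey.introns:
            by_class[i.pos_class] = by_class.get(i.pos_class, 0) + 1
        n_genes = len({i.gene_id for i in small_survey.introns})
        assert by_class["first"] == n_genes
        assert by_class["last"] == n_genes
        assert by_class.get("internal", 0) == len(small_survey.introns) - 2 * n_genes


class TestRoundTrip:
    def test_regeneration_is_byte_identical(self, toy_dataset, tmp_path):
        s1 = extract_survey(toy_dataset.fasta, toy_dataset.gtf, seed=3, train_models=False)
        s2 = extract_survey(toy_dataset.fasta, toy_dataset.gtf, seed=3, train_models=False)
        f1, f2 = s1.intron_frame, s2.intron_frame
        assert f1.equals(f2)

    def test_bed_export(self, small_survey, tmp_path):
        from genearch.gene_model import export_bed6

        out = tmp_path / "introns.bed"
        export_bed6(small_survey.introns, out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(small_survey.introns)
        chrom, start, end, name, score, strand = lines[0].split("\t")
        assert int(end) > int(start) >= 0
        assert strand in "+-"
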