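"""Transcript parsing, canonical selection, and feature extraction."""

import numpy as np
import pytest

from utr3evo import genome_features as gf

TOY_GENOME = {"chr1": "".join("ACGT"[i % 4] for i in range(200))}


def _toy_gff(cds_start=21, cds_end=80, exons=((1, 100),), strand="+"):
    lines = ["##gff-version 3"]
    start = min(a for a, _ in exons)
    end = max(b for _, b in exons)
    lines.append(f"chr1\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=g1")
    lines.append(f"chr1\ttoy\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID=t1;Parent=g1")
    for i, (a, b) in enumerate(exons, 1):
        lines.append(
            f"chr1\ttoy\texon\t{a}\t{b}\t.\t{strand}\t.\tID=t1.e{i};Parent=t1"
        )
    lines.append(
        f"chr1\ttoy\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\tID=t1.c;Parent=t1"
    )
    return "\n".join(lines) + "\n"


def _model(**kw):
    defaults = dict(
        transcript_id="t1",
        gene_id="g1",
        chrom="chr1",
        strand="+",
        exons=[(1, 100)],
        cds_start=21,
        cds_end=80,
    )
    defaults.update(kw)
    return gf.TranscriptModel(**defaults)


class TestParseAnnotation:
    def test_round_trip_single_gene(self):
        by_gene, rejected = gf.parse_annotation(_toy_gff(), TOY_GENOME)
        assert rejected == []
        (t,) = by_gene["g1"]
        assert (t.transcript_id, t.chrom, t.strand) == ("t1", "chr1", "+")
        assert t.exons == [(1, 100)]
        assert (t.cds_start, t.cds_end) == (21, 80)

    def test_cds_not_multiple_of_three_rejected(self):
        gff = _toy_gff(cds_start=21, cds_end=81)  # 61 nt
        by_gene, rejected = gf.parse_annotation(gff, TOY_GENOME)
        assert by_gene == {}
        assert rejected and "multiple of 3" in rejected[0][1]

    def test_unknown_chromosome_rejected(self):
        gff = _toy_gff().replace("chr1", "chrX")
        by_gene, rejected = gf.parse_annotation(gff, TOY_GENOME)
        assert by_gene == {}
        assert any("chromosome" in reason for _, reason in rejected)

    def test_two_isoforms_grouped_under_gene(self):
        gff = _toy_gff() + (
            "chr1\ttoy\tmRNA\t1\t100\t.\t+\t.\tID=t2;Parent=g1\n"
            "chr1\ttoy\texon\t1\t100\t.\t+\t.\tID=t2.e1;Parent=t2\n"
            "chr1\ttoy\tCDS\t21\t50\t.\t+\t0\tID=t2.c;Parent=t2\n"
        )
        by_gene, _ = gf.parse_annotation(gff, TOY_GENOME)
        assert sorted(t.transcript_id for t in by_gene["g1"]) == ["t1", "t2"]


class TestSelectCanonical:
    def test_longest_cds_wins(self):
        a = _model(transcript_id="a", cds_start=21, cds_end=320, exons=[(1, 400)])
        b = _model(transcript_id="b", cds_start=21, cds_end=472, exons=[(1, 500)])
        assert gf.select_canonical([a, b]) is b

    def test_nonstop_isoform_never_selected(self):
        long_nostop = _model(transcript_id="a", stop_ok=False, cds_start=1, cds_end=600, exons=[(1, 700)])
        short_stop = _model(transcript_id="b", stop_ok=True, cds_start=1, cds_end=300, exons=[(1, 700)])
        assert gf.select_canonical([long_nostop, short_stop]) is short_stop

    def test_all_nonstop_returns_none(self):
        assert gf.select_canonical([_model(stop_ok=False)]) is None

    def test_tie_breaks_to_smallest_id(self):
        a = _model(transcript_id="tB")
        b = _model(transcript_id="tA")
        assert gf.select_canonical([a, b]).transcript_id == "tA"

    def test_permutation_invariant(self):
        iso = [
            _model(transcript_id=f"t{i}", cds_start=21, cds_end=20 + 30 * (i + 1), exons=[(1, 200)])
            for i in range(4)
        ]
        picks = {gf.select_canonical(p).transcript_id for p in ([iso], [iso[::-1]], [iso[2:] + iso[:2]])
                 for p in [p[0]]}
        assert len(picks) == 1


class TestExtractFeatures:
    def test_plus_strand_lengths(self):
        fs = gf.extract_features(_model(), TOY_GENOME)
        assert (fs.L5, fs.Lc, fs.L3) == (20, 60, 20)
        assert fs.utr5_seq == TOY_GENOME["chr1"][:20]

    def test_minus_strand_utr3_is_revcomp_of_left_end(self):
        from Bio.Seq import Seq

        fs = gf.extract_features(_model(strand="-"), TOY_GENOME)
        assert (fs.L5, fs.Lc, fs.L3) == (20, 60, 20)
        assert fs.utr3_seq == str(Seq(TOY_GENOME["chr1"][:20]).reverse_complement())

    def test_intron_in_utr3_matches_manual_splice(self):
        # exons 1-120 and 151-200; CDS 21-100; intron splits the 3'UTR
        t = _model(exons=[(1, 120), (151, 200)], cds_start=21, cds_end=100)
        fs = gf.extract_features(t, TOY_GENOME)
        seq = TOY_GENOME["chr1"]
        manual_spliced = seq[0:120] + seq[150:200]
        assert fs.L3 == 20 + 50
        assert fs.utr3_seq == manual_spliced[100:]
        assert fs.L5 + fs.Lc + fs.L3 == t.spliced_length()

    def test_exon_beyond_chromosome_end_fatal(self):
        t = _model(exons=[(1, 500)], cds_start=21, cds_end=80)
        with pytest.raises(ValueError, match="chromosome end"):
            gf.extract_features(t, TOY_GENOME)


class TestRoundTripOnSyntheticGenomes:
    def test_planted_utr3_lengths_recovered_exactly(self, small_genomes):
        lengths, genomes = small_genomes
        for species, genome in genomes.items():
            by_gene, rejected = gf.parse_annotation(
                genome.gff3, {genome.chrom: genome.sequence}
            )
            assert rejected == []
            for gene_id, isoforms in by_gene.items():
                canon = gf.select_canonical(isoforms)
                assert canon is not None
                assert canon.transcript_id == f"{gene_id}.t1"
                fs = gf.extract_features(canon, {genome.chrom: genome.sequence})
                assert fs.L3 == lengths.loc[gene_id, species]
                assert fs.cds_seq[-3:] in gf.STOP_CODONS
                assert fs.L5 + fs.Lc + fs.L3 == canon.spliced_length()


class TestLengthHistogram:
    def test_all_lengths_below_window_in_bin_zero(self):
        hist = gf.length_histogram(range(50), window=50)
        assert hist.tolist() == [50]

    def test_boundary_length_goes_to_next_bin(self):
        assert gf.length_histogram([50], window=50).tolist() == [0, 1]

    def test_empty_input_empty_histogram(self):
        assert gf.length_histogram([], window=50).size == 0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            gf.length_histogram([-1])

    @pytest.mark.parametrize("window", [1, 7, 50, 1000])
    def test_total_count_preserved(self, window, rng):
        lengths = rng.integers(0, 5000, size=200)
        assert gf.length_histogram(lengths, window).sum() == 200


class TestSummarizeLengths:
    def test_basic_summary(self):
        s = gf.summarize_lengths([1, 2, 3], genome_size=100)
        assert (s.total, s.mean, s.median, s.percent_of_genome) == (6, 2.0, 2.0, 6.0)

    def test_constant_list_all_quantiles_equal(self):
        s = gf.summarize_lengths([7] * 10, genome_size=100)
        assert s.q25 == s.median == s.q75 == 7.0

    def test_quantiles_match_sort_interpolate_oracle(self):
        lengths = list(range(1, 101))

        def quantile_oracle(xs, q):
            xs = sorted(xs)
            pos = q * (len(xs) - 1)
            lo = int(pos)
            frac = pos - lo
            return xs[lo] + frac * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])

        s = gf.summarize_lengths(lengths, genome_size=10**6)
        assert s.q25 == pytest.approx(quantile_oracle(lengths, 0.25))
        assert s.q75 == pytest.approx(quantile_oracle(lengths, 0.75))
        assert s.q25 <= s.median <= s.q75 <= s.maximum

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            gf.summarize_lengths([], genome_size=100)
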