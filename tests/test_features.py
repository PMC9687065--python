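import numpy as np
import pytest
from conftest import make_transcript, random_transcript
from oracles import brute_dej, brute_longest_orf, brute_uorfs, brute_utr3

from nmdkit.features import (
    FeatureConfig,
    GenomicInterval,
    GtfParseError,
    NmdFeatureSet,
    TranscriptModel,
    annotate_transcripts,
    assign_orf,
    collapse_to_gene,
    detect_dej,
    detect_uorfs,
    is_evaluable,
    measure_utr3,
    median_utr3_length,
    read_fasta,
    read_gtf,
    write_fasta,
    write_gtf,
)


class TestInterval:
    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5, "+")

    def test_rejects_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, ".")


class TestTranscriptModel:
    def test_cds_not_multiple_of_three(self):
        with pytest.raises(GtfParseError):
            make_transcript([100], cds=(10, 21))

    def test_mixed_strands_rejected(self):
        exons = [
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 200, 300, "-"),
        ]
        with pytest.raises(GtfParseError):
            TranscriptModel("t", "g", exons)

    def test_overlapping_exons_rejected(self):
        exons = [
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 50, 150, "+"),
        ]
        with pytest.raises(GtfParseError):
            TranscriptModel("t", "g", exons)

    def test_junctions_minus_strand(self):
        # 5'->3' exon lengths (60, 40): single junction at 60 on either strand
        for strand in "+-":
            t = make_transcript([60, 40], strand=strand)
            assert t.junctions() == [60]
            assert t.length == 100


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "one.gtf"
        path.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        (model,) = read_gtf(path)
        assert (model.exons[0].start, model.exons[0].end) == (100, 200)
        assert model.length == 100

    def test_round_trip(self, tmp_path, default_annotation):
        _, models, _, _ = default_annotation
        path = tmp_path / "rt.gtf"
        write_gtf(models, path)
        back = {m.transcript_id: m for m in read_gtf(path)}
        assert len(back) == len(models)
        for m in models:
            b = back[m.transcript_id]
            assert b.exons == m.exons
            assert (b.cds_start, b.cds_end) == (m.cds_start, m.cds_end)
            assert b.gene_id == m.gene_id

    def test_bad_cds_length_raises(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\tCDS\t10\t20\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(GtfParseError):
            read_gtf(path)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 40, "b": "TTTT"}
        path = tmp_path / "s.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs


class TestAssignOrf:
    def test_hand_example(self):
        t = make_transcript([13])
        out = assign_orf(t, "AAATGGCGTAGCC")
        assert (out.cds_start, out.cds_end) == (2, 11)
        assert is_evaluable(out)

    def test_no_atg_not_evaluable(self):
        t = make_transcript([12])
        out = assign_orf(t, "CCCCCCCCCCCC")
        assert not out.has_cds()
        assert not is_evaluable(out)

    def test_annotated_cds_takes_precedence(self):
        # longest ORF spans 0..12, annotation says 6..12: annotation wins
        seq = "ATGAAAATGTAACC"
        t = make_transcript([14], cds=(6, 12))
        out = assign_orf(t, seq)
        assert (out.cds_start, out.cds_end) == (6, 12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            assign_orf(make_transcript([10]), "ACGT")

    def test_matches_longest_orf_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 300))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            t = make_transcript([n])
            out = assign_orf(t, seq)
            expected = brute_longest_orf(seq)
            got = (out.cds_start, out.cds_end) if out.has_cds() else None
            assert got == expected


class TestDetectDej:
    def test_single_exon(self):
        t = make_transcript([300], cds=(3, 123))
        assert detect_dej(t) == (False, None)

    def test_spec_positive_case(self):
        t = make_transcript([200, 100], cds=(3, 123))
        has, dist = detect_dej(t)
        assert (has, dist) == (True, 77.0)

    def test_spec_negative_case(self):
        t = make_transcript([200, 100], cds=(1, 160))
        has, dist = detect_dej(t)
        assert (has, dist) == (False, 40.0)

    def test_boundary_strictly_greater(self):
        # distance exactly at the threshold is not a dEJ
        t = make_transcript([200, 100], cds=(0, 150))
        assert detect_dej(t, FeatureConfig(dej_threshold=50)) == (False, 50.0)
        assert detect_dej(t, FeatureConfig(dej_threshold=49))[0] is True


class TestDetectUorfs:
    def test_no_atg(self):
        t = make_transcript([20], cds=(6, 18))
        assert detect_uorfs(t, "CCCCCC" + "ATGAAATGACC"[:14]) == 0

    def test_two_codon_uorf_threshold(self):
        seq = "ATGTAA" + "ATGAAATAA" + "C"
        t = make_transcript([len(seq)], cds=(6, 15))
        assert detect_uorfs(t, seq, FeatureConfig(uorf_min_codons=2)) == 1
        assert detect_uorfs(t, seq, FeatureConfig(uorf_min_codons=3)) == 0

    def test_overlapping_uorf_excluded(self):
        # uORF stop lands past the main start codon
        seq = "CATGAA" + "ATGAAATAA"
        t = make_transcript([len(seq)], cds=(6, 15))
        assert detect_uorfs(t, seq, FeatureConfig(uorf_min_codons=2)) == 0


class TestMeasureUtr3:
    def test_orf_at_end(self):
        t = make_transcript([120], cds=(3, 120))
        length, _ = measure_utr3(t, FeatureConfig(long_utr3_rule="absolute_nt", long_utr3_value=10))
        assert length == 0

    def test_subtraction(self):
        t = make_transcript([2000], cds=(2, 500))
        length, _ = measure_utr3(t, FeatureConfig(long_utr3_rule="absolute_nt", long_utr3_value=1e9))
        assert length == 1500

    def test_median_multiple_rule(self):
        t = make_transcript([1000], cds=(1, 100))
        cfg = FeatureConfig(long_utr3_rule="multiple_of_annotation_median", long_utr3_value=2.0)
        _, is_long = measure_utr3(t, cfg, annotation_median=400.0)
        assert is_long  # 900 >= 2 * 400
        _, is_long = measure_utr3(t, cfg, annotation_median=500.0)
        assert not is_long

    def test_median_helper(self):
        ts = [
            make_transcript([100], cds=(1, 40), transcript_id=f"t{i}")
            for i in range(3)
        ]
        assert median_utr3_length(ts) == 60.0


class TestCollapse:
    def _fs(self, tid, gid, dej=None, uorf=None, long3=None, evaluable=True):
        return NmdFeatureSet(
            tid, gid, evaluable,
            has_dej=dej, dej_distance=None,
            utr3_length=100, is_long_utr3=long3, n_uorfs=uorf,
        )

    def test_any_positive_transcript_makes_gene_positive(self):
        frame = collapse_to_gene([
            self._fs("t1", "g", dej=True, uorf=0, long3=False),
            self._fs("t2", "g", dej=False, uorf=0, long3=False),
        ])
        assert bool(frame.loc["g", "has_dej"]) is True

    def test_no_evaluable_transcripts(self):
        frame = collapse_to_gene([self._fs("t1", "g", evaluable=False)])
        assert not frame.loc["g", "evaluable"]

    def test_all_negative(self):
        frame = collapse_to_gene([
            self._fs("t1", "g", dej=False, uorf=0, long3=False),
            self._fs("t2", "g", dej=False, uorf=0, long3=False),
        ])
        assert not frame.loc["g", ["has_dej", "has_uorf", "is_long_utr3"]].any()


class TestOracleEquivalence:
    """Nucleotide-level brute force vs the detectors on random transcripts."""

    def test_500_random_transcripts(self, rng):
        cfg = FeatureConfig()
        for i in range(500):
            model, seq = random_transcript(rng, transcript_id=f"t{i}")
            has, dist = detect_dej(model, cfg)
            exp_has, exp_dist = brute_dej(
                model.exon_lengths_5to3(), model.cds_end, cfg.dej_threshold
            )
            assert (has, dist) == (exp_has, exp_dist), f"dEJ mismatch on t{i}"
            assert detect_uorfs(model, seq, cfg) == brute_uorfs(
                seq, model.cds_start, cfg.uorf_min_codons
            ), f"uORF mismatch on t{i}"
            length, _ = measure_utr3(
                model, FeatureConfig(long_utr3_rule="absolute_nt", long_utr3_value=1e9)
            )
            assert length == brute_utr3(model.length, model.cds_end)

    def test_strand_invariance(self, rng):
        cfg = FeatureConfig()
        for i in range(100):
            model, seq = random_transcript(rng, transcript_id=f"s{i}")
            # mirror the locus: same 5'->3' structure on the other strand
            flipped = make_transcript(
                model.exon_lengths_5to3(),
                cds=(model.cds_start, model.cds_end),
                strand="-" if model.strand == "+" else "+",
                transcript_id=f"s{i}f",
            )
            assert detect_dej(flipped, cfg) == detect_dej(model, cfg)
            assert detect_uorfs(flipped, seq, cfg) == detect_uorfs(model, seq, cfg)

    def test_threshold_monotonicity(self, rng):
        for i in range(100):
            model, _ = random_transcript(rng)
            calls = [
                detect_dej(model, FeatureConfig(dej_threshold=thr))[0]
                for thr in (10, 50, 100, 500)
            ]
            # increasing the threshold can only switch True -> False
            for earlier, later in zip(calls, calls[1:]):
                assert earlier or not later


class TestAnnotatePipeline:
    def test_feature_table_roundtrip(self, default_annotation):
        _, models, sequences, _ = default_annotation
        sets = annotate_transcripts(models, sequences)
        assert len(sets) == len(models)
        gene = collapse_to_gene(sets)
        assert gene.index.is_unique

    def test_missing_sequence_raises(self, default_annotation):
        _, models, sequences, _ = default_annotation
        with pytest.raises(KeyError):
            annotate_transcripts(models[:1], {})
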