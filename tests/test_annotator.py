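import numpy as np
import pytest

from asnmd.annotation import ExonInterval, GenomeSequence
from asnmd.annotator import (
    ChainConflictError,
    IsoformVariant,
    annotate_event,
    build_isoform_pair,
    check_transcript_nmd,
    confusion_metrics,
    evaluate_predictions,
    filter_annotations,
    find_compatible_transcripts,
    scan_orf,
    summarize_flags,
)
from asnmd.simulate import LocusSpec, make_locus, random_isoform
from conftest import orf_oracle


class TestFindCompatibleTranscripts:
    def test_inclusion_reference_has_se_present(self, loci):
        locus = loci["poison_exon"]
        out = find_compatible_transcripts(locus.event, locus.annotation_index())
        assert len(out) == 1
        _, se_present = out[0]
        assert se_present is True

    def test_exclusion_reference_has_se_absent(self, loci):
        locus = loci["nmd_ex_frameshift"]
        out = find_compatible_transcripts(locus.event, locus.annotation_index())
        assert len(out) == 1
        assert out[0][1] is False

    def test_conflicting_middle_exon_incompatible(self, loci):
        import copy

        locus = loci["poison_exon"]
        event = copy.deepcopy(locus.event)
        # shift the SE bounds so the annotated middle exon no longer matches
        event.se_exon = ExonInterval(event.contig, event.se_exon.start + 3,
                                     event.se_exon.end - 3, event.strand)
        assert find_compatible_transcripts(event, locus.annotation_index()) == []


class TestBuildIsoformPair:
    def test_reference_with_se_reconstructs_exclusion(self, loci):
        locus = loci["poison_exon"]
        (tm, _), = find_compatible_transcripts(locus.event, locus.annotation_index())
        inc, exc = build_isoform_pair(locus.event, tm)
        assert not inc.reconstructed and exc.reconstructed
        assert len(inc.exon_chain) == len(exc.exon_chain) + 1

    def test_reference_without_se_reconstructs_inclusion(self, loci):
        locus = loci["nmd_ex_frameshift"]
        (tm, _), = find_compatible_transcripts(locus.event, locus.annotation_index())
        inc, exc = build_isoform_pair(locus.event, tm)
        assert inc.reconstructed and not exc.reconstructed
        se = locus.event.se_exon
        assert any(e.start == se.start and e.end == se.end for e in inc.exon_chain)

    def test_se_overlapping_flank_is_chain_conflict(self, loci):
        import copy

        locus = loci["poison_exon"]
        (tm, _), = find_compatible_transcripts(locus.event, locus.annotation_index())
        event = copy.deepcopy(locus.event)
        up = event.upstream_exon
        event.se_exon = ExonInterval(event.contig, up.end - 5, event.se_exon.end, event.strand)
        with pytest.raises(ChainConflictError):
            build_isoform_pair(event, tm)


def _isoform_from_lengths(lengths, mrna, start_tx):
    """Helper: lay an explicit mRNA onto a plus-strand contig without introns
    of interest (50-nt gaps) and return the isoform + genome."""
    contig = "C" * 20
    exons, gpos, off = [], 20, 0
    pieces = [contig]
    for L in lengths:
        pieces.append(mrna[off : off + L])
        exons.append(ExonInterval("t", gpos + 1, gpos + L, "+"))
        gpos += L
        off += L
        pieces.append("C" * 50)
        gpos += 50
    genome = GenomeSequence({"t": "".join(pieces)})
    iso = IsoformVariant("T", "inclusion", exons, False, exons[0].start + start_tx - 1)
    return iso, genome


class TestScanOrf:
    def _mrna(self, total, stop_last_base, start_tx=1):
        body = ["C"] * total
        body[start_tx - 1 : start_tx + 2] = list("ATG")
        body[stop_last_base - 3 : stop_last_base] = list("TAA")
        return "".join(body)

    def test_dj_60_is_nmd(self):
        iso, genome = _isoform_from_lengths([90, 60, 150], self._mrna(300, 90), 1)
        orf = scan_orf(iso, genome)
        assert (orf.stop_tx, orf.dj, orf.is_nmd) == (90, 60, True)

    def test_dj_30_not_nmd(self):
        iso, genome = _isoform_from_lengths([90, 60, 150], self._mrna(300, 120), 1)
        orf = scan_orf(iso, genome)
        assert (orf.dj, orf.is_nmd) == (30, False)

    def test_stop_in_last_exon_negative_dj(self):
        iso, genome = _isoform_from_lengths([90, 60, 150], self._mrna(300, 153), 1)
        orf = scan_orf(iso, genome)
        assert orf.dj == -3 and not orf.is_nmd

    def test_stopless_isoform_flagged(self):
        body = "C" * 300
        mrna = "ATG" + body[3:]
        iso, genome = _isoform_from_lengths([90, 60, 150], mrna, 1)
        orf = scan_orf(iso, genome)
        assert orf.status == "no_stop" and orf.stop_tx is None and not orf.is_nmd

    def test_n_in_codon_is_not_a_stop(self):
        mrna = list(self._mrna(300, 90))
        mrna[87:90] = list("TNA")  # would-be stop contains N
        mrna[117:120] = list("TAA")  # next in-frame stop ends at tx 120
        iso, genome = _isoform_from_lengths([90, 60, 150], "".join(mrna), 1)
        orf = scan_orf(iso, genome)
        assert orf.stop_tx == 120

    def test_start_lost_when_cds_start_inside_skipped_exon(self, loci):
        locus = loci["poison_exon"]
        (tm, _), = find_compatible_transcripts(locus.event, locus.annotation_index())
        inc, exc = build_isoform_pair(locus.event, tm)
        # move the CDS start into the SE exon; the exclusion form loses it
        exc.cds_start_genomic = locus.event.se_exon.start + 1
        orf = scan_orf(exc, locus.genome)
        assert orf.status == "start_lost" and not orf.is_nmd

    def test_matches_bruteforce_oracle_on_random_isoforms(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            iso, genome = random_isoform(rng)
            got = scan_orf(iso, genome)
            want = orf_oracle(iso, genome)
            assert want is not None
            assert got.start_tx == want["start_tx"]
            assert got.stop_tx == want["stop_tx"]
            assert got.dj == want["dj"]
            assert got.utr3_len == want["utr3_len"]
            assert got.is_nmd == want["is_nmd"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            iso, genome = random_isoform(rng)
            nmd_at = [scan_orf(iso, genome, t).is_nmd for t in (0, 25, 50, 100, 400)]
            # once non-NMD at some threshold, stays non-NMD at higher ones
            assert nmd_at == sorted(nmd_at, reverse=True)


class TestClassification:
    def test_frame_conservation_for_orf_preserving(self, loci):
        locus = loci["orf_preserving"]
        idx = locus.annotation_index()
        (tm, _), = find_compatible_transcripts(locus.event, idx)
        inc, exc = build_isoform_pair(locus.event, tm)
        io, eo = scan_orf(inc, locus.genome), scan_orf(exc, locus.genome)
        se_len = len(locus.event.se_exon)
        assert io.stop_tx - eo.stop_tx == se_len
        assert io.is_nmd == eo.is_nmd

    def test_nmd_ex_requires_exclusion_only_decay(self, loci):
        locus = loci["nmd_ex_frameshift"]
        ann = annotate_event(locus.event, locus.annotation_index(), locus.genome)
        assert ann.flag == "NMD_ex"
        forms = {(iso.form, orf.is_nmd) for iso, orf in ann.per_isoform}
        assert ("exclusion", True) in forms and ("inclusion", False) in forms

    def test_aggregates_on_poison_event(self, loci):
        locus = loci["poison_exon"]
        ann = annotate_event(locus.event, locus.annotation_index(), locus.genome)
        assert ann.aggregates["max_dj"] == locus.truth["dj_inclusion"]
        assert 0 < ann.aggregates["min_stop_pos_f"] <= 1


class TestFilterAndSummaries:
    def test_non_atg_event_removed(self, loci):
        locus = loci["non_atg_start"]
        ann = annotate_event(locus.event, locus.annotation_index(), locus.genome)
        kept, removed = filter_annotations([ann])
        assert kept == [] and removed["non_ATG_filtered"] == 1
        assert ann.flag == "non_ATG_filtered"

    def test_summarize_counts_and_gene_rollup(self, loci):
        anns = [
            annotate_event(loci[sc].event, loci[sc].annotation_index(), loci[sc].genome)
            for sc in ("poison_exon", "nmd_ex_frameshift", "orf_preserving")
        ]
        summary = summarize_flags(anns)
        assert summary["flag_counts"] == {"NMD_in": 1, "NMD_ex": 1, "ORF_preserving": 1}
        assert summary["total"] == 3
        assert summary["genes_nmd_in"] == ["GENE_POISON_EXON"]
        assert summary["genes_nmd_ex"] == ["GENE_NMD_EX_FRAMESHIFT"]


class TestCheckTranscriptNmd:
    def test_dj_boundary_strictly_greater_than_50(self, tmp_path):
        rows = []
        for dj, expect in ((49, False), (50, False), (51, True)):
            locus = make_locus(LocusSpec("poison_exon", dj_target=dj, seed=dj))
            d = tmp_path / f"dj{dj}"
            d.mkdir()
            locus.write_fasta(d / "g.fa")
            locus.write_gtf(d / "a.gtf")
            genome = GenomeSequence.from_fasta(d / "g.fa")
            table = check_transcript_nmd(d / "a.gtf", genome)
            row = table.iloc[0]
            assert row["dj"] == dj
            assert bool(row["is_nmd"]) is expect

    def test_noncoding_not_assessed(self, tmp_path):
        gtf = tmp_path / "nc.gtf"
        gtf.write_text(
            'c\tx\texon\t1\t60\t.\t+\t.\tgene_id "G"; transcript_id "T"; transcript_type "lncRNA";\n'
        )
        fa = tmp_path / "nc.fa"
        fa.write_text(">c\n" + "ACGT" * 20 + "\n")
        table = check_transcript_nmd(gtf, GenomeSequence.from_fasta(fa))
        assert table.iloc[0]["status"] == "not_assessed"


class TestEvaluatePredictions:
    def test_confusion_formulas_match_direct_arithmetic(self):
        m = confusion_metrics(tp=45, fp=2, fn=3)
        assert m["precision"] == pytest.approx(45 / 47, abs=1e-12)
        assert m["recall"] == pytest.approx(45 / 48, abs=1e-12)
        f1 = 2 * (45 / 47) * (45 / 48) / ((45 / 47) + (45 / 48))
        assert m["f1"] == pytest.approx(f1, abs=1e-12)
        assert m["f1"] == pytest.approx(0.9474, abs=5e-5)

    def test_perfect_predictions(self):
        pred = {"a": "NMD_in", "b": "ORF_preserving"}
        truth = {"a": "NMD", "b": "non-NMD"}
        m = evaluate_predictions(pred, truth)
        assert (m["coverage"], m["precision"], m["recall"], m["f1"]) == (1.0, 1.0, 1.0, 1.0)

    def test_no_positive_predictions_undefined_precision(self):
        pred = {"a": "ORF_preserving"}
        truth = {"a": "NMD", "b": "NMD"}
        m = evaluate_predictions(pred, truth)
        assert m["recall"] == 0.0
        assert m["precision"] is None
        assert m["coverage"] == 0.5
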