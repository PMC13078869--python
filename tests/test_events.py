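import copy

import pytest

from asnmd.annotation import ExonInterval
from asnmd.events import (
    EventFormatError,
    JunctionCounts,
    SpliceEvent,
    convert_suppa_ioe,
    filter_dynamic,
    flag_known_mxe,
    mxe_count_filter,
    psi_pattern_cluster,
    read_rmats_se,
    write_rmats_se,
)

RMATS_HEADER = (
    "ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
    "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
    "IJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\t"
    "IncLevel1\tIncLevel2\tIncLevelDifference\tFDR"
)


def _write_rmats(tmp_path, rows, header=RMATS_HEADER):
    path = tmp_path / "se.txt"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def _make_event(ujc, djc, **kw):
    defaults = dict(
        event_id="e1", gene_id="g", gene_name="g", contig="c", strand="+",
        se_exon=ExonInterval("c", 101, 150, "+"),
        upstream_exon=ExonInterval("c", 1, 50, "+"),
        downstream_exon=ExonInterval("c", 201, 250, "+"),
        counts=JunctionCounts(ujc=list(ujc), djc=list(djc), sjc=[0] * len(ujc)),
    )
    defaults.update(kw)
    return SpliceEvent(**defaults)


class TestReadRmats:
    def test_zero_based_start_converted(self, tmp_path):
        path = _write_rmats(tmp_path, [
            "e1\tg\tg\tc\t+\t100\t150\t0\t50\t200\t250\t5,5\t5,5\t5,5\t5,5\t0.5,0.6\t0.2,0.3\t0.3\t0.01",
        ])
        (ev,) = read_rmats_se(path)
        assert (ev.se_exon.start, ev.se_exon.end) == (101, 150)
        assert len(ev.se_exon) == 50
        assert ev.upstream_exon.start == 1

    def test_na_psi_becomes_missing(self, tmp_path):
        path = _write_rmats(tmp_path, [
            "e1\tg\tg\tc\t+\t100\t150\t0\t50\t200\t250\t5,5\t5,5\t5,5\t5,5\t0.5,NA\t0.2,0.3\t0.3\t0.01",
        ])
        (ev,) = read_rmats_se(path)
        assert ev.psi[:2] == [0.5, None]

    def test_missing_column_is_format_error(self, tmp_path):
        header = RMATS_HEADER.replace("\tupstreamES", "")
        path = _write_rmats(tmp_path, [
            "e1\tg\tg\tc\t+\t100\t150\t50\t200\t250\t5\t5\t5\t5\t0.5\t0.2\t0.3\t0.01",
        ], header=header)
        with pytest.raises(EventFormatError, match="upstreamES"):
            read_rmats_se(path)

    def test_minus_strand_upstream_is_5prime_flank(self, tmp_path):
        # file written with genomic-left exon in the upstream columns
        path = _write_rmats(tmp_path, [
            "e1\tg\tg\tc\t-\t100\t150\t0\t50\t200\t250\t5,5\t5,5\t5,5\t5,5\t0.5,0.6\t0.2,0.3\t0.3\t0.01",
        ])
        (ev,) = read_rmats_se(path)
        assert ev.upstream_exon.start == 201  # genomic right = 5' flank on minus

    def test_roundtrip_on_canonical_columns(self, tmp_path, loci):
        events = [loci[sc].event for sc in ("poison_exon", "orf_preserving", "utr3_exon")]
        out = tmp_path / "rt.txt"
        write_rmats_se(events, out, extended_counts=True)
        back = read_rmats_se(out, extended_counts=True)
        for a, b in zip(events, back):
            assert a.se_exon == b.se_exon
            assert a.upstream_exon == b.upstream_exon
            assert a.downstream_exon == b.downstream_exon
            assert a.psi == b.psi
            assert a.delta_psi == pytest.approx(b.delta_psi)
            assert a.fdr == pytest.approx(b.fdr)
            assert a.counts.ujc == b.counts.ujc
            assert a.counts.djc == b.counts.djc


class TestConvertSuppa:
    def test_se_identifier_matches_annotation_exon(self, loci):
        locus = loci["orf_preserving"]
        index = locus.annotation_index()
        ev = locus.event
        ioe_line = (
            f"{ev.contig}\t{ev.gene_id}\t{ev.gene_id};SE:{ev.contig}:"
            f"{ev.upstream_exon.end}-{ev.se_exon.start}:"
            f"{ev.se_exon.end}-{ev.downstream_exon.start}:+\tt1\tt1,t2"
        )
        content = "seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n" + ioe_line + "\n"
        import io, tempfile, os
        path = tempfile.mktemp()
        with open(path, "w") as fh:
            fh.write(content)
        try:
            events, skipped = convert_suppa_ioe(path, index)
        finally:
            os.unlink(path)
        assert skipped == 0
        assert events[0].se_exon == ev.se_exon
        assert events[0].upstream_exon == ev.upstream_exon
        assert events[0].downstream_exon == ev.downstream_exon

    def test_non_se_event_skipped_and_counted(self, tmp_path, loci):
        index = loci["orf_preserving"].annotation_index()
        path = tmp_path / "x.ioe"
        path.write_text(
            "seqname\tgene_id\tevent_id\talt\ttotal\n"
            "c\tg\tg;A3:c:100-200:100-250:+\tt1\tt1,t2\n"
        )
        events, skipped = convert_suppa_ioe(path, index)
        assert events == [] and skipped == 1

    def test_unknown_boundary_is_row_error(self, tmp_path, loci):
        index = loci["orf_preserving"].annotation_index()
        path = tmp_path / "x.ioe"
        path.write_text(
            "seqname\tgene_id\tevent_id\talt\ttotal\n"
            "nochr\tg\tg;SE:nochr:10-20:30-40:+\tt1\tt1,t2\n"
        )
        with pytest.raises(EventFormatError):
            convert_suppa_ioe(path, index)


class TestFilterDynamic:
    def _ev(self, dpsi, fdr, psi=()):
        return _make_event([5, 5], [5, 5], delta_psi=dpsi, fdr=fdr, psi=list(psi))

    def test_boundary_dpsi_not_strictly_greater_dropped(self):
        assert filter_dynamic([self._ev(0.10, 0.01)]) == []

    def test_negative_dpsi_kept(self):
        evs = [self._ev(-0.25, 0.001)]
        assert filter_dynamic(evs) == evs

    def test_high_fdr_dropped(self):
        assert filter_dynamic([self._ev(0.4, 0.2)]) == []

    def test_subset_and_idempotent(self):
        evs = [self._ev(d, f) for d, f in [(0.2, 0.01), (0.05, 0.01), (0.3, 0.5)]]
        once = filter_dynamic(evs)
        assert set(id(e) for e in once) <= set(id(e) for e in evs)
        assert filter_dynamic(once) == once

    def test_psi_range_prefilter(self):
        keep = self._ev(0.3, 0.01, psi=[0.1, 0.5])
        drop = self._ev(0.3, 0.01, psi=[0.01, 0.5])
        assert filter_dynamic([keep, drop], apply_psi_range=True) == [keep]


class TestMxeCountFilter:
    def test_one_sided_junctions_excluded(self):
        ev = _make_event([10, 10], [0, 0])
        assert mxe_count_filter(ev) == "exclude_mxe_like"  # mean min 0 < 2

    def test_ratio_at_or_below_threshold_excluded(self):
        ev = _make_event([100, 100], [4, 4])  # mean min 4 >= 2; ratio 8/200 = 0.04
        assert mxe_count_filter(ev) == "exclude_mxe_like"

    def test_balanced_junctions_kept(self):
        ev = _make_event([100, 100], [7, 7])  # ratio 14/200 = 0.07
        assert mxe_count_filter(ev) == "keep"

    def test_permutation_invariant_across_samples(self):
        base = ([3, 50, 8, 1], [9, 2, 40, 7])
        verdicts = set()
        import itertools
        for perm in itertools.permutations(range(4)):
            ujc = [base[0][i] for i in perm]
            djc = [base[1][i] for i in perm]
            verdicts.add(mxe_count_filter(_make_event(ujc, djc)))
        assert len(verdicts) == 1

    def test_missing_counts_kept_with_mark(self):
        ev = _make_event([1], [1], counts=None)
        assert mxe_count_filter(ev) == "keep"
        assert "mxe_unfiltered" in ev.marks


class TestFlagKnownMxe:
    def test_overlap_marks_event(self, tmp_path):
        ev = _make_event([5, 5], [5, 5])
        bed = tmp_path / "m.bed"
        bed.write_text("c\t139\t200\tmxe\t0\t+\n")  # 1-based [140,200]
        flag_known_mxe([ev], bed)
        assert "known_mxe" in ev.marks

    def test_opposite_strand_not_marked(self, tmp_path):
        ev = _make_event([5, 5], [5, 5])
        bed = tmp_path / "m.bed"
        bed.write_text("c\t139\t200\tmxe\t0\t-\n")
        flag_known_mxe([ev], bed)
        assert "known_mxe" not in ev.marks

    def test_empty_reference_no_marks(self, tmp_path):
        ev = _make_event([5, 5], [5, 5])
        bed = tmp_path / "m.bed"
        bed.write_text("")
        flag_known_mxe([ev], bed)
        assert ev.marks == set()


class TestPsiPatternCluster:
    @pytest.mark.parametrize(
        "series,label",
        [
            ([0.20, 0.25, 0.40], "UU"),
            ([0.50, 0.46], "N"),
            ([0.50, 0.30, 0.33], "DN"),  # FC exactly 1.10 is not > 1.1
            ([0.0, 0.2], "U"),
            ([0.0, 0.0], "N"),
            ([0.4, 0.2, 0.5, 0.5], "DUN"),
        ],
    )
    def test_fold_change_rule(self, series, label):
        assert psi_pattern_cluster(series) == label

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            psi_pattern_cluster([0.5])
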