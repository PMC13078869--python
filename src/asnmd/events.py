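"""Skipped-exon event tables: rMATS SE.JCEC and SUPPA2 ioe readers, the
significance / PSI-range filter, mutually-exclusive-exon (MXE) screens and
PSI pattern clustering.

An SE (cassette) event is one alternative exon between two constitutive
flanking exons.  ``upstream`` / ``downstream`` always refer to transcript
orientation (upstream = 5' flank), so on the minus strand the upstream
exon is genomically to the right of the cassette.  rMATS 0-based starts
are converted to the package's 1-based inclusive convention at read time;
BED intervals are 0-based half-open per the BED standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import AnnotationIndex, ExonInterval

logger = logging.getLogger(__name__)

RMATS_REQUIRED_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
    "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncLevel1", "IncLevel2", "IncLevelDifference", "FDR",
]
RMATS_EXTENDED_COLUMNS = ["UJC_SAMPLE_1", "DJC_SAMPLE_1", "UJC_SAMPLE_2", "DJC_SAMPLE_2"]


class EventFormatError(ValueError):
    """Missing column or unparseable row in an event table."""


@dataclass
class JunctionCounts:
    """Per-sample junction read support for one SE event.

    ujc/djc: reads on the upstream- and downstream-inclusion junctions;
    sjc: reads on the skipping junction.  Lists are ordered sample 1
    replicates then sample 2 replicates; ``conditions`` carries the
    matching condition label per entry.
    """

    ujc: list[int]
    djc: list[int]
    sjc: list[int]
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, values in (("UJC", self.ujc), ("DJC", self.djc), ("SJC", self.sjc)):
            if any(v < 0 for v in values):
                raise ValueError(f"negative {name} count")


@dataclass
class SpliceEvent:
    event_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    se_exon: ExonInterval
    upstream_exon: ExonInterval
    downstream_exon: ExonInterval
    psi: list[float | None] = field(default_factory=list)
    delta_psi: float | None = None
    fdr: float | None = None
    counts: JunctionCounts | None = None
    source: str = "rmats"
    marks: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        up, dn = self.upstream_exon, self.downstream_exon
        if self.strand == "+":
            ok = up.end < self.se_exon.start and self.se_exon.end < dn.start
        else:
            ok = dn.end < self.se_exon.start and self.se_exon.end < up.start
        if not ok:
            raise ValueError(
                f"event {self.event_id}: flanking exons do not bracket the SE exon "
                f"in transcript orientation"
            )
        for p in self.psi:
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"event {self.event_id}: PSI {p} outside [0,1]")


def _parse_psi_list(text: str) -> list[float | None]:
    out: list[float | None] = []
    for tok in str(text).split(","):
        tok = tok.strip()
        out.append(None if tok in ("NA", "", "nan") else float(tok))
    return out


def _parse_count_list(text: str) -> list[int]:
    return [int(tok) for tok in str(text).split(",") if tok.strip() not in ("", "NA")]


def read_rmats_se(path: str | Path, extended_counts: bool = False) -> list[SpliceEvent]:
    """Read an rMATS SE.JCEC table into :class:`SpliceEvent` records.

    The extended dialect additionally carries per-replicate UJC/DJC columns
    (separate upstream / downstream inclusion-junction counts); the
    standard dialect leaves ``counts`` unset.  0-based exon starts become
    1-based inclusive.  On minus-strand rows whose upstream fields name the
    genomic-left exon, upstream/downstream labels are swapped so that
    upstream is always the 5' flank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RMATS_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventFormatError(f"rMATS table missing required column(s): {missing}")
    if extended_counts:
        missing = [c for c in RMATS_EXTENDED_COLUMNS if c not in df.columns]
        if missing:
            raise EventFormatError(f"extended rMATS dialect missing column(s): {missing}")

    events: list[SpliceEvent] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            contig, strand = row["chr"], row["strand"]
            se = ExonInterval(contig, int(row["exonStart_0base"]) + 1, int(row["exonEnd"]), strand)
            up = ExonInterval(contig, int(row["upstreamES"]) + 1, int(row["upstreamEE"]), strand)
            dn = ExonInterval(contig, int(row["downstreamES"]) + 1, int(row["downstreamEE"]), strand)
        except (ValueError, TypeError) as exc:
            raise EventFormatError(f"rMATS row at line {lineno}: {exc}") from exc
        if strand == "-" and up.end < se.start:
            up, dn = dn, up  # file used genomic-left = upstream; normalize to 5' flank
        psi1 = _parse_psi_list(row["IncLevel1"])
        psi2 = _parse_psi_list(row["IncLevel2"])
        counts = None
        if extended_counts:
            ujc = _parse_count_list(row["UJC_SAMPLE_1"]) + _parse_count_list(row["UJC_SAMPLE_2"])
            djc = _parse_count_list(row["DJC_SAMPLE_1"]) + _parse_count_list(row["DJC_SAMPLE_2"])
            sjc = _parse_count_list(row["SJC_SAMPLE_1"]) + _parse_count_list(row["SJC_SAMPLE_2"])
            conditions = ["sample1"] * len(_parse_count_list(row["UJC_SAMPLE_1"])) + \
                         ["sample2"] * len(_parse_count_list(row["UJC_SAMPLE_2"]))
            counts = JunctionCounts(ujc=ujc, djc=djc, sjc=sjc, conditions=conditions)
        events.append(
            SpliceEvent(
                event_id=str(row["ID"]),
                gene_id=str(row["GeneID"]),
                gene_name=str(row["geneSymbol"]),
                contig=contig,
                strand=strand,
                se_exon=se,
                upstream_exon=up,
                downstream_exon=dn,
                psi=psi1 + psi2,
                delta_psi=float(row["IncLevelDifference"]),
                fdr=float(row["FDR"]),
                counts=counts,
                source="rmats",
            )
        )
    return events


def write_rmats_se(events: Sequence[SpliceEvent], path: str | Path, extended_counts: bool = False) -> None:
    """Write events back to the rMATS SE.JCEC dialect (inverse of read)."""
    rows = []
    for ev in events:
        up, dn = ev.upstream_exon, ev.downstream_exon
        if ev.strand == "-":
            up, dn = dn, up  # emit genomic-left exon in the upstream columns
        n1 = ev.counts.conditions.count("sample1") if ev.counts and ev.counts.conditions else max(
            1, len(ev.psi) // 2)
        psi1, psi2 = ev.psi[:n1], ev.psi[n1:]
        fmt_psi = lambda vals: ",".join("NA" if v is None else f"{v:g}" for v in vals)
        row = {
            "ID": ev.event_id, "GeneID": ev.gene_id, "geneSymbol": ev.gene_name,
            "chr": ev.contig, "strand": ev.strand,
            "exonStart_0base": ev.se_exon.start - 1, "exonEnd": ev.se_exon.end,
            "upstreamES": up.start - 1, "upstreamEE": up.end,
            "downstreamES": dn.start - 1, "downstreamEE": dn.end,
            "IJC_SAMPLE_1": "", "SJC_SAMPLE_1": "", "IJC_SAMPLE_2": "", "SJC_SAMPLE_2": "",
            "IncLevel1": fmt_psi(psi1), "IncLevel2": fmt_psi(psi2),
            "IncLevelDifference": "" if ev.delta_psi is None else f"{ev.delta_psi:g}",
            "FDR": "" if ev.fdr is None else f"{ev.fdr:g}",
        }
        if ev.counts is not None:
            fmt = lambda vals: ",".join(str(v) for v in vals)
            row["SJC_SAMPLE_1"] = fmt(ev.counts.sjc[:n1])
            row["SJC_SAMPLE_2"] = fmt(ev.counts.sjc[n1:])
            if extended_counts:
                row["UJC_SAMPLE_1"] = fmt(ev.counts.ujc[:n1])
                row["UJC_SAMPLE_2"] = fmt(ev.counts.ujc[n1:])
                row["DJC_SAMPLE_1"] = fmt(ev.counts.djc[:n1])
                row["DJC_SAMPLE_2"] = fmt(ev.counts.djc[n1:])
        rows.append(row)
    cols = list(RMATS_REQUIRED_COLUMNS)
    if extended_counts:
        cols += RMATS_EXTENDED_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def convert_suppa_ioe(ioe_path: str | Path, annotation: AnnotationIndex) -> tuple[list[SpliceEvent], int]:
    """Convert a SUPPA2 ``.ioe`` file to SE events.

    SE event identifiers encode ``SE:chr:e1-s2:e2-s3:strand`` where e1 is
    the upstream-exon end, s2/e2 the cassette bounds and s3 the
    downstream-exon start (all genomic, ascending).  The far ends of the
    flanking exons are completed from the annotation (the containing
    reference exons).  Non-SE event lines are skipped; the skip count is
    returned alongside the events.
    """
    events: list[SpliceEvent] = []
    skipped = 0
    with open(ioe_path) as fh:
        header = fh.readline()
        if not header.startswith("seqname"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            seqname, gene_id, event_id = parts[0], parts[1], parts[2]
            core = event_id.split(";", 1)[1] if ";" in event_id else event_id
            if not core.startswith("SE:"):
                skipped += 1
                continue
            try:
                _, contig, j1, j2, strand = core.split(":")
                e1, s2 = (int(x) for x in j1.split("-"))
                e2, s3 = (int(x) for x in j2.split("-"))
            except ValueError as exc:
                raise EventFormatError(f"ioe line {lineno}: unparseable SE identifier {event_id!r}") from exc
            left_far = _far_boundary(annotation, contig, strand, boundary=e1, side="left")
            right_far = _far_boundary(annotation, contig, strand, boundary=s3, side="right")
            if left_far is None or right_far is None:
                raise EventFormatError(
                    f"ioe line {lineno}: flanking exon boundaries not found in annotation "
                    f"for {event_id!r}"
                )
            left = ExonInterval(contig, left_far, e1, strand)
            right = ExonInterval(contig, s3, right_far, strand)
            up, dn = (left, right) if strand == "+" else (right, left)
            events.append(
                SpliceEvent(
                    event_id=core,
                    gene_id=gene_id,
                    gene_name=gene_id,
                    contig=contig,
                    strand=strand,
                    se_exon=ExonInterval(contig, s2, e2, strand),
                    upstream_exon=up,
                    downstream_exon=dn,
                    source="suppa2",
                )
            )
    if skipped:
        logger.info("convert_suppa_ioe: skipped %d non-SE event lines", skipped)
    return events, skipped


def _far_boundary(annotation: AnnotationIndex, contig: str, strand: str, boundary: int, side: str) -> int | None:
    """Far end of a reference exon whose near edge sits at ``boundary``.

    side='left': exon ends at boundary, return the smallest start;
    side='right': exon starts at boundary, return the largest end.
    """
    tids = annotation.exon_boundary_index.get((contig, strand, boundary), ())
    best: int | None = None
    for tid in tids:
        for exon in annotation.transcripts[tid].exons:
            if side == "left" and exon.end == boundary:
                best = exon.start if best is None else min(best, exon.start)
            elif side == "right" and exon.start == boundary:
                best = exon.end if best is None else max(best, exon.end)
    return best


def filter_dynamic(
    events: Sequence[SpliceEvent],
    min_abs_dpsi: float = 0.10,
    max_fdr: float = 0.05,
    psi_floor: float = 0.03,
    psi_ceil: float = 0.95,
    apply_psi_range: bool = False,
) -> list[SpliceEvent]:
    """Keep significantly dynamic events: |dPSI| > 0.10 and FDR < 0.05.

    Both inequalities are strict.  The optional PSI-range prefilter keeps
    events whose smallest per-sample PSI lies strictly inside
    (psi_floor, psi_ceil); it only applies when PSI values are present.
    """
    kept: list[SpliceEvent] = []
    dropped_missing = 0
    for ev in events:
        if ev.delta_psi is None or ev.fdr is None:
            dropped_missing += 1
            continue
        if not (abs(ev.delta_psi) > min_abs_dpsi and ev.fdr < max_fdr):
            continue
        if apply_psi_range:
            observed = [p for p in ev.psi if p is not None]
            if observed:
                lo = min(observed)
                if not (psi_floor < lo < psi_ceil):
                    continue
        kept.append(ev)
    if dropped_missing:
        logger.warning("filter_dynamic: dropped %d events lacking dPSI/FDR", dropped_missing)
    return kept


def mxe_count_filter(event: SpliceEvent, average: str = "mean_of_min", ratio_on: str = "summed") -> str:
    """Screen one event for a mutually-exclusive-exon signature.

    MXE pairs masquerading as SE events show one-sided inclusion-junction
    support.  Keep iff (a) the mean over samples of per-sample
    min(UJC, DJC) is >= 2 AND (b) min(sum UJC, sum DJC)/max(...) > 0.05.
    Events without counts are kept with an 'mxe_unfiltered' mark.
    Returns 'keep' or 'exclude_mxe_like'.
    """
    if event.counts is None or not event.counts.ujc or not event.counts.djc:
        event.marks.add("mxe_unfiltered")
        return "keep"
    ujc, djc = event.counts.ujc, event.counts.djc
    if len(ujc) != len(djc):
        raise ValueError("UJC/DJC sample count mismatch")

    mins = [min(u, d) for u, d in zip(ujc, djc)]
    if average == "mean_of_min":
        avg_min = sum(mins) / len(mins)
    elif average == "min_of_mean":
        avg_min = min(sum(ujc) / len(ujc), sum(djc) / len(djc))
    else:
        raise ValueError(f"unknown average mode {average!r}")

    if ratio_on == "summed":
        u, d = sum(ujc), sum(djc)
    elif ratio_on == "per_sample_mean":
        u, d = sum(ujc) / len(ujc), sum(djc) / len(djc)
    else:
        raise ValueError(f"unknown ratio mode {ratio_on!r}")
    ratio = 0.0 if max(u, d) == 0 else min(u, d) / max(u, d)

    if avg_min >= 2 and ratio > 0.05:
        return "keep"
    event.marks.add("exclude_mxe_like")
    return "exclude_mxe_like"


def _read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    # BED: 0-based half-open; converted to 1-based inclusive here
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "."
            intervals.append((contig, start0 + 1, end0, strand))
    return intervals


def flag_known_mxe(events: Sequence[SpliceEvent], mxe_reference_bed: str | Path) -> list[SpliceEvent]:
    """Mark events whose cassette exon overlaps a known-MXE reference
    interval (same strand, >= 1 bp) with 'known_mxe'."""
    intervals = _read_bed_intervals(mxe_reference_bed)
    for ev in events:
        se = ev.se_exon
        for contig, start, end, strand in intervals:
            if contig != ev.contig:
                continue
            if strand != "." and strand != ev.strand:
                continue
            if start <= se.end and se.start <= end:
                ev.marks.add("known_mxe")
                break
    return list(events)


def psi_pattern_cluster(psi_series: Sequence[float]) -> str:
    """Pattern label over adjacent-stage fold changes of mean PSI.

    For each adjacent pair FC = psi[t+1]/psi[t]; U if FC > 1.1, D if
    FC < 0.9, else N.  A zero followed by a positive value is U by
    convention; two zeros give N.
    """
    if len(psi_series) < 2:
        raise ValueError("need at least two stages")
    label = []
    for a, b in zip(psi_series, psi_series[1:]):
        if a < 0 or b < 0 or (a > 0 and not math.isfinite(a)):
            raise ValueError("PSI means must be finite and non-negative")
        if a == 0:
            label.append("U" if b > 0 else "N")
            continue
        fc = b / a
        label.append("U" if fc > 1.1 else ("D" if fc < 0.9 else "N"))
    return "".join(label)
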