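"""Event-level NMD annotation: isoform simulation, ORF scanning and the
50-nt rule.

For each skipped-exon event the annotator retrieves compatible reference
transcripts, builds the inclusion and exclusion isoform for each
(reconstructing whichever form is absent from the annotation), scans the
open reading frame of both, and measures DJ — the signed distance from the
stop codon to the last exon-exon junction.  A stop more than
``dj_threshold`` (default 50) nucleotides upstream of the last junction
marks the isoform for nonsense-mediated decay; events are then classified
NMD_in (poison exon: inclusion decays), NMD_ex (exclusion decays), or one
of the non-NMD flags describing the exon's effect on the ORF / UTRs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import (
    STOP_CODONS,
    AnnotationIndex,
    ExonInterval,
    GenomeSequence,
    NotMappableError,
    TranscriptModel,
    genomic_to_transcript,
    load_annotation,
    spliced_sequence,
    validate_start_codon,
)
from .events import SpliceEvent

logger = logging.getLogger(__name__)

DEFAULT_DJ_THRESHOLD = 50

NMD_FLAGS = ("NMD_in", "NMD_ex", "NMD_both")
NON_NMD_FLAGS = (
    "ORF_preserving", "ORF_changing", "UTR_5prime", "UTR_3prime",
    "non_coding", "no_transcript", "non_ATG_filtered", "MXE_filtered",
)
ALL_FLAGS = NMD_FLAGS + NON_NMD_FLAGS


class ChainConflictError(ValueError):
    """The SE exon overlaps a flanking exon of the chosen transcript."""


@dataclass
class IsoformVariant:
    """One simulated isoform (inclusion or exclusion form) of an event."""

    source_transcript_id: str
    form: str  # "inclusion" | "exclusion"
    exon_chain: list[ExonInterval]
    reconstructed: bool
    cds_start_genomic: int | None

    @property
    def strand(self) -> str:
        return self.exon_chain[0].strand

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exon_chain)


@dataclass
class OrfResult:
    """Outcome of scanning one isoform's ORF.

    ``stop_tx`` is the transcript position of the stop codon's LAST base;
    ``dj`` = (position of the last exon-exon junction) - stop_tx, negative
    when the stop lies in the last exon, absent for single-exon or
    stopless isoforms.
    """

    start_tx: int | None
    stop_tx: int | None
    dj: int | None
    utr3_len: int | None
    tx_len: int
    stop_pos_fraction: float | None
    stop_exon_number: int | None
    n_exons: int
    is_nmd: bool
    status: str = "ok"  # ok | no_stop | start_lost | non_coding


@dataclass
class EventAnnotation:
    event_id: str
    flag: str
    per_isoform: list[tuple[IsoformVariant, OrfResult]] = field(default_factory=list)
    gene_id: str = ""
    gene_name: str = ""
    aggregates: dict = field(default_factory=dict)
    nmd_score: float | None = None
    marks: set[str] = field(default_factory=set)
    se_exon: ExonInterval | None = None


def find_compatible_transcripts(
    event: SpliceEvent, index: AnnotationIndex
) -> list[tuple[TranscriptModel, bool]]:
    """Transcripts usable to simulate the event's two isoforms.

    A transcript is compatible when its chain contains the upstream exon's
    donor boundary and the downstream exon's acceptor boundary (transcript
    orientation) with at most the SE exon between them.  The returned flag
    records whether the SE exon (exact bounds) is present in the chain.
    """
    # junction-side boundaries of the two flanking exons, in genomic coords
    if event.strand == "+":
        donor_boundary = event.upstream_exon.end      # 3' edge of 5' flank
        acceptor_boundary = event.downstream_exon.start
    else:
        donor_boundary = event.upstream_exon.start
        acceptor_boundary = event.downstream_exon.end

    candidates = (
        index.exon_boundary_index.get((event.contig, event.strand, donor_boundary), set())
        & index.exon_boundary_index.get((event.contig, event.strand, acceptor_boundary), set())
    )
    out: list[tuple[TranscriptModel, bool]] = []
    for tid in sorted(candidates):
        tm = index.transcripts[tid]
        up_idx = dn_idx = None
        for i, exon in enumerate(tm.exons):  # transcript order
            if event.strand == "+":
                if exon.end == donor_boundary:
                    up_idx = i
                if exon.start == acceptor_boundary:
                    dn_idx = i
            else:
                if exon.start == donor_boundary:
                    up_idx = i
                if exon.end == acceptor_boundary:
                    dn_idx = i
        if up_idx is None or dn_idx is None or dn_idx <= up_idx:
            continue
        between = tm.exons[up_idx + 1 : dn_idx]
        if len(between) == 0:
            out.append((tm, False))
        elif len(between) == 1 and (
            between[0].start == event.se_exon.start and between[0].end == event.se_exon.end
        ):
            out.append((tm, True))
        # any other exon configuration between the flanks → incompatible
    return out


def build_isoform_pair(
    event: SpliceEvent, transcript: TranscriptModel
) -> tuple[IsoformVariant, IsoformVariant]:
    """Inclusion and exclusion isoform for one compatible transcript.

    The form observed in the reference keeps its chain; the other form is
    reconstructed by inserting or deleting the SE exon between the matched
    flanking exons.  All other exons and the CDS start are untouched.
    """
    se = event.se_exon
    for exon in transcript.exons:
        if exon.overlaps(se) and not (exon.start == se.start and exon.end == se.end):
            raise ChainConflictError(
                f"SE exon {se.start}-{se.end} overlaps exon {exon.start}-{exon.end} "
                f"of {transcript.transcript_id}"
            )

    has_se = any(e.start == se.start and e.end == se.end for e in transcript.exons)
    if has_se:
        inclusion_chain = list(transcript.exons)
        exclusion_chain = [e for e in transcript.exons if not (e.start == se.start and e.end == se.end)]
        inc_reconstructed, exc_reconstructed = False, True
    else:
        exclusion_chain = list(transcript.exons)
        inclusion_chain = list(transcript.exons)
        # insert in transcript order: after the upstream (5') flank
        if event.strand == "+":
            pos = next(i for i, e in enumerate(inclusion_chain) if e.end == event.upstream_exon.end)
        else:
            pos = next(i for i, e in enumerate(inclusion_chain) if e.start == event.upstream_exon.start)
        inclusion_chain = inclusion_chain[: pos + 1] + [se] + inclusion_chain[pos + 1 :]
        inc_reconstructed, exc_reconstructed = True, False

    make = lambda form, chain, rec: IsoformVariant(
        source_transcript_id=transcript.transcript_id,
        form=form,
        exon_chain=chain,
        reconstructed=rec,
        cds_start_genomic=transcript.cds_start_genomic,
    )
    return (
        make("inclusion", inclusion_chain, inc_reconstructed),
        make("exclusion", exclusion_chain, exc_reconstructed),
    )


def scan_orf(
    isoform: IsoformVariant,
    genome: GenomeSequence,
    dj_threshold: int = DEFAULT_DJ_THRESHOLD,
) -> OrfResult:
    """Translate from the CDS start and locate the first in-frame stop.

    Codons containing N are treated as non-stop (conservative: unknown
    sequence never fabricates a premature termination codon).  DJ is
    measured from the stop codon's last base to the last exon-exon
    junction (the cumulative length of all exons but the last);
    ``is_nmd`` requires dj strictly greater than ``dj_threshold``.
    """
    chain = isoform.exon_chain
    tx_len = isoform.spliced_length()
    n_exons = len(chain)

    if isoform.cds_start_genomic is None:
        return OrfResult(None, None, None, None, tx_len, None, None, n_exons, False, "non_coding")

    try:
        start_tx = genomic_to_transcript(chain, isoform.cds_start_genomic)
    except NotMappableError:
        # CDS start removed by the splice (start inside the skipped exon)
        return OrfResult(None, None, None, None, tx_len, None, None, n_exons, False, "start_lost")

    seq = spliced_sequence(chain, genome)
    stop_tx = None
    for pos in range(start_tx - 1, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            stop_tx = pos + 3  # 1-based position of the codon's last base
            break

    if stop_tx is None:
        return OrfResult(start_tx, None, None, None, tx_len, None, None, n_exons, False, "no_stop")

    last_junction_tx = tx_len - len(chain[-1])  # 0 for single-exon chains
    dj = last_junction_tx - stop_tx if n_exons > 1 else None
    utr3_len = tx_len - stop_tx
    stop_pos_fraction = stop_tx / tx_len
    cum = 0
    stop_exon_number = None
    for i, exon in enumerate(chain, start=1):
        cum += len(exon)
        if stop_tx <= cum:
            stop_exon_number = i
            break
    is_nmd = dj is not None and dj > dj_threshold
    return OrfResult(
        start_tx, stop_tx, dj, utr3_len, tx_len, stop_pos_fraction,
        stop_exon_number, n_exons, is_nmd, "ok",
    )


def _se_tx_interval(isoform: IsoformVariant, se: ExonInterval) -> tuple[int, int] | None:
    """Transcript-coordinate span of the SE exon within an inclusion chain."""
    offset = 0
    for exon in isoform.exon_chain:
        if exon.start == se.start and exon.end == se.end:
            return offset + 1, offset + len(exon)
        offset += len(exon)
    return None


def classify_event(
    event: SpliceEvent,
    per_isoform: Sequence[tuple[IsoformVariant, IsoformVariant, OrfResult, OrfResult]],
    dj_threshold: int = DEFAULT_DJ_THRESHOLD,
    vote: str = "any",
) -> EventAnnotation:
    """Assign the event-level NMD flag from per-transcript isoform pairs.

    ``per_isoform`` holds (inclusion, exclusion, inclusion ORF, exclusion
    ORF) per compatible transcript.  Voting (default ``any``): NMD_in when
    at least one transcript shows (inclusion NMD, exclusion non-NMD) and
    none shows the reverse; NMD_ex is the mirror; both directions present,
    or both forms decaying in every transcript, give NMD_both.  With
    ``vote='all'`` the directional pattern must hold in every informative
    transcript.  Start-lost forms are excluded from voting.
    """
    if not per_isoform:
        return EventAnnotation(event.event_id, "no_transcript",
                               gene_id=event.gene_id, gene_name=event.gene_name,
                               marks=set(event.marks), se_exon=event.se_exon)

    pairs = []  # flattened per-isoform records for the annotation
    for inc, exc, inc_orf, exc_orf in per_isoform:
        pairs.append((inc, inc_orf))
        pairs.append((exc, exc_orf))

    coding = [
        (inc, exc, io, eo)
        for inc, exc, io, eo in per_isoform
        if io.status != "non_coding" and eo.status != "non_coding"
    ]
    ann = EventAnnotation(event.event_id, "non_coding", per_isoform=pairs,
                          gene_id=event.gene_id, gene_name=event.gene_name,
                          marks=set(event.marks), se_exon=event.se_exon)
    if not coding:
        return ann

    informative = [
        (inc, exc, io, eo)
        for inc, exc, io, eo in coding
        if io.status != "start_lost" and eo.status != "start_lost"
    ]
    if not informative:
        ann.flag = "ORF_changing"  # start lost in every usable transcript
        ann.marks.add("start_lost")
        return ann

    in_votes = sum(1 for _, _, io, eo in informative if io.is_nmd and not eo.is_nmd)
    ex_votes = sum(1 for _, _, io, eo in informative if eo.is_nmd and not io.is_nmd)
    both_votes = sum(1 for _, _, io, eo in informative if io.is_nmd and eo.is_nmd)

    if in_votes and ex_votes:
        ann.flag = "NMD_both"
        logger.warning("event %s: conflicting NMD directions across transcripts", event.event_id)
        return ann
    required = len(informative) if vote == "all" else 1
    if in_votes and in_votes + both_votes >= required:
        ann.flag = "NMD_in"
        return ann
    if ex_votes and ex_votes + both_votes >= required:
        ann.flag = "NMD_ex"
        return ann
    if both_votes == len(informative) and both_votes > 0:
        ann.flag = "NMD_both"
        return ann

    # non-NMD classification from the inclusion isoforms
    se_len = len(event.se_exon)
    utr5, utr3 = [], []
    for inc, exc, io, eo in informative:
        span = _se_tx_interval(inc, event.se_exon)
        if span is None or io.start_tx is None:
            utr5.append(False)
            utr3.append(False)
            continue
        se_a, se_b = span
        utr5.append(se_b < io.start_tx)
        utr3.append(io.stop_tx is not None and se_a > io.stop_tx)
    if utr5 and all(utr5):
        ann.flag = "UTR_5prime"
        return ann
    if utr3 and all(utr3):
        ann.flag = "UTR_3prime"
        return ann

    stop_in_se = False
    for inc, exc, io, eo in informative:
        span = _se_tx_interval(inc, event.se_exon)
        if span and io.stop_tx is not None and span[0] <= io.stop_tx <= span[1]:
            stop_in_se = True
    ann.flag = "ORF_preserving" if (se_len % 3 == 0 and not stop_in_se) else "ORF_changing"
    return ann


def annotate_event(
    event: SpliceEvent,
    index: AnnotationIndex,
    genome: GenomeSequence,
    dj_threshold: int = DEFAULT_DJ_THRESHOLD,
    vote: str = "any",
) -> EventAnnotation:
    """Full single-event pipeline: retrieve, simulate, scan, classify."""
    compat = find_compatible_transcripts(event, index)
    per = []
    for tm, _present in compat:
        inc, exc = build_isoform_pair(event, tm)
        per.append((inc, exc, scan_orf(inc, genome, dj_threshold), scan_orf(exc, genome, dj_threshold)))
    ann = classify_event(event, per, dj_threshold, vote)
    ann.marks |= {
        f"start_codon_{validate_start_codon(tm, genome)}" for tm, _ in compat
    }
    _aggregate_features(ann)
    return ann


def _aggregate_features(ann: EventAnnotation) -> None:
    djs = [orf.dj for _, orf in ann.per_isoform if orf.dj is not None]
    fracs = [orf.stop_pos_fraction for _, orf in ann.per_isoform if orf.stop_pos_fraction is not None]
    to_end = [orf.tx_len - orf.stop_tx for _, orf in ann.per_isoform if orf.stop_tx is not None]
    if djs:
        ann.aggregates["max_dj"] = max(djs)
    if fracs:
        ann.aggregates["min_stop_pos_f"] = min(fracs)
    if to_end:
        ann.aggregates["min_stop_pos_to_end"] = min(to_end)


def annotate_events(
    events: Iterable[SpliceEvent],
    index: AnnotationIndex,
    genome: GenomeSequence,
    dj_threshold: int = DEFAULT_DJ_THRESHOLD,
    vote: str = "any",
) -> list[EventAnnotation]:
    return [annotate_event(ev, index, genome, dj_threshold, vote) for ev in events]


def filter_annotations(
    annotations: Sequence[EventAnnotation],
) -> tuple[list[EventAnnotation], Counter]:
    """Remove non-ATG-start and MXE-marked events (post-annotation filter).

    An event is dropped as ``non_ATG_filtered`` when every compatible
    transcript's start codon failed ATG validation, and as
    ``MXE_filtered`` when the event carries a known-MXE or
    junction-imbalance mark.  Removal counts are returned.
    """
    kept: list[EventAnnotation] = []
    removed: Counter = Counter()
    for ann in annotations:
        start_marks = {m for m in ann.marks if m.startswith("start_codon_")}
        if start_marks and start_marks <= {"start_codon_non-ATG", "start_codon_absent"} \
                and "start_codon_non-ATG" in start_marks:
            ann.flag = "non_ATG_filtered"
            removed["non_ATG_filtered"] += 1
            continue
        if "known_mxe" in ann.marks or "exclude_mxe_like" in ann.marks:
            ann.flag = "MXE_filtered"
            removed["MXE_filtered"] += 1
            continue
        kept.append(ann)
    if removed:
        logger.info("filter_annotations: removed %s", dict(removed))
    return kept, removed


def summarize_flags(annotations: Sequence[EventAnnotation]) -> dict:
    """Per-flag counts plus per-gene lists of NMD_in / NMD_ex genes."""
    flag_counts = Counter(ann.flag for ann in annotations)
    genes_in = sorted({ann.gene_id for ann in annotations if ann.flag == "NMD_in"})
    genes_ex = sorted({ann.gene_id for ann in annotations if ann.flag == "NMD_ex"})
    return {
        "flag_counts": dict(flag_counts),
        "total": len(annotations),
        "genes_nmd_in": genes_in,
        "genes_nmd_ex": genes_ex,
    }


def check_transcript_nmd(
    gtf_source, genome: GenomeSequence, dj_threshold: int = DEFAULT_DJ_THRESHOLD
):
    """Per-transcript NMD status straight from a GTF (no events needed).

    Suited to long-read isoform GTFs carrying CDS annotations: each coding
    transcript's own chain is ORF-scanned and judged by the 50-nt rule;
    non-coding transcripts are reported as not assessed.  Returns a
    pandas DataFrame.
    """
    import pandas as pd

    index = load_annotation(gtf_source)
    rows = []
    for tid in sorted(index.transcripts):
        tm = index.transcripts[tid]
        iso = IsoformVariant(tid, "reference", tm.exons, False, tm.cds_start_genomic)
        orf = scan_orf(iso, genome, dj_threshold)
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": tm.gene_id,
                "status": "not_assessed" if orf.status == "non_coding" else orf.status,
                "is_nmd": orf.is_nmd if orf.status != "non_coding" else None,
                "dj": orf.dj,
                "stop_tx": orf.stop_tx,
                "tx_len": orf.tx_len,
                "n_exons": orf.n_exons,
            }
        )
    return pd.DataFrame(rows)


def evaluate_predictions(predicted: dict[str, str], truth: dict[str, str]) -> dict:
    """Coverage, precision, recall and F1 for NMD calls against labels.

    ``predicted`` maps event id -> flag (NMD_in/NMD_ex count as
    NMD-positive; ids absent from ``predicted`` are unprocessed).
    ``truth`` maps event id -> {"NMD", "non-NMD"}.  coverage =
    processed/total; precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2PR/(P+R).  A zero denominator yields None (undefined), not 0.
    """
    total = len(truth)
    processed = [eid for eid in truth if eid in predicted]
    tp = fp = fn = 0
    for eid in processed:
        pred_pos = predicted[eid] in ("NMD_in", "NMD_ex", "NMD_both")
        true_pos = truth[eid] == "NMD"
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos and not true_pos:
            fp += 1
        elif true_pos:
            fn += 1
    coverage = len(processed) / total if total else None
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {"coverage": coverage, "precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def confusion_metrics(tp: int, fp: int, fn: int) -> dict:
    """Metrics straight from confusion counts (same formulas as above)."""
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}
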