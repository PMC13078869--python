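"""Splice-switching antisense-oligonucleotide candidate design.

Candidates are tiled across a target region (typically a poison exon plus
flanking intronic sequence) as fixed-length windows at a fixed offset
(defaults 20 nt / 6 nt), converted to the antisense strand, screened for
sequence uniqueness against a reference, and annotated with overlapping
features and splicing-factor motif hits (IUPAC patterns on the sense RNA,
e.g. the PTBP core CUCUYY).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .annotation import ExonInterval, GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20
DEFAULT_OFFSET = 6

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


class MotifPatternError(ValueError):
    """Motif pattern contains a non-IUPAC symbol."""


class AdapterError(RuntimeError):
    """An external uniqueness adapter failed; no silent fallback."""


@dataclass
class AsoCandidate:
    candidate_id: str
    target_interval: ExonInterval
    sense_seq: str
    antisense_seq: str
    unique: bool | None = None
    ambiguous: bool = False  # window contains N
    overlaps: list[dict] = field(default_factory=list)
    chemistry: str = ""  # free text, e.g. "2'-MOE phosphorothioate"


def tile_windows(
    region: ExonInterval, window_len: int = DEFAULT_WINDOW, offset: int = DEFAULT_OFFSET,
    anchor_end: bool = False,
) -> list[ExonInterval]:
    """Window intervals starting at region.start, region.start+offset, ...

    Count = floor((L - window_len)/offset) + 1; every window lies fully
    inside the region.  ``anchor_end`` optionally appends a final window
    flush with the region end when the arithmetic leaves a gap.
    """
    L = len(region)
    if L < window_len:
        logger.warning("region length %d < window %d: no candidates", L, window_len)
        return []
    n = (L - window_len) // offset + 1
    windows = [
        ExonInterval(region.contig, region.start + i * offset,
                     region.start + i * offset + window_len - 1, region.strand)
        for i in range(n)
    ]
    if anchor_end and windows[-1].end < region.end:
        windows.append(ExonInterval(region.contig, region.end - window_len + 1,
                                    region.end, region.strand))
    return windows


def make_antisense(window: ExonInterval, genome: GenomeSequence, target_strand: str,
                   candidate_id: str = "") -> AsoCandidate:
    """Antisense oligo for one window: reverse complement of the sense
    sequence read on ``target_strand``."""
    plus = genome.fetch(window.contig, window.start, window.end)
    sense = plus if target_strand == "+" else reverse_complement(plus)
    return AsoCandidate(
        candidate_id=candidate_id or f"{window.contig}:{window.start}-{window.end}",
        target_interval=ExonInterval(window.contig, window.start, window.end, target_strand),
        sense_seq=sense,
        antisense_seq=reverse_complement(sense),
        ambiguous="N" in sense,
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        hit = haystack.find(needle, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1  # overlapping occurrences count


def count_genome_occurrences(genome: GenomeSequence, seq: str) -> int:
    """Exact occurrences of ``seq`` or its reverse complement in the
    reference, both strands, with a palindromic double-count guard."""
    rc = reverse_complement(seq)
    total = 0
    for _, contig_seq in genome.items():
        total += _count_occurrences(contig_seq, seq)
        if rc != seq:
            total += _count_occurrences(contig_seq, rc)
    return total


def uniqueness_filter(
    candidates: Sequence[AsoCandidate],
    reference: GenomeSequence | None = None,
    adapter: Callable[[str], bool] | None = None,
    keep_all: bool = False,
) -> list[AsoCandidate]:
    """Flag candidates whose target sequence occurs exactly once.

    Built-in mode counts exact occurrences of the sense target (and its
    reverse complement) across the reference — a stricter criterion than
    a mismatch-tolerant aligner.  An external adapter, when given, is
    authoritative; adapter failure raises, never silently falls back.
    Non-unique candidates are dropped unless ``keep_all``.
    """
    if adapter is None and reference is None:
        raise ValueError("either a reference genome or an external adapter is required")
    out = []
    for cand in candidates:
        if adapter is not None:
            try:
                cand.unique = bool(adapter(cand.sense_seq))
            except Exception as exc:
                raise AdapterError(f"uniqueness adapter failed on {cand.candidate_id}: {exc}") from exc
        else:
            cand.unique = count_genome_occurrences(reference, cand.sense_seq) == 1
        if cand.unique or keep_all:
            out.append(cand)
    return out


def _motif_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[ch] for ch in pattern.upper()))
    except KeyError as exc:
        raise MotifPatternError(f"non-IUPAC symbol {exc.args[0]!r} in motif {pattern!r}") from None


def annotate_overlaps(
    candidates: Sequence[AsoCandidate],
    features: Sequence[tuple[ExonInterval, str]] = (),
    motif_patterns: Sequence[str] = (),
) -> list[AsoCandidate]:
    """Attach feature overlaps (>= 1 bp) and sense-RNA motif hits.

    Motifs are IUPAC patterns matched on the sense RNA of each window
    (T read as U); hit positions are window-relative, 1-based.
    """
    regexes = [(p, _motif_regex(p)) for p in motif_patterns]
    for cand in candidates:
        tgt = cand.target_interval
        for interval, label in features:
            if interval.contig == tgt.contig and interval.start <= tgt.end and tgt.start <= interval.end:
                cand.overlaps.append({"type": "feature", "label": label,
                                      "start": interval.start, "end": interval.end})
        rna = cand.sense_seq.upper().replace("T", "U")
        for pattern, rx in regexes:
            for m in rx.finditer(rna):
                cand.overlaps.append({"type": "motif", "label": pattern,
                                      "start": m.start() + 1, "end": m.end()})
    return list(candidates)


def design_asos(
    region: ExonInterval,
    genome: GenomeSequence,
    window_len: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    reference: GenomeSequence | None = None,
    motif_patterns: Sequence[str] = (),
    features: Sequence[tuple[ExonInterval, str]] = (),
    keep_all: bool = False,
    anchor_end: bool = False,
) -> list[AsoCandidate]:
    """End-to-end design: tile, antisense, uniqueness, overlap annotation."""
    windows = tile_windows(region, window_len, offset, anchor_end=anchor_end)
    candidates = [
        make_antisense(w, genome, region.strand, candidate_id=f"aso_{i + 1:04d}")
        for i, w in enumerate(windows)
    ]
    if reference is not None:
        candidates = uniqueness_filter(candidates, reference=reference, keep_all=keep_all)
    if features or motif_patterns:
        candidates = annotate_overlaps(candidates, features, motif_patterns)
    return candidates
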