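"""Transcript models from GENCODE-style GTF plus genome sequence access.

Coordinates are 1-based inclusive genomic throughout the package; the only
conversions from 0-based conventions (rMATS starts, BED) happen in
:mod:`asnmd.events`.  Exons of a transcript are kept in transcript
(5'->3') order, so on the minus strand genomic starts decrease along the
chain, matching GENCODE ``exon_number`` semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; message names the line number."""


class CoordinateError(ValueError):
    """A genomic coordinate falls outside its contig or exon chain."""


class NotMappableError(ValueError):
    """A genomic position is intronic or outside the exon chain."""


@dataclass(frozen=True)
class ExonInterval:
    """A genomic interval, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ExonInterval") -> bool:
        return self.contig == other.contig and self.start <= other.end and other.start <= self.end


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name.

    Wraps either an in-memory dict or a pyfaidx FASTA handle behind one
    fetch interface.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: str(seq).upper() for name, seq in contigs.items()}
        for name, seq in self._contigs.items():
            if not name:
                raise ValueError("empty contig name")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name}: non-ACGTN characters {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, contig: str) -> int:
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the plus-strand sequence of [start, end], 1-based inclusive."""
        try:
            seq = self._contigs[contig]
        except KeyError:
            raise CoordinateError(f"unknown contig {contig!r}") from None
        if start < 1 or end > len(seq):
            raise CoordinateError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def items(self) -> Iterable[tuple[str, str]]:
        return self._contigs.items()


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: list[ExonInterval]
    exon_numbers: list[int] = field(default_factory=list)
    cds_start_genomic: int | None = None
    cds_end_genomic: int | None = None
    biotype: str = ""

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


def _sort_exons_transcript_order(exons: list[ExonInterval], strand: str) -> list[ExonInterval]:
    return sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))


def spliced_sequence(exons: list[ExonInterval], genome: GenomeSequence) -> str:
    """5'->3' mRNA sequence of an exon chain.

    Exon pieces are concatenated in genomic order and the whole string is
    reverse-complemented for minus-strand chains.
    """
    contigs = {e.contig for e in exons}
    if len(contigs) != 1:
        raise ValueError(f"exon chain spans multiple contigs: {sorted(contigs)}")
    strands = {e.strand for e in exons}
    if len(strands) != 1:
        raise ValueError("exon chain mixes strands")
    genomic = sorted(exons, key=lambda e: e.start)
    seq = "".join(genome.fetch(e.contig, e.start, e.end) for e in genomic)
    if strands.pop() == "-":
        seq = reverse_complement(seq)
    return seq


def genomic_to_transcript(exons: list[ExonInterval], genomic_pos: int) -> int:
    """Map a genomic position to its 1-based spliced-transcript position.

    ``exons`` must be in transcript (5'->3') order.  Raises
    :class:`NotMappableError` for intronic or out-of-chain positions.
    """
    offset = 0
    for exon in exons:
        if exon.start <= genomic_pos <= exon.end:
            if exon.strand == "+":
                return offset + (genomic_pos - exon.start) + 1
            return offset + (exon.end - genomic_pos) + 1
        offset += len(exon)
    raise NotMappableError(f"position {genomic_pos} not exonic in chain")


def transcript_to_genomic(exons: list[ExonInterval], tx_pos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` (1-based both sides)."""
    if tx_pos < 1:
        raise NotMappableError(f"transcript position {tx_pos} < 1")
    offset = 0
    for exon in exons:
        if tx_pos <= offset + len(exon):
            within = tx_pos - offset - 1
            if exon.strand == "+":
                return exon.start + within
            return exon.end - within
        offset += len(exon)
    raise NotMappableError(f"transcript position {tx_pos} beyond chain length {offset}")


def validate_start_codon(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Classify the annotated start codon as 'ATG', 'non-ATG' or 'absent'.

    Reads the three spliced bases at the annotated CDS start; an unknown
    base (N) makes the codon non-ATG.
    """
    if model.cds_start_genomic is None:
        return "absent"
    tx_pos = genomic_to_transcript(model.exons, model.cds_start_genomic)
    seq = spliced_sequence(model.exons, genome)
    if tx_pos + 2 > len(seq):
        raise ValueError(
            f"{model.transcript_id}: CDS start at transcript position {tx_pos} "
            f"leaves fewer than 3 bases"
        )
    codon = seq[tx_pos - 1 : tx_pos + 2]
    return "ATG" if codon == "ATG" else "non-ATG"


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # accepts both `key "value";` and `key value;` dialects
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def _iter_gtf_records(lines: Iterable[str]) -> Iterator[tuple[int, list[str], dict[str, str]]]:
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        yield lineno, fields, _parse_attributes(fields[8])


@dataclass
class AnnotationIndex:
    """Transcript models plus junction and exon-boundary lookup tables.

    junction_index keys are (contig, strand, donor_end, acceptor_start) in
    genomic coordinates: the last base of the 5' exon and the first base of
    the 3' exon of each splice junction.
    """

    transcripts: dict[str, TranscriptModel]
    junction_index: dict[tuple[str, str, int, int], set[str]] = field(default_factory=dict)
    exon_boundary_index: dict[tuple[str, str, int], set[str]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotationIndex":
        index = cls(transcripts={})
        for tm in transcripts:
            index.transcripts[tm.transcript_id] = tm
            genomic = sorted(tm.exons, key=lambda e: e.start)
            for left, right in zip(genomic, genomic[1:]):
                key = (tm.contig, tm.strand, left.end, right.start)
                index.junction_index.setdefault(key, set()).add(tm.transcript_id)
            for exon in tm.exons:
                for boundary in (exon.start, exon.end):
                    bkey = (tm.contig, tm.strand, boundary)
                    index.exon_boundary_index.setdefault(bkey, set()).add(tm.transcript_id)
        return index

    def transcripts_for_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


def load_annotation(gtf_source: str | Path | Iterable[str], assign_exon_numbers: bool = True) -> AnnotationIndex:
    """Parse a GENCODE-style GTF into an :class:`AnnotationIndex`.

    Exon features must carry ``gene_id`` and ``transcript_id``; CDS and
    start_codon features are optional.  When a transcript lacks
    ``exon_number`` attributes and ``assign_exon_numbers`` is set, numbers
    1..n are assigned in 5'->3' transcript order.  The CDS start is taken
    from the start_codon feature when present, otherwise from the 5'-most
    CDS codon (still subject to ATG validation downstream).
    """
    if isinstance(gtf_source, (str, Path)):
        with open(gtf_source) as fh:
            return load_annotation(list(fh), assign_exon_numbers=assign_exon_numbers)

    exons: dict[str, list[tuple[ExonInterval, int | None]]] = {}
    meta: dict[str, dict[str, str]] = {}
    cds_spans: dict[str, list[ExonInterval]] = {}
    start_codons: dict[str, list[ExonInterval]] = {}

    for lineno, fields, attrs in _iter_gtf_records(gtf_source):
        feature = fields[2]
        if feature not in ("exon", "CDS", "start_codon"):
            continue
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if tid is None or gid is None:
            raise GtfParseError(
                f"GTF line {lineno}: {feature} feature missing gene_id/transcript_id"
            )
        try:
            interval = ExonInterval(fields[0], int(fields[3]), int(fields[4]), fields[6])
        except ValueError as exc:
            raise GtfParseError(f"GTF line {lineno}: {exc}") from exc
        if feature == "exon":
            num = attrs.get("exon_number")
            exon_num = int(num) if num is not None else None
            exons.setdefault(tid, []).append((interval, exon_num))
            meta.setdefault(tid, {})["gene_id"] = gid
            meta[tid].setdefault("gene_name", attrs.get("gene_name", gid))
            if "transcript_type" in attrs:
                meta[tid]["biotype"] = attrs["transcript_type"]
            elif "transcript_biotype" in attrs:
                meta[tid]["biotype"] = attrs["transcript_biotype"]
        elif feature == "CDS":
            cds_spans.setdefault(tid, []).append(interval)
        else:
            start_codons.setdefault(tid, []).append(interval)

    models: list[TranscriptModel] = []
    for tid, exon_list in exons.items():
        if not exon_list:
            logger.warning("transcript %s has zero exons; excluded", tid)
            continue
        strand = exon_list[0][0].strand
        numbered = all(num is not None for _, num in exon_list)
        if numbered:
            ordered = [e for e, _ in sorted(exon_list, key=lambda p: p[1])]
            numbers = sorted(num for _, num in exon_list)
        else:
            if not assign_exon_numbers:
                logger.warning("transcript %s lacks exon_number attributes; excluded", tid)
                continue
            ordered = _sort_exons_transcript_order([e for e, _ in exon_list], strand)
            numbers = list(range(1, len(ordered) + 1))

        cds_start = cds_end = None
        if tid in start_codons:
            sc = _sort_exons_transcript_order(start_codons[tid], strand)
            cds_start = sc[0].start if strand == "+" else sc[0].end
        if tid in cds_spans:
            spans = _sort_exons_transcript_order(cds_spans[tid], strand)
            if cds_start is None:
                cds_start = spans[0].start if strand == "+" else spans[0].end
            cds_end = spans[-1].end if strand == "+" else spans[-1].start

        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta[tid]["gene_id"],
                gene_name=meta[tid].get("gene_name", meta[tid]["gene_id"]),
                strand=strand,
                exons=ordered,
                exon_numbers=numbers,
                cds_start_genomic=cds_start,
                cds_end_genomic=cds_end,
                biotype=meta[tid].get("biotype", ""),
            )
        )
    return AnnotationIndex.from_transcripts(models)
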