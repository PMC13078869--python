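"""Deterministic synthetic loci with known ground-truth NMD flags, plus a
synthetic feature/efficiency dataset for the scoring model.

Sequence design trick: exon and intron bodies are drawn from {A,C,G}
only, so the sole thymines in a locus are the planted start codon and the
planted TAA stops.  Because every stop codon begins with T, a planted
stop can then terminate only the reading frame aligned to its own T —
which gives exact, provable control over which isoform (inclusion or
exclusion) encounters a premature termination codon and at which DJ.
The base following ATG is restricted to C/G so no accidental TGA arises
in a shifted frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationIndex,
    ExonInterval,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)
from .events import JunctionCounts, SpliceEvent, write_rmats_se

SCENARIOS = (
    "poison_exon",
    "nmd_ex_frameshift",
    "orf_preserving",
    "orf_changing_nonNMD",
    "utr5_exon",
    "utr3_exon",
    "non_atg_start",
    "mxe_pair",
    "single_exon",
    "no_stop",
)

# flag each scenario must produce through annotate -> filter
EXPECTED_FLAGS = {
    "poison_exon": "NMD_in",
    "nmd_ex_frameshift": "NMD_ex",
    "orf_preserving": "ORF_preserving",
    "orf_changing_nonNMD": "ORF_changing",
    "utr5_exon": "UTR_5prime",
    "utr3_exon": "UTR_3prime",
    "non_atg_start": "non_ATG_filtered",
    "mxe_pair": "MXE_filtered",
    "single_exon": "no_transcript",
    "no_stop": "ORF_changing",
}

INTRON_LEN = 100
FLANK_LEN = 60


class LocusSpecError(ValueError):
    """Internally inconsistent locus parameters (e.g. unreachable DJ)."""


@dataclass
class LocusSpec:
    scenario: str
    dj_target: int = 60
    seed: int = 0
    strand: str = "+"
    contig: str = "chrS"
    gene_id: str = "GENE1"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise LocusSpecError(f"unknown scenario {self.scenario!r}")


@dataclass
class Locus:
    spec: LocusSpec
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    event: SpliceEvent
    truth: dict
    mxe_bed: list[tuple[str, int, int, str]] = field(default_factory=list)

    def annotation_index(self) -> AnnotationIndex:
        return AnnotationIndex.from_transcripts(self.transcripts)

    # -- text writers (FASTA / GTF / rMATS TSV / BED) -----------------------
    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        rows = []
        for tm in self.transcripts:
            g_start = min(e.start for e in tm.exons)
            g_end = max(e.end for e in tm.exons)
            attr_base = (
                f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}"; '
                f'gene_name "{tm.gene_name}"; transcript_type "{tm.biotype}";'
            )
            rows.append((g_start, f"{tm.contig}\tsim\ttranscript\t{g_start}\t{g_end}\t.\t{tm.strand}\t.\t{attr_base}"))
            for num, exon in zip(tm.exon_numbers, tm.exons):
                rows.append((exon.start,
                             f"{tm.contig}\tsim\texon\t{exon.start}\t{exon.end}\t.\t{tm.strand}\t.\t"
                             f'{attr_base} exon_number {num};'))
            for feat, intervals in tm.__dict__.get("_extra_features", {}).items():
                for (s, e) in intervals:
                    rows.append((s, f"{tm.contig}\tsim\t{feat}\t{s}\t{e}\t.\t{tm.strand}\t.\t{attr_base}"))
        with open(path, "w") as fh:
            fh.write("##description: synthetic locus\n")
            for _, line in sorted(rows, key=lambda r: r[0]):
                fh.write(line + "\n")

    def write_events_tsv(self, path: str | Path, extended: bool = True) -> None:
        write_rmats_se([self.event], path, extended_counts=extended)

    def write_mxe_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, start, end, strand in self.mxe_bed:
                fh.write(f"{contig}\t{start - 1}\t{end}\tmxe\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# sequence assembly helpers (transcript space, plus strand)

def _random_body(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACG"), size=n))


def _plant(seq: list[str], last_base_pos: int, codon: str = "TAA") -> None:
    """Write ``codon`` so its LAST base sits at 1-based ``last_base_pos``."""
    i = last_base_pos - 3
    if i < 0 or last_base_pos > len(seq):
        raise LocusSpecError(f"codon at {last_base_pos} outside sequence")
    seq[i : i + 3] = list(codon)


def _frame_align(pos_last_base: int, start_tx: int) -> int:
    """Shift a codon's last-base position (by 0..-2) into the reading frame
    anchored at ``start_tx``; codon first base must satisfy
    (pos-2 - start_tx) % 3 == 0."""
    shift = (pos_last_base - 2 - start_tx) % 3
    return pos_last_base - shift


def _tx_range_to_genomic(chain: list[ExonInterval], a: int, b: int) -> list[tuple[int, int]]:
    """Genomic intervals covered by transcript positions [a, b]."""
    from .annotation import transcript_to_genomic

    out: list[tuple[int, int]] = []
    offset = 0
    for exon in chain:
        lo, hi = offset + 1, offset + len(exon)
        s, e = max(a, lo), min(b, hi)
        if s <= e:
            g1 = transcript_to_genomic(chain, s)
            g2 = transcript_to_genomic(chain, e)
            out.append((min(g1, g2), max(g1, g2)))
        offset = hi
    return out


def _mirror_locus(locus: Locus) -> Locus:
    """Reverse-complement the whole contig and remap every coordinate.

    Produces the minus-strand mirror of a plus-strand locus; flags must be
    invariant under this transformation.
    """
    (contig_name, seq), = locus.genome.items()
    L = len(seq)
    genome = GenomeSequence({contig_name: reverse_complement(seq)})
    flip = lambda iv: ExonInterval(iv.contig, L - iv.end + 1, L - iv.start + 1,
                                   "-" if iv.strand == "+" else "+")
    flip_pos = lambda p: L - p + 1

    transcripts = []
    for tm in locus.transcripts:
        new = TranscriptModel(
            transcript_id=tm.transcript_id,
            gene_id=tm.gene_id,
            gene_name=tm.gene_name,
            strand="-" if tm.strand == "+" else "+",
            exons=[flip(e) for e in tm.exons],  # transcript order is preserved
            exon_numbers=list(tm.exon_numbers),
            cds_start_genomic=None if tm.cds_start_genomic is None else flip_pos(tm.cds_start_genomic),
            cds_end_genomic=None if tm.cds_end_genomic is None else flip_pos(tm.cds_end_genomic),
            biotype=tm.biotype,
        )
        if "_extra_features" in tm.__dict__:
            new.__dict__["_extra_features"] = {
                feat: [(flip_pos(e), flip_pos(s)) for (s, e) in ivs]
                for feat, ivs in tm.__dict__["_extra_features"].items()
            }
        transcripts.append(new)

    ev = locus.event
    event = SpliceEvent(
        event_id=ev.event_id, gene_id=ev.gene_id, gene_name=ev.gene_name,
        contig=ev.contig, strand="-" if ev.strand == "+" else "+",
        se_exon=flip(ev.se_exon),
        upstream_exon=flip(ev.upstream_exon),
        downstream_exon=flip(ev.downstream_exon),
        psi=list(ev.psi), delta_psi=ev.delta_psi, fdr=ev.fdr,
        counts=ev.counts, source="synthetic", marks=set(ev.marks),
    )
    mxe_bed = [(c, flip_pos(e), flip_pos(s), "-" if st == "+" else "+")
               for (c, s, e, st) in locus.mxe_bed]
    return Locus(locus.spec, genome, transcripts, event, dict(locus.truth), mxe_bed)


# ---------------------------------------------------------------------------

def make_locus(spec: LocusSpec) -> Locus:
    """Build one synthetic locus: genome + transcript model(s) + SE event
    + truth record, deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed + 7_000_000)
    locus = _build_plus_strand(spec, rng)
    if spec.strand == "-":
        locus = _mirror_locus(locus)
    return locus


def _build_plus_strand(spec: LocusSpec, rng: np.random.Generator) -> Locus:
    sc = spec.scenario
    dj = spec.dj_target

    if sc == "single_exon":
        return _build_single_exon(spec, rng)

    # exon lengths in transcript order; index of the SE exon in the
    # inclusion chain
    if sc == "utr3_exon":
        lens = [120, 180, 30, 150]  # A, B, SE, C
        se_idx = 2
    elif sc == "utr5_exon":
        lens = [120, 75, 150, 180]  # A, SE, B, C
        se_idx = 1
    elif sc in ("poison_exon", "mxe_pair"):
        # SE is second-to-last so a PTC inside it can sit close to the
        # last junction: DJ target range is (0, se_len - 3]
        lens = [120, 99, 180]  # A, SE, C
        se_idx = 1
    else:
        se_len = {"orf_preserving": 48, "nmd_ex_frameshift": 50,
                  "orf_changing_nonNMD": 50, "non_atg_start": 48, "no_stop": 50}[sc]
        lens = [120, se_len, 200, 180]  # A, SE, B, C
        se_idx = 1

    cum = np.cumsum(lens)
    total = int(cum[-1])
    mrna = _random_body(rng, total)

    inc_last_junction = total - lens[-1]
    exc_len_removed = lens[se_idx]
    exc_total = total - exc_len_removed
    exc_last_junction = inc_last_junction - exc_len_removed

    # start codon placement; for the poison scenarios the start frame is
    # tuned (within a 3-nt window) so the PTC lands at dj_target EXACTLY
    if sc == "utr5_exon":
        start_tx = int(cum[1]) + 10  # inside B, downstream of the SE
    elif sc in ("poison_exon", "mxe_pair"):
        p_in = inc_last_junction - dj
        se_lo, se_hi = int(cum[0]) + 3, int(cum[1])
        if not (se_lo <= p_in - 2 and p_in <= se_hi):
            raise LocusSpecError(f"dj_target {dj} puts the PTC outside the SE exon")
        start_tx = 10 + ((p_in - 2 - 10) % 3)
    else:
        start_tx = 10  # inside A
    start_codon = "CTG" if sc == "non_atg_start" else "ATG"
    mrna[start_tx - 1 : start_tx + 2] = list(start_codon)
    if mrna[start_tx + 2] == "A":
        mrna[start_tx + 2] = "C"  # avoid TGA in the +1 frame

    truth: dict = {"scenario": sc, "expected_flag": EXPECTED_FLAGS[sc]}

    if sc in ("poison_exon", "mxe_pair"):
        # PTC inside the SE; inclusion DJ equals dj_target exactly
        _plant(mrna, p_in)
        truth["dj_inclusion"] = inc_last_junction - p_in
        # normal stop in the last exon (same frame for both isoforms: SE % 3 == 0)
        q = _frame_align(total - 6, start_tx)
        _plant(mrna, q)
        truth["dj_exclusion"] = exc_last_junction - (q - exc_len_removed)
    elif sc == "nmd_ex_frameshift":
        # exclusion frameshifts into a PTC in exon B at dj_target
        p_ex = exc_last_junction - dj
        p_ex = p_ex - ((p_ex - 2 - start_tx) % 3)
        if not (lens[0] + 3 <= p_ex - 2 and p_ex <= lens[0] + lens[2]):
            raise LocusSpecError(f"dj_target {dj} puts the exclusion PTC outside exon B")
        _plant(mrna, p_ex + exc_len_removed)  # same base in inclusion coordinates
        truth["dj_exclusion"] = exc_last_junction - p_ex
        # inclusion reads through (shifted frame) to a normal stop in the last exon
        q = _frame_align(total - 6, start_tx)
        _plant(mrna, q)
        truth["dj_inclusion"] = inc_last_junction - q
    elif sc in ("orf_preserving", "non_atg_start"):
        q = _frame_align(total - 6, start_tx)
        _plant(mrna, q)
        truth["dj_inclusion"] = inc_last_junction - q
        truth["dj_exclusion"] = exc_last_junction - (q - exc_len_removed)
    elif sc == "orf_changing_nonNMD":
        # inclusion: normal stop in the last exon
        q = _frame_align(total - 6, start_tx)
        _plant(mrna, q)
        truth["dj_inclusion"] = inc_last_junction - q
        # exclusion: frameshifted stop, also in the last exon (dj < 0)
        p_ex = exc_total - 15
        p_ex = p_ex - ((p_ex - 2 - start_tx) % 3)
        if p_ex - 2 <= exc_last_junction or p_ex + exc_len_removed >= q - 2:
            raise LocusSpecError("exclusion stop placement collides")
        _plant(mrna, p_ex + exc_len_removed)
        truth["dj_exclusion"] = exc_last_junction - p_ex
    elif sc == "utr5_exon":
        q = _frame_align(total - 6, start_tx)
        _plant(mrna, q)
        truth["dj_inclusion"] = inc_last_junction - q
        truth["dj_exclusion"] = exc_last_junction - (q - exc_len_removed)
    elif sc == "utr3_exon":
        # stop near the end of exon B: small positive DJ in both isoforms
        q = _frame_align(int(cum[1]) - 5, start_tx)  # cum[1] = end of B
        _plant(mrna, q)
        truth["dj_inclusion"] = inc_last_junction - q
        truth["dj_exclusion"] = exc_last_junction - q
        if truth["dj_inclusion"] > 50 or truth["dj_exclusion"] > 50:
            raise LocusSpecError("UTR3 scenario DJ exceeds the NMD threshold")
    elif sc == "no_stop":
        pass  # no stop planted anywhere: both isoforms run off the 3' end

    # ---- lay the exons onto a genomic contig (plus strand) ----------------
    contig_parts: list[str] = ["".join(_random_body(rng, FLANK_LEN))]
    exon_intervals: list[ExonInterval] = []
    gpos = FLANK_LEN
    off = 0
    for i, length in enumerate(lens):
        exon_seq = "".join(mrna[off : off + length])
        contig_parts.append(exon_seq)
        exon_intervals.append(ExonInterval(spec.contig, gpos + 1, gpos + length, "+"))
        gpos += length
        off += length
        if i < len(lens) - 1:
            intron = "".join(_random_body(rng, INTRON_LEN))
            contig_parts.append(intron)
            gpos += INTRON_LEN
    contig_parts.append("".join(_random_body(rng, FLANK_LEN)))
    genome = GenomeSequence({spec.contig: "".join(contig_parts)})

    from .annotation import transcript_to_genomic

    inclusion_chain = exon_intervals
    cds_start_genomic = transcript_to_genomic(inclusion_chain, start_tx)

    # annotate the inclusion isoform for most scenarios; for the
    # exclusion-triggered scenario the annotated reference is the exclusion
    # form, so the inclusion isoform must be reconstructed by the annotator
    if sc == "nmd_ex_frameshift":
        ref_chain = [e for j, e in enumerate(exon_intervals) if j != se_idx]
        biotype = "nonsense_mediated_decay" if sc == "poison_exon" else "protein_coding"
    else:
        ref_chain = inclusion_chain
        biotype = "nonsense_mediated_decay" if sc in ("poison_exon", "mxe_pair") else "protein_coding"

    tm = TranscriptModel(
        transcript_id=f"{spec.gene_id}-T1",
        gene_id=spec.gene_id,
        gene_name=spec.gene_id,
        strand="+",
        exons=ref_chain,
        exon_numbers=list(range(1, len(ref_chain) + 1)),
        cds_start_genomic=cds_start_genomic,
        biotype=biotype,
    )
    # start_codon + CDS rows for the GTF writer
    ref_start_tx = start_tx if ref_chain is inclusion_chain else start_tx  # start is 5' of the SE
    cds_end_tx = ref_start_tx + 60  # nominal span; ATG validation reads the true bases
    tm.__dict__["_extra_features"] = {
        "start_codon": _tx_range_to_genomic(ref_chain, ref_start_tx, ref_start_tx + 2),
        "CDS": _tx_range_to_genomic(ref_chain, ref_start_tx, cds_end_tx),
    }

    se = exon_intervals[se_idx]
    upstream = exon_intervals[se_idx - 1]
    downstream = exon_intervals[se_idx + 1]

    if sc == "mxe_pair":
        counts = JunctionCounts(ujc=[30, 28, 32, 30], djc=[0, 0, 0, 1], sjc=[12, 14, 11, 13],
                                conditions=["sample1", "sample1", "sample2", "sample2"])
    else:
        counts = JunctionCounts(ujc=[14, 16, 13, 15], djc=[13, 15, 12, 14], sjc=[10, 12, 28, 30],
                                conditions=["sample1", "sample1", "sample2", "sample2"])

    event = SpliceEvent(
        event_id=f"{sc}_1",
        gene_id=spec.gene_id,
        gene_name=spec.gene_id,
        contig=spec.contig,
        strand="+",
        se_exon=se,
        upstream_exon=upstream,
        downstream_exon=downstream,
        psi=[0.62, 0.65, 0.22, 0.25],
        delta_psi=0.40,
        fdr=1e-4,
        counts=counts,
        source="synthetic",
    )

    mxe_bed = [(spec.contig, se.start, se.end, "+")] if sc == "mxe_pair" else []
    truth["start_tx"] = start_tx
    return Locus(spec, genome, [tm], event, truth, mxe_bed)


def _build_single_exon(spec: LocusSpec, rng: np.random.Generator) -> Locus:
    body = _random_body(rng, 420)
    start_tx = 10
    body[start_tx - 1 : start_tx + 2] = list("ATG")
    if body[start_tx + 2] == "A":
        body[start_tx + 2] = "C"
    _plant(body, _frame_align(400, start_tx))
    contig = "".join(_random_body(rng, FLANK_LEN)) + "".join(body) + "".join(_random_body(rng, FLANK_LEN))
    genome = GenomeSequence({spec.contig: contig})
    exon = ExonInterval(spec.contig, FLANK_LEN + 1, FLANK_LEN + len(body), "+")
    tm = TranscriptModel(
        transcript_id=f"{spec.gene_id}-T1", gene_id=spec.gene_id, gene_name=spec.gene_id,
        strand="+", exons=[exon], exon_numbers=[1],
        cds_start_genomic=exon.start + start_tx - 1, biotype="protein_coding",
    )
    tm.__dict__["_extra_features"] = {
        "start_codon": [(tm.cds_start_genomic, tm.cds_start_genomic + 2)],
        "CDS": [(tm.cds_start_genomic, tm.cds_start_genomic + 60)],
    }
    # event coordinates that match no annotated splice boundaries
    event = SpliceEvent(
        event_id="single_exon_1", gene_id=spec.gene_id, gene_name=spec.gene_id,
        contig=spec.contig, strand="+",
        se_exon=ExonInterval(spec.contig, exon.start + 150, exon.start + 200, "+"),
        upstream_exon=ExonInterval(spec.contig, exon.start + 50, exon.start + 100, "+"),
        downstream_exon=ExonInterval(spec.contig, exon.start + 260, exon.start + 300, "+"),
        psi=[0.5, 0.5, 0.5, 0.5], delta_psi=0.2, fdr=1e-3,
        counts=JunctionCounts(ujc=[10, 11, 10, 12], djc=[10, 9, 11, 10], sjc=[10, 10, 9, 11],
                              conditions=["sample1", "sample1", "sample2", "sample2"]),
        source="synthetic",
    )
    truth = {"scenario": "single_exon", "expected_flag": "no_transcript", "start_tx": start_tx}
    return Locus(spec, genome, [tm], event, truth, [])


def make_all_loci(seed: int = 0, strand: str = "+") -> dict[str, Locus]:
    """One locus per scenario, each on its own contig."""
    out = {}
    for i, sc in enumerate(SCENARIOS):
        spec = LocusSpec(scenario=sc, seed=seed + i, strand=strand,
                         contig=f"chr{sc}", gene_id=f"GENE_{sc.upper()}")
        out[sc] = make_locus(spec)
    return out


# ---------------------------------------------------------------------------
# random isoforms for oracle testing

def random_isoform(rng: np.random.Generator, max_exons: int = 6):
    """A random exon chain on a random contig (full ACGT alphabet, so
    stop codons arise naturally), with a random exonic CDS start.

    Returns (IsoformVariant, GenomeSequence).
    """
    from .annotator import IsoformVariant

    n_exons = int(rng.integers(1, max_exons + 1))
    lens = [int(rng.integers(30, 250)) for _ in range(n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    contig_len = sum(lens) + (n_exons + 1) * 50
    seq = "".join(rng.choice(list("ACGT"), size=contig_len))
    genome = GenomeSequence({"chrR": seq})

    exons = []
    gpos = 50
    for length in lens:
        exons.append(ExonInterval("chrR", gpos + 1, gpos + length, strand))
        gpos += length + 50
    if strand == "-":
        exons = exons[::-1]

    tx_len = sum(lens)
    start_tx = int(rng.integers(1, max(2, tx_len - 10)))
    from .annotation import transcript_to_genomic

    cds_start = transcript_to_genomic(exons, start_tx)
    iso = IsoformVariant("random", "inclusion", exons, False, cds_start)
    return iso, genome


# ---------------------------------------------------------------------------
# synthetic features + efficiency labels for the scoring model

GENERATOR_COEFFS = {"a": 0.005, "b": 0.5, "utr3_break": 1150.0}


def make_efficiency_dataset(n: int = 200, noise_sd: float = 0.05, seed: int = 7) -> pd.DataFrame:
    """Synthetic 9-feature table with a known generative efficiency model.

    efficiency = a * max(interaction, 0) + b * 1[utr3_len > 1150] + noise,
    mirroring the dominant interaction effect (stop position x Max DJ) and
    the long-3'-UTR bump.  ``nmd_class`` is 1 above the median efficiency.
    Generator coefficients are recorded in ``DataFrame.attrs``.
    """
    if n < 20:
        raise ValueError(f"need n >= 20, got {n}")
    rng = np.random.default_rng(seed)
    min_stop_pos_f = rng.uniform(0.05, 1.0, n)
    max_dj = rng.uniform(-400.0, 800.0, n).round()
    interaction = min_stop_pos_f * max_dj
    utr3_len = np.exp(rng.uniform(np.log(60), np.log(4000), n)).round()
    a, b, brk = GENERATOR_COEFFS["a"], GENERATOR_COEFFS["b"], GENERATOR_COEFFS["utr3_break"]
    efficiency = (
        a * np.clip(interaction, 0.0, None)
        + b * (utr3_len > brk).astype(float)
        + rng.normal(0.0, noise_sd, n)
    )
    df = pd.DataFrame(
        {
            "event_id": [f"sim_{i:04d}" for i in range(n)],
            "min_stop_pos_f": min_stop_pos_f,
            "max_dj": max_dj,
            "interaction": interaction,
            "utr3_len": utr3_len,
            "se_len": rng.integers(30, 300, n),
            "se_pos_to_le": rng.integers(0, 20, n),
            "min_stop_pos_to_end": rng.uniform(30.0, 3000.0, n).round(),
            "start_exon": rng.integers(1, 10, n),
            "ori_utr3_mfe_per_nt": rng.uniform(-0.45, 0.0, n),
            "efficiency": efficiency,
        }
    )
    df["nmd_class"] = (df["efficiency"] > df["efficiency"].median()).astype(int)
    df.attrs["generator"] = dict(GENERATOR_COEFFS, noise_sd=noise_sd, seed=seed)
    return df
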