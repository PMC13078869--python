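import numpy as np
import pytest

from asnmd.annotation import ExonInterval, GenomeSequence
from asnmd.simulate import make_all_loci


@pytest.fixture(scope="session")
def loci():
    """One synthetic locus per scenario (plus strand)."""
    return make_all_loci(seed=0)


@pytest.fixture(scope="session")
def loci_minus():
    return make_all_loci(seed=0, strand="-")


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chr1": "AACCGGTT"})


def orf_oracle(isoform, genome, dj_threshold=50):
    """Independent brute-force ORF scan: rebuilds the spliced string from a
    per-base genomic position list and walks codons by string indexing."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    pos_list, chars = [], []
    for exon in isoform.exon_chain:
        contig_seq = dict(genome.items())[exon.contig]
        if exon.strand == "+":
            rng = range(exon.start, exon.end + 1)
        else:
            rng = range(exon.end, exon.start - 1, -1)
        for p in rng:
            pos_list.append(p)
            base = contig_seq[p - 1]
            chars.append(base if exon.strand == "+" else comp[base])
    seq = "".join(chars)
    tx_len = len(seq)

    if isoform.cds_start_genomic is None or isoform.cds_start_genomic not in pos_list:
        return None
    start_idx = pos_list.index(isoform.cds_start_genomic)  # 0-based

    stop_last = None
    i = start_idx
    while i + 3 <= tx_len:
        if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
            stop_last = i + 3  # 1-based last base
            break
        i += 3
    n_exons = len(isoform.exon_chain)
    last_junction = tx_len - len(isoform.exon_chain[-1])
    if stop_last is None:
        return {"start_tx": start_idx + 1, "stop_tx": None, "dj": None,
                "utr3_len": None, "is_nmd": False}
    dj = last_junction - stop_last if n_exons > 1 else None
    return {
        "start_tx": start_idx + 1,
        "stop_tx": stop_last,
        "dj": dj,
        "utr3_len": tx_len - stop_last,
        "is_nmd": dj is not None and dj > dj_threshold,
    }
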