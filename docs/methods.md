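# Methods

## Transcript models and coordinates

All genomic coordinates inside the package are 1-based inclusive; the
only conversions (rMATS `exonStart_0base`, BED half-open intervals)
happen at the I/O boundary in `asnmd.events`. Exon chains are stored in
transcript (5′→3′) order, so on the minus strand genomic starts decrease
along the chain, matching GENCODE `exon_number` semantics. Transcripts
lacking `exon_number` attributes are numbered 1..n in transcript order
at load time. GTF attributes are accepted in both the quoted GENCODE
dialect (`key "value";`) and the bare dialect (`key value;`).

When a GTF carries CDS features but no `start_codon` feature, the
5′-most CDS base is taken as the start-codon candidate; it is still
subject to ATG validation, so a mis-annotated CDS cannot silently pass
the non-ATG filter.

## ORF scanning and the 50-nt rule

For each isoform the scanner maps the annotated CDS start into spliced
coordinates, reads codons in frame, and takes the first of TAA/TAG/TGA
as the stop. Conventions, all configurable where noted:

- **DJ anchor** — DJ is measured from the stop codon's *last* base to
  the last exon–exon junction (the cumulative length of all exons but
  the last). An isoform is NMD-flagged iff DJ > threshold, strictly,
  with threshold 50 nt by default (`--dj-threshold`). The anchor choice
  shifts DJ by at most 2 nt; the strict inequality at 50 is load-bearing
  and covered by boundary tests at DJ = 49/50/51.
- **Unknown bases** — a codon containing N is neither a start nor a
  stop. This is deliberately conservative: unknown sequence never
  fabricates a PTC.
- **Single-exon isoforms** have no junction, hence no DJ, and are never
  NMD-flagged. Stopless isoforms are reported with status `no_stop`.
- **Start-lost isoforms** (CDS start inside the skipped exon) are
  excluded from event-level voting rather than guessed at; the event is
  still classified from the remaining transcripts.
- Selenocysteine recoding and stop-codon readthrough are not modelled.

## Event classification

A transcript is *compatible* with an SE event when its chain contains
the upstream exon's donor boundary and the downstream exon's acceptor
boundary with at most the SE exon between them. The unobserved isoform
is reconstructed by inserting or deleting the SE exon; this is what
allows unannotated poison exons to be called.

Event flags are decided by voting over compatible transcripts
(default `any`): at least one transcript with (inclusion NMD, exclusion
non-NMD) and none with the reverse gives `NMD_in`; the mirror gives
`NMD_ex`; conflicting directions, or both forms decaying everywhere,
give `NMD_both`. `--vote all` requires the directional pattern in every
informative transcript. Non-NMD events are then placed by geometry:
entirely 5′ of every start codon → `UTR_5prime`; entirely 3′ of the
stop → `UTR_3prime`; otherwise `ORF_preserving` when the SE length is a
multiple of 3 and the exon contains no in-frame stop, else
`ORF_changing`.

The post-annotation filter removes events whose every compatible
transcript fails ATG validation (`non_ATG_filtered`) and events with an
MXE signature (`MXE_filtered`).

## MXE screening

MXE pairs mis-called as SE events show one-sided inclusion-junction
support. With per-sample upstream/downstream inclusion counts
(UJC/DJC), an event is kept iff

1. mean over samples of min(UJC, DJC) ≥ 2, and
2. min(ΣUJC, ΣDJC) / max(ΣUJC, ΣDJC) > 0.05.

"Average minimum" is read as the mean of per-sample minima (the
per-sample minimum detects consistently one-sided junctions), and the
ratio uses summed counts; both readings are switchable
(`average=`, `ratio_on=`) since the alternative interpretations are
defensible. Events without UJC/DJC (standard SE.JCEC dialect) pass with
an explicit `mxe_unfiltered` mark so downstream counts can distinguish
"kept" from "unfilterable". A known-MXE BED reference marks any event
whose cassette overlaps a reference interval on the same strand by
≥ 1 bp.

## Dynamic-event filter and PSI patterns

Significantly dynamic events satisfy |ΔPSI| > 0.10 AND FDR < 0.05, both
strict. An optional prefilter keeps events whose per-sample PSI minimum
lies strictly inside (0.03, 0.95). PSI pattern labels concatenate
adjacent-stage fold-change calls: U if FC > 1.1, D if FC < 0.9, else N;
0 → positive is U by convention, 0 → 0 is N.

## NMD-efficiency model

The regressor is XGBoost with squared-error objective and the default
hyperparameter set: seed 321, max_depth 7, eta 0.05,
subsample 0.5495662, colsample_bytree 0.8133278, alpha 0, lambda 1,
gamma 0.2, min_child_weight 1, up to 50,000 rounds with RMSE early
stopping after 100 stagnant rounds on a held-out fold (0.85:0.15 split
on the model seed). The package default is single-threaded training so
two runs on the same table are bit-identical on any host; the thread
count is a parameter. Hyperparameter search is out of scope — the
defaults are taken as given. Feature attribution is exposed through the
booster's gain importances.

The nine features are min stop-position fraction, max DJ, their exact
product, reference-transcript 3′-UTR length, SE length, last-exon-number
minus SE-number, min stop-to-end distance, start-codon exon number, and
3′-UTR folding energy per nucleotide. The reference transcript is the
compatible transcript with an annotated CDS, ties broken toward the
longest CDS span. Events with no stop codon or no junction in any
isoform are unscorable and receive a missing score, never 0.

**Folding energy.** Two engines: `external_fold` shells out to the
`RNAfold` executable (kcal/mol); `builtin_proxy` is a Nussinov-style
dynamic program — maximum non-crossing Watson–Crick+GU pairs with a
minimum hairpin loop of 3, scored −1 per pair — divided by sequence
length. The proxy shares the sign convention and rank behaviour of a
thermodynamic fold but not its energy scale, so the engine is recorded
with every feature table and a model trained with one engine refuses to
score features from the other unless forced. The builtin engine is the
default so the package has no runtime dependency on an external binary.

**ROC/cutoff.** AUC uses the midrank convention; the score cutoff
maximizes Youden's J (sensitivity + specificity − 1), ties broken
toward the higher cutoff. The criterion choice is this package's
convention.

## ASO design

Windows of 20 nt are tiled from the region start at 6-nt offsets:
count = floor((L−20)/6) + 1, pure arithmetic with no end-anchored
window unless `--anchor-end` is passed. The antisense oligo is the
reverse complement of the sense-strand target. The built-in uniqueness
screen counts exact occurrences of the sense sequence and its reverse
complement over the supplied reference (palindromic targets counted
once) and keeps candidates occurring exactly once — a deliberately
stricter criterion than a mismatch-tolerant aligner, suited to
desk-scale references; an external aligner can be plugged in through
the adapter hook, and adapter failures raise rather than silently
falling back. Motif annotation matches IUPAC patterns (e.g. the PTBP
core CUCUYY) on the sense RNA of each window. Oligo chemistry is
carried as free text only.

## Synthetic loci

The generator builds one locus per scenario — poison exon, exclusion
frameshift, ORF-preserving/-changing, 5′/3′-UTR exons, non-ATG start,
MXE-like junction imbalance, single-exon gene, stopless ORF — each with
a genome FASTA, GTF, rMATS-dialect event table and a machine-checkable
truth record.

Coding bodies are drawn from {A, C, G} only, so the sole thymines in a
locus are the planted ATG and TAA codons. Since every stop codon starts
with T, a planted stop can terminate only the reading frame aligned to
its own T; the base after ATG is restricted to C/G to exclude a TGA in
the shifted frame. This yields exact control: the poison scenario tunes
the start frame so the inclusion isoform's DJ equals the requested
target to the nucleotide (the DJ = 49/50/51 boundary fixtures rely on
this), and the frameshift scenarios plant exclusion-frame stops that
the inclusion frame provably cannot read. Minus-strand loci are exact
reverse-complement mirrors of the plus-strand construction, which is
also the strand-invariance test.

Scenario conventions: an SE event cannot produce a one-exon isoform
(the exclusion form keeps both flanks), so the single-exon scenario is
a locus whose only transcript has one exon — incompatible with the
event, designed flag `no_transcript` — while the one-exon ORF itself
(no junction, never NMD) is exercised through the per-transcript GTF
checker. The stopless scenario uses an SE length indivisible by 3 and
is flagged `ORF_changing`.

The efficiency dataset draws the nine features from realistic ranges
(stop fraction U(0.05, 1); DJ U(−400, 800) nt; 3′-UTR length
log-uniform 60–4,000 nt; proxy-scale folding energies U(−0.45, 0) per
nt) and generates the response as
`0.005·max(interaction, 0) + 0.5·1[utr3_len > 1150] + N(0, sd)` —
a dominant stop-position × DJ interaction plus a long-3′-UTR bump, the
two strongest effects the score model is expected to recover. The
binary NMD class is a median split of the response. What passing tests
show is that the pipeline's geometry, arithmetic and learning machinery
are correct under these controlled conditions; they do not certify
performance on real RNA-seq, where PSI noise, annotation
incompleteness, coordinated distant splicing and non-canonical decay
determinants all enter.

## Problem sizes and numerical choices

The oracle-equivalence checks run 1,000 random isoforms (exact match
required on stop position, DJ and 3′-UTR length); the uniqueness oracle
runs on a 100-kb synthetic reference; the score model trains on 200
labelled rows (held-out fold of 30). The noise-free learning check uses
800 rows because the step discontinuity in the generative model needs
enough held-out coverage near the break to be representable by trees at
R² ≥ 0.99. Events are processed in input order and per-isoform output
is sorted by transcript id, so output bytes are reproducible.

## Known limitations

- Only skipped-exon events are classified; the ORF scanner is
  chain-generic, but event construction for alternative 5′/3′ splice
  sites and intron retention is not implemented.
- Coordinated distant splicing on one transcript is not modelled; each
  event is judged against reference exon chains independently.
- The built-in uniqueness screen is exact-match; mismatch-tolerant
  off-target assessment requires an external aligner adapter.
- The builtin folding proxy is not on the kcal/mol scale; models are
  engine-locked for that reason.
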