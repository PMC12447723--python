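# Methods

This note documents the models and procedures implemented in `splicekit`,
the parameters that matter, the design choices made where several options
were defensible, and what the synthetic benchmarks do and do not show.

## Coordinates and the score-file offset convention

All coordinates are 0-based, half-open, on the forward strand; conversion to
and from 1-based formats (GTF/GFF3) happens only in `formats_io`. A splice
boundary sits *between* two bases; the `offset` column of a score record is
the forward-strand coordinate of the base immediately to the right of the
boundary. For an intron on forward interval [s, e):

| strand | left boundary (offset s) | right boundary (offset e) |
|--------|--------------------------|---------------------------|
| `+`    | donor (G of GT)          | acceptor (first exon base) |
| `-`    | acceptor                 | donor                      |

This single rightward rule is symmetric across strands and is enforced by
round-trip tests. Whether an aligner-facing score file marks the left or
right base of a boundary is a convention; this one is ours and is documented
rather than inferred.

## Training data

Positives are the donor/acceptor boundaries of annotated introns whose
genomic dinucleotide, read on the transcript strand, is GT (donor) or AG
(acceptor); non-canonical boundaries are dropped and counted. GC..AG and
AT..AC splicing is deliberately out of scope. Sites shared by several
transcripts are deduplicated genome-wide by (chrom, position, strand, type).

Negatives are unannotated GT/AG read on the strand **opposite** to an
annotated gene body. Annotation is incomplete in most genomes, so a
same-strand unannotated GT may well be a real donor; the antisense strand of
a known gene is a far safer negative universe. Regions covered by genes on
both strands are excluded entirely, and annotated sites can never become
negatives. Intergenic GT/AG never enter training; they appear only in the
calibration/evaluation population. Negatives are downsampled uniformly
without replacement to exactly `min(available, 3 × positives)` — exact
rather than probabilistic, so the 1:3 target is testable to equality.

Each site becomes a one-hot 4×202 window (100 bp of context on each side of
the dinucleotide, rows A,C,G,T, N as an all-zero column), read on the site's
strand. 102 bp and 302 bp windows are supported through the `flank`
parameter. Training-time sites whose window would cross a contig end are
skipped (no padding) to avoid composition artifacts; at scan time windows
are zero-padded instead, because the aligner must find a score for every
candidate key.

## Model

One joint donor/acceptor classifier; the two central window columns are
always GT or AG, and the network distinguishes site types from them, so a
separate donor and acceptor model is unnecessary. Architecture:

    conv(16 features, kernel 5) → ReLU → maxpool(2)
  → conv(16 features, kernel 5) → ReLU → maxpool(2)
  → flatten (16×47) → dense(2) → softmax

3,138 trainable parameters for the 202 bp window. The network is
implemented directly in NumPy (im2col convolutions, analytic backprop,
Adam); a finite-difference gradient check in the test suite guards the
hand-written layers. The raw score t of a window is the softmax probability
of the site class, in [0,1]; a freshly initialized model (zero dense head)
scores 0.5 everywhere.

Training: cross-entropy, Adam (lr 1e-3), batch 64, at most 100 epochs,
early stopping after 3 epochs without validation improvement, best-epoch
weights restored. Donor and acceptor examples are mixed and weighted
uniformly. Chromosomes at odd positions in the FASTA supply training and
validation; genes (not sites, not transcripts) are split 80/20 under the
seed, so overlapping isoforms cannot leak across the split; even-position
chromosomes are held out entirely. All randomness — simulation, negative
downsampling, gene split, weight init, batch shuffling, query mutation —
derives deterministically from one pipeline seed.

The last max-pooling layer (16 features × 47 positions) is exposed for
embedding and for activation-rate analysis: the activation rate of a cell
over a window set is the frequency of the cell being non-zero, and the
difference of rates between positive and negative sets shows which cells
respond to boundary signal versus flank composition.

## Calibration

Raw scores are not probabilities, especially when the 1:3 training ratio
differs from the genome-wide base rate (~1 real site per hundreds of
GT/AG). Scores are therefore binned — b = 50 equal bins over [0,1), bin
i = ⌊t·b⌋ with t = 1 clipped into bin b−1 — against annotation on the
held-out even chromosomes: Pᵢ annotated sites and Nᵢ unannotated GT/AG per
bin. The calibrated score is

    s(t) = 2·log₂[ Pᵢ/(Pᵢ+Nᵢ) · (P+N)/P ]

the log odds of the bin's empirical probability against the null model in
which every candidate is equally likely to be real; a bin at exactly the
global positive fraction scores 0. The 2·log₂ scale matches BLOSUM-style
aligner scoring. Scores are rounded half-away-from-zero and clamped to
[−64, 64] for the integer score file.

Degenerate bins, on which the formula is undefined or infinite, are
resolved as: empty bin → borrow the counts of the nearest non-empty bin
(ties to the lower bin); Pᵢ = 0 → floor; Nᵢ = 0 → cap. Whether calibration
counts should come from training or held-out chromosomes is not dictated by
the transform itself; held-out chromosomes were chosen because they match
the genome-wide prediction regime the scores are used in.

## Spliced alignment

A reference global DP over four states — H (closed), E (gap in query),
F (gap in reference), Ẽ (intron) — with affine gap costs q (open) and e
(extend), intron open cost q̃, and boundary costs d(i), a(i) looked up at
the intron's left and right offsets. Calibrated scores are bonuses:
d(i) = −s_donor(i) and a(i) = −s_acceptor(i) at scored boundaries, and a
flat non-canonical cost D_max elsewhere. On the minus strand the left
boundary is the biological acceptor and the right one the donor, so lookups
swap roles while coordinates stay forward-strand.

Because intron extension is free, the closable intron value at (i, j) equals
max over donors u ≤ i − L of H(u, j) − d(u) − q̃ (L = minimum intron length,
default 4 = GT + AG); the kernel maintains that running maximum per query
column, giving O(nm) time, and is numba-compiled. An optional maximum
intron length switches to a bounded rescan. Traceback prefers
match/mismatch > intron > gap-in-query > gap-in-reference on ties, then the
leftmost donor, making outputs deterministic.

Default parameters: match +2, mismatch −4, q = 4, e = 2, q̃ = 25,
D_max = 20. The intron-open cost is deliberately high relative to the
maximum calibrated bonus (~13 under default binning): the CNN's pooled
representation blurs position by ~4 bp, so candidates immediately adjacent
to a real site also score well, and a cheap intron open would make spurious
micro-introns next to real junctions profitable. With q̃ = 25 a junction is
only moved or introduced when residue evidence or genuine signal supports
it.

Correctness is established against an independent exhaustive-search oracle
(memoized recursion over (i, j, state) with explicit whole-intron jump
moves, limited to references ≤ 12 bp) on hundreds of random instances, and
against an independent affine-gap aligner in the no-intron limit.

## Evaluation

* **ROC / rAUC** — every GT/AG on the even chromosomes is a candidate,
  labeled by annotation; rAUC is the area under the ROC restricted to
  sensitivity > 50% and FPR < 10%, rescaled by the region area to [0,1]
  (a random classifier scores 0, a perfect one 1). Annotation errors in
  real genomes surface as apparent FP/FN; on the synthetic fixture the
  annotation is exact by construction.
* **Junction accuracy** — a predicted junction counts as annotated only on
  exact equality of both intron boundaries and the strand;
  %unannotated = 100·(1 − hits/predicted). Junctions are counted per
  alignment (not deduplicated); both raw counts are reported.
* **Base-level Sn/Sp** — interval intersection arithmetic, verified against
  a per-base set oracle.
* **Identity stratification** — alignments are binned by identity
  (matches / aligned columns; default bin width 2%) and %unannotated is
  reported per bin.
* **Expected false sites** — genome_size × dinucleotide_frequency × FPR;
  e.g. 3×10⁹ × 2/16 × 1% = 3.75 million expected false donors, an order of
  magnitude more than real donor sites, which is why calibrated scores
  rather than hard calls are fed to the aligner.

## Synthetic fixture

The generator emulates exactly the features the method consumes: multiple
chromosomes (default 4 × 150 kb), non-overlapping multi-exon genes on both
strands (280 genes, 4 exons each; exons 80–250 bp, introns 60–200 bp),
composition bias (exon GC 0.65, intron GC 0.25, background 0.45), a
GTRAG-like donor consensus with a biased exonic 3′ end, and an acceptor
polypyrimidine tract (18 bp, 95% pyrimidine) ending in YAG. Background
sequence is i.i.d., so ~70 decoy GT/AG per real site remain on held-out
chromosomes.

The consensus strength is a dial: the defaults are intentionally
higher-information than real vertebrate splice signals so that a few
thousand training windows suffice for the small CNN (real training sets are
two to three orders of magnitude larger), while bare GT..AG matching stays
ambiguous. Consequences for interpreting results: passing benchmarks show
the pipeline is correct and that calibrated learned scores beat flat
GT..AG scoring *under these conditions*; they do not estimate accuracy on
real genomes, where weaker signals, alternative splicing, non-i.i.d.
background, and annotation errors all apply.

Query transcripts for the alignment benchmark are the exon concatenation
with seeded point substitutions (15%) and 1-bp indels (2%), giving ~85%
identity — inside the band where residue evidence alone starts failing and
splice scores matter. At ≥95% identity residue alignment alone places
almost all junctions correctly and the two scoring schemes converge, which
mirrors the published observation that splice-model gains shrink as read
accuracy rises. Alignments run against the exact gene span; a flanking
margin would force the global DP to wrap the margins in spurious flanking
introns (a read mapper would clip instead).

## Known limitations

* GT..AG only; GC..AG and AT..AC splice sites are ignored end to end.
* The DP is a reference implementation: global, unbanded, no
  seeding/chaining; it is not a read mapper.
* Scores are predicted from the reference genome only; sample-specific
  variants that create or destroy splice sites are invisible.
* The printed architecture total of the original small-model family is not
  reconstructible from its description; this implementation documents its
  own parameter count (3,138) instead.
* Calibration quality depends on the held-out chromosomes carrying enough
  annotated sites per bin; tiny genomes produce coarse tables (degenerate
  bins fall back to the rules above).
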