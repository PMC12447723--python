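"""Labeled donor/acceptor windows from a genome plus annotation.

Positives are annotated intron boundaries whose genomic dinucleotide (read on
the transcript strand) is canonical: GT for donors, AG for acceptors.
Non-canonical boundaries are dropped.  Negatives are unannotated GT/AG read on
the strand *opposite* to an annotated gene body — incomplete annotations make
same-strand unannotated GT/AG unreliable as negatives, whereas the antisense
strand of a known gene is very unlikely to splice.  Regions covered by genes
on both strands are excluded entirely.  Negatives are then downsampled to a
fixed negative:positive ratio (3 by default).

Each retained site becomes a one-hot window of 2*flank + 2 columns (202 bp by
default) centered on the dinucleotide, read on the site's strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GeneModel, GenomeSequence, revcomp

DONOR, ACCEPTOR = "donor", "acceptor"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SpliceSite:
    """A candidate splice boundary (score-file offset convention)."""

    chrom: str
    pos: int
    strand: str
    site_type: str  # 'donor' | 'acceptor'
    label: int  # 1 positive, 0 negative
    gene_id: str = ""

    @property
    def key(self):
        return (self.chrom, self.pos, self.strand, self.site_type)


@dataclass
class SpliceSiteExample:
    site: SpliceSite
    window: np.ndarray  # 4 x W one-hot


@dataclass
class DatasetSplit:
    train: list[SpliceSiteExample]
    validation: list[SpliceSiteExample]
    test_chromosomes: list[str]


def one_hot(seq: str) -> np.ndarray:
    """4 x len(seq) one-hot matrix, rows A,C,G,T; N gives an all-zero column."""
    m = np.zeros((4, len(seq)), dtype=np.float32)
    for j, c in enumerate(seq):
        i = _BASE_INDEX.get(c)
        if i is not None:
            m[i, j] = 1.0
    return m


def intron_boundary_sites(gene: GeneModel) -> list[tuple[int, str]]:
    """(offset, site_type) for every intron of a transcript.

    For forward-strand intron [s, e): on '+' the donor is the left boundary
    (offset s) and the acceptor the right (offset e); on '-' the roles swap.
    """
    out = []
    for s, e in gene.introns:
        if gene.strand == "+":
            out.append((s, DONOR))
            out.append((e, ACCEPTOR))
        else:
            out.append((s, ACCEPTOR))
            out.append((e, DONOR))
    return out


def _dinuc_start(pos: int, strand: str, site_type: str) -> int:
    """Forward-strand start of the 2bp splice signal for a site."""
    if (strand, site_type) in (("+", DONOR), ("-", ACCEPTOR)):
        return pos  # left intron boundary: first two intron bases
    return pos - 2  # right intron boundary: last two intron bases


def site_dinucleotide(site_pos: int, strand: str, site_type: str, seq: str) -> str:
    """The splice dinucleotide read on the site's strand (GT/AG if canonical)."""
    d0 = _dinuc_start(site_pos, strand, site_type)
    fwd = seq[d0 : d0 + 2]
    return fwd if strand == "+" else revcomp(fwd)


def extract_annotated_sites(
    genes: list[GeneModel], genome: dict[str, str]
) -> tuple[list[SpliceSite], int]:
    """Positive donor/acceptor sites from annotation; returns (sites, n_dropped).

    Sites whose dinucleotide is not GT (donor) / AG (acceptor) are dropped;
    duplicates across transcripts are deduplicated by (chrom, pos, strand, type).
    """
    canonical = {DONOR: "GT", ACCEPTOR: "AG"}
    seen: dict[tuple, SpliceSite] = {}
    n_dropped = 0
    for g in genes:
        seq = genome[g.chrom]
        for pos, st in intron_boundary_sites(g):
            key = (g.chrom, pos, g.strand, st)
            if key in seen:
                continue
            if site_dinucleotide(pos, g.strand, st, seq) != canonical[st]:
                n_dropped += 1
                continue
            seen[key] = SpliceSite(g.chrom, pos, g.strand, st, 1, g.gene_id)
    return list(seen.values()), n_dropped


def _both_strand_overlap(genes: list[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome intervals covered by genes on both strands (excluded)."""

    def merged(ivs):
        out = []
        for s, e in sorted(ivs):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    by_cs: dict[tuple[str, str], list] = {}
    for g in genes:
        by_cs.setdefault((g.chrom, g.strand), []).append((g.tx_start, g.tx_end))
    excl: dict[str, list[tuple[int, int]]] = {}
    chroms = {c for c, _ in by_cs}
    for c in chroms:
        plus = merged(by_cs.get((c, "+"), []))
        minus = merged(by_cs.get((c, "-"), []))
        ivs = []
        for ps, pe in plus:
            for ms, me in minus:
                s, e = max(ps, ms), min(pe, me)
                if s < e:
                    ivs.append((s, e))
        excl[c] = merged(ivs)
    return excl


def extract_negative_sites(
    genes: list[GeneModel], genome: dict[str, str]
) -> list[SpliceSite]:
    """Unannotated GT/AG on the opposite strand of annotated gene bodies.

    A forward-strand "AC"/"CT" inside a '+' gene is a GT/AG on '-'; inside a
    '-' gene, forward "GT"/"AG" are candidates on '+'.  Positions overlapped
    by genes on both strands are skipped, as are annotated sites.
    """
    ann_sites, _ = extract_annotated_sites(genes, genome)
    annotated = {s.key for s in ann_sites}
    excl = _both_strand_overlap(genes)
    out: dict[tuple, SpliceSite] = {}
    for g in genes:
        seq = genome[g.chrom]
        banned = excl.get(g.chrom, [])
        opp = "-" if g.strand == "+" else "+"
        for p in range(g.tx_start, g.tx_end - 1):
            if any(s <= p and p + 2 <= e for s, e in banned):
                continue
            dn = seq[p : p + 2]
            if opp == "-":
                # GT on '-' reads "AC" forward; AG reads "CT"
                if dn == "AC":
                    cand = SpliceSite(g.chrom, p + 2, "-", DONOR, 0, g.gene_id)
                elif dn == "CT":
                    cand = SpliceSite(g.chrom, p, "-", ACCEPTOR, 0, g.gene_id)
                else:
                    continue
            else:
                if dn == "GT":
                    cand = SpliceSite(g.chrom, p, "+", DONOR, 0, g.gene_id)
                elif dn == "AG":
                    cand = SpliceSite(g.chrom, p + 2, "+", ACCEPTOR, 0, g.gene_id)
                else:
                    continue
            if cand.key in annotated or cand.key in out:
                continue
            out[cand.key] = cand
    return list(out.values())


def downsample_negatives(
    positives: list[SpliceSite],
    negatives: list[SpliceSite],
    ratio: int = 3,
    seed: int = 0,
) -> list[SpliceSite]:
    """Uniformly keep exactly min(len(negatives), ratio*len(positives)) negatives."""
    n_keep = min(len(negatives), ratio * len(positives))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=n_keep, replace=False)
    return [negatives[i] for i in sorted(idx)]


def make_window(
    site: SpliceSite, genome: dict[str, str], flank: int = 100
) -> np.ndarray | None:
    """One-hot 4 x (2*flank+2) window on the site's strand; None if out of bounds."""
    seq = genome[site.chrom]
    d0 = _dinuc_start(site.pos, site.strand, site.site_type)
    lo, hi = d0 - flank, d0 + 2 + flank
    if lo < 0 or hi > len(seq):
        return None
    s = seq[lo:hi]
    if site.strand == "-":
        s = revcomp(s)
    return one_hot(s)


def build_examples(
    sites: list[SpliceSite], genome: dict[str, str], flank: int = 100
) -> tuple[list[SpliceSiteExample], int]:
    """Windows for all sites; sites too close to a contig end are skipped."""
    out, n_skipped = [], 0
    for s in sites:
        w = make_window(s, genome, flank)
        if w is None:
            n_skipped += 1
        else:
            out.append(SpliceSiteExample(s, w))
    return out, n_skipped


def split_by_chromosome(
    examples: list[SpliceSiteExample],
    genomes: list[GenomeSequence],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Odd-index chromosomes feed train/validation (split by gene); even ones test.

    Genes, not sites, are partitioned so that all sites of a gene land in the
    same split (overlapping isoforms cannot leak between train and validation).
    """
    if len(genomes) < 2:
        raise ValueError(
            "need at least 2 chromosomes: odd-index ones train, even-index ones test"
        )
    odd = {g.name for g in genomes if g.index_in_file % 2 == 1}
    even = [g.name for g in genomes if g.index_in_file % 2 == 0]
    pool = [e for e in examples if e.site.chrom in odd]
    gene_ids = sorted({e.site.gene_id for e in pool})
    rng = np.random.default_rng(seed)
    rng.shuffle(gene_ids)
    n_train = int(len(gene_ids) * train_fraction + 1e-9)
    train_genes = set(gene_ids[:n_train])
    train = [e for e in pool if e.site.gene_id in train_genes]
    val = [e for e in pool if e.site.gene_id not in train_genes]
    return DatasetSplit(train, val, even)


def stack_windows(examples: list[SpliceSiteExample]) -> tuple[np.ndarray, np.ndarray]:
    """(N,4,W) float32 window tensor and (N,) int label vector."""
    X = np.stack([e.window for e in examples]).astype(np.float32)
    y = np.array([e.site.label for e in examples], dtype=np.int64)
    return X, y
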