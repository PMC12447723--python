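"""Synthetic genomes with planted splice grammar.

The generator emulates the inputs the rest of the package consumes: a
multi-chromosome genome (FASTA), multi-exon gene models on both strands
(BED12) whose introns all begin GT and end AG, an extended donor consensus
(GTRAG-like intron start plus a biased exonic 3' end), an acceptor
polypyrimidine tract ending in YAG, and exon/intron base-composition bias.
Background sequence is i.i.d. with its own GC content, so every chromosome
also carries many decoy GT/AG dinucleotides that are not splice sites.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    GeneModel,
    GenomeSequence,
    revcomp,
    write_bed12,
    write_fasta,
)
from .training_data import ACCEPTOR, DONOR, SpliceSite

BASES = "ACGT"

# position-specific base probabilities (A, C, G, T); the planted signal is an
# idealized, high-information version of the GTRAG-like donor / YAG acceptor
# consensus so that the desk-scale training sets (a few thousand windows)
# carry enough signal for the small CNN, while decoy GT/AG stay plentiful
DONOR_EXON_CONSENSUS = (  # last three exonic bases before the intron
    (0.45, 0.45, 0.05, 0.05),
    (0.85, 0.05, 0.05, 0.05),
    (0.02, 0.01, 0.95, 0.02),
)
DONOR_INTRON_CONSENSUS = (  # intron bases after the invariant GT
    (0.70, 0.01, 0.27, 0.02),  # R: purine-biased third intron base
    (0.95, 0.02, 0.01, 0.02),
    (0.01, 0.01, 0.96, 0.02),
    (0.05, 0.05, 0.05, 0.85),
)
ACCEPTOR_Y_CONSENSUS = (0.01, 0.49, 0.01, 0.49)  # Y of YAG at intron -3


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 4
    chrom_length: int = 150_000
    n_genes: int = 280
    exons_per_gene: int = 4
    exon_len_range: tuple[int, int] = (80, 250)
    intron_len_range: tuple[int, int] = (60, 200)
    intergenic_range: tuple[int, int] = (150, 500)
    exon_gc: float = 0.65
    intron_gc: float = 0.25
    background_gc: float = 0.45
    minus_fraction: float = 0.5
    donor_exon_consensus: tuple = DONOR_EXON_CONSENSUS
    donor_intron_consensus: tuple = DONOR_INTRON_CONSENSUS
    polypyrimidine_len: int = 18
    polypyrimidine_prob: float = 0.95
    acceptor_y_consensus: tuple = ACCEPTOR_Y_CONSENSUS
    seed: int = 0

    def __post_init__(self) -> None:
        min_intron = (
            2 + len(self.donor_intron_consensus) + self.polypyrimidine_len + 3
        )
        if self.intron_len_range[0] < min_intron:
            raise ValueError(f"introns must be >= {min_intron} bp for the motifs")
        if self.exons_per_gene < 2:
            raise ValueError("need >= 2 exons per gene to plant introns")


@dataclass
class SyntheticGenome:
    config: SyntheticConfig
    genomes: list[GenomeSequence]
    genes: list[GeneModel]
    truth_sites: list[SpliceSite] = field(default_factory=list)

    @property
    def genome_dict(self) -> dict[str, str]:
        return {g.name: g.seq for g in self.genomes}

    def annotated_junctions(self) -> set[tuple[str, int, int, str]]:
        out = set()
        for g in self.genes:
            for s, e in g.introns:
                out.add((g.chrom, s, e, g.strand))
        return out

    def write(self, out_dir) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "genome.fa"),
            "bed": os.path.join(out_dir, "annotation.bed"),
            "truth": os.path.join(out_dir, "truth_sites.tsv"),
        }
        write_fasta(self.genomes, paths["fasta"])
        write_bed12(self.genes, paths["bed"])
        with open(paths["truth"], "w") as fh:
            fh.write("chrom\toffset\tstrand\tsite_type\tgene_id\n")
            for s in self.truth_sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.site_type}\t{s.gene_id}\n")
        return paths


def _sample(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _sample_probs(rng: np.random.Generator, probs) -> int:
    return int(rng.choice(4, p=np.asarray(probs) / np.sum(probs)))


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _build_gene_sense(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Sense-strand gene sequence and its exon intervals (gene-local coords)."""
    exon_lens = rng.integers(*cfg.exon_len_range, size=cfg.exons_per_gene, endpoint=True)
    intron_lens = rng.integers(
        *cfg.intron_len_range, size=cfg.exons_per_gene - 1, endpoint=True
    )
    parts: list[np.ndarray] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for k, el in enumerate(exon_lens):
        exon = _sample(rng, int(el), cfg.exon_gc)
        if k > 0:  # first exonic base after an acceptor, mildly G-biased
            exon[0] = _sample_probs(rng, (0.2, 0.15, 0.5, 0.15))
        if k < len(intron_lens):  # exonic 3' end feeding the donor
            for i, probs in enumerate(cfg.donor_exon_consensus):
                exon[len(exon) - len(cfg.donor_exon_consensus) + i] = _sample_probs(
                    rng, probs
                )
        parts.append(exon)
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if k < len(intron_lens):
            il = int(intron_lens[k])
            intron = _sample(rng, il, cfg.intron_gc)
            intron[0], intron[1] = 2, 3  # G, T
            for i, probs in enumerate(cfg.donor_intron_consensus):
                intron[2 + i] = _sample_probs(rng, probs)
            tract_end = il - 3
            for i in range(tract_end - cfg.polypyrimidine_len, tract_end):
                if rng.random() < cfg.polypyrimidine_prob:
                    intron[i] = 1 if rng.random() < 0.5 else 3  # C or T
            intron[il - 3] = _sample_probs(rng, cfg.acceptor_y_consensus)
            intron[il - 2], intron[il - 1] = 0, 2  # A, G
            parts.append(intron)
            pos += il
    return _to_str(np.concatenate(parts)), exons


def generate(config: SyntheticConfig | None = None) -> SyntheticGenome:
    """Plant genes into background chromosomes; returns sequences, models, truth."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    chrom_seqs = [
        _sample(rng, cfg.chrom_length, cfg.background_gc)
        for _ in range(cfg.n_chromosomes)
    ]
    cursors = [cfg.intergenic_range[0]] * cfg.n_chromosomes
    genes: list[GeneModel] = []
    truth: list[SpliceSite] = []
    for gi in range(cfg.n_genes):
        ci = gi % cfg.n_chromosomes
        sense_seq, sense_exons = _build_gene_sense(cfg, rng)
        L = len(sense_seq)
        start = cursors[ci] + int(rng.integers(*cfg.intergenic_range, endpoint=True))
        if start + L > cfg.chrom_length - cfg.intergenic_range[0]:
            raise ValueError(
                f"infeasible packing: gene {gi} does not fit on chromosome {ci + 1}; "
                "increase chrom_length or reduce n_genes"
            )
        strand = "-" if rng.random() < cfg.minus_fraction else "+"
        if strand == "+":
            placed = sense_seq
            exons = [(start + a, start + b) for a, b in sense_exons]
        else:
            placed = revcomp(sense_seq)
            exons = sorted((start + L - b, start + L - a) for a, b in sense_exons)
        codes = np.array([BASES.index(c) for c in placed], dtype=chrom_seqs[ci].dtype)
        chrom_seqs[ci][start : start + L] = codes
        name = f"gene{gi + 1}"
        gene = GeneModel(f"chr{ci + 1}", strand, start, start + L, exons, name, name)
        genes.append(gene)
        cursors[ci] = start + L
        for s, e in gene.introns:
            if strand == "+":
                truth.append(SpliceSite(gene.chrom, s, "+", DONOR, 1, name))
                truth.append(SpliceSite(gene.chrom, e, "+", ACCEPTOR, 1, name))
            else:
                truth.append(SpliceSite(gene.chrom, s, "-", ACCEPTOR, 1, name))
                truth.append(SpliceSite(gene.chrom, e, "-", DONOR, 1, name))
    genomes = [
        GenomeSequence(f"chr{i + 1}", _to_str(chrom_seqs[i]), i + 1)
        for i in range(cfg.n_chromosomes)
    ]
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return SyntheticGenome(cfg, genomes, genes, truth)


def spliced_transcript(gene: GeneModel, genome: dict[str, str]) -> str:
    """mRNA-like sequence: exons concatenated, reverse-complemented on '-'."""
    seq = "".join(genome[gene.chrom][a:b] for a, b in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


def mutate_query(
    seq: str, substitution_rate: float, indel_rate: float, seed: int = 0
) -> str:
    """Seeded point errors for alignment tests at controlled identity.

    Each base is substituted with probability ``substitution_rate``; single-
    base deletions and insertions each occur at ``indel_rate/2`` per base.
    """
    if not (0 <= substitution_rate <= 0.3 and 0 <= indel_rate <= 0.3):
        raise ValueError("rates must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    out = []
    for c in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if c in BASES and rng.random() < substitution_rate:
            c = rng.choice([b for b in BASES if b != c])
        out.append(c)
        if r >= indel_rate / 2 and r < indel_rate:
            out.append(BASES[rng.integers(4)])  # insertion
    return "".join(out)
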