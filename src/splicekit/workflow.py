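"""End-to-end orchestration: simulate -> training data -> train -> calibrate
-> scan -> align -> evaluate.

Odd-index chromosomes supply training/validation examples (split 80/20 by
gene); even-index chromosomes are held out and used for everything test-like:
raw-score ROC/rAUC, the calibration population (every GT/AG labeled by
annotation), and the spliced-alignment junction benchmark.

One pipeline seed governs every stochastic stage; per-stage seeds are derived
from it deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibration, cnn_model, evaluation, genome_scan, spliced_dp
from . import synthetic_fixtures as synth
from . import training_data as td
from .formats_io import GenomeSequence, ScoreRecord, ScoreTable


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage sub-seed in [0, 2^31)."""
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(stage)) % (2**31))


@dataclass
class PipelineResult:
    sim: synth.SyntheticGenome
    model: cnn_model.CnnModel
    table: calibration.CalibrationTable
    train_state: cnn_model.TrainState
    records: list[ScoreRecord]  # even-chromosome splice scores
    rauc: float
    counts: dict = field(default_factory=dict)
    flank: int = 100

    @property
    def score_table(self) -> ScoreTable:
        return ScoreTable(self.records)


def run_training_pipeline(
    sim_config: synth.SyntheticConfig | None = None,
    seed: int = 0,
    flank: int = 100,
    neg_ratio: int = 3,
    max_epochs: int = 100,
    patience: int = 3,
) -> PipelineResult:
    """Full training workflow on a synthetic genome; scores held-out chromosomes."""
    cfg = sim_config or synth.SyntheticConfig(seed=derive_seed(seed, 0))
    sim = synth.generate(cfg)
    genome = sim.genome_dict

    positives, n_noncanonical = td.extract_annotated_sites(sim.genes, genome)
    negatives = td.extract_negative_sites(sim.genes, genome)
    kept = td.downsample_negatives(positives, negatives, neg_ratio, derive_seed(seed, 1))
    examples, n_skipped = td.build_examples(positives + kept, genome, flank)
    split = td.split_by_chromosome(examples, sim.genomes, 0.8, derive_seed(seed, 2))

    model = cnn_model.CnnModel(
        cnn_model.CnnConfig(window=2 * flank + 2, seed=derive_seed(seed, 3))
    )
    state = cnn_model.train(
        model, split,
        max_epochs=max_epochs, patience=patience, seed=derive_seed(seed, 4),
    )

    even = [g for g in sim.genomes if g.index_in_file % 2 == 0]
    cands, t = genome_scan.raw_candidate_scores(even, model, flank)
    truth_keys = {
        (s.chrom, s.pos, s.strand, genome_scan.TYPE_CODE[s.site_type])
        for s in sim.truth_sites
    }
    labels = np.array(
        [(c[0], c[1], c[2], genome_scan.TYPE_CODE[c[3]]) in truth_keys for c in cands]
    )
    fpr, tpr = evaluation.roc(t, labels.astype(int))
    r = evaluation.rauc(fpr, tpr)
    table = calibration.build_table(t, labels)
    scores = np.atleast_1d(table.calibrate(t))
    order = {g.name: g.index_in_file for g in sim.genomes}
    records = [
        ScoreRecord(c[0], c[1], c[2], genome_scan.TYPE_CODE[c[3]], int(s))
        for c, s in zip(cands, scores)
    ]
    records.sort(key=lambda rr: (order[rr.chrom], rr.offset, rr.strand, rr.site_type))

    counts = {
        "n_positive": len(positives),
        "n_noncanonical_dropped": n_noncanonical,
        "n_negative_available": len(negatives),
        "n_negative_kept": len(kept),
        "n_window_skipped": n_skipped,
        "n_train": len(split.train),
        "n_validation": len(split.validation),
        "n_test_candidates": len(cands),
    }
    return PipelineResult(sim, model, table, state, records, r, counts, flank)


def _junction_costs_for_slice(
    scores: ScoreTable, chrom: str, lo: int, hi: int, strand: str
) -> tuple[dict[int, float], dict[int, float]]:
    """Slice-local DP cost inputs for aligning a transcript of one strand.

    The DP opens introns at their left reference boundary and closes at the
    right one.  On '+' those are the biological donor and acceptor; on '-'
    the left boundary is the biological acceptor and the right the donor, so
    the lookups swap roles while coordinates stay forward-strand.
    """
    open_type, close_type = ("D", "A") if strand == "+" else ("A", "D")
    d, a = {}, {}
    for off in range(lo, hi + 1):
        s = scores.get(chrom, off, strand, open_type)
        if s is not None:
            d[off - lo] = float(s)
        s = scores.get(chrom, off, strand, close_type)
        if s is not None:
            a[off - lo] = float(s)
    return d, a


def _uniform_costs_for_slice(
    genome: dict[str, str], chrom: str, lo: int, hi: int, strand: str
) -> tuple[dict[int, float], dict[int, float]]:
    """GT..AG-only scoring: every canonical candidate scores 0 (flat)."""
    seq = GenomeSequence(chrom, genome[chrom][lo:hi], 1)
    d, a = {}, {}
    for _, off, s, st in genome_scan.enumerate_candidates(seq):
        if s != strand:
            continue
        left_is_open = (strand == "+") == (st == td.DONOR)
        (d if left_is_open else a)[off] = 0.0
    return d, a


def alignment_identity(ref: str, query: str, aln: spliced_dp.SplicedAlignment) -> float:
    """Matches over aligned M columns of a spliced alignment."""
    i = j = matches = columns = 0
    for op, ln in aln.cigar:
        if op == "M":
            for _ in range(ln):
                columns += 1
                if ref[i] == query[j]:
                    matches += 1
                i += 1
                j += 1
        elif op == "D" or op == "N":
            i += ln
        else:
            j += ln
    return matches / columns if columns else 0.0


@dataclass
class BenchmarkResult:
    n_predicted: int
    n_hits: int
    pct_unannotated: float | None
    identities: list[float]
    per_gene: list[tuple[str, int, int]] = field(default_factory=list)


def junction_benchmark(
    result: PipelineResult,
    seed: int = 0,
    substitution_rate: float = 0.15,
    indel_rate: float = 0.02,
    scheme: str = "learned",
    params: spliced_dp.AlignParams | None = None,
    margin: int = 0,
    max_genes: int | None = None,
) -> BenchmarkResult:
    """Align mutated transcripts of held-out genes; score junction accuracy.

    ``scheme`` is "learned" (calibrated CNN scores) or "uniform" (every
    GT..AG candidate scores 0).  Queries are the forward-orientation exon
    concatenation with seeded substitutions/indels; predicted junctions are
    compared with the full annotation by exact boundary match.
    """
    sim = result.sim
    genome = sim.genome_dict
    params = params or spliced_dp.AlignParams()
    even = {g.name for g in sim.genomes if g.index_in_file % 2 == 0}
    genes = [g for g in sim.genes if g.chrom in even]
    if max_genes is not None:
        genes = genes[:max_genes]
    annotated = sim.annotated_junctions()
    score_table = result.score_table
    n_pred = n_hit = 0
    identities: list[float] = []
    per_gene = []
    for k, gene in enumerate(genes):
        lo = max(0, gene.tx_start - margin)
        hi = min(len(genome[gene.chrom]), gene.tx_end + margin)
        ref = genome[gene.chrom][lo:hi]
        exonic = "".join(genome[gene.chrom][a:b] for a, b in gene.exons)
        query = synth.mutate_query(
            exonic, substitution_rate, indel_rate, derive_seed(seed, 100 + k)
        )
        if scheme == "learned":
            d, a = _junction_costs_for_slice(score_table, gene.chrom, lo, hi, gene.strand)
        elif scheme == "uniform":
            d, a = _uniform_costs_for_slice(genome, gene.chrom, lo, hi, gene.strand)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        aln = spliced_dp.align(ref, query, params, d, a)
        identities.append(alignment_identity(ref, query, aln))
        hits = sum(
            1
            for u, v in aln.junctions
            if (gene.chrom, lo + u, lo + v, gene.strand) in annotated
        )
        n_pred += len(aln.junctions)
        n_hit += hits
        per_gene.append((gene.name, len(aln.junctions), hits))
    pct = round(100.0 * (1.0 - n_hit / n_pred), 2) if n_pred else None
    return BenchmarkResult(n_pred, n_hit, pct, identities, per_gene)
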