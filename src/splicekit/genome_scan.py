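"""Score every GT/AG on both strands of a genome and emit splice-score records.

Unlike training (which skips sites too close to a contig end), scanning
zero-pads windows so that every genomic candidate receives a score: the
aligner must never miss a lookup key.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .calibration import CalibrationTable
from .cnn_model import CnnModel
from .formats_io import GenomeSequence, ScoreRecord
from .training_data import ACCEPTOR, DONOR, one_hot

# forward-strand dinucleotide -> (strand, site_type, offset delta from dinuc start)
_PATTERNS = {
    "GT": ("+", DONOR, 0),  # '+' donor: offset = first intron base
    "AG": ("+", ACCEPTOR, 2),  # '+' acceptor: offset = first base after AG
    "AC": ("-", DONOR, 2),  # GT on '-': right intron boundary
    "CT": ("-", ACCEPTOR, 0),  # AG on '-': left intron boundary
}

TYPE_CODE = {DONOR: "D", ACCEPTOR: "A"}


def enumerate_candidates(
    chrom: GenomeSequence,
) -> Iterator[tuple[str, int, str, str]]:
    """All (chrom, offset, strand, site_type) candidates of one sequence."""
    for name, off, strand, st, _ in _enumerate_with_position(chrom):
        yield (name, off, strand, st)


def _enumerate_with_position(chrom: GenomeSequence):
    """Candidates plus the forward position of the dinucleotide itself."""
    seq = chrom.seq
    for p in range(len(seq) - 1):
        hit = _PATTERNS.get(seq[p : p + 2])
        if hit is not None:
            strand, st, delta = hit
            yield (chrom.name, p + delta, strand, st, p)


def _window_batch(
    padded: np.ndarray, d0s: np.ndarray, minus: np.ndarray, width: int
) -> np.ndarray:
    """Gather (B,4,width) windows from a flank-padded one-hot chromosome.

    ``padded`` is one_hot(seq) with ``flank`` zero columns on each side, so
    the window of a candidate whose dinucleotide starts at forward position
    d0 begins at padded column d0.  Minus-strand windows are reverse-
    complemented: in one-hot form a flip of the channel axis (A<->T, C<->G,
    rows being A,C,G,T) together with a flip of the position axis.
    """
    view = np.lib.stride_tricks.sliding_window_view(padded, width, axis=1)
    w = view[:, d0s, :].transpose(1, 0, 2).copy()
    w[minus] = w[minus][:, ::-1, ::-1]
    return w


def raw_candidate_scores(
    genomes: list[GenomeSequence],
    model: CnnModel,
    flank: int = 100,
    skip_n: bool = False,
    batch_size: int = 512,
) -> tuple[list[tuple[str, int, str, str]], np.ndarray]:
    """Raw model score t in [0,1] for every GT/AG candidate of the genome.

    Returns candidates (chrom, offset, strand, site_type) in genome order and
    the matching score vector.  Windows at sequence ends are zero-padded;
    with ``skip_n`` candidates whose window overlaps an N run are suppressed.
    """
    width = 2 * flank + 2
    if model.config.window != width:
        raise ValueError(
            f"model window {model.config.window} does not match flank {flank} "
            f"(expected width {width})"
        )
    all_cands: list[tuple[str, int, str, str]] = []
    all_t: list[np.ndarray] = []
    for chrom in genomes:
        cands = list(_enumerate_with_position(chrom))
        if skip_n and cands:
            is_n = np.frombuffer(chrom.seq.encode(), dtype=np.uint8) == ord("N")
            cum = np.concatenate([[0], np.cumsum(is_n)])
            L = len(chrom.seq)
            cands = [
                c
                for c in cands
                if cum[min(c[4] + 2 + flank, L)] - cum[max(c[4] - flank, 0)] == 0
            ]
        if not cands:
            continue
        padded = np.zeros((4, len(chrom.seq) + 2 * flank), dtype=np.float32)
        padded[:, flank : flank + len(chrom.seq)] = one_hot(chrom.seq)
        d0s = np.array([c[4] for c in cands], dtype=np.int64)
        minus = np.array([c[2] == "-" for c in cands])
        for i in range(0, len(cands), batch_size):
            sl = slice(i, i + batch_size)
            windows = _window_batch(padded, d0s[sl], minus[sl], width)
            all_t.append(np.atleast_1d(model.forward(windows)))
        all_cands.extend((c[0], c[1], c[2], c[3]) for c in cands)
    t = np.concatenate(all_t) if all_t else np.empty(0)
    return all_cands, t


def scan(
    genomes: list[GenomeSequence],
    model: CnnModel,
    table: CalibrationTable,
    flank: int = 100,
    skip_n: bool = False,
    batch_size: int = 512,
) -> list[ScoreRecord]:
    """One calibrated ScoreRecord per candidate, sorted by (chrom, offset)."""
    cands, t = raw_candidate_scores(genomes, model, flank, skip_n, batch_size)
    scores = np.atleast_1d(table.calibrate(t)) if len(t) else []
    order = {g.name: g.index_in_file for g in genomes}
    records = [
        ScoreRecord(chrom, off, strand, TYPE_CODE[st], int(sc))
        for (chrom, off, strand, st), sc in zip(cands, scores)
    ]
    records.sort(key=lambda r: (order[r.chrom], r.offset, r.strand, r.site_type))
    return records
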