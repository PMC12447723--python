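"""Accuracy metrics: ROC / restricted AUC for site prediction, junction and
base-level accuracy for alignments, and the expected-false-site estimate.

rAUC restricts the ROC to the region that matters for spliced alignment —
sensitivity above ``min_tpr`` (default 50%) and false positive rate below
``max_fpr`` (default 10%) — and rescales the area under the curve within that
region to [0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_curve


def roc(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) arrays over all thresholds; requires both classes present."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both positive and negative examples")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr


def rauc(
    fpr: np.ndarray,
    tpr: np.ndarray,
    min_tpr: float = 0.5,
    max_fpr: float = 0.1,
) -> float:
    """Area under the ROC within {FPR <= max_fpr, TPR >= min_tpr}, rescaled.

    The curve is treated as piecewise linear between ROC vertices; the region
    area max_fpr * (1 - min_tpr) normalizes the result into [0, 1].
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    grid = np.unique(np.concatenate([fpr[fpr <= max_fpr], [0.0, max_fpr]]))
    y = np.interp(grid, fpr, tpr)
    contrib = np.clip(y - min_tpr, 0.0, 1.0 - min_tpr)
    area = float(np.trapezoid(contrib, grid))
    return area / (max_fpr * (1.0 - min_tpr))


def junction_accuracy(
    predicted_junctions,
    annotated_junctions,
) -> tuple[int, int, float | None]:
    """(n_predicted, n_annotated_hits, %unannotated).

    Junctions are (chrom, intron_start, intron_end, strand) and match only on
    exact boundary equality.  %unannotated = 100 * (1 - hits/predicted),
    rounded to 2 decimals; None if nothing was predicted.
    """
    annotated = set(annotated_junctions)
    predicted = list(predicted_junctions)
    n_pred = len(predicted)
    if n_pred == 0:
        return 0, 0, None
    n_hit = sum(1 for j in predicted if j in annotated)
    return n_pred, n_hit, round(100.0 * (1.0 - n_hit / n_pred), 2)


def pct_unannotated(n_predicted: int, n_annotated: int) -> float:
    """100 * (1 - #annotated/#predicted), to two decimals."""
    if n_predicted <= 0:
        raise ValueError("no predicted junctions")
    return round(100.0 * (1.0 - n_annotated / n_predicted), 2)


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _coverage(intervals) -> int:
    return sum(e - s for s, e in _merge(intervals))


def _intersection(a, b) -> int:
    a, b = _merge(a), _merge(b)
    total = i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def base_sn_sp(predicted_intervals, annotated_intervals) -> tuple[float, float]:
    """Base-level sensitivity and specificity in percent.

    Inputs are dicts chrom -> list of (start, end) half-open intervals.
    Sn = 100*|pred & annot|/|annot|; Sp = 100*|pred & annot|/|pred|.
    """
    annot_total = sum(_coverage(v) for v in annotated_intervals.values())
    if annot_total == 0:
        raise ValueError("annotation is empty")
    pred_total = sum(_coverage(v) for v in predicted_intervals.values())
    inter = sum(
        _intersection(predicted_intervals.get(c, []), annotated_intervals[c])
        for c in annotated_intervals
    )
    sn = 100.0 * inter / annot_total
    sp = 100.0 * inter / pred_total if pred_total else 0.0
    return sn, sp


def identity_binning(
    identities,
    n_predicted,
    n_hits,
    bin_width: float = 0.02,
):
    """Junction error rate stratified by alignment identity.

    Returns a list of (bin_lo, bin_hi, n_alignments, n_predicted, n_hits,
    pct_unannotated-or-None) covering [0, 1] in fixed-width bins that have at
    least one alignment.
    """
    ident = np.asarray(identities, dtype=float)
    npred = np.asarray(n_predicted, dtype=int)
    nhit = np.asarray(n_hits, dtype=int)
    idx = np.minimum((ident / bin_width).astype(int), int(np.ceil(1.0 / bin_width)) - 1)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        tot_pred = int(npred[sel].sum())
        tot_hit = int(nhit[sel].sum())
        pct = pct_unannotated(tot_pred, tot_hit) if tot_pred else None
        rows.append(
            (round(b * bin_width, 6), round((b + 1) * bin_width, 6),
             int(sel.sum()), tot_pred, tot_hit, pct)
        )
    return rows


def expected_false_sites(genome_size: float, dinucleotide_freq: float, fpr: float) -> float:
    """Expected false predictions: genome_size * dinucleotide_freq * fpr.

    E.g. a 3 Gb genome, GT frequency 2/16 per base and a 1% false positive
    rate yields 3.75 million expected false donor sites.
    """
    if genome_size <= 0 or dinucleotide_freq <= 0 or fpr < 0:
        raise ValueError("arguments must be positive (fpr >= 0)")
    return genome_size * dinucleotide_freq * fpr
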