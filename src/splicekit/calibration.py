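"""Raw CNN scores to empirical 2*log2 log-odds, via binned counts.

Raw scores t in [0,1] are divided into b bins (50 by default); bin i holds
P_i annotated sites and N_i unannotated GT/AG.  P_i/(P_i+N_i) estimates the
probability that a candidate in bin i is a real splice site, and the
calibrated score is the log-odds of that estimate against the null model in
which every GT/AG is equally likely to be real:

    s(t) = 2*log2( P_i/(P_i+N_i) * (P+N)/P ),   i = floor(t*b)

The 2*log2 scale keeps scores interoperable with BLOSUM-scaled aligners;
scores are integer-quantized and clamped (default [-64, 64]) for the
splice-score file.

Degenerate bins (the formula is undefined or infinite there): an empty bin
borrows the counts of the nearest non-empty bin (ties to the lower bin);
P_i = 0 maps to the floor, N_i = 0 to the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BINS = 50
DEFAULT_FLOOR = -64
DEFAULT_CAP = 64


@dataclass
class CalibrationTable:
    b: int = DEFAULT_BINS
    P: np.ndarray = field(default_factory=lambda: np.zeros(DEFAULT_BINS, dtype=np.int64))
    N: np.ndarray = field(default_factory=lambda: np.zeros(DEFAULT_BINS, dtype=np.int64))
    floor_score: int = DEFAULT_FLOOR
    cap_score: int = DEFAULT_CAP

    @property
    def total_positive(self) -> int:
        return int(self.P.sum())

    @property
    def total_negative(self) -> int:
        return int(self.N.sum())

    def bin_index(self, t) -> np.ndarray:
        """floor(t*b), clipped so t = 1.0 lands in bin b-1."""
        return np.minimum((np.asarray(t, dtype=float) * self.b).astype(int), self.b - 1)

    def _effective_counts(self, i: int) -> tuple[int, int]:
        """Counts for bin i, borrowing from the nearest non-empty bin if empty."""
        if self.P[i] + self.N[i] > 0:
            return int(self.P[i]), int(self.N[i])
        occupied = np.nonzero(self.P + self.N)[0]
        if len(occupied) == 0:
            raise ValueError("calibration table has no counts")
        dist = np.abs(occupied - i)
        # tie -> lower bin: stable argmin over (distance, bin index)
        j = occupied[np.lexsort((occupied, dist))[0]]
        return int(self.P[j]), int(self.N[j])

    def transform(self, t):
        """Calibrated real-valued score s(t); accepts a scalar or array."""
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        P_tot, N_tot = self.total_positive, self.total_negative
        if P_tot == 0:
            raise ValueError("calibration table has no positive counts")
        out = np.empty(len(tt))
        for k, i in enumerate(self.bin_index(tt)):
            p_i, n_i = self._effective_counts(int(i))
            if p_i == 0:
                out[k] = float(self.floor_score)
            elif n_i == 0:
                out[k] = float(self.cap_score)
            else:
                prob = p_i / (p_i + n_i)
                out[k] = 2.0 * np.log2(prob * (P_tot + N_tot) / P_tot)
        return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def quantize(self, s):
        """Round half away from zero, clamp to [floor_score, cap_score]."""
        ss = np.asarray(s, dtype=float)
        q = np.sign(ss) * np.floor(np.abs(ss) + 0.5)
        q = np.clip(q, self.floor_score, self.cap_score)
        q = q.astype(int)
        return int(q) if q.ndim == 0 else q

    def calibrate(self, t):
        """transform + quantize in one step: integer splice score(s) for raw t."""
        return self.quantize(self.transform(t))

    # ---- serialization ------------------------------------------------------

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "calib_P": self.P,
            "calib_N": self.N,
            "calib_meta": np.array([self.b, self.floor_score, self.cap_score]),
        }

    @classmethod
    def from_arrays(cls, arrays) -> "CalibrationTable":
        b, floor, cap = (int(x) for x in arrays["calib_meta"])
        return cls(b, np.array(arrays["calib_P"]), np.array(arrays["calib_N"]), floor, cap)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin\tP\tN\ts\n")
            for i in range(self.b):
                s = self.transform((i + 0.5) / self.b)
                fh.write(f"{i}\t{self.P[i]}\t{self.N[i]}\t{s:.4f}\n")


def build_table(
    raw_scores: np.ndarray,
    is_annotated: np.ndarray,
    b: int = DEFAULT_BINS,
    floor_score: int = DEFAULT_FLOOR,
    cap_score: int = DEFAULT_CAP,
) -> CalibrationTable:
    """Per-bin positive/negative counts from raw scores and annotation labels."""
    t = np.asarray(raw_scores, dtype=float)
    lab = np.asarray(is_annotated, dtype=bool)
    if len(t) == 0:
        raise ValueError("cannot build a calibration table from no scores")
    if len(t) != len(lab):
        raise ValueError("scores and labels differ in length")
    if t.min() < 0 or t.max() > 1:
        raise ValueError("raw scores must lie in [0, 1]")
    table = CalibrationTable(
        b,
        np.zeros(b, dtype=np.int64),
        np.zeros(b, dtype=np.int64),
        floor_score,
        cap_score,
    )
    idx = table.bin_index(t)
    np.add.at(table.P, idx[lab], 1)
    np.add.at(table.N, idx[~lab], 1)
    return table
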