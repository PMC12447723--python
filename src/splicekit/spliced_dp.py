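"""Reference spliced-alignment dynamic program with donor/acceptor scores.

Global nucleotide alignment with affine gaps plus an intron state that lets
the reference advance at no per-base cost between a donor and an acceptor:

    H[i][j] = max( H[i-1][j-1] + s(i,j),  E[i][j],  F[i][j],  Et[i][j] - a(i) )
    E[i+1][j] = max( H[i][j] - q,  E[i][j] ) - e        (gap in query)
    F[i][j+1] = max( H[i][j] - q,  F[i][j] ) - e        (gap in reference)
    Et[i+1][j] = max( H[i][j] - d(i) - qt,  Et[i][j] )  (intron state)

where q/e are the affine gap open/extend penalties, qt the intron-open
penalty, and d(i)/a(i) the donor/acceptor costs at reference boundary i
(score-file offset convention: the intron occupies reference [u, v) with
donor cost looked up at u and acceptor cost at v).

Sign convention: calibrated splice scores are log-odds where higher is
better, while d/a enter the recurrence as costs; scored junction boundaries
therefore use d(i) = -s_donor(i) and a(i) = -s_acceptor(i) (a bonus for
well-supported junctions), and unscored boundaries cost ``D_max``.

Because intron extension is free, Et[i][j] closable at i equals
max over donors u <= i - min_intron of (H[u][j] - d(u) - qt); the production
kernel (numba-compiled) maintains that running maximum per query column.
Introns shorter than ``min_intron_len`` (default 4: GT + AG) are disallowed.

Traceback tie-breaking: match/mismatch > intron > gap-in-query > gap-in-ref,
then the leftmost donor for equal-scoring intron placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

NEG = -1e18


@dataclass
class AlignParams:
    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = 4.0  # q
    gap_extend: float = 2.0  # e
    intron_open: float = 25.0  # qt; high enough to suppress spurious micro-introns
    noncanonical_cost: float = 20.0  # D_max: d/a at unscored boundaries
    min_intron_len: int = 4
    max_intron_len: int | None = None

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.intron_open) < 0:
            raise ValueError("gap and intron penalties must be >= 0")
        if self.noncanonical_cost < 0:
            raise ValueError("noncanonical junction cost must be >= 0")


@dataclass
class SplicedAlignment:
    score: float
    cigar: list[tuple[str, int]]  # ops over M (match/mismatch), I, D, N
    junctions: list[tuple[int, int]]  # intron intervals [u, v) on the reference

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def junction_cost_arrays(
    n: int,
    params: AlignParams,
    donor_scores: dict[int, float] | None = None,
    acceptor_scores: dict[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary d(i) and a(i) cost arrays of length n+1 for a reference of
    length n.  Boundaries present in the score dicts cost minus their score;
    all others cost D_max."""
    d = np.full(n + 1, params.noncanonical_cost, dtype=np.float64)
    a = np.full(n + 1, params.noncanonical_cost, dtype=np.float64)
    for off, s in (donor_scores or {}).items():
        if 0 <= off <= n:
            d[off] = -float(s)
    for off, s in (acceptor_scores or {}).items():
        if 0 <= off <= n:
            a[off] = -float(s)
    return d, a


@njit(cache=True)
def _dp_kernel(sub, d, a, q, e, qt, min_intron, max_intron):  # pragma: no cover
    n, m = sub.shape
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    # traceback: ptrH 0=diag 1=E 2=F 3=intron; ptrE/ptrF 1=extend; donor_of
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    donor_of = np.full((n + 1, m + 1), -1, dtype=np.int64)
    # running intron-open maxima per query column (donors u <= i - min_intron)
    tbest = np.full(m + 1, NEG)
    targ = np.full(m + 1, -1, dtype=np.int64)

    H[0, 0] = 0.0
    for j in range(1, m + 1):
        open_f = H[0, j - 1] - q
        ext_f = F[0, j - 1]
        if open_f >= ext_f:
            F[0, j] = open_f - e
            ptrF[0, j] = 0
        else:
            F[0, j] = ext_f - e
            ptrF[0, j] = 1
        H[0, j] = F[0, j]
        ptrH[0, j] = 2
    for i in range(1, n + 1):
        u = i - min_intron
        if u >= 0:
            for j in range(m + 1):
                if max_intron > 0:
                    # bounded window: rescan eligible donors (reference scale only)
                    best = NEG
                    barg = -1
                    lo = i - max_intron
                    if lo < 0:
                        lo = 0
                    for uu in range(lo, u + 1):
                        cand = H[uu, j] - d[uu] - qt
                        if cand > best:
                            best = cand
                            barg = uu
                    tbest[j] = best
                    targ[j] = barg
                else:
                    cand = H[u, j] - d[u] - qt
                    if cand > tbest[j]:
                        tbest[j] = cand
                        targ[j] = u
        # j = 0 column
        open_e0 = H[i - 1, 0] - q
        ext_e0 = E[i - 1, 0]
        if open_e0 >= ext_e0:
            E[i, 0] = open_e0 - e
            ptrE[i, 0] = 0
        else:
            E[i, 0] = ext_e0 - e
            ptrE[i, 0] = 1
        H[i, 0] = E[i, 0]
        ptrH[i, 0] = 1
        intr0 = tbest[0] - a[i]
        if intr0 > H[i, 0]:
            H[i, 0] = intr0
            ptrH[i, 0] = 3
            donor_of[i, 0] = targ[0]
        for j in range(1, m + 1):
            open_e = H[i - 1, j] - q
            ext_e = E[i - 1, j]
            if open_e >= ext_e:
                E[i, j] = open_e - e
                ptrE[i, j] = 0
            else:
                E[i, j] = ext_e - e
                ptrE[i, j] = 1
            open_f = H[i, j - 1] - q
            ext_f = F[i, j - 1]
            if open_f >= ext_f:
                F[i, j] = open_f - e
                ptrF[i, j] = 0
            else:
                F[i, j] = ext_f - e
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + sub[i - 1, j - 1]
            intr = tbest[j] - a[i]
            # preference on ties: diag > intron > E > F
            best = diag
            ptr = 0
            if intr > best:
                best = intr
                ptr = 3
            if E[i, j] > best:
                best = E[i, j]
                ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            H[i, j] = best
            ptrH[i, j] = ptr
            if ptr == 3:
                donor_of[i, j] = targ[j]
    return H, ptrH, ptrE, ptrF, donor_of


def _substitution_matrix(ref: str, query: str, params: AlignParams) -> np.ndarray:
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    qq = np.frombuffer(query.encode(), dtype=np.uint8)
    eq = r[:, None] == qq[None, :]
    return np.where(eq, params.match, params.mismatch).astype(np.float64)


def align(
    ref: str,
    query: str,
    params: AlignParams | None = None,
    donor_scores: dict[int, float] | None = None,
    acceptor_scores: dict[int, float] | None = None,
) -> SplicedAlignment:
    """Global spliced alignment of query against ref with traceback.

    ``donor_scores``/``acceptor_scores`` map reference boundary offsets to
    calibrated splice scores (higher is better); unscored boundaries cost
    ``params.noncanonical_cost``.
    """
    params = params or AlignParams()
    if not ref or not query:
        raise ValueError("ref and query must be non-empty")
    n = len(ref)
    d, a = junction_cost_arrays(n, params, donor_scores, acceptor_scores)
    sub = _substitution_matrix(ref, query, params)
    max_intron = params.max_intron_len if params.max_intron_len is not None else 0
    H, ptrH, ptrE, ptrF, donor_of = _dp_kernel(
        sub, d, a,
        float(params.gap_open), float(params.gap_extend), float(params.intron_open),
        int(params.min_intron_len), int(max_intron),
    )
    # traceback from (n, m)
    i, j = n, len(query)
    ops: list[tuple[str, int]] = []
    junctions: list[tuple[int, int]] = []

    def push(op: str, length: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                push("M")
                i, j = i - 1, j - 1
            elif p == 3:
                u = int(donor_of[i, j])
                junctions.append((u, i))
                push("N", i - u)
                i = u
            elif p == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            push("D")
            ext = ptrE[i, j]
            i -= 1
            if ext == 0:
                state = "H"
        else:  # F
            push("I")
            ext = ptrF[i, j]
            j -= 1
            if ext == 0:
                state = "H"
    ops.reverse()
    junctions.reverse()
    return SplicedAlignment(float(H[n, len(query)]), ops, junctions)


def oracle_align(
    ref: str,
    query: str,
    params: AlignParams | None = None,
    donor_scores: dict[int, float] | None = None,
    acceptor_scores: dict[int, float] | None = None,
    max_ref: int = 12,
    max_query: int = 8,
) -> float:
    """Optimal score by exhaustive search over monotone paths (tiny inputs).

    Independent of the production kernel: memoized recursion over
    (i, j, state) with explicit whole-intron jump moves enumerating every
    donor/acceptor pair, no running-max bookkeeping, no compiled code.
    """
    params = params or AlignParams()
    n, m = len(ref), len(query)
    if n > max_ref or m > max_query:
        raise ValueError(f"oracle limited to ref<={max_ref}, query<={max_query}")
    d, a = junction_cost_arrays(n, params, donor_scores, acceptor_scores)
    q, e, qt = params.gap_open, params.gap_extend, params.intron_open
    lmin = params.min_intron_len
    lmax = params.max_intron_len if params.max_intron_len is not None else n

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score of a full alignment of ref[:i], query[:j] whose last
        # operation left the DP in `state` ('H' = closed, 'E'/'F' = open gap)
        if i == 0 and j == 0:
            return 0.0 if state == "H" else NEG
        out = NEG
        if state == "H":
            if i > 0 and j > 0:
                s = params.match if ref[i - 1] == query[j - 1] else params.mismatch
                out = max(out, best(i - 1, j - 1, "H") + s)
            out = max(out, best(i, j, "E"), best(i, j, "F"))
            # close an intron [u, i): enumerate every admissible donor u
            for u in range(max(0, i - lmax), i - lmin + 1):
                prev = best(u, j, "H")
                if prev > NEG / 2:
                    out = max(out, prev - d[u] - qt - a[i])
            return out
        if state == "E":
            if i > 0:
                out = max(best(i - 1, j, "H") - q - e, best(i - 1, j, "E") - e)
            return out
        if j > 0:
            out = max(best(i, j - 1, "H") - q - e, best(i, j - 1, "F") - e)
        return out

    result = best(n, m, "H")
    best.cache_clear()
    return float(result)


def consensus_preference_demo(
    ref: str,
    query: str,
    params: AlignParams,
    donor_scores: dict[int, float],
    acceptor_scores: dict[int, float],
) -> list[tuple[int, int]]:
    """Junctions chosen when residue-level alignment alone is ambiguous.

    With several junction placements of equal residue score, the DP picks the
    one whose donor+acceptor splice scores are highest (ties resolved to the
    leftmost intron start).
    """
    return align(ref, query, params, donor_scores, acceptor_scores).junctions
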