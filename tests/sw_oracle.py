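"""Independent full-scan Smith-Waterman oracle for alignment tests.

A from-scratch affine-gap local-alignment DP (numba-accelerated) over
the FULL query x consensus matrix, with the same scoring scheme and the
same mask-and-repeat hit enumeration protocol as the package's seeded
aligner — but sharing no code with it.  Small instances only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
NEG = -(10**9)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


@njit(cache=True)
def _sw_fill(q, t):
    n, m = len(q), len(t)
    best = np.zeros((n + 1, m + 1), dtype=np.int32)
    gx = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    gy = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    bi, bj, bscore = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if q[i - 1] >= 4 or t[j - 1] >= 4:
                s = -10_000
            elif q[i - 1] == t[j - 1]:
                s = MATCH
            else:
                s = MISMATCH
            gx[i, j] = max(best[i - 1, j] + GAP_OPEN, gx[i - 1, j] + GAP_EXTEND)
            gy[i, j] = max(best[i, j - 1] + GAP_OPEN, gy[i, j - 1] + GAP_EXTEND)
            h = best[i - 1, j - 1] + s
            v = h
            if gx[i, j] > v:
                v = gx[i, j]
            if gy[i, j] > v:
                v = gy[i, j]
            if v < 0:
                v = 0
            best[i, j] = v
            if v > bscore:
                bscore, bi, bj = v, i, j
    return best, gx, gy, bi, bj, bscore


def _traceback(q, t, best, gx, gy, i, j):
    """Recover aligned blocks from the DP matrices; returns
    (q_start, q_end, t_start, t_end, matches, columns)."""
    qi, tj = i, j
    matches = cols = 0
    state = "H"
    while qi > 0 and tj > 0:
        if state == "H":
            if best[qi, tj] == 0:
                break
            s = MATCH if q[qi - 1] == t[tj - 1] else MISMATCH
            if q[qi - 1] >= 4 or t[tj - 1] >= 4:
                s = -10_000
            if best[qi, tj] == best[qi - 1, tj - 1] + s:
                matches += int(q[qi - 1] == t[tj - 1])
                cols += 1
                qi -= 1
                tj -= 1
            elif best[qi, tj] == gx[qi, tj]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cols += 1
            if gx[qi, tj] == best[qi - 1, tj] + GAP_OPEN:
                state = "H"
            qi -= 1
        else:
            cols += 1
            if gy[qi, tj] == best[qi, tj - 1] + GAP_OPEN:
                state = "H"
            tj -= 1
    return qi, i, tj, j, matches, cols


_RC = str.maketrans("ACGTNX", "TGCANX")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def sw_scan_hits(
    fragment: str,
    consensus_set: dict[str, str],
    min_score: int,
    min_identity: float,
    max_hits: int = 8,
) -> list[tuple]:
    """All non-redundant local hits by full-matrix scan with read masking.

    Returns tuples (read_start, read_end, cons_id, c_start, c_end,
    strand, score) using the same selection and tie-break rules as the
    package aligner: best (score, cons_id, c_start, '+ first', read
    start) first, then the read interval is masked and the scan repeats.
    """
    L = len(fragment)
    masked = list(fragment.upper())
    hits = []
    for _ in range(max_hits):
        cands = []
        fwd = "".join(masked)
        rev = _revcomp(fwd)
        for cid in sorted(consensus_set):
            t_enc = encode(consensus_set[cid])
            for strand, q in (("+", fwd), ("-", rev)):
                q_enc = encode(q)
                best, gx, gy, bi, bj, score = _sw_fill(q_enc, t_enc)
                if score < min_score:
                    continue
                qs, qe, ts, te, m, cols = _traceback(q_enc, t_enc, best, gx, gy, bi, bj)
                if cols == 0 or m / cols < min_identity:
                    continue
                if strand == "+":
                    rs, re = qs, qe
                else:
                    rs, re = L - qe, L - qs
                cands.append((rs, re, cid, ts, te, strand, int(score)))
        if not cands:
            break
        bestc = min(
            cands, key=lambda c: (-c[6], c[2], c[3], 0 if c[5] == "+" else 1, c[0])
        )
        hits.append(bestc)
        for i in range(bestc[0], bestc[1]):
            masked[i] = "X"
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits
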