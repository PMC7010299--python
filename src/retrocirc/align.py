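"""Local alignment of fragments to repeat consensus sequences.

Finds every significant local alignment (both strands) of a fragment
against a consensus set and chains read-adjacent hits into ordered
segment structures — the split-read evidence from which splice classes
and back-splice junctions are called.

Strategy: exact-word seeding -> diagonal clustering into consensus
windows -> affine local alignment of the (mask-updated) fragment against
each window, iterating so that non-redundant hits are enumerated in
score order.  Significance is a BLASTN-style Karlin-Altschul e-value
with database length equal to the total consensus length.  Scoring:
match +1, mismatch -2, gap of length k costs 5 + 2(k-1).

A final rescue pass re-examines uncovered read flanks of at least
``min_word`` nt next to a significant hit: a short back-splice anchor
can be perfectly real yet never e-value-significant on its own, so it is
accepted on exact-match length and identity instead, and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .consensus import RepeatConsensus
from .seq import revcomp

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
_KA_K = 0.621  # tabulated ungapped K for the +1/-2 scheme
_MASK_SCORE = -10_000


@dataclass
class AlignParams:
    min_word: int = 11
    evalue_max: float = 1e-5
    min_identity: float = 0.85
    rescue_word: int = 7
    window_pad: int = 40
    diag_band: int = 25
    max_hits: int = 8


@dataclass
class SegmentHit:
    """One local alignment of a read interval to a consensus interval.

    Read coordinates are always on the fragment as given (plus frame);
    consensus coordinates are always on the consensus plus frame.
    """

    read_id: str
    read_start: int
    read_end: int
    consensus_id: str
    c_start: int
    c_end: int
    strand: str
    score: float
    identity: float
    evalue: float
    rescued: bool = False

    def read_interval_mirrored(self, read_len: int) -> tuple[int, int]:
        return read_len - self.read_end, read_len - self.read_start


@dataclass
class SegmentChain:
    read_id: str
    hits: list[SegmentHit]
    consensus_id: str
    strand: str
    score: float = 0.0
    primary: bool = False


@lru_cache(maxsize=1)
def karlin_lambda() -> float:
    """Ungapped Karlin-Altschul lambda for the scoring scheme under
    uniform base composition: solves 0.25 e^(l*match) + 0.75 e^(l*mismatch) = 1."""
    f = lambda l: 0.25 * math.exp(l * MATCH) + 0.75 * math.exp(l * MISMATCH) - 1.0
    return float(brentq(f, 1e-6, 10.0))


def evalue(score: float, query_len: int, db_len: int) -> float:
    return _KA_K * query_len * db_len * math.exp(-karlin_lambda() * score)


def min_significant_score(query_len: int, db_len: int, evalue_max: float) -> int:
    """Smallest integer score with e-value <= evalue_max."""
    s = math.log(_KA_K * query_len * db_len / evalue_max) / karlin_lambda()
    return max(1, math.ceil(s))


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTNX"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "X" in (a, b):
                m[a, b] = _MASK_SCORE
            elif "N" in (a, b):
                m[a, b] = MISMATCH
            else:
                m[a, b] = MATCH if a == b else MISMATCH
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = m
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


@dataclass
class _Candidate:
    read_start: int
    read_end: int
    consensus_id: str
    c_start: int
    c_end: int
    strand: str
    score: float
    identity: float
    matches: int


class FragmentAligner:
    """Aligns many fragments against a fixed consensus set.

    Builds the word indices once; exposes :meth:`align` per fragment.
    """

    def __init__(
        self,
        consensus_set: dict[str, RepeatConsensus] | list[RepeatConsensus],
        params: AlignParams | None = None,
    ):
        if isinstance(consensus_set, list):
            consensus_set = {c.id: c for c in consensus_set}
        if not consensus_set:
            raise ValueError("empty consensus set")
        self.consensus = dict(sorted(consensus_set.items()))
        self.params = params or AlignParams()
        self.db_len = sum(len(c) for c in self.consensus.values())
        k = self.params.min_word
        self._index = {cid: _kmer_index(c.sequence, k) for cid, c in self.consensus.items()}
        kr = self.params.rescue_word
        self._rescue_index = {
            cid: _kmer_index(c.sequence, kr) for cid, c in self.consensus.items()
        }

    # ------------------------------------------------------------- seeding
    def _windows(
        self, query: str, cons_id: str, word: int, rescue: bool = False
    ) -> list[tuple[int, int]]:
        idx = (self._rescue_index if rescue else self._index)[cons_id]
        cons_len = len(self.consensus[cons_id])
        diags: list[int] = []
        for i in range(len(query) - word + 1):
            w = query[i : i + word]
            if "X" in w:
                continue
            for cpos in idx.get(w, ()):
                diags.append(cpos - i)
        if not diags:
            return []
        diags.sort()
        pad = self.params.window_pad
        qlen = len(query)
        windows: list[tuple[int, int]] = []
        lo = hi = diags[0]
        for d in diags[1:]:
            if d - hi <= self.params.diag_band:
                hi = d
            else:
                windows.append((lo, hi))
                lo = hi = d
        windows.append((lo, hi))
        out = []
        for lo, hi in windows:
            ws = max(0, lo - pad)
            we = min(cons_len, hi + qlen + pad)
            if we > ws:
                out.append((ws, we))
        return _merge_intervals(out)

    # ----------------------------------------------------------- alignment
    def _window_candidates(
        self, masked_fwd: str, masked_rev: str, rescue: bool = False
    ) -> list[_Candidate]:
        aligner = _aligner()
        L = len(masked_fwd)
        cands: list[_Candidate] = []
        word = self.params.rescue_word if rescue else self.params.min_word
        for cid, cons in self.consensus.items():
            for strand, q in (("+", masked_fwd), ("-", masked_rev)):
                if len(q) < word:
                    continue
                for ws, we in self._windows(q, cid, word, rescue=rescue):
                    alns = aligner.align(q, cons.sequence[ws:we])
                    if len(alns) == 0:
                        continue
                    a = alns[0]
                    if a.score <= 0:
                        continue
                    qb, tb = a.aligned
                    qs, qe = int(qb[0][0]), int(qb[-1][1])
                    ts, te = ws + int(tb[0][0]), ws + int(tb[-1][1])
                    matches, cols = _alignment_stats(q, cons.sequence, a.aligned, ws)
                    if strand == "+":
                        rs, re_ = qs, qe
                    else:
                        rs, re_ = L - qe, L - qs
                    cands.append(
                        _Candidate(
                            rs, re_, cid, ts, te, strand,
                            float(a.score), matches / cols if cols else 0.0, matches,
                        )
                    )
        return cands

    def align(self, fragment: str, read_id: str = "read") -> list[SegmentHit]:
        """All non-redundant significant hits of one fragment, sorted by
        read position; see module docstring for the search strategy."""
        p = self.params
        fragment = fragment.upper()
        if len(fragment) < p.min_word:
            return []
        m = len(fragment)
        min_score = min_significant_score(m, self.db_len, p.evalue_max)

        masked = list(fragment)
        hits: list[SegmentHit] = []
        for _ in range(p.max_hits):
            fwd = "".join(masked)
            rev = revcomp(fwd)  # X passes through the complement table unchanged
            cands = [
                c
                for c in self._window_candidates(fwd, rev)
                if c.score >= min_score and c.identity >= p.min_identity
            ]
            if not cands:
                break
            best = min(
                cands,
                key=lambda c: (-c.score, c.consensus_id, c.c_start,
                               0 if c.strand == "+" else 1, c.read_start),
            )
            hits.append(
                SegmentHit(
                    read_id, best.read_start, best.read_end, best.consensus_id,
                    best.c_start, best.c_end, best.strand, best.score,
                    best.identity, evalue(best.score, m, self.db_len),
                )
            )
            for i in range(best.read_start, best.read_end):
                masked[i] = "X"

        if hits:
            hits.extend(self._rescue(fragment, masked, hits, read_id))
        hits.sort(key=lambda h: (h.read_start, h.read_end, h.consensus_id))
        return hits

    def _rescue(
        self, fragment: str, masked: list[str],
        primary: list[SegmentHit], read_id: str,
    ) -> list[SegmentHit]:
        p = self.params
        m = len(fragment)
        out: list[SegmentHit] = []
        for us, ue in _uncovered(masked, p.min_word):
            sub = fragment[us:ue]
            cands = [
                c
                for c in self._window_candidates(sub, revcomp(sub), rescue=True)
                if c.matches >= p.min_word and c.identity >= p.min_identity
            ]
            if not cands:
                continue
            neighbour = _nearest_hit(primary, us, ue)

            def rank(c: _Candidate):
                same_locus = (
                    c.consensus_id == neighbour.consensus_id
                    and c.strand == neighbour.strand
                )
                geometry_ok = same_locus and not (
                    c.c_start + us < neighbour.c_end
                    and neighbour.c_start < c.c_end + us
                )
                return (-c.matches, -c.score, not same_locus, not geometry_ok,
                        c.consensus_id, c.c_start)

            best = min(cands, key=rank)
            out.append(
                SegmentHit(
                    read_id, us + best.read_start, us + best.read_end,
                    best.consensus_id, best.c_start, best.c_end, best.strand,
                    best.score, best.identity,
                    evalue(best.score, m, self.db_len), rescued=True,
                )
            )
        return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    out: list[tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _uncovered(masked: list[str], min_len: int) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, ch in enumerate(masked + ["X"]):
        if ch != "X" and start is None:
            start = i
        elif ch == "X" and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    return out


def _nearest_hit(hits: list[SegmentHit], us: int, ue: int) -> SegmentHit:
    def dist(h: SegmentHit) -> int:
        if h.read_end <= us:
            return us - h.read_end
        if h.read_start >= ue:
            return h.read_start - ue
        return 0

    return min(hits, key=lambda h: (dist(h), -h.score))


def _alignment_stats(query: str, target: str, aligned, t_offset: int) -> tuple[int, int]:
    """(matches, aligned columns incl. gaps) from PairwiseAligner blocks."""
    qb, tb = aligned
    matches = 0
    block_cols = 0
    for (qs, qe), (ts, te) in zip(qb, tb):
        block_cols += qe - qs
        for i in range(qe - qs):
            if query[qs + i] == target[t_offset + ts + i]:
                matches += 1
    q_span = int(qb[-1][1]) - int(qb[0][0])
    t_span = int(tb[-1][1]) - int(tb[0][0])
    block_q = sum(int(e) - int(s) for s, e in qb)
    block_t = sum(int(e) - int(s) for s, e in tb)
    gaps = (q_span - block_q) + (t_span - block_t)
    return matches, block_cols + gaps


def align_fragment(
    fragment: str,
    consensus_set: dict[str, RepeatConsensus] | list[RepeatConsensus],
    read_id: str = "read",
    params: AlignParams | None = None,
) -> list[SegmentHit]:
    """One-shot convenience wrapper around :class:`FragmentAligner`."""
    return FragmentAligner(consensus_set, params).align(fragment, read_id)


# ------------------------------------------------------------------ chains

def chain_segments(
    hits: list[SegmentHit],
    max_read_gap: int = 10,
    max_read_overlap: int = 10,
) -> list[SegmentChain]:
    """Greedily chain read-adjacent hits on one consensus and strand.

    Hits whose read intervals are separated by at most ``max_read_gap``
    or overlap by at most ``max_read_overlap`` join one chain; leftovers
    become singleton chains.  Chains are scored by summed hit scores and
    the best-scoring chain is marked primary.
    """
    if not hits:
        return []
    read_id = hits[0].read_id
    groups: dict[tuple[str, str], list[SegmentHit]] = {}
    for h in hits:
        groups.setdefault((h.consensus_id, h.strand), []).append(h)

    chains: list[SegmentChain] = []
    for (cid, strand), hs in sorted(groups.items()):
        hs = sorted(hs, key=lambda h: (h.read_start, h.read_end))
        current = [hs[0]]
        for h in hs[1:]:
            prev = current[-1]
            gap = h.read_start - prev.read_end
            if -max_read_overlap <= gap <= max_read_gap:
                current.append(h)
            else:
                chains.append(SegmentChain(read_id, current, cid, strand))
                current = [h]
        chains.append(SegmentChain(read_id, current, cid, strand))

    for c in chains:
        c.score = sum(h.score for h in c.hits)
    best = min(
        chains,
        key=lambda c: (-c.score, c.consensus_id, c.strand, c.hits[0].read_start),
    )
    best.primary = True
    return chains


def primary_chain(chains: list[SegmentChain]) -> SegmentChain | None:
    for c in chains:
        if c.primary:
            return c
    return None


# ---------------------------------------------------------------------- IO

HITS_TSV_HEADER = (
    "read_id\tread_start\tread_end\tconsensus_id\tc_start\tc_end\t"
    "strand\tscore\tidentity\tevalue\trescued"
)


def write_hits_tsv(hits: list[SegmentHit], path) -> None:
    """Hits as TSV, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(HITS_TSV_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.read_start + 1}\t{h.read_end}\t"
                f"{h.consensus_id}\t{h.c_start + 1}\t{h.c_end}\t{h.strand}\t"
                f"{h.score:g}\t{h.identity:.4f}\t{h.evalue:.3g}\t"
                f"{int(h.rescued)}\n"
            )


def read_hits_tsv(path) -> list[SegmentHit]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                SegmentHit(
                    f[0], int(f[1]) - 1, int(f[2]), f[3], int(f[4]) - 1,
                    int(f[5]), f[6], float(f[7]), float(f[8]), float(f[9]),
                    bool(int(f[10])),
                )
            )
    return out
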