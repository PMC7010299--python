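"""Read taxonomy and back-splice junction extraction.

Every fragment gets exactly one category, the partition used for
repeat-derived RIP/input reads: LTR (touches a long terminal repeat),
NONSPLICED (one internal consensus locus), NORMAL_SPLICED (two collinear
loci skipping an internal gap), BACK_SPLICED (downstream locus followed
by an upstream locus on the read — the circular-RNA signature),
AMBIGUOUS, or UNALIGNED.  LTR takes precedence so the taxonomy stays a
partition.  For a back-splice, the junction is (acceptor = upstream 5'
start, donor = downstream 3' end) on the consensus plus frame, leftmost-
canonicalized when flank microhomology makes the breakpoint ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import SegmentChain, SegmentHit, chain_segments, primary_chain
from .consensus import RepeatConsensus
from .seq import revcomp

CATEGORIES = (
    "LTR", "NONSPLICED", "NORMAL_SPLICED", "BACK_SPLICED", "UNALIGNED",
    "AMBIGUOUS",
)


@dataclass
class ReadClassification:
    read_id: str
    category: str
    consensus_id: str | None = None
    junction: tuple[int, int, str] | None = None  # (acceptor, donor, strand)


@dataclass
class BackspliceJunction:
    consensus_id: str
    acceptor: int  # 5' start of the upstream (acceptor-side) segment
    donor: int  # 3' end (half-open) of the downstream segment
    strand: str
    support: int = 1
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.consensus_id, self.acceptor, self.donor, self.strand)


def canonicalize_junction(
    cons_seq: str, acceptor: int, donor: int
) -> tuple[int, int]:
    """Leftmost-shift a back-splice junction through flank microhomology.

    The circle fuses cons[donor-1] -> cons[acceptor]; placements related
    by cons[acceptor-1] == cons[donor-1] describe the same circle, so all
    shift-equivalent placements map to the leftmost one.
    """
    while acceptor > 0 and cons_seq[acceptor - 1] == cons_seq[donor - 1]:
        acceptor -= 1
        donor -= 1
    return acceptor, donor


from dataclasses import dataclass as _dataclass


@_dataclass
class _Entry:
    """One transcript-frame segment: an aligned hit or a gap-filled
    virtual placement (hit is None)."""

    span: tuple[int, int]
    c_start: int
    c_end: int
    hit: SegmentHit | None


def _approx_find(haystack: str, needle: str, max_mm: int) -> list[tuple[int, int]]:
    """(position, mismatches) of every placement with <= max_mm substitutions."""
    import numpy as np

    n, k = len(haystack), len(needle)
    if k == 0 or k > n:
        return []
    hay = np.frombuffer(haystack.encode(), dtype="S1")
    ndl = np.frombuffer(needle.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(hay, k)
    mm = (windows != ndl).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(mm <= max_mm)]


def _fill_gaps(
    entries: list[_Entry],
    frame_read: str,
    cons_seq: str,
    min_fill: int = 6,
    max_fill: int = 18,
) -> list[_Entry]:
    """Place short unaligned read gaps between segments onto the consensus.

    A retained acceptor-side piece shorter than the aligner word (e.g. the
    8-nt remnant in the shortest partial-retention circle) never aligns on
    its own; an exact (or 1-mismatch, for pieces >= 8 nt) search of the
    gap string — or of its prefixes/suffixes, since sequencing errors can
    erode neighbouring segment boundaries into the gap — recovers its
    placement when a geometry-consistent one exists.
    """
    out = list(entries)
    # A short piece is only placeable within the neighbourhood of the
    # chain it connects; searching the whole consensus invites spurious
    # exact matches that outrank the true (possibly error-bearing) one.
    lo = max(0, min(e.c_start for e in entries) - 1000)
    hi = min(len(cons_seq), max(e.c_end for e in entries) + 1000)
    hay = cons_seq[lo:hi]
    inserted = []
    for a, b in zip(entries, entries[1:]):
        gs, ge = a.span[1], b.span[0]
        g = ge - gs
        if not (min_fill <= g <= max_fill):
            continue
        gap_str = frame_read[gs:ge]
        pieces = [(gs, ge)]  # full gap, then eroded-boundary variants
        for k in range(min(g, 10), min_fill - 1, -1):
            if k < g:
                pieces.append((gs, gs + k))
                pieces.append((ge - k, ge))
        best = None
        for ps, pe in pieces:
            piece = frame_read[ps:pe]
            max_mm = 1 if len(piece) >= 8 else 0
            for pos, mm in _approx_find(hay, piece, max_mm):
                pos += lo
                trial = _Entry((ps, pe), pos, pos + len(piece), None)
                if not (_consistent(a, trial) and _consistent(trial, b)):
                    continue
                dist = min(abs(pos - a.c_end), abs(b.c_start - (pos + len(piece))))
                key = (mm, -(pe - ps), dist, pos)
                if best is None or key < best[0]:
                    best = (key, trial)
        if best is not None:
            inserted.append(best[1])
    if inserted:
        out.extend(inserted)
        out.sort(key=lambda e: e.span)
    return out


def _consistent(a: _Entry, b: _Entry) -> bool:
    return b.c_start > a.c_end or b.c_start < a.c_start


def classify_fragment(
    chain: SegmentChain | None,
    cons: RepeatConsensus | None,
    fragment: str | None = None,
    min_ltr_overlap: int = 20,
    min_word: int = 11,
    other_family_hit: bool = False,
) -> ReadClassification:
    """Classify one fragment from its primary chain.

    ``fragment`` (the read sequence) enables breakpoint refinement under
    sequencing error; without it the raw segment boundaries are used.
    """
    if chain is None or not chain.hits:
        return ReadClassification("", "UNALIGNED")
    read_id = chain.read_id
    if other_family_hit:
        return ReadClassification(read_id, "AMBIGUOUS", chain.consensus_id)

    if cons is not None:
        for h in chain.hits:
            for ltr in cons.ltr_regions():
                if ltr.overlap(h.c_start, h.c_end) >= min_ltr_overlap:
                    return ReadClassification(read_id, "LTR", chain.consensus_id)

    hits = chain.hits
    if len(hits) == 1:
        return ReadClassification(read_id, "NONSPLICED", chain.consensus_id)

    # Work in the plus frame of the aligned strand: for minus-strand
    # chains, mirror read intervals so segment order reads 5'->3' along
    # the transcript, making classification strand-invariant.
    if chain.strand == "-":
        L = len(fragment) if fragment is not None else max(h.read_end for h in hits)
        frame_read = revcomp(fragment) if fragment is not None else None
        entries = sorted(
            (_Entry(h.read_interval_mirrored(L), h.c_start, h.c_end, h) for h in hits),
            key=lambda e: e.span,
        )
    else:
        frame_read = fragment
        entries = sorted(
            (_Entry((h.read_start, h.read_end), h.c_start, h.c_end, h) for h in hits),
            key=lambda e: e.span,
        )

    if frame_read is not None and cons is not None:
        entries = _fill_gaps(entries, frame_read, cons.sequence)

    # Consecutive-pair geometry along the transcript: a read from a
    # circle may cross both the back-splice point and a forward skip
    # joint, giving >=3 segments; exactly one back-splice pair with no
    # conflicting pair is still an unambiguous back-spliced read.
    pairs = []
    for a, b in zip(entries, entries[1:]):
        if b.c_start > a.c_end:
            pairs.append(("FWD", a, b))
        elif b.c_start < a.c_start:
            pairs.append(("BACK", a, b))
        else:
            pairs.append(("CONFLICT", a, b))
    kinds = [k for k, _, _ in pairs]
    if "CONFLICT" in kinds or kinds.count("BACK") > 1:
        return ReadClassification(read_id, "AMBIGUOUS", chain.consensus_id)

    if kinds.count("BACK") == 1:
        category = "BACK_SPLICED"
        _, first, second = next(p for p in pairs if p[0] == "BACK")
    else:
        category = "NORMAL_SPLICED"
        _, first, second = pairs[0]

    donor, acceptor = first.c_end, second.c_start
    if frame_read is not None and cons is not None:
        donor, acceptor = _refine_breakpoint(
            frame_read, cons.sequence, first, second, min_word
        )
    if category == "BACK_SPLICED" and cons is not None:
        acceptor, donor = canonicalize_junction(cons.sequence, acceptor, donor)
    return ReadClassification(
        read_id, category, chain.consensus_id, (acceptor, donor, chain.strand)
    )


def _refine_breakpoint(
    read: str,
    cons_seq: str,
    first: _Entry,
    second: _Entry,
    min_word: int,
    shift: int = 6,
    window: int = 30,
) -> tuple[int, int]:
    """Refine (donor, acceptor) by scanning the split position.

    A sequencing error adjacent to the splice point truncates or extends
    local alignments and shifts the raw boundaries; scanning candidate
    read split positions p and counting matches on each side over a
    fixed span recovers the true breakpoint.  Assumes gapless segments
    (the default error model); gapped hits fall back to the raw
    boundaries.  Works identically for aligned hits and gap-filled
    virtual placements.
    """
    (s1, e1), (s2, e2) = first.span, second.span
    # Per-segment read->consensus offsets only hold for gapless alignments.
    if (e1 - s1) != (first.c_end - first.c_start) or (e2 - s2) != (
        second.c_end - second.c_start
    ):
        return first.c_end, second.c_start
    # In the working frame (mirrored for minus-strand chains) a gapless
    # hit ascends the consensus with a constant offset.
    off1 = first.c_start - s1
    off2 = second.c_start - s2

    def donor_at(p: int) -> int:
        return p + off1

    def acceptor_at(p: int) -> int:
        return p + off2

    # Keep a minimal anchor inside each segment; virtual placements are
    # exact, so a 3-nt residual suffices there.
    anchor1 = min_word if first.hit is not None else 3
    anchor2 = min_word if second.hit is not None else 3
    p_lo = max(min(e1, s2) - shift, s1 + anchor1, 1)
    p_hi = min(max(e1, s2) + shift, e2 - anchor2, len(read) - 1)
    if p_hi < p_lo:
        return first.c_end, second.c_start

    # Score every candidate split over ONE fixed read span so candidates
    # are comparable: matches under the donor-side mapping left of p plus
    # matches under the acceptor-side mapping right of p.
    q_lo = max(s1, p_lo - window, -min(off1, off2))
    q_hi = min(e2, p_hi + window, len(cons_seq) - max(off1, off2))
    if q_hi <= q_lo:
        return first.c_end, second.c_start
    m1 = [0] * (q_hi - q_lo + 1)  # prefix sums of donor-side matches
    m2 = [0] * (q_hi - q_lo + 1)
    for j in range(q_lo, q_hi):
        i = j - q_lo
        m1[i + 1] = m1[i] + (read[j] == cons_seq[j + off1])
        m2[i + 1] = m2[i] + (read[j] == cons_seq[j + off2])

    best = None  # (-score, |p - raw boundary|, p)
    for p in range(p_lo, p_hi + 1):
        d, a = donor_at(p), acceptor_at(p)
        if not (0 < d <= len(cons_seq)) or not (0 <= a < len(cons_seq)):
            continue
        i = p - q_lo
        score = m1[i] + (m2[-1] - m2[i])
        key = (-score, abs(p - e1), p)
        if best is None or key < best[0]:
            best = (key, p)
    if best is None:
        return first.c_end, second.c_start
    return donor_at(best[1]), acceptor_at(best[1])


def classify_read(
    hits: list[SegmentHit],
    consensus_set: dict[str, RepeatConsensus],
    fragment: str | None = None,
    max_read_gap: int = 10,
    max_read_overlap: int = 10,
    min_ltr_overlap: int = 20,
    min_word: int = 11,
) -> ReadClassification:
    """Pipeline-level classification of one fragment from its hit list.

    Builds chains, picks the primary, and applies the two-family rule: a
    significant (non-rescued) hit on a second consensus family outside
    the primary chain's read span makes the fragment AMBIGUOUS rather
    than an inter-element fusion call.
    """
    if not hits:
        return ReadClassification("", "UNALIGNED")
    chains = chain_segments(hits, max_read_gap, max_read_overlap)
    best = primary_chain(chains)
    if best is not None:
        best = _stitch_chains(best, chains, max_read_gap + 8)
    other_family = False
    if best is not None:
        covered = [(h.read_start, h.read_end) for h in best.hits]
        for h in hits:
            if h.consensus_id == best.consensus_id or h.rescued:
                continue
            span = h.read_end - h.read_start
            overlap = sum(
                max(0, min(h.read_end, e) - max(h.read_start, s))
                for s, e in covered
            )
            if span - overlap >= min_word:
                other_family = True
                break
    cons = consensus_set.get(best.consensus_id) if best else None
    rc = classify_fragment(
        best, cons, fragment, min_ltr_overlap, min_word,
        other_family_hit=other_family,
    )
    return rc


def _stitch_chains(
    best: SegmentChain, chains: list[SegmentChain], max_stitch_gap: int
) -> SegmentChain:
    """Merge same-locus chains separated by a fillable read gap.

    A retained piece shorter than the aligner word, possibly widened by
    error-eroded segment boundaries, leaves an unaligned gap larger than
    the chaining tolerance; the gap-placement step can still resolve it,
    so such chains are reunited before classification.
    """
    hits = list(best.hits)
    pool = [
        c for c in chains
        if c is not best
        and c.consensus_id == best.consensus_id
        and c.strand == best.strand
    ]
    changed = True
    while changed:
        changed = False
        lo = min(h.read_start for h in hits)
        hi = max(h.read_end for h in hits)
        for c in list(pool):
            c_lo = min(h.read_start for h in c.hits)
            c_hi = max(h.read_end for h in c.hits)
            gap = max(lo - c_hi, c_lo - hi)
            if gap <= max_stitch_gap:
                hits.extend(c.hits)
                pool.remove(c)
                changed = True
    if len(hits) == len(best.hits):
        return best
    hits.sort(key=lambda h: (h.read_start, h.read_end))
    return SegmentChain(
        best.read_id, hits, best.consensus_id, best.strand,
        score=sum(h.score for h in hits), primary=True,
    )


def call_junctions(
    classifications: list[ReadClassification],
) -> list[BackspliceJunction]:
    """One canonicalized junction call per BACK_SPLICED read
    (pre-clustering); minus-strand chains are already in the plus frame."""
    out = []
    for rc in classifications:
        if rc.category != "BACK_SPLICED":
            continue
        acceptor, donor, strand = rc.junction
        out.append(
            BackspliceJunction(
                rc.consensus_id, acceptor, donor, strand,
                support=1, read_ids=[rc.read_id],
            )
        )
    return out


# ---------------------------------------------------------------------- IO

CLASS_TSV_HEADER = "read_id\tcategory\tconsensus_id\tacceptor\tdonor\tstrand"


def write_classifications_tsv(rows: list[ReadClassification], path) -> None:
    """Classification TSV, junction coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(CLASS_TSV_HEADER + "\n")
        for rc in rows:
            if rc.junction:
                a, d, s = rc.junction
                j = f"{a + 1}\t{d}\t{s}"
            else:
                j = ".\t.\t."
            fh.write(
                f"{rc.read_id}\t{rc.category}\t{rc.consensus_id or '.'}\t{j}\n"
            )


def read_classifications_tsv(path) -> list[ReadClassification]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            junction = None
            if f[3] != ".":
                junction = (int(f[3]) - 1, int(f[4]), f[5])
            out.append(
                ReadClassification(
                    f[0], f[1], None if f[2] == "." else f[2], junction
                )
            )
    return out
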