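"""Circular-isoform reconstruction and verification.

Clusters per-read junction calls, reconstructs circular isoforms from
retention patterns (full retention, skipped internal intervals, partial
acceptor-side retention), verifies circularity by in-silico divergent
PCR, tests whether the fused junction sequence exists in genomic DNA,
and designs junction-spanning target sequences.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .align import AlignParams, FragmentAligner
from .classify import BackspliceJunction
from .consensus import RepeatConsensus
from .seq import check_alphabet, revcomp


# ------------------------------------------------------------- clustering

def cluster_junctions(
    calls: list[BackspliceJunction], tolerance: int = 0
) -> list[BackspliceJunction]:
    """Merge junction calls agreeing within ``tolerance`` nt.

    Calls must already be canonicalized.  Single-linkage on the Chebyshev
    distance of (acceptor, donor) within one (consensus, strand) group;
    cluster coordinates are the support-weighted mode.  Clusters are
    sorted by support descending, then coordinates.
    """
    groups: dict[tuple[str, str], list[BackspliceJunction]] = {}
    for c in calls:
        groups.setdefault((c.consensus_id, c.strand), []).append(c)

    clusters: list[BackspliceJunction] = []
    for (cid, strand), members in sorted(groups.items()):
        members = sorted(members, key=lambda j: (j.acceptor, j.donor))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if (
                    abs(a.acceptor - b.acceptor) <= tolerance
                    and abs(a.donor - b.donor) <= tolerance
                ):
                    parent[find(i)] = find(j)
        by_root: dict[int, list[BackspliceJunction]] = {}
        for i, m in enumerate(members):
            by_root.setdefault(find(i), []).append(m)
        for group in by_root.values():
            coords = Counter((m.acceptor, m.donor) for m in group)
            top = max(coords.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
            acceptor, donor = top[0]
            read_ids = [r for m in group for r in m.read_ids]
            clusters.append(
                BackspliceJunction(
                    cid, acceptor, donor, strand, support=len(group),
                    read_ids=read_ids,
                )
            )
    clusters.sort(key=lambda c: (-c.support, c.consensus_id, c.acceptor, c.donor))
    return clusters


# ------------------------------------------------------------- isoforms

@dataclass
class RetentionPattern:
    """Which parts of [acceptor, donor) survive in one circular isoform.

    ``skipped``: internal consensus intervals removed (e.g. the 253-nt
    segment for the 354-nt circle).  ``acceptor_keep``: if set, only the
    first k nt of the acceptor-side region (adjacent to the junction)
    are retained — the 277–296-nt partial-retention class.
    """

    name: str = "full"
    skipped: list[tuple[int, int]] = field(default_factory=list)
    acceptor_keep: int | None = None


@dataclass
class CircularIsoform:
    consensus_id: str
    junction: tuple[int, int, str]  # (acceptor, donor, strand)
    segments: list[tuple[int, int]]
    sequence: str  # canonical rotation: starts at the acceptor
    name: str = ""
    support: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def reconstruct_isoforms(
    junction: BackspliceJunction,
    cons: RepeatConsensus,
    patterns: list[RetentionPattern] | None = None,
) -> list[CircularIsoform]:
    """Build one circular isoform per retention pattern.

    Full retention gives a circle of length donor - acceptor; skipping an
    internal interval removes its length; partial retention keeps only
    the first k nt of the acceptor-side region.
    """
    a, d = junction.acceptor, junction.donor
    if not (0 <= a < d <= len(cons)):
        raise ValueError(f"junction ({a},{d}) outside consensus {cons.id}")
    patterns = patterns or [RetentionPattern("full")]
    out = []
    for pat in patterns:
        for s, e in pat.skipped:
            if not (a <= s < e <= d):
                raise ValueError(
                    f"retention interval [{s},{e}) outside junction span "
                    f"[{a},{d})"
                )
        kept = _subtract_intervals((a, d), sorted(pat.skipped))
        if pat.acceptor_keep is not None:
            k = pat.acceptor_keep
            if k < 0:
                raise ValueError("acceptor_keep must be >= 0")
            first = kept[0]
            if first[0] != a:
                raise ValueError("first retained interval must start at acceptor")
            kept[0] = (a, min(a + k, first[1]))
            kept = [iv for iv in kept if iv[1] > iv[0]]
        seq = "".join(cons.sequence[s:e] for s, e in kept)
        if junction.strand == "-":
            seq = revcomp(seq)
        out.append(
            CircularIsoform(
                cons.id, (a, d, junction.strand), kept, seq,
                name=pat.name, support=junction.support,
            )
        )
    return out


def _subtract_intervals(
    span: tuple[int, int], skipped: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    a, d = span
    kept = []
    pos = a
    for s, e in skipped:
        if s < pos:
            raise ValueError("skipped intervals overlap")
        if s > pos:
            kept.append((pos, s))
        pos = e
    if pos < d:
        kept.append((pos, d))
    if not kept:
        raise ValueError("retention pattern removes the whole circle")
    return kept


def circular_sequence(isoform: CircularIsoform) -> str:
    """Circle string in canonical rotation (starting at the acceptor;
    minus-strand isoforms are the reverse complement of the plus circle)."""
    return isoform.sequence


def infer_retention_patterns(
    junction: BackspliceJunction,
    normal_splice_junctions: list[BackspliceJunction] | list[tuple[int, int]],
) -> list[RetentionPattern]:
    """Retention patterns evidenced by forward-splice calls.

    A NORMAL_SPLICED junction (donor', acceptor') with
    acceptor <= donor' < acceptor' <= donor marks an internal interval
    [donor', acceptor') skipped in some molecules: full retention plus
    one pattern per distinct evidenced skip.
    """
    a, d = junction.acceptor, junction.donor
    patterns = [RetentionPattern("full")]
    seen = set()
    for ns in normal_splice_junctions:
        if isinstance(ns, BackspliceJunction):
            dprime, aprime = ns.donor, ns.acceptor  # forward splice: donor < acceptor
        else:
            aprime, dprime = ns  # stored as (acceptor, donor)
            dprime, aprime = min(aprime, dprime), max(aprime, dprime)
        if not (a <= dprime < aprime <= d) or (dprime, aprime) in seen:
            continue
        seen.add((dprime, aprime))
        patterns.append(
            RetentionPattern(f"skip_{dprime + 1}_{aprime}", [(dprime, aprime)])
        )
    return patterns


# --------------------------------------------------------- divergent PCR

def divergent_pcr(
    circle: str,
    fwd_primer: str,
    rev_primer: str,
    max_product: int = 1000,
    circular: bool = True,
) -> str | None:
    """In-silico PCR on a circular (or linear) template.

    Searches the doubled circle string for a forward-primer site followed
    by the reverse complement of the reverse primer within
    ``max_product``; a primer pair divergent on the linear sequence can
    only amplify across the junction of the circular template, so a
    product on the circle with none on the linear form is the
    circularity diagnostic.  Exact primer matching by default; returns
    the shortest (then leftmost) amplicon, or None.
    """
    for p in (fwd_primer, rev_primer):
        if len(p) < 15:
            raise ValueError("primers must be >= 15 nt")
        check_alphabet(p, "ACGT")
    space = circle + circle if circular else circle
    rev_site = revcomp(rev_primer)
    products = []
    start = space.find(fwd_primer)
    while start != -1:
        if circular and start >= len(circle):
            break
        j = space.find(rev_site, start)
        while j != -1:
            end = j + len(rev_site)
            length = end - start
            if length > max_product:
                break
            if not circular or length <= len(circle):
                products.append((length, start, space[start:end]))
            j = space.find(rev_site, j + 1)
        start = space.find(fwd_primer, start + 1)
    if not products:
        return None
    products.sort(key=lambda t: (t[0], t[1]))
    return products[0][2]


def pick_divergent_primers(
    circle: str, primer_len: int = 20, offset: int = 40
) -> tuple[str, str]:
    """Primers divergent on the linear form: forward ending ``offset`` nt
    before the junction point (circle end), reverse complementary to the
    first region after it."""
    L = len(circle)
    if L < 2 * offset + 2 * primer_len:
        offset = max(1, (L - 2 * primer_len) // 4)
    fwd = circle[L - offset - primer_len : L - offset]
    rev = revcomp(circle[offset : offset + primer_len])
    return fwd, rev


# ------------------------------------------------------- genomic origin

@dataclass
class GenomicOriginReport:
    junction_id: str
    assumed_junction_sequence: str
    fusion_point: int
    n_reads_checked: int
    n_junction_covering: int
    verdict: str  # NO_GENOMIC_COPY | GENOMIC_COPY_SUSPECTED
    covering_read_ids: list[str] = field(default_factory=list)


def assumed_junction_sequence(
    junction: BackspliceJunction, cons: RepeatConsensus, flank: int = 177
) -> str:
    """The junction DNA that WOULD exist if the back-spliced sequence had
    a genomic copy: ``flank`` nt upstream of the donor fused to ``flank``
    nt downstream of the acceptor (default 177/177 -> ~354 nt)."""
    a, d = junction.acceptor, junction.donor
    if d - flank < 0 or a + flank > len(cons):
        raise ValueError("flank exceeds available consensus sequence")
    return cons.sequence[d - flank : d] + cons.sequence[a : a + flank]


def genomic_origin_test(
    junction: BackspliceJunction,
    cons: RepeatConsensus,
    dna_reads: list[tuple[str, str]],
    flank: int = 177,
    min_overhang: int = 10,
    max_residual: int = 1,
    align_params: AlignParams | None = None,
) -> GenomicOriginReport:
    """Does the fused junction sequence exist in genomic DNA?

    Aligns DNA reads to the assumed junction sequence and counts reads
    covering the fusion point contiguously with at least ``min_overhang``
    matched nt on each side.  A count at or below ``max_residual``
    (default 1, tolerating a single residual read, e.g. from
    chromatin-binding RNA carried through a ChIP library) returns
    NO_GENOMIC_COPY.
    """
    if flank < min_overhang:
        raise ValueError("flank must be >= min_overhang")
    template = assumed_junction_sequence(junction, cons, flank)
    ref = RepeatConsensus("assumed_junction", template, [])
    aligner = FragmentAligner({ref.id: ref}, align_params)
    fusion = flank
    covering: list[str] = []
    for read_id, seq in dna_reads:
        for h in aligner.align(seq, read_id):
            left = min(h.c_end, fusion) - h.c_start
            right = h.c_end - max(h.c_start, fusion)
            if left >= min_overhang and right >= min_overhang:
                covering.append(read_id)
                break
    n_cov = len(covering)
    verdict = "NO_GENOMIC_COPY" if n_cov <= max_residual else "GENOMIC_COPY_SUSPECTED"
    jid = f"{junction.consensus_id}:{junction.acceptor + 1}-{junction.donor}:{junction.strand}"
    return GenomicOriginReport(
        jid, template, fusion, len(dna_reads), n_cov, verdict, covering
    )


# ------------------------------------------------------- sequence design

def design_junction_target(
    junction: BackspliceJunction,
    cons: RepeatConsensus,
    upstream_len: int = 204,
    acceptor_region_end: int | None = None,
) -> str:
    """Junction-spanning RNAi/probe target: the last ``upstream_len`` nt
    before the donor plus the entire acceptor-side region (by default the
    region starting at the acceptor, e.g. 204 + 85 = 289 nt)."""
    if upstream_len < 0:
        raise ValueError("upstream_len must be >= 0")
    a, d = junction.acceptor, junction.donor
    if d - upstream_len < 0:
        raise ValueError("upstream_len exceeds donor-side sequence")
    if acceptor_region_end is None:
        region = next((r for r in cons.regions if r.start == a), None)
        if region is None:
            raise ValueError(
                "no annotated region starts at the acceptor; pass "
                "acceptor_region_end explicitly"
            )
        acceptor_region_end = region.end
    return cons.sequence[d - upstream_len : d] + cons.sequence[a:acceptor_region_end]


def insert_restriction_sites(
    template: str, insertions: list[tuple[int, str]]
) -> str:
    """Insert marker sites (e.g. BamHI/EcoRI tags on an in-vitro
    transcription template) at positions given on the original template;
    edits are applied right-to-left so positions never shift."""
    positions = [p for p, _ in insertions]
    if len(set(positions)) != len(positions):
        raise ValueError("overlapping insertion positions")
    out = template
    for pos, site in sorted(insertions, key=lambda t: -t[0]):
        if not (0 <= pos <= len(template)):
            raise ValueError(f"insertion position {pos} outside template")
        check_alphabet(site, "ACGTN")
        out = out[:pos] + site + out[pos:]
    return out


# ---------------------------------------------------------------------- IO

def write_junctions_tsv(junctions: list[BackspliceJunction], path) -> None:
    with open(path, "w") as fh:
        fh.write("consensus_id\tacceptor\tdonor\tstrand\tsupport\tread_ids\n")
        for j in junctions:
            fh.write(
                f"{j.consensus_id}\t{j.acceptor + 1}\t{j.donor}\t{j.strand}\t"
                f"{j.support}\t{','.join(j.read_ids)}\n"
            )


def read_junctions_tsv(path) -> list[BackspliceJunction]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                BackspliceJunction(
                    f[0], int(f[1]) - 1, int(f[2]), f[3], int(f[4]),
                    f[5].split(",") if f[5] else [],
                )
            )
    return out


def write_isoforms(isoforms: list[CircularIsoform], fasta_path, json_path) -> None:
    with open(fasta_path, "w") as fh:
        for iso in isoforms:
            a, d, s = iso.junction
            fh.write(
                f">{iso.consensus_id}|{iso.name}|{a + 1}-{d}|{s}|"
                f"len={iso.length}\n{iso.sequence}\n"
            )
    payload = [
        {
            "consensus_id": iso.consensus_id,
            "name": iso.name,
            "junction": {"acceptor": iso.junction[0] + 1, "donor": iso.junction[1],
                          "strand": iso.junction[2]},
            "segments": [[s + 1, e] for s, e in iso.segments],
            "length": iso.length,
            "support": iso.support,
        }
        for iso in isoforms
    ]
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
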