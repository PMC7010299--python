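"""Synthetic-data generator emulating the CRM1 back-splicing system.

Generates, with full ground truth: a CRM1-like consensus element whose
donor region is an 85-nt, a 253-nt and a 269-nt segment in that order
(607 nt total); a background genome carrying full and fragmented element
copies; linear and circular transcript pools sharing one back-splice
site (the 354-, 607- and 277–296-nt circle classes); and error-bearing
paired-end Sanger-FASTQ reads for RIP, input and DNA compartments.

All randomness flows from a single integer seed per call; identical
seeds and parameters give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus import Region, RepeatConsensus, write_gff3
from .seq import mutate, random_seq, revcomp

logger = logging.getLogger(__name__)

# Default region lengths for the CRM1-like element.  The donor region
# (85+253+269 = 607 nt) sits between the protease-coding region and an
# intergenic spacer; the two LTRs are identical copies, as in a real
# LTR retrotransposon.
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "LTR5": 450,
    "GAG": 500,
    "PR": 250,
    "RT": 500,
    "RNH": 250,
    "INT": 350,
    "REGION85": 85,
    "REGION253": 253,
    "REGION269": 269,
    "OTHER": 300,
    "LTR3": 450,
}


def build_consensus(
    seed: int,
    region_lengths: Mapping[str, int] | None = None,
    element_id: str = "CRM1",
) -> RepeatConsensus:
    """Build a random consensus element with the given region layout.

    Regions are laid out in ``DEFAULT_REGION_LENGTHS`` order; LTR3 is a
    copy of LTR5.  The two bases flanking the back-splice site are
    deterministically adjusted so the junction has no flank microhomology
    and therefore a unique canonical placement.
    """
    lengths = dict(DEFAULT_REGION_LENGTHS)
    if region_lengths:
        unknown = set(region_lengths) - set(lengths)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        lengths.update(region_lengths)
    if any(v < 0 for v in lengths.values()):
        raise ValueError("region lengths must be >= 0")

    rng = np.random.default_rng(seed)
    parts: dict[str, str] = {}
    for label, n in lengths.items():
        if label == "LTR3":
            parts[label] = parts["LTR5"]
        else:
            parts[label] = random_seq(rng, n)

    seq = []
    regions = []
    pos = 0
    for label, n in lengths.items():
        if n > 0:
            regions.append(Region(label, pos, pos + n))
            seq.append(parts[label])
            pos += n
    cons = RepeatConsensus(element_id, "".join(seq), regions)

    if cons.has_region("REGION85") and cons.has_region("REGION269"):
        cons.sequence = _break_junction_microhomology(
            cons.sequence, cons.backsplice_acceptor, cons.backsplice_donor
        )
    return cons


def _break_junction_microhomology(seq: str, acceptor: int, donor: int) -> str:
    """Edit <=2 bases so the back-splice junction has a unique placement.

    The circle fuses seq[donor-1] -> seq[acceptor]; the breakpoint can
    shift left iff seq[acceptor-1] == seq[donor-1] and right iff
    seq[acceptor] == seq[donor].  Pick replacement bases that break both.
    """
    s = list(seq)

    def other(*avoid: str) -> str:
        return next(b for b in "ACGT" if b not in avoid)

    if acceptor >= 1 and s[acceptor - 1] == s[donor - 1]:
        s[donor - 1] = other(s[acceptor - 1], s[donor] if donor < len(s) else "")
    if donor < len(s) and s[acceptor] == s[donor]:
        s[donor] = other(s[acceptor], s[donor - 1])
    return "".join(s)


# ------------------------------------------------------------------ genome

def plant_elements(
    genome_len: int,
    cons: RepeatConsensus,
    n_full: int,
    n_fragmented: int,
    seed: int,
    divergence: float = 0.02,
    min_fragment: int = 100,
    extra_inserts: Sequence[tuple[str, str]] = (),
) -> tuple[str, list[dict]]:
    """Plant element copies into a random background genome.

    Full copies are the whole consensus; fragmented copies are random
    consensus sub-intervals (emulating truncated insertions).  Copies are
    mutated at the ``divergence`` substitution rate, inserted on a random
    strand at non-overlapping positions, and every insertion is recorded
    as a GFF3-style annotation dict.  ``extra_inserts`` plants arbitrary
    labelled sequences (e.g. a fused junction copy for positive controls).
    """
    L = len(cons)
    if genome_len < n_full * L:
        raise ValueError(
            f"genome of {genome_len} nt cannot hold {n_full} full copies "
            f"of a {L}-nt element"
        )
    rng = np.random.default_rng(seed)

    pieces: list[tuple[str, dict]] = []  # (sequence to insert, annotation stub)
    for i in range(n_full):
        pieces.append(
            (
                cons.sequence,
                {"type": "full_element", "ID": f"{cons.id}.full.{i}", "c_start": 0,
                 "c_end": L},
            )
        )
    for i in range(n_fragmented):
        flen = int(rng.integers(min_fragment, max(min_fragment + 1, L)))
        fstart = int(rng.integers(0, L - flen + 1))
        pieces.append(
            (
                cons.sequence[fstart : fstart + flen],
                {"type": "fragment", "ID": f"{cons.id}.frag.{i}",
                 "c_start": fstart, "c_end": fstart + flen},
            )
        )
    for label, insert_seq in extra_inserts:
        pieces.append((insert_seq, {"type": "insert", "ID": label,
                                    "c_start": 0, "c_end": len(insert_seq)}))

    total_insert = sum(len(p) for p, _ in pieces)
    if total_insert > genome_len:
        raise ValueError("insertions exceed genome capacity")

    genome = list(random_seq(rng, genome_len))
    taken: list[tuple[int, int]] = []
    records: list[dict] = []
    for piece, meta in pieces:
        strand = "+" if rng.random() < 0.5 else "-"
        placed = piece if meta["type"] == "insert" else mutate(piece, divergence, rng)
        if strand == "-":
            placed = revcomp(placed)
        for _ in range(10_000):
            start = int(rng.integers(0, genome_len - len(placed) + 1))
            end = start + len(placed)
            if all(end <= s or start >= e for s, e in taken):
                break
        else:  # pragma: no cover - astronomically unlikely at sane densities
            raise ValueError("could not place insertions without overlap")
        taken.append((start, end))
        genome[start:end] = placed
        records.append(
            {
                "seqid": "genome",
                "type": meta["type"],
                "start": start,
                "end": end,
                "strand": strand,
                "attributes": {
                    "ID": meta["ID"],
                    "consensus": cons.id,
                    "c_start": str(meta["c_start"] + 1),
                    "c_end": str(meta["c_end"]),
                },
            }
        )
    records.sort(key=lambda r: r["start"])
    return "".join(genome), records


# -------------------------------------------------------------- transcripts

@dataclass
class IsoformSpec:
    """One transcript to synthesize from the consensus.

    ``segments`` are 0-based half-open consensus intervals, in transcript
    order.  For CIRCULAR specs the first segment starts at the back-splice
    acceptor and the last ends at the donor, so every circle in a set
    shares the element's single back-splice site.  ``rip_enrichment`` is
    the over-sampling factor applied in the RIP compartment.
    """

    id: str
    kind: str  # LINEAR | CIRCULAR
    segments: list[tuple[int, int]]
    strand: str = "+"
    abundance: float = 1.0
    rip_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("LINEAR", "CIRCULAR"):
            raise ValueError(f"bad isoform kind {self.kind}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass
class Transcript:
    id: str
    sequence: str  # plus-frame sequence; strand applies at read emission
    kind: str
    strand: str
    junction: tuple[int, int] | None  # (acceptor, donor) on the consensus
    abundance: float = 1.0
    rip_enrichment: float = 1.0
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def make_transcripts(
    cons: RepeatConsensus, specs: Iterable[IsoformSpec]
) -> list[Transcript]:
    """Materialize transcript sequences from segment specs.

    LINEAR transcripts are the concatenation of their segments; CIRCULAR
    transcripts are stored in canonical rotation, starting at the acceptor
    (REGION85 side first), with the junction recorded as (acceptor, donor).
    """
    out = []
    for spec in specs:
        for s, e in spec.segments:
            if not (0 <= s < e <= len(cons)):
                raise ValueError(
                    f"{spec.id}: segment [{s},{e}) outside consensus of "
                    f"length {len(cons)}"
                )
        seq = "".join(cons.sequence[s:e] for s, e in spec.segments)
        junction = None
        if spec.kind == "CIRCULAR":
            junction = (spec.segments[0][0], spec.segments[-1][1])
        out.append(
            Transcript(
                spec.id, seq, spec.kind, spec.strand, junction,
                spec.abundance, spec.rip_enrichment, list(spec.segments),
            )
        )
    return out


def default_isoform_specs(
    cons: RepeatConsensus,
    circ_abundance: float = 0.05,
    linear_abundance: float = 1.0,
    rip_enrichment: float = 7.0,
) -> list[IsoformSpec]:
    """The study-system transcript pool.

    Circular isoforms (all sharing the one back-splice site): the
    85+269 = 354-nt circle and the 277/296-nt partial-retention variants
    on both strands, the full 607-nt circle on the sense strand only.
    Linear RNAs covering the same region: RNA-85, RNA-269 and RNA-85+269.
    Circles are far less abundant than linear transcripts, as observed
    for circRNA generally; centromere-derived RNAs share one RIP
    enrichment factor.
    """
    r85 = cons.region("REGION85")
    r253 = cons.region("REGION253") if cons.has_region("REGION253") else None
    r269 = cons.region("REGION269")
    seg85 = (r85.start, r85.end)
    seg269 = (r269.start, r269.end)
    span = (r85.start, r269.end)

    def circ(name, segments, strand):
        return IsoformSpec(
            name, "CIRCULAR", segments, strand,
            abundance=circ_abundance, rip_enrichment=rip_enrichment,
        )

    def lin(name, segments, strand="+"):
        return IsoformSpec(
            name, "LINEAR", segments, strand,
            abundance=linear_abundance, rip_enrichment=rip_enrichment,
        )

    specs = [
        circ("circ354+", [seg85, seg269], "+"),
        circ("circ354-", [seg85, seg269], "-"),
        circ("circ607+", [span], "+"),  # sense strand only
        circ("circ277+", [(r85.start, r85.start + 8), seg269], "+"),
        circ("circ277-", [(r85.start, r85.start + 8), seg269], "-"),
        circ("circ296+", [(r85.start, r85.start + 27), seg269], "+"),
        circ("circ296-", [(r85.start, r85.start + 27), seg269], "-"),
        lin("RNA-85", [seg85]),
        lin("RNA-269", [seg269]),
        lin("RNA-85+269", [span]),
    ]
    if r253 is None:
        # Architecture without an intervening segment (e.g. wheat-style):
        # only the fully retained circle exists.
        specs = [s for s in specs if s.id in ("circ607+", "RNA-85+269")]
    return specs


# ------------------------------------------------------------------- reads

@dataclass
class ReadTruth:
    read_id: str
    template: str
    start: int  # fragment start in the template plus-frame (canonical) coords
    insert: int
    flipped: bool  # True if R1 is the 3'-end read of the physical fragment
    compartment: str
    crosses_junction: bool  # fragment spans the circle origin


@dataclass
class SimTruth:
    """Ground truth for one simulated library."""

    compartment: str
    reads: list[ReadTruth] = field(default_factory=list)
    templates: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "compartment": self.compartment,
            "templates": self.templates,
            "reads": [asdict(r) for r in self.reads],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls(payload["compartment"], templates=payload["templates"])
        truth.reads = [ReadTruth(**r) for r in payload["reads"]]
        return truth


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str


def _compartment_weights(
    templates: Sequence[Transcript], compartment: str
) -> np.ndarray:
    w = np.array(
        [
            t.abundance * (t.rip_enrichment if compartment == "RIP" else 1.0)
            for t in templates
        ],
        dtype=float,
    )
    return w


def simulate_reads(
    templates: Sequence[Transcript],
    n_pairs: int,
    seed: int,
    read_len: int = 125,
    insert_mean: float = 180.0,
    insert_sd: float = 20.0,
    err_rate: float = 0.0,
    compartment: str = "INPUT",
    run_id: str = "sim",
    qual_char: str = "I",
) -> tuple[list[FastqRead], list[FastqRead], SimTruth]:
    """Simulate a paired-end library from a transcript/template pool.

    Fragment starts are drawn in a strand-covariant frame (mirrored for
    minus-strand templates), so reverse-complementing a template's
    sequence and flipping its strand label yields, for the same seed,
    exactly the reverse-complement reads.  Circular templates use a
    uniform start with wrap-around through the doubled sequence; the RIP
    compartment over-samples templates by their ``rip_enrichment``
    factor.  Substitution errors only; Sanger quality encoding.
    ``SimTruth.start`` records the fragment start on the stored
    (consensus plus-frame) sequence.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not (0 <= err_rate < 1):
        raise ValueError("err_rate must be in [0, 1)")

    usable = []
    for t in templates:
        if t.kind == "LINEAR" and len(t) < read_len:
            logger.warning(
                "template %s (%d nt) shorter than read length %d; skipped",
                t.id, len(t), read_len,
            )
            continue
        usable.append(t)
    weights = _compartment_weights(usable, compartment)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no template with positive weight")
    probs = weights / total

    rng = np.random.default_rng(seed)
    r1_out, r2_out = [], []
    truth = SimTruth(compartment)
    for t in usable:
        truth.templates[t.id] = {
            "kind": t.kind,
            "strand": t.strand,
            "length": len(t),
            "junction": list(t.junction) if t.junction else None,
            "abundance": t.abundance,
            "rip_enrichment": t.rip_enrichment,
        }

    for i in range(n_pairs):
        ti = int(rng.choice(len(usable), p=probs))
        t = usable[ti]
        L = len(t)
        max_insert = L if t.kind == "CIRCULAR" else L
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)),
                             read_len, max_insert))
        if t.kind == "CIRCULAR":
            s = int(rng.integers(0, L))
            start = s if t.strand == "+" else (L - s - insert) % L
            frag = (t.sequence + t.sequence)[start : start + insert]
            crosses = start + insert > L
        else:
            s = int(rng.integers(0, L - insert + 1))
            start = s if t.strand == "+" else L - s - insert
            frag = t.sequence[start : start + insert]
            crosses = False
        read_id = f"{run_id}:{i}"
        r1, r2, flipped = _emit_pair(frag, read_len, err_rate, rng)
        q = qual_char * read_len
        r1_out.append(FastqRead(read_id, r1, q))
        r2_out.append(FastqRead(read_id, r2, q))
        truth.reads.append(
            ReadTruth(read_id, t.id, start, insert, flipped, compartment, crosses)
        )
    return r1_out, r2_out, truth


def _emit_pair(
    frag: str, read_len: int, err_rate: float, rng: np.random.Generator
) -> tuple[str, str, bool]:
    physical = frag
    flipped = bool(rng.random() < 0.5)  # non-stranded library
    if flipped:
        physical = revcomp(physical)
    r1 = mutate(physical[:read_len], err_rate, rng)
    r2 = mutate(revcomp(physical[-read_len:]), err_rate, rng)
    return r1, r2, flipped


def simulate_junction_pairs(
    template: Transcript,
    n_pairs: int,
    seed: int,
    read_len: int = 125,
    insert_mean: float = 180.0,
    insert_sd: float = 20.0,
    err_rate: float = 0.0,
    min_anchor: int = 11,
    acceptor_ext_ranges: list[tuple[int, int]] | None = None,
    run_id: str = "bsj",
) -> tuple[list[FastqRead], list[FastqRead], SimTruth]:
    """Paired reads whose fragment crosses the circle's back-splice point
    with at least ``min_anchor`` nt on each side (a split shorter than the
    aligner word size is undetectable by any split-read method).

    ``acceptor_ext_ranges`` optionally restricts how far the fragment
    extends past the circle origin, so that every consensus segment the
    fragment implies is long enough to be resolvable — needed for
    partial-retention circles whose acceptor-side remnant is shorter
    than the aligner word (see the methods note on identifiability).
    Inserts are capped at 2*read_len - 10 so every pair is joinable by
    the overlap-merging step and the whole fragment is analyzable.
    """
    if template.kind != "CIRCULAR":
        raise ValueError("junction reads require a circular template")
    L = len(template)
    rng = np.random.default_rng(seed)
    r1_out, r2_out = [], []
    truth = SimTruth("RIP")
    truth.templates[template.id] = {
        "kind": template.kind, "strand": template.strand, "length": L,
        "junction": list(template.junction), "abundance": template.abundance,
        "rip_enrichment": template.rip_enrichment,
    }
    for i in range(n_pairs):
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)),
                             max(read_len, 2 * min_anchor),
                             min(L, 2 * read_len - 10)))
        # acceptor-side extent past the origin; donor side gets the rest
        lo, hi = min_anchor, insert - min_anchor
        if acceptor_ext_ranges:
            allowed = [
                e
                for rlo, rhi in acceptor_ext_ranges
                for e in range(max(lo, rlo), min(hi, rhi) + 1)
            ]
            if not allowed:
                raise ValueError(
                    "no admissible acceptor extent for the given ranges"
                )
            ext = int(rng.choice(allowed))
        else:
            ext = int(rng.integers(lo, hi + 1))
        start = L - insert + ext
        frag = (template.sequence + template.sequence)[start : start + insert]
        read_id = f"{run_id}:{i}"
        r1, r2, flipped = _emit_pair(frag, read_len, err_rate, rng)
        q = "I" * read_len
        r1_out.append(FastqRead(read_id, r1, q))
        r2_out.append(FastqRead(read_id, r2, q))
        truth.reads.append(
            ReadTruth(read_id, template.id, start, insert, flipped, "RIP", True)
        )
    return r1_out, r2_out, truth


def simulate_library_counts(
    templates: Sequence[Transcript],
    n_reads: int,
    seed: int,
    compartment: str = "INPUT",
) -> dict[str, int]:
    """Multinomial per-template read counts for one library.

    Uses exactly the same compartment weighting as :func:`simulate_reads`;
    suitable for enrichment statistics at library sizes where emitting
    individual reads adds nothing.
    """
    weights = _compartment_weights(templates, compartment)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no template with positive weight")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / total)
    return {t.id: int(c) for t, c in zip(templates, counts)}


def ltr_spec(cons: RepeatConsensus, extent: int = 250) -> IsoformSpec:
    """A linear transcript spanning the 5' LTR into the element body,
    sourcing the LTR read class."""
    ltr = cons.region("LTR5")
    return IsoformSpec(
        "RNA-LTR", "LINEAR", [(ltr.start, min(ltr.end + extent, len(cons)))],
        "+", abundance=1.0, rip_enrichment=7.0,
    )


def fragment_footprint(
    t: Transcript, start: int, insert: int
) -> list[tuple[int, int]]:
    """Consensus intervals covered by a fragment, in fragment order.

    For circular templates the fragment may wrap through the origin; the
    returned pieces follow the fragment 5'->3' in the template plus frame.
    """
    L = len(t)
    if t.kind == "CIRCULAR" and start + insert > L:
        t_intervals = [(start, L), (0, start + insert - L)]
    else:
        t_intervals = [(start, start + insert)]
    seg_offsets = []
    pos = 0
    for s, e in t.segments:
        seg_offsets.append((pos, pos + (e - s), s))
        pos += e - s
    pieces = []
    for ts, te in t_intervals:
        for off_s, off_e, c_s in seg_offsets:
            lo, hi = max(ts, off_s), min(te, off_e)
            if hi > lo:
                pieces.append((c_s + (lo - off_s), c_s + (hi - off_s)))
    return pieces


def expected_category(
    t: Transcript,
    start: int,
    insert: int,
    cons: RepeatConsensus,
    min_word: int = 11,
    min_ltr_overlap: int = 20,
    min_fill: int = 6,
) -> str:
    """Ground-truth taxonomy category for an error-free fragment.

    Mirrors the identifiability rules of the classifier: consensus
    pieces of at least ``min_word`` effective nt are alignable; a
    shorter middle piece of at least ``min_fill`` effective nt between
    two alignable pieces is placeable by gap-filling; anything smaller
    is invisible.  "Effective" length discounts joint microhomology — a
    neighbouring alignment extends through bases that match across the
    splice joint, eroding a short piece's unambiguous support.  LTR
    overlap takes precedence; the visible pieces' pairwise geometry then
    decides the spliced category.
    """
    pieces = fragment_footprint(t, start, insert)
    ltr_ov = sum(
        r.overlap(s, e) for r in cons.ltr_regions() for s, e in pieces
    )
    if ltr_ov >= min_ltr_overlap:
        return "LTR"
    seq = cons.sequence
    eff = []
    for i, (s, e) in enumerate(pieces):
        h_left = h_right = 0
        if i > 0:  # previous alignment extends forward across the joint
            pe = pieces[i - 1][1]
            while (
                pe + h_left < len(seq) and s + h_left < e
                and seq[pe + h_left] == seq[s + h_left]
            ):
                h_left += 1
        if i < len(pieces) - 1:  # next alignment extends backward
            cs = pieces[i + 1][0]
            while (
                cs - 1 - h_right >= 0 and e - 1 - h_right >= s
                and seq[cs - 1 - h_right] == seq[e - 1 - h_right]
            ):
                h_right += 1
        eff.append(max(0, (e - s) - h_left - h_right))
    visible = []
    for i, (s, e) in enumerate(pieces):
        if eff[i] >= min_word:
            visible.append((s, e))
        elif (
            eff[i] >= min_fill
            and 0 < i < len(pieces) - 1
            and eff[i - 1] >= min_word
            and eff[i + 1] >= min_word
        ):
            visible.append((s, e))
    if not visible:
        return "UNALIGNED"
    if len(visible) == 1:
        return "NONSPLICED"
    back = fwd = conflict = 0
    for (s1, e1), (s2, e2) in zip(visible, visible[1:]):
        if s2 > e1:
            fwd += 1
        elif s2 < s1:
            back += 1
        else:
            conflict += 1
    if conflict or back > 1:
        return "AMBIGUOUS"
    if back == 1:
        return "BACK_SPLICED"
    return "NORMAL_SPLICED"


# --------------------------------------------------------------------- IO

def write_fastq(reads: Iterable[FastqRead], path, mate: int | None = None) -> None:
    suffix = f"/{mate}" if mate else ""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}{suffix}\n{r.sequence}\n+\n{r.quality}\n")


def write_genome_fasta(genome: str, path, seqid: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{seqid}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_insertions_gff3(records: list[dict], path) -> None:
    write_gff3(records, path)
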