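"""FASTQ parsing and overlap merging of paired-end reads.

Overlapping mates are joined into single fragments before consensus
alignment, mirroring the SeqPrep-style joining step used for repeat
read analysis (quality floor 30, minimum merged length 25).  Unmerged
pairs are carried forward as two independent fragments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from Bio import SeqIO

from .seq import check_alphabet, revcomp
from .synthetic import FastqRead


@dataclass
class MergedFragment:
    id: str
    sequence: str
    quality: str
    source: str  # MERGED | UNMERGED_R1 | UNMERGED_R2


@dataclass
class MergeStats:
    pairs: int = 0
    merged: int = 0
    unmerged: int = 0
    discarded_short: int = 0


def parse_fastq(path) -> list[FastqRead]:
    """Read a (optionally gzipped) FASTQ file; Sanger quality encoding."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seq = str(rec.seq).upper()
            check_alphabet(seq)
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append(FastqRead(rec.id.split("/")[0], seq, qual))
    return out


def _trim3(read: FastqRead, qual_floor: int) -> FastqRead:
    """Trim low-quality 3' tail (all trailing bases below the floor)."""
    end = len(read.sequence)
    while end > 0 and ord(read.quality[end - 1]) - 33 < qual_floor:
        end -= 1
    return FastqRead(read.id, read.sequence[:end], read.quality[:end])


def _best_overlap(s1: str, s2c: str, min_overlap: int) -> tuple[int, int]:
    """Best 3' overlap of s1 with the reverse-complemented mate s2c.

    Score = matches - mismatches over the overlap (N counts as neither);
    ties go to the longest overlap.  Returns (overlap_len, mismatches),
    (0, 0) if nothing reaches min_overlap.
    """
    best = (0, 0, float("-inf"))
    for o in range(min(len(s1), len(s2c)), min_overlap - 1, -1):
        a = s1[len(s1) - o :]
        b = s2c[:o]
        mm = sum(
            1 for x, y in zip(a, b) if x != y and x != "N" and y != "N"
        )
        score = (o - mm) - mm
        if score > best[2]:
            best = (o, mm, score)
    return best[0], best[1]


def merge_pairs(
    r1: list[FastqRead],
    r2: list[FastqRead],
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
    qual_floor: int = 30,
    min_len: int = 25,
) -> tuple[list[MergedFragment], list[tuple[FastqRead, FastqRead]], MergeStats]:
    """Merge overlapping mates into single fragments.

    A pair merges iff the best 3' overlap of R1 with the reverse
    complement of R2 reaches ``min_overlap`` with a mismatch fraction at
    most ``max_mismatch_rate``; overlap bases take the higher-quality
    call.  Merged products shorter than ``min_len`` are discarded and the
    pair is carried as unmerged.
    """
    if len(r1) != len(r2):
        raise ValueError(f"unpaired input: {len(r1)} R1 vs {len(r2)} R2 reads")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    merged: list[MergedFragment] = []
    unmerged: list[tuple[FastqRead, FastqRead]] = []
    stats = MergeStats(pairs=len(r1))
    for a, b in zip(r1, r2):
        check_alphabet(a.sequence)
        check_alphabet(b.sequence)
        ta, tb = _trim3(a, qual_floor), _trim3(b, qual_floor)
        bc = FastqRead(tb.id, revcomp(tb.sequence), tb.quality[::-1])
        o, mm = _best_overlap(ta.sequence, bc.sequence, min_overlap)
        if o >= min_overlap and (mm / o) <= max_mismatch_rate:
            seq, qual = _join(ta, bc, o)
            if len(seq) >= min_len:
                merged.append(MergedFragment(a.id, seq, qual, "MERGED"))
                stats.merged += 1
                continue
            stats.discarded_short += 1
        unmerged.append((a, b))
        stats.unmerged += 1
    return merged, unmerged, stats


def _join(a: FastqRead, bc: FastqRead, o: int) -> tuple[str, str]:
    head_s, head_q = a.sequence[: len(a.sequence) - o], a.quality[: len(a.sequence) - o]
    tail_s, tail_q = bc.sequence[o:], bc.quality[o:]
    ov_s, ov_q = [], []
    for i in range(o):
        x, qx = a.sequence[len(a.sequence) - o + i], a.quality[len(a.quality) - o + i]
        y, qy = bc.sequence[i], bc.quality[i]
        if qy > qx or (x == "N" and y != "N"):
            ov_s.append(y)
            ov_q.append(qy)
        else:
            ov_s.append(x)
            ov_q.append(qx)
    return head_s + "".join(ov_s) + tail_s, head_q + "".join(ov_q) + tail_q


def as_fragments(
    merged: list[MergedFragment],
    unmerged: list[tuple[FastqRead, FastqRead]],
) -> list[MergedFragment]:
    """Full fragment set: merged products plus unmerged mates carried as
    independent fragments (R2 reverse-complemented onto the R1 frame)."""
    out = list(merged)
    for a, b in unmerged:
        out.append(MergedFragment(f"{a.id}/1", a.sequence, a.quality, "UNMERGED_R1"))
        out.append(
            MergedFragment(
                f"{b.id}/2", revcomp(b.sequence), b.quality[::-1], "UNMERGED_R2"
            )
        )
    return out


def write_fragments_fastq(fragments: list[MergedFragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"@{f.id} source={f.source}\n{f.sequence}\n+\n{f.quality}\n")


def read_fragments_fastq(path) -> list[MergedFragment]:
    out = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            source = "MERGED"
            for token in rec.description.split():
                if token.startswith("source="):
                    source = token.split("=", 1)[1]
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append(MergedFragment(rec.id, str(rec.seq).upper(), qual, source))
    return out
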