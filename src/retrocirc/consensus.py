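"""Repeat consensus container with labelled sub-regions, plus FASTA/GFF3 IO.

A :class:`RepeatConsensus` models one retrotransposon family consensus —
for the centromeric retrotransposons of maize (CRM) this is a full element
with two identical long terminal repeats (LTR5/LTR3), internal coding
regions (gag, protease, RT, RNase H, integrase) and, for the CRM1-like
family, a donor region split into three contiguous segments of 85, 253 and
269 nt whose back-splicing produces the circular RNAs this package detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_LABELS = {
    "LTR5", "LTR3", "GAG", "PR", "RT", "RNH", "INT",
    "REGION85", "REGION253", "REGION269", "OTHER",
}

DONOR_LABELS = ("REGION85", "REGION253", "REGION269")


@dataclass(frozen=True)
class Region:
    """Labelled interval on a consensus, 0-based half-open, plus strand
    unless noted."""

    label: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class RepeatConsensus:
    """A repeat family consensus sequence and its annotated sub-regions."""

    id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        for r in self.regions:
            if not (0 <= r.start <= r.end <= n):
                raise ValueError(
                    f"region {r.label} [{r.start},{r.end}) outside consensus "
                    f"of length {n}"
                )
        donor = [self.region(lbl) for lbl in DONOR_LABELS if self.has_region(lbl)]
        for a, b in zip(donor, donor[1:]):
            if a.end != b.start:
                raise ValueError(
                    f"donor sub-regions must be adjacent and ordered: "
                    f"{a.label} ends at {a.end}, {b.label} starts at {b.start}"
                )

    def has_region(self, label: str) -> bool:
        return any(r.label == label for r in self.regions)

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"no region labelled {label} on consensus {self.id}")

    def region_seq(self, label: str) -> str:
        r = self.region(label)
        return self.sequence[r.start : r.end]

    def ltr_regions(self) -> list[Region]:
        return [r for r in self.regions if r.label in ("LTR5", "LTR3")]

    @property
    def backsplice_acceptor(self) -> int:
        """5' start of the acceptor-side donor segment (REGION85)."""
        return self.region("REGION85").start

    @property
    def backsplice_donor(self) -> int:
        """3' end (half-open) of the donor-side segment (REGION269)."""
        return self.region("REGION269").end

    # ------------------------------------------------------------------ IO
    def to_fasta(self, path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.id, description="")
        SeqIO.write([rec], path, "fasta")

    def regions_to_gff3(self, path) -> None:
        write_gff3(
            (
                {
                    "seqid": self.id,
                    "source": "retrocirc",
                    "type": "region",
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "attributes": {"ID": f"{self.id}.{r.label}", "label": r.label},
                }
                for r in self.regions
            ),
            path,
        )


def load_consensus(fasta_path, gff3_path=None) -> dict[str, RepeatConsensus]:
    """Read one or more consensus sequences (and optional region GFF3)."""
    out: dict[str, RepeatConsensus] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out[rec.id] = RepeatConsensus(rec.id, str(rec.seq).upper(), [])
    if gff3_path is not None:
        for row in read_gff3(gff3_path):
            cons = out.get(row["seqid"])
            if cons is None:
                continue
            label = row["attributes"].get("label", row["type"])
            cons.regions.append(
                Region(label, row["start"], row["end"], row["strand"])
            )
        for cons in out.values():
            cons.validate()
    return out


# ---------------------------------------------------------------- GFF3 IO
# Writers take 0-based half-open records and emit 1-based inclusive GFF3.

def write_gff3(records: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in records:
            attrs = ";".join(f"{k}={v}" for k, v in row["attributes"].items())
            fh.write(
                "\t".join(
                    [
                        row["seqid"],
                        row.get("source", "retrocirc"),
                        row.get("type", "region"),
                        str(row["start"] + 1),
                        str(row["end"]),
                        str(row.get("score", ".")),
                        row.get("strand", "+"),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            rows.append(
                {
                    "seqid": f[0],
                    "source": f[1],
                    "type": f[2],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "attributes": attrs,
                }
            )
    return rows
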