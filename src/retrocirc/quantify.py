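"""Class-count tables, RPM tracks, RIP/input enrichment, coverage, and
3C-qPCR interaction normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES, ReadClassification


def tabulate_classes(
    classifications: list[ReadClassification],
    library_total: int | None = None,
) -> pd.DataFrame:
    """Per (consensus family x category) read counts.

    Rows are consensus families (UNALIGNED fragments land on the '.'
    row); columns are the taxonomy categories, which partition the
    fragments.  ``library_total`` (total merged fragments) is carried in
    ``df.attrs`` for downstream normalization.
    """
    counts: dict[tuple[str, str], int] = {}
    for rc in classifications:
        family = rc.consensus_id or "."
        counts[(family, rc.category)] = counts.get((family, rc.category), 0) + 1
    families = sorted({f for f, _ in counts})
    df = pd.DataFrame(
        [[counts.get((f, c), 0) for c in CATEGORIES] for f in families],
        index=families,
        columns=list(CATEGORIES),
        dtype=int,
    )
    df.attrs["library_total"] = (
        library_total if library_total is not None else len(classifications)
    )
    return df


def rpm_track(
    placements: list[tuple[int, int]],
    bin_size: int,
    library_total: int,
    region_len: int,
    mapq_min: int = 20,
) -> np.ndarray:
    """Reads-per-million track over fixed bins.

    ``placements`` are (position, mapq) pairs; placements below
    ``mapq_min`` are excluded, mirroring a uniquely-mapped-reads filter.
    Bin value = 1e6 * reads_in_bin / library_total.
    """
    if library_total <= 0:
        raise ZeroDivisionError("library_total must be > 0")
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n_bins = (region_len + bin_size - 1) // bin_size
    track = np.zeros(n_bins)
    for pos, mapq in placements:
        if mapq <= mapq_min:
            continue
        if 0 <= pos < region_len:
            track[pos // bin_size] += 1
    return track * 1e6 / library_total


def write_bedgraph(track: np.ndarray, bin_size: int, path, chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track):
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:g}\n")


@dataclass
class EnrichmentRecord:
    feature_id: str
    rip_count: int
    input_count: int
    rip_total: int
    input_total: int
    enrichment: float


def relative_enrichment(
    rip_count: int,
    rip_total: int,
    input_count: int,
    input_total: int,
    pseudocount: float = 1.0,
) -> float:
    """RIP-over-input ratio of proportions for one feature.

    ((rip_count + pc) / rip_total) / ((input_count + pc) / input_total);
    the pseudocount on counts (not totals) keeps zero-count features
    finite with negligible bias at realistic library scales.
    """
    if rip_count < 0 or input_count < 0:
        raise ValueError("counts must be >= 0")
    if rip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be > 0")
    return ((rip_count + pseudocount) / rip_total) / (
        (input_count + pseudocount) / input_total
    )


def enrichment_table(
    rip_counts: dict[str, int],
    input_counts: dict[str, int],
    rip_total: int,
    input_total: int,
    pseudocount: float = 1.0,
) -> list[EnrichmentRecord]:
    out = []
    for fid in sorted(set(rip_counts) | set(input_counts)):
        r, i = rip_counts.get(fid, 0), input_counts.get(fid, 0)
        out.append(
            EnrichmentRecord(
                fid, r, i, rip_total, input_total,
                relative_enrichment(r, rip_total, i, input_total, pseudocount),
            )
        )
    return out


def coverage_estimate(
    total_read_bases: float, region_size: int, reads_only: bool = False
) -> float:
    """Fold coverage of a region: total read bases / region size.

    With ``reads_only`` the numerator is interpreted as a read count,
    the literal reads-per-nucleotide reading; base-level coverage is the
    default since that is what published fold-coverage figures (tens to
    hundreds of x) correspond to.
    """
    if region_size <= 0:
        raise ZeroDivisionError("region_size must be > 0")
    return total_read_bases / region_size


def normalize_3c(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
    efficiency: float = 2.0,
) -> float:
    """Relative 3C interaction frequency from quantification cycles.

    Target amplicon Ct is normalized to an internal reference amplicon
    and to the randomized-ligation control template (e.g. a digested and
    re-ligated BAC), all on the exponential-amplification scale:
    (E^-ct_ts / E^-ct_rs) / (E^-ct_tc / E^-ct_rc).  Adding a constant to
    all four Ct values leaves the result unchanged.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if any(ct is None for ct in cts):
        raise ValueError("all four Ct values are required")
    if any(ct <= 0 for ct in cts):
        raise ValueError("Ct values must be > 0")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must be in (1, 2]")
    e = efficiency
    return (e ** -ct_target_sample / e ** -ct_ref_sample) / (
        e ** -ct_target_control / e ** -ct_ref_control
    )


def read_ct_csv(path) -> pd.DataFrame:
    """Ct input CSV with columns amplicon, sample, ct[, efficiency]."""
    df = pd.read_csv(path)
    required = {"amplicon", "sample", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    return df
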