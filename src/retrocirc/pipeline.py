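"""End-to-end orchestration: simulate or load reads, then
merge -> align -> classify -> call circles -> check genome -> quantify,
writing every stage product plus a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .align import AlignParams, FragmentAligner, write_hits_tsv
from .classify import (
    ReadClassification, call_junctions, classify_read,
    write_classifications_tsv,
)
from .consensus import RepeatConsensus
from .params import PipelineParams
from .quantify import enrichment_table, tabulate_classes
from .readprep import MergedFragment, as_fragments, merge_pairs, write_fragments_fastq
from .reconstruct import (
    cluster_junctions, genomic_origin_test, infer_retention_patterns,
    reconstruct_isoforms, write_isoforms, write_junctions_tsv,
)
from . import synthetic

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def align_library(
    fragments: list[MergedFragment],
    consensus_set: dict[str, RepeatConsensus],
    params: PipelineParams,
):
    aligner = FragmentAligner(
        consensus_set,
        AlignParams(
            min_word=params.min_word,
            evalue_max=params.evalue_max,
            min_identity=params.min_identity,
        ),
    )
    all_hits = []
    classifications: list[ReadClassification] = []
    for frag in fragments:
        hits = aligner.align(frag.sequence, frag.id)
        all_hits.extend(hits)
        rc = classify_read(
            hits, consensus_set, frag.sequence,
            params.max_read_gap, params.max_read_overlap,
            params.min_ltr_overlap, params.min_word,
        )
        if not rc.read_id:
            rc.read_id = frag.id
        classifications.append(rc)
    return all_hits, classifications


def call_circles(
    classifications: list[ReadClassification],
    consensus_set: dict[str, RepeatConsensus],
    params: PipelineParams,
):
    """Cluster back-splice calls and reconstruct isoforms, inferring
    skipped-interval retention from co-occurring forward-splice calls."""
    calls = call_junctions(classifications)
    clusters = cluster_junctions(calls, params.junction_tolerance)
    forward = [
        rc.junction
        for rc in classifications
        if rc.category == "NORMAL_SPLICED" and rc.junction
    ]
    isoforms = []
    for cl in clusters:
        cons = consensus_set[cl.consensus_id]
        fwd = [(a, d) for a, d, _ in forward]
        patterns = infer_retention_patterns(cl, fwd)
        isoforms.extend(reconstruct_isoforms(cl, cons, patterns))
    return clusters, isoforms


def run_pipeline(
    run_dir,
    consensus_set: dict[str, RepeatConsensus],
    rip_pairs=None,
    input_pairs=None,
    dna_reads=None,
    params: PipelineParams | None = None,
    simulate: bool = False,
    n_pairs: int = 2000,
) -> dict:
    """Run every stage and return the manifest dict.

    ``*_pairs`` are (r1, r2) lists of FastqRead; with ``simulate`` the
    default synthetic library is generated instead.  Outputs land in
    ``run_dir``; reruns with identical inputs are byte-identical.
    """
    params = params or PipelineParams()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "params": params.to_dict(),
        "outputs": [],
        "inputs": {},
    }

    if simulate:
        cons = next(iter(consensus_set.values()))
        specs = synthetic.default_isoform_specs(cons)
        templates = synthetic.make_transcripts(cons, specs)
        rip_pairs = synthetic.simulate_reads(
            templates, n_pairs, seed=params.seed, compartment="RIP",
            run_id="rip",
        )[:2]
        input_pairs = synthetic.simulate_reads(
            templates, n_pairs, seed=params.seed + 1, compartment="INPUT",
            run_id="input",
        )[:2]

    results = {}
    for name, pairs in (("rip", rip_pairs), ("input", input_pairs)):
        if pairs is None:
            continue
        r1, r2 = pairs
        merged, unmerged, stats = merge_pairs(
            r1, r2, params.min_overlap, params.max_mismatch_rate,
            params.qual_floor, params.min_merged_len,
        )
        fragments = as_fragments(merged, unmerged)
        frag_path = run_dir / f"{name}.fragments.fastq"
        write_fragments_fastq(fragments, frag_path)
        hits, classifications = align_library(fragments, consensus_set, params)
        write_hits_tsv(hits, run_dir / f"{name}.hits.tsv")
        write_classifications_tsv(
            classifications, run_dir / f"{name}.classes.tsv"
        )
        table = tabulate_classes(classifications, stats.pairs)
        table.to_csv(run_dir / f"{name}.class_table.tsv", sep="\t")
        results[name] = {
            "stats": stats,
            "fragments": fragments,
            "classifications": classifications,
            "table": table,
        }
        manifest["outputs"] += [
            f"{name}.fragments.fastq", f"{name}.hits.tsv",
            f"{name}.classes.tsv", f"{name}.class_table.tsv",
        ]

    clusters, isoforms = [], []
    if "rip" in results:
        pooled = list(results["rip"]["classifications"])
        if "input" in results:
            pooled += results["input"]["classifications"]
        clusters, isoforms = call_circles(pooled, consensus_set, params)
        write_junctions_tsv(clusters, run_dir / "junctions.tsv")
        write_isoforms(
            isoforms, run_dir / "isoforms.fasta", run_dir / "isoforms.json"
        )
        manifest["outputs"] += ["junctions.tsv", "isoforms.fasta", "isoforms.json"]

    if dna_reads is not None and clusters:
        reports = []
        for cl in clusters:
            cons = consensus_set[cl.consensus_id]
            rep = genomic_origin_test(
                cl, cons, dna_reads, params.flank, params.min_overhang,
                params.max_residual,
            )
            reports.append(rep)
        with open(run_dir / "genomic_origin.tsv", "w") as fh:
            fh.write(
                "junction\tn_reads_checked\tn_junction_covering\tverdict\n"
            )
            for rep in reports:
                fh.write(
                    f"{rep.junction_id}\t{rep.n_reads_checked}\t"
                    f"{rep.n_junction_covering}\t{rep.verdict}\n"
                )
        manifest["outputs"].append("genomic_origin.tsv")
        results["genomic_origin"] = reports

    if "rip" in results and "input" in results:
        rip_counts = _family_counts(results["rip"]["classifications"])
        in_counts = _family_counts(results["input"]["classifications"])
        table = enrichment_table(
            rip_counts, in_counts,
            results["rip"]["stats"].pairs, results["input"]["stats"].pairs,
            params.pseudocount,
        )
        with open(run_dir / "enrichment.tsv", "w") as fh:
            fh.write(
                "feature\trip_count\tinput_count\trip_total\tinput_total\t"
                "enrichment\n"
            )
            for rec in table:
                fh.write(
                    f"{rec.feature_id}\t{rec.rip_count}\t{rec.input_count}\t"
                    f"{rec.rip_total}\t{rec.input_total}\t"
                    f"{rec.enrichment:.4f}\n"
                )
        manifest["outputs"].append("enrichment.tsv")

    for out in manifest["outputs"]:
        p = run_dir / out
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"declared output missing or empty: {p}")
        manifest["inputs"][out] = _sha256(p)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    results["junctions"] = clusters
    results["isoforms"] = isoforms
    return results


def _family_counts(classifications: list[ReadClassification]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rc in classifications:
        if rc.consensus_id:
            counts[rc.consensus_id] = counts.get(rc.consensus_id, 0) + 1
    return counts
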