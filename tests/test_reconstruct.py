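"""Isoform reconstruction, junction clustering, divergent PCR, genomic
origin testing, and sequence design."""

import numpy as np
import pytest

from retrocirc import synthetic as syn
from retrocirc.classify import BackspliceJunction
from retrocirc.reconstruct import (
    RetentionPattern, assumed_junction_sequence, circular_sequence,
    cluster_junctions, design_junction_target, divergent_pcr,
    genomic_origin_test, infer_retention_patterns, insert_restriction_sites,
    pick_divergent_primers, reconstruct_isoforms,
)
from retrocirc.seq import revcomp, rotate, rotation_canonical


@pytest.fixture
def junction(cons):
    return BackspliceJunction(
        cons.id, cons.backsplice_acceptor, cons.backsplice_donor, "+", support=10
    )


def _skip253(cons):
    r = cons.region("REGION253")
    return (r.start, r.end)


class TestClusterJunctions:
    def _call(self, a, d, strand="+", rid="r"):
        return BackspliceJunction("CRM1", a, d, strand, 1, [rid])

    def test_exact_match_clustering(self):
        calls = [self._call(100, 900, rid=f"a{i}") for i in range(4)]
        calls.append(self._call(300, 700, rid="b"))
        clusters = cluster_junctions(calls)
        assert [(c.acceptor, c.donor, c.support) for c in clusters] == [
            (100, 900, 4), (300, 700, 1),
        ]

    def test_tolerance_merges_near_calls(self):
        # single-linkage oracle on the 2-call instance: distance 1 <= 2
        calls = [self._call(100, 900), self._call(101, 899)]
        clusters = cluster_junctions(calls, tolerance=2)
        assert len(clusters) == 1 and clusters[0].support == 2
        assert cluster_junctions(calls, tolerance=0)[0].support == 1

    def test_support_weighted_mode_coordinates(self):
        calls = [self._call(100, 900) for _ in range(3)] + [self._call(101, 901)]
        (cl,) = cluster_junctions(calls, tolerance=2)
        assert (cl.acceptor, cl.donor) == (100, 900)

    def test_strands_cluster_separately(self):
        calls = [self._call(100, 900, "+"), self._call(100, 900, "-")]
        assert len(cluster_junctions(calls)) == 2

    def test_empty_input(self):
        assert cluster_junctions([]) == []


class TestReconstructIsoforms:
    def test_skip_253_gives_354(self, cons, junction):
        (iso,) = reconstruct_isoforms(
            junction, cons, [RetentionPattern("skip253", [_skip253(cons)])]
        )
        assert iso.length == 354
        assert iso.sequence == cons.region_seq("REGION85") + cons.region_seq("REGION269")

    def test_full_retention_gives_607(self, cons, junction):
        (iso,) = reconstruct_isoforms(junction, cons)
        assert iso.length == 607
        assert iso.length == junction.donor - junction.acceptor

    def test_partial_retention_bounds_277_and_296(self, cons, junction):
        for k, expected in ((8, 277), (27, 296)):
            (iso,) = reconstruct_isoforms(
                junction, cons,
                [RetentionPattern(f"k{k}", [_skip253(cons)], acceptor_keep=k)],
            )
            assert iso.length == expected

    def test_bad_retention_interval_rejected(self, cons, junction):
        with pytest.raises(ValueError):
            reconstruct_isoforms(
                junction, cons, [RetentionPattern("bad", [(0, 50)])]
            )

    def test_minus_strand_isoform_is_reverse_complement(self, cons, junction):
        minus = BackspliceJunction(
            cons.id, junction.acceptor, junction.donor, "-", support=1
        )
        (plus_iso,) = reconstruct_isoforms(junction, cons)
        (minus_iso,) = reconstruct_isoforms(minus, cons)
        # oracle via explicit reverse complement, compared as circles
        assert rotation_canonical(minus_iso.sequence) == rotation_canonical(
            revcomp(plus_iso.sequence)
        )

    def test_canonical_rotation_identity(self, cons, junction):
        (iso,) = reconstruct_isoforms(junction, cons)
        s = circular_sequence(iso)
        assert rotation_canonical(rotate(s, 17)) == rotation_canonical(s)

    def test_retention_inference_from_forward_splices(self, cons, junction):
        r253 = cons.region("REGION253")
        fwd = [(r253.end, r253.start), (r253.end, r253.start)]  # (acceptor', donor')
        pats = infer_retention_patterns(junction, fwd)
        isos = reconstruct_isoforms(junction, cons, pats)
        assert sorted(i.length for i in isos) == [354, 607]


class TestDivergentPCR:
    def test_circle_offset_example(self, templates):
        # primers at circle offsets 300 and 40 (1-based) on the 354-nt
        # circle: product spans 55 + 40 = 95 nt across the junction
        circ = next(t for t in templates if t.id == "circ354+").sequence
        fwd = circ[299:319]
        rev = revcomp(circ[20:40])
        product = divergent_pcr(circ, fwd, rev, max_product=500)
        assert product is not None and len(product) == 95
        doubled = circ * 2
        assert product == doubled[299:394]

    def test_divergent_primers_discriminate_circularity(self, templates):
        for t in templates:
            if t.kind != "CIRCULAR":
                continue
            fwd, rev = pick_divergent_primers(t.sequence)
            assert divergent_pcr(t.sequence, fwd, rev, 500, circular=True) is not None
            assert divergent_pcr(t.sequence, fwd, rev, 500, circular=False) is None

    def test_absent_primer_gives_no_product(self, templates):
        circ = next(t for t in templates if t.id == "circ354+").sequence
        fwd, rev = pick_divergent_primers(circ)
        assert divergent_pcr("ACGT" * 200, fwd, rev, 500) is None

    def test_primer_validation(self, templates):
        circ = next(t for t in templates if t.id == "circ354+").sequence
        with pytest.raises(ValueError):
            divergent_pcr(circ, "ACGTACGTACGTACG!", "ACGTACGTACGTACGT", 500)
        with pytest.raises(ValueError):
            divergent_pcr(circ, "ACGT", "ACGTACGTACGTACGT", 500)


class TestGenomicOrigin:
    def test_assumed_junction_sequence_default_flank(self, cons, junction):
        seq = assumed_junction_sequence(junction, cons, 177)
        assert len(seq) == 354
        a, d = junction.acceptor, junction.donor
        assert seq == cons.sequence[d - 177 : d] + cons.sequence[a : a + 177]

    def test_fusion_free_genome_has_zero_covering_reads(self, cons, junction):
        genome, _ = syn.plant_elements(20000, cons, 2, 1, seed=71)
        gt = syn.Transcript("g", genome, "LINEAR", "+", None)
        r1, r2, _ = syn.simulate_reads([gt], 800, seed=72, read_len=100,
                                       insert_mean=300, insert_sd=30)
        reads = [(x.id + "/1", x.sequence) for x in r1]
        reads += [(x.id + "/2", x.sequence) for x in r2]
        rep = genomic_origin_test(junction, cons, reads)
        assert rep.n_junction_covering == 0
        assert rep.verdict == "NO_GENOMIC_COPY"

    def test_planted_fusion_matches_bruteforce_count(self, cons, junction):
        fused = assumed_junction_sequence(junction, cons, 177)
        genome, recs = syn.plant_elements(
            20000, cons, 1, 1, seed=73, extra_inserts=[("fused", fused)]
        )
        frec = next(r for r in recs if r["attributes"]["ID"] == "fused")
        fusion_pos = (
            frec["start"] + 177 if frec["strand"] == "+" else frec["end"] - 177
        )
        gt = syn.Transcript("g", genome, "LINEAR", "+", None)
        r1, r2, truth = syn.simulate_reads([gt], 2000, seed=74, read_len=100,
                                           insert_mean=300, insert_sd=30)
        reads = [(x.id + "/1", x.sequence) for x in r1]
        reads += [(x.id + "/2", x.sequence) for x in r2]
        rep = genomic_origin_test(junction, cons, reads)
        # brute-force oracle from the seeded truth: which reads span the
        # fusion point with >= 10 nt on each side?
        expected = set()
        for x in truth.reads:
            left = (x.start, x.start + 100)
            right = (x.start + x.insert - 100, x.start + x.insert)
            m1, m2 = ("/2", "/1") if x.flipped else ("/1", "/2")
            for rid, (s, e) in ((x.read_id + m1, left), (x.read_id + m2, right)):
                if s + 10 <= fusion_pos <= e - 10:
                    expected.add(rid)
        assert rep.n_junction_covering == len(expected)
        assert set(rep.covering_read_ids) == expected
        assert rep.verdict == "GENOMIC_COPY_SUSPECTED"

    def test_verdict_monotone_in_max_residual(self, cons, junction):
        fused = assumed_junction_sequence(junction, cons, 177)
        reads = [("only", fused[177 - 30 : 177 + 30])]
        r0 = genomic_origin_test(junction, cons, reads, max_residual=0)
        r1_ = genomic_origin_test(junction, cons, reads, max_residual=1)
        assert r0.verdict == "GENOMIC_COPY_SUSPECTED"
        assert r1_.verdict == "NO_GENOMIC_COPY"

    def test_flank_bounds_checked(self, cons, junction):
        with pytest.raises(ValueError):
            genomic_origin_test(junction, cons, [], flank=5, min_overhang=10)


class TestSequenceDesign:
    def test_default_target_is_289_nt(self, cons, junction):
        target = design_junction_target(junction, cons)
        assert len(target) == 204 + 85 == 289
        d = junction.donor
        assert target[:204] == cons.sequence[d - 204 : d]
        assert target[204:] == cons.region_seq("REGION85")

    @pytest.mark.parametrize("upstream,expected", [(0, 85), (100, 185)])
    def test_upstream_length_arithmetic(self, cons, junction, upstream, expected):
        assert len(design_junction_target(junction, cons, upstream)) == expected

    def test_negative_upstream_rejected(self, cons, junction):
        with pytest.raises(ValueError):
            design_junction_target(junction, cons, -1)

    def test_restriction_site_insertion_lengths(self):
        rng = np.random.default_rng(11)
        template = "".join(rng.choice(list("ACGT"), size=1659))
        edited = insert_restriction_sites(
            template, [(400, "GGATCC"), (1200, "GAATTC")]
        )
        assert len(edited) == 1671
        assert edited[400:406] == "GGATCC"
        assert edited[1206:1212] == "GAATTC"  # shifted by the first insert

    def test_empty_insertions_identity(self):
        assert insert_restriction_sites("ACGT", []) == "ACGT"

    def test_insertion_at_origin(self):
        edited = insert_restriction_sites("ACGTACGT", [(0, "GGATCC")])
        assert edited.startswith("GGATCC") and len(edited) == 14

    def test_duplicate_positions_conflict(self):
        with pytest.raises(ValueError):
            insert_restriction_sites("ACGT" * 10, [(5, "GGATCC"), (5, "GAATTC")])


def test_wheat_style_architecture_reconstructs_323(tmp_path):
    wcons = syn.build_consensus(
        3, region_lengths={"REGION85": 135, "REGION253": 0, "REGION269": 188},
        element_id="wheatRT",
    )
    j = BackspliceJunction(
        wcons.id, wcons.backsplice_acceptor, wcons.backsplice_donor, "+", 1
    )
    (iso,) = reconstruct_isoforms(j, wcons)
    assert iso.length == 135 + 188 == 323
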