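"""Generator correctness: consensus architecture, genome planting,
transcript construction, and read simulation with ground truth."""

import pytest

from retrocirc import synthetic as syn
from retrocirc.seq import revcomp, rotate, rotation_canonical


class TestBuildConsensus:
    def test_donor_region_spans_607_nt(self, cons):
        r85, r269 = cons.region("REGION85"), cons.region("REGION269")
        assert r269.end - r85.start == 607
        assert len(cons.region("REGION253")) == 253

    def test_same_seed_reproduces_sequence(self):
        assert syn.build_consensus(3).sequence == syn.build_consensus(3).sequence

    def test_total_length_equals_sum_of_region_lengths(self, cons):
        # recompute from the emitted region annotations
        assert len(cons.sequence) == sum(r.end - r.start for r in cons.regions)
        starts = sorted(r.start for r in cons.regions)
        assert starts[0] == 0
        assert cons.region("LTR5").start == 0
        assert cons.region("LTR3").end == len(cons)

    def test_ltrs_are_identical_copies(self, cons):
        assert cons.region_seq("LTR5") == cons.region_seq("LTR3")

    def test_junction_has_no_flank_microhomology(self, cons):
        s, a, d = cons.sequence, cons.backsplice_acceptor, cons.backsplice_donor
        assert s[a - 1] != s[d - 1]
        assert s[a] != s[d]

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            syn.build_consensus(1, region_lengths={"GAG": -5})


class TestPlantElements:
    def test_empty_plan_gives_pure_background(self, cons):
        genome, recs = syn.plant_elements(5000, cons, 0, 0, seed=1)
        assert len(genome) == 5000 and recs == []

    def test_record_count_and_full_copy_lengths(self, cons):
        genome, recs = syn.plant_elements(30000, cons, 3, 2, seed=2, divergence=0.0)
        assert len(recs) == 5
        full = [r for r in recs if r["type"] == "full_element"]
        assert len(full) == 3
        assert all(r["end"] - r["start"] == len(cons) for r in full)

    def test_extracted_insertions_reproduce_consensus(self, cons):
        # string-comparison oracle at zero divergence
        genome, recs = syn.plant_elements(30000, cons, 2, 3, seed=5, divergence=0.0)
        for r in recs:
            piece = genome[r["start"] : r["end"]]
            if r["strand"] == "-":
                piece = revcomp(piece)
            cs = int(r["attributes"]["c_start"]) - 1
            ce = int(r["attributes"]["c_end"])
            assert piece == cons.sequence[cs:ce]

    def test_capacity_error(self, cons):
        with pytest.raises(ValueError):
            syn.plant_elements(2 * len(cons) - 1, cons, 2, 0, seed=1)


class TestMakeTranscripts:
    def test_linear_spec_is_consensus_substring(self, cons):
        r85 = cons.region("REGION85")
        spec = syn.IsoformSpec("x", "LINEAR", [(r85.start, r85.end)])
        (t,) = syn.make_transcripts(cons, [spec])
        assert t.sequence == cons.region_seq("REGION85")
        assert t.junction is None

    def test_default_strand_assignment(self, cons):
        ids = {s.id for s in syn.default_isoform_specs(cons)}
        # full 607 circle sense-only; partial-retention circles on both strands
        assert "circ607+" in ids and "circ607-" not in ids
        assert {"circ354+", "circ354-", "circ277+", "circ277-",
                "circ296+", "circ296-"} <= ids
        assert {"RNA-85", "RNA-269", "RNA-85+269"} <= ids

    def test_circ354_sequence_and_rotation_equivalence(self, cons, templates):
        circ = next(t for t in templates if t.id == "circ354+")
        expected = cons.region_seq("REGION85") + cons.region_seq("REGION269")
        assert circ.sequence == expected
        # every rotation describes the same circle
        canon = rotation_canonical(circ.sequence)
        for off in (1, 17, 100, 353):
            assert rotation_canonical(rotate(circ.sequence, off)) == canon

    def test_segment_outside_consensus_rejected(self, cons):
        spec = syn.IsoformSpec("bad", "LINEAR", [(0, len(cons) + 1)])
        with pytest.raises(ValueError):
            syn.make_transcripts(cons, [spec])


class TestSimulateReads:
    def test_error_free_read_is_template_substring(self):
        t = syn.Transcript("lin", "ACGT" * 50, "LINEAR", "+", None)
        r1, r2, truth = syn.simulate_reads([t], 1, seed=1, read_len=50)
        x = truth.reads[0]
        frag = t.sequence[x.start : x.start + x.insert]
        assert r1[0].sequence in (frag[:50], revcomp(frag[-50:]))

    def test_junction_crossing_placements_by_enumeration(self, templates):
        # brute force: a 100-nt read on a 354-nt circle crosses the
        # origin for exactly 99 of the 354 start positions
        circ = next(t for t in templates if t.id == "circ354+")
        L, rl = len(circ), 100
        crossing = sum(1 for s in range(L) if s + rl > L)
        assert crossing == 99
        # and each crossing placement wraps through the doubled string
        doubled = circ.sequence * 2
        for s in range(L - rl + 1, L):
            read = doubled[s : s + rl]
            assert len(read) == rl
            assert read.endswith(circ.sequence[: s + rl - L])

    def test_zero_abundance_template_emits_no_reads(self, templates):
        circ = next(t for t in templates if t.id == "circ354+")
        silent = syn.Transcript("silent", "A" * 300, "LINEAR", "+", None, abundance=0.0)
        r1, r2, truth = syn.simulate_reads([circ, silent], 200, seed=3)
        assert all(x.template != "silent" for x in truth.reads)

    def test_determinism_and_conservation(self, templates):
        a = syn.simulate_reads(templates, 100, seed=9, err_rate=0.01)
        b = syn.simulate_reads(templates, 100, seed=9, err_rate=0.01)
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert [r.sequence for r in a[1]] == [r.sequence for r in b[1]]
        assert len(a[0]) == len(a[1]) == 100
        assert len(a[2].reads) == 100
        assert len({x.read_id for x in a[2].reads}) == 100

    def test_wrap_reads_are_doubled_string_substrings(self, templates):
        circ = next(t for t in templates if t.id == "circ607+")
        r1, r2, truth = syn.simulate_reads([circ], 100, seed=4)
        doubled = circ.sequence * 2
        for rec, x in zip(r1, truth.reads):
            assert x.start + x.insert <= 2 * len(circ)
            frag = doubled[x.start : x.start + x.insert]
            assert rec.sequence in (frag[:125], revcomp(frag[-125:]))

    def test_strand_flip_gives_reverse_complement_reads(self, cons):
        r85, r269 = cons.region("REGION85"), cons.region("REGION269")
        plus = syn.Transcript("t+", cons.sequence[r85.start:r269.end], "LINEAR", "+", None)
        minus = syn.Transcript(
            "t-", revcomp(plus.sequence), "LINEAR", "-", None
        )
        a1, a2, _ = syn.simulate_reads([plus], 30, seed=6)
        b1, b2, _ = syn.simulate_reads([minus], 30, seed=6)
        for ra1, ra2, rb1, rb2 in zip(a1, a2, b1, b2):
            assert rb1.sequence == ra2.sequence
            assert rb2.sequence == ra1.sequence

    def test_short_linear_template_skipped_with_warning(self, caplog):
        t = syn.Transcript("short", "ACGTACGT", "LINEAR", "+", None)
        ok = syn.Transcript("ok", "ACGT" * 100, "LINEAR", "+", None)
        with caplog.at_level("WARNING"):
            r1, _, truth = syn.simulate_reads([t, ok], 10, seed=1, read_len=50)
        assert "short" in caplog.text
        assert all(x.template == "ok" for x in truth.reads)

    def test_bad_parameters_rejected(self, templates):
        with pytest.raises(ValueError):
            syn.simulate_reads(templates, 1, seed=1, read_len=0)
        with pytest.raises(ValueError):
            syn.simulate_reads(templates, 1, seed=1, err_rate=1.0)


def test_library_counts_follow_compartment_weights(templates):
    bg = syn.Transcript("bg", "A" * 500, "LINEAR", "+", None,
                        abundance=20.0, rip_enrichment=1.0)
    pool = list(templates) + [bg]
    counts_rip = syn.simulate_library_counts(pool, 100_000, seed=1, compartment="RIP")
    counts_in = syn.simulate_library_counts(pool, 100_000, seed=2, compartment="INPUT")
    assert sum(counts_rip.values()) == sum(counts_in.values()) == 100_000
    # enriched (centromeric) templates are over-sampled in RIP relative
    # to the unenriched background
    enriched = [t.id for t in templates]
    rip_frac = sum(counts_rip[c] for c in enriched) / 100_000
    in_frac = sum(counts_in[c] for c in enriched) / 100_000
    assert rip_frac > 2 * in_frac


def test_expected_category_footprint(cons, templates):
    circ = next(t for t in templates if t.id == "circ354+")
    a, d = cons.backsplice_acceptor, cons.backsplice_donor
    # wrapping fragment with generous anchors crosses the back-splice
    assert syn.expected_category(circ, len(circ) - 60, 120, cons) == "BACK_SPLICED"
    # fragment inside the 269-part only
    assert syn.expected_category(circ, 100, 120, cons) == "NONSPLICED"
    ltr = syn.make_transcripts(cons, [syn.ltr_spec(cons)])[0]
    assert syn.expected_category(ltr, 0, 150, cons) == "LTR"
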