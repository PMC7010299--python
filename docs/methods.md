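# Methods

## Overview of the procedure

`retrocirc` detects back-spliced (circular) RNA from repetitive
elements by anchoring all evidence on a repeat-family consensus rather
than on a genome assembly.  The stages are:

1. **Read joining** (`readprep`): overlapping paired-end mates are
   merged into single fragments.  3′ tails below the quality floor
   (default Q30) are trimmed first; the best 3′ overlap of R1 with the
   reverse-complemented R2 is accepted if it reaches `min_overlap`
   (10 nt) with a mismatch fraction ≤ 0.1 (ties go to the longest
   overlap, overlap bases take the higher-quality call).  Merged
   products shorter than 25 nt are discarded and the pair is carried
   forward unmerged, as two independent fragments.
2. **Consensus alignment** (`align`): every significant local
   alignment of a fragment against the consensus set, on both strands.
   Exact 11-mer seeding, diagonal clustering into consensus windows,
   affine local alignment per window (match +1, mismatch −2, a gap of
   length k costs 5 + 2(k−1); Biopython's `PairwiseAligner` is the
   alignment engine), then iterative masking of the aligned read
   interval so non-redundant hits are enumerated in score order.
   Significance is a BLASTN-style Karlin–Altschul e-value with λ
   solved numerically from the scoring scheme under uniform base
   composition and K = 0.621 (the tabulated ungapped value for +1/−2);
   the database length is the total consensus length and the ceiling
   is 1e-5.  Hits below 85% identity are dropped.
3. **Anchor rescue**: a genuine back-splice anchor of 11–18 nt can
   never reach e-value significance against a multi-kilobase consensus
   (E ≈ 0.1 for an exact 11-mer), so uncovered read flanks of at least
   `min_word` (11) nt adjacent to a significant hit are re-examined
   with a smaller seed word and accepted on exact-match count
   (≥ 11) and identity instead.  Rescued hits are flagged and excluded
   from e-value-level comparisons.
4. **Taxonomy** (`classify`): each fragment receives exactly one
   category.  Any hit overlapping a long terminal repeat by ≥ 20 nt
   makes the fragment **LTR** (precedence keeps the taxonomy a
   partition).  Otherwise hits on one consensus and strand are chained
   along the read (gap ≤ 10 nt, overlap ≤ 10 nt) and consecutive
   segment pairs are read 5′→3′ in the transcript frame (minus-strand
   chains are mirrored first, which makes classification
   strand-invariant): a pair whose second segment starts *downstream*
   of the first segment's end is a forward splice; a pair whose second
   segment starts *upstream* of the first segment's start is a back
   splice.  One back-splice pair with no conflicting pair ⇒
   **BACK_SPLICED** (a read from a small circle legitimately crosses
   both the back-splice point and a forward skip joint, giving three
   segments); only forward pairs ⇒ **NORMAL_SPLICED**; a single
   segment ⇒ **NONSPLICED**; conflicts, two back-splice pairs, or
   significant hits on two element families ⇒ **AMBIGUOUS**.
5. **Junction extraction**: for a back-splice pair, donor = consensus
   end of the downstream segment, acceptor = consensus start of the
   upstream segment.  The breakpoint is *refined* by scanning candidate
   read split positions over a fixed read span and counting matches
   under the donor-side and acceptor-side mappings (prefix sums; ties
   resolve toward the raw aligner boundary) — this recovers the true
   junction when a sequencing error truncates or extends a local
   alignment at the splice flank.  Junctions are then canonicalized to
   the leftmost placement across flank microhomology
   (`cons[acceptor−1] == cons[donor−1]` ⇒ shift left), which makes all
   shift-equivalent placements of one circle map to one key.
6. **Gap placement**: a retained piece shorter than the aligner word
   (the 8-nt remnant of the shortest partial-retention circle) never
   aligns on its own.  Unaligned read gaps of 6–18 nt between chained
   segments are searched verbatim (1 mismatch allowed from 8 nt up;
   prefixes/suffixes tried because errors erode neighbouring segment
   boundaries into the gap) within ±1 kb of the chain, and a
   geometry-consistent placement is inserted as a virtual segment.
   Same-locus chains separated by such a fillable gap are stitched
   before classification.
7. **Clustering and reconstruction** (`reconstruct`): per-read junction
   calls agreeing within `junction_tolerance` (default 0; single
   linkage on Chebyshev distance) merge, cluster coordinates are the
   support-weighted mode.  A circular isoform is built per retention
   pattern: full retention (length = donor − acceptor), skipped
   internal intervals (length reduced by theirs), partial retention of
   the first k nt of the acceptor-side region.  The pipeline infers
   skip patterns from co-occurring forward-splice calls inside the
   back-splice span; partial retention requires explicit flags (or
   full-length evidence), since reads rarely pin the retained length.
   The canonical circle string starts at the acceptor; minus-strand
   isoforms are the reverse complement; rotation equivalence is decided
   via the lexicographically least rotation (Booth's algorithm).
8. **Verification**: `divergent_pcr` searches the doubled circle string
   for a forward-primer site followed by the reverse complement of the
   reverse primer within `max_product` — a primer pair divergent on the
   linear form amplifies only across the circle junction.
   `genomic_origin_test` builds the assumed junction DNA (177 nt
   upstream of the donor fused to 177 nt downstream of the acceptor,
   ≈ 354 nt total), aligns genomic DNA reads to it and counts reads
   covering the fusion point contiguously with ≥ 10 matched nt per
   side; up to `max_residual` = 1 covering read still returns
   NO_GENOMIC_COPY (a single residual read can arise from
   chromatin-binding RNA carried through a ChIP library).
9. **Quantification** (`quantify`): per-family × category count
   tables; RPM tracks with a MAPQ > 20 filter; RIP/input relative
   enrichment as a pseudocount-adjusted ratio of proportions with
   total merged fragments as denominators; fold coverage as read
   bases / region size (the literal reads-per-nucleotide reading is
   available behind `reads_only`, but published fold-coverage figures
   correspond to base-level coverage); and 3C-qPCR relative interaction
   frequency (E^−Ct of the target over a reference amplicon, sample
   over randomized-ligation control; E ∈ (1, 2], default 2, and the
   statistic is invariant to shifting all four Ct values).

## The synthetic-data generator

`synthetic` emulates the CRM1 study system and is the ground truth for
every test:

- **Consensus element** (~3.7 kb by default): LTR5 (450 nt, copied
  verbatim to LTR3), gag/protease/RT/RNase-H/integrase regions, then
  the donor region — REGION85 (85 nt), REGION253 (253 nt), REGION269
  (269 nt), contiguous and in that order — and an intergenic spacer.
  Background composition is i.i.d. uniform A/C/G/T (the simplest
  null).  Two bases flanking the back-splice site are deterministically
  edited so the default junction has no microhomology, i.e. a unique
  canonical placement.
- **Transcript pool**: circles circ354 (85+269, both strands), circ607
  (fully retained, sense strand only), circ277/circ296 (8 or 27 nt of
  the 85 retained, both strands) — all sharing the one back-splice
  site — plus linear RNA-85, RNA-269 and RNA-85+269, and optionally an
  LTR-spanning transcript.  Circle abundance defaults to 0.05 relative
  to 1.0 for linear RNAs (circRNA is far less abundant than its linear
  counterparts), and centromeric transcripts share a RIP enrichment
  factor of 7 (the order of magnitude implied by RIP-vs-input
  nonspliced read counts after library-size normalization).
- **Reads**: paired-end 125 nt, insert 180 ± 20 (mirroring a
  125-bp paired-end RIP library with mostly-overlapping mates),
  substitutions-only error model (indels default 0 — this keeps every
  alignment oracle exact; genomic element copies diverge at 2%
  substitutions, a stated guess, since copy divergence is not
  otherwise specified).  Circular templates are sampled with uniform
  start and wrap-around through the doubled sequence.  Fragment starts
  are drawn in a strand-covariant frame, so reverse-complementing a
  template and flipping its strand label reproduces exactly the
  reverse-complement reads for the same seed.  All randomness flows
  from one integer seed; outputs are byte-identical across reruns.
- **Genomes**: full and fragmented element copies planted
  non-overlapping in uniform background, each annotated; arbitrary
  labelled inserts (e.g. a fused junction copy) support positive
  controls for the genomic-origin test.

What the generator does **not** model: indel sequencing errors (unless
enabled), polymorphism structure among element copies beyond uniform
substitution divergence, transcription-level strand biases within a
class, RNase-R biochemistry, and chromatin/R-loop structure.  Passing
tests therefore demonstrate correctness of the detection logic under a
clean substitution-noise model, not robustness to structural variation
or library artefacts.

## Identifiability limits

Split-read evidence cannot resolve a consensus segment shorter than
the aligner can anchor.  Concretely:

- A junction overhang below `min_word` (11 nt) is undetectable; reads
  must cross the back-splice with ≥ 11 nt on each side to count as
  recoverable, and the junction-read generator enforces this.
- For partial-retention circles the acceptor-side remnant (8–27 nt)
  may itself be shorter than the word.  An 8-nt remnant is placeable
  only by the gap-fill search, which requires the flanking segments to
  be alignable: an acceptor-side extent of 11–18 nt on a circ277 read
  leaves a sub-word trailing segment and the read degrades to
  NONSPLICED; extents in (27, 38) on circ296 behave analogously.  The
  generator's `acceptor_ext_ranges` expresses these admissible extents,
  and the ground-truth `expected_category` mirrors the same rules,
  additionally discounting joint microhomology (a neighbouring
  alignment extends through bases that match across a splice joint,
  eroding a short piece's unambiguous support).
- Reads in the unresolvable regimes still classify as BACK_SPLICED
  when a downstream-then-upstream pair is visible, but the acceptor
  lands on the nearest alignable segment: such reads form low-support
  *satellite* junction clusters near the primary junction (visible in
  the README example).  At realistic circle abundances these satellites
  are well separated from the primary cluster by support.
- Refinement decides breakpoints by match counts; an error base that
  coincidentally matches the alternative mapping at the immediate
  junction flank (probability ≈ err_rate/3 per flank) makes the
  shifted placement genuinely better-supported at the read level, an
  irreducible per-read error of well under 1% at 1% sequencing error.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `qual_floor` | 30 | 3′ quality trim before overlap search (Phred) |
| `min_merged_len` | 25 | discard merged products below this length (nt) |
| `min_overlap` / `max_mismatch_rate` | 10 nt / 0.1 | overlap acceptance |
| `evalue_max` | 1e-5 | alignment significance ceiling |
| `min_word` | 11 | seed word; minimum rescue anchor (nt) |
| `min_identity` | 0.85 | minimum hit identity (suits ~2% diverged repeats) |
| `max_read_gap` / `max_read_overlap` | 10 / 10 nt | chaining tolerance |
| `min_ltr_overlap` | 20 nt | LTR-class threshold |
| `junction_tolerance` | 0 nt | clustering distance |
| `flank` | 177 nt | assumed-junction flank (→ ~354-nt template) |
| `min_overhang` | 10 nt | fusion-point coverage per side |
| `max_residual` | 1 read | tolerated junction-covering DNA reads |
| `mapq_min` | 20 | RPM track filter |
| `pseudocount` | 1 | enrichment ratio floor (on counts, not totals) |
| `efficiency` | 2.0 | qPCR amplification efficiency, E ∈ (1, 2] |

The quality floor 30, length floor 25, e-value ceiling 1e-5 and
MAPQ > 20 follow the published settings for this kind of analysis; the
word size, identity floor, chaining tolerances and overhang are
package defaults chosen for ~2%-diverged repeat families and
documented here.  Coordinates are 0-based half-open in memory and
1-based inclusive in every report file.

## Problem sizes used in the checks

The acceptance tests run at desk scale: 1,000 junction-crossing reads
per error rate for junction recovery; an 800-pair mixed library for
the taxonomy matrix; 20 × 15-kb genomes (400 read pairs each) plus one
planted-fusion genome (1,500 pairs) for the genomic-origin check; 200
mixed fragments against a ~2-kb consensus for the Smith–Waterman
equivalence; and multinomial library counts at 5 × 10⁶ reads per
library (≥ 10⁴ per feature) for enrichment recovery — the enrichment
statistic depends only on per-feature counts, so count-level
simulation with the identical compartment weighting is used there.

## Known limitations

- Inter-family fusions are deliberately reported AMBIGUOUS, not
  called; the method analyses within-family splicing.
- Junction coordinates are consensus-anchored; mapping them back to
  individual genomic copies is out of scope.
- The circular:linear molar ratio is not estimable from these data and
  is not reported.
- Satellite junction clusters from sub-word retained pieces (above)
  are reported as-is; downstream consumers should rank clusters by
  support.
- Full-length isoform reconstruction beyond skip patterns requires
  external evidence (clone/amplicon sequences) supplied as retention
  flags.
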