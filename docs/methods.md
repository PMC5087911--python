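# Methods

## The measurement model

`ejscar` models the repair of two nuclease-induced double-strand ends (DSEs)
in an intrachromosomal reporter. Cleavage at two I-SceI-type sites excises
the spacer between them (34 bp in the "close" geometry, 3200 bp in the
"distant" geometry) and leaves two ends, each with a 4-nt 3'-protruding
overhang. The substrate is described by its two retained arms, the overhang,
the spacer length and an orientation flag (`ReporterSubstrate`); the k=4
reference junction `left_arm + overhang + right_arm` is the coordinate frame
(0-based, half-open) for all deletion arithmetic. Reference junctions for
k = 3, 2, 1 remove `4 − k` overhang bases at the junction position, i.e.
they retain the overhang suffix.

The substrate is configuration, not code: the package ships a seeded toy
substrate generator (3.4-kb arms by default, so kilobase-scale resection
fits) rather than any particular laboratory sequence, and classification
logic depends only on the arm sequences and the four overhang bases. The
orientation of the two cut sites (whether the two overhangs are mutually
annealable) is a config flag defaulting to `compatible`; it annotates the
excised ends but does not enter the parsing arithmetic, which counts total
overhang bases retained at the joint regardless of which end contributed
them.

## Junction parsing

A read is parsed with two exact anchors: the maximal prefix match against
`left_arm + overhang` (length *a*) and the maximal suffix match against
`overhang + right_arm` (length *b*). If either anchor is shorter than
`min_anchor` (default 15 bp) the read is `Unalignable` and excluded from all
denominators. When *a* + *b* exceeds the read length the anchors overlap;
the overlap length is reported as `mh_len` (the bases attributable to either
side) and resolved by the leftmost convention — the overlap is assigned to
the left arm — which is the standard deterministic normalization for
ambiguous indel boundaries. At most four joint bases count as retained
overhang (`k_retained`); any surplus matched overhang (e.g. a tandem
overhang duplication) is classified as inserted sequence. Per-side
double-stranded deletions are `del_left = max(0, |left_arm| − a)` and
symmetrically on the right; the read between the anchors is the inserted
segment.

Two conventions worth stating explicitly:

* `del_total = del_left + del_right + (4 − k_retained)` — lost overhang
  bases count toward the deletion size, so a junction that lost all four
  protruding nucleotides but no double-stranded bases is a 4-bp deletion.
  Whether published deletion-size distributions count overhang bases is
  generally not stated; this convention is fixed here and applied
  consistently.
* For a perfect k=4 rejoin both anchors span the full overhang, so `mh_len`
  equals 4 there; for deletion junctions `mh_len` is the genuine junction
  microhomology between the two resected flanks.

An optional mismatch-tolerant anchor mode (≤ 1 mismatch per 20 matched bp)
absorbs isolated substitutions such as sequencing errors; the default is
exact matching, appropriate for near-error-free Sanger-derived reads. An
optional primer-trimming step removes exact matches to the amplification
primers when reads still carry them.

The standalone `junction_microhomology(left, right)` is the suffix–prefix
overlap of the two flanks (the maximal block attributable to both), verified
against exhaustive split enumeration in the test suite.

## Insertion origin assignment

Inserted segments of at least 45 bp — the conventional size above which a
sequence search is informative — are aligned to an ordered reference
collection with `Bio.Align.PairwiseAligner` in local mode using
megablast-like scoring (match +1, mismatch −2, gap −2.5). A hit requires
≥ 90 % identity over ≥ 20 aligned bases (`min_core`); no published
identity/coverage criterion exists for this step, so a conservative
threshold was fixed once (20 bp is also the donor-disjointness k-mer size of
the fixture genome). Both strands are searched; score ties resolve by source
order (reporter first, so a sequence present both in the reporter and
elsewhere is called a duplication), then by the aligner's deterministic
first optimal alignment.

Categories: best hit in the reporter → `partial_duplication`; in the genome
or repeat-element source → `ECS` (repeats are chromosomal sequence); any
other source (nuclease expression plasmid, mitochondrion, ...) → `other`;
no qualifying hit → `unidentified`. Insertion bases outside the hit interval
are per-border unidentified (N-addition) lengths. Reporter duplications are
annotated with cut-site adjacency (within 1 kb, 5' or 3') and flagged
`hr_suspect` when the copy extends into the excised spacer with a border
microhomology ≥ 4 bp — a pattern compatible with a homology-primed
sister-chromatid event — without being placed in a separate category.

Border microhomology is the exact match between the recipient flank at the
junction and the donor sequence immediately beyond the copied interval, in
insert orientation — the annealing signature expected if the insert arose by
microhomology-mediated template switching. A border preceded or followed by
unidentified bases returns "not assessable" rather than 0.

## The simulator

`synthetic_data` generates reads by explicit grammar
`left_arm[:la−del_left] + overhang[:k_left] + ins + overhang[4−k_right:] +
right_arm[del_right:]`, with:

* class mix — defaults are the distant-end control condition
  (HiFi/Insertion/Deletion/Deletion-with-insertion = 0.36/0.04/0.46/0.14);
  the `close` preset uses 0.57/0.07/0.26/0.10;
* deletion sizes per resected side from a two-component mixture: geometric
  (mean 8 bp) for the short mode plus uniform 100–3000 bp for the resection
  tail (weight 0.35 distant, 0.08 with range 100–600 close), reproducing a
  short-deletion mode plus long tail qualitatively, not any published curve;
* insertion lengths from geometric (mean 6 bp) plus uniform 45–250 bp
  (weight 0.5 distant / 0.05 close);
* insertion origins partial-duplication/ECS/untemplated = 0.35/0.45/0.20;
  duplications copy from within 1 kb of a cut site on the full reporter;
  ECS captures copy a donor-genome interval *chosen so its flanks share the
  drawn microhomology with the recipient flanks* (border MH distribution
  with P(≥ 2 bp) = 2/3, matching the reported fraction of assessable
  borders with microhomology; if no donor interval satisfies the constraint
  after bounded retries the event falls back to MH = 0 and the truth notes
  it);
* per-border non-templated N-additions with probability 0.6 (distant;
  1 − (1 − 0.6)² ≈ 0.84 of templated inserts get at least one unidentified
  border, close to the observed ~83 %), lengths uniform 1–25 bp — a
  terminal-transferase-like mechanism; successive short template-switch
  rounds, an alternative explanation for unidentified borders, are not
  modelled;
* a fixture donor genome (20 kb, uniform composition, seeded) constructed to
  share no 20-mer with the substrate.

**Canonical truth.** With a fixed substrate, roughly one in four event
borders chance-matches the adjacent reference base, so the raw generative
coordinates of a read are not uniquely recoverable even from error-free
sequence. The simulator therefore stores, besides the raw record, the
leftmost-maximal canonical coordinates computed by an independent reparse,
and flags reads where the two differ as `boundary_ambiguous`. Recovery
testing measures the classifier against canonical truth (≥ 99 % required;
observed 100 %) and additionally requires every disagreement with raw truth
to carry the ambiguity flag.

Determinism: one `numpy` generator drives everything, seeded with a
domain-separated seed sequence so the read stream is independent of the
fixture-genome stream even when the same integer seeds both; structural
choices use integer draws only.

**What the simulator does not emulate.** Sequencing error beyond the
optional mismatch knob, chimeric clones, replication-fork mechanics,
cell-to-cell heterogeneity, and any biology of repair-factor choice: class
probabilities are inputs, not predictions. Passing round-trip tests
therefore demonstrates that the parsing, origin-search and bookkeeping are
mutually consistent and deterministic — not that the event frequencies of
any real experiment would be recovered.

## Statistics

* Class tables report counts and percentages on the sequenced-junction
  denominator, rounded half-up to the printed precision (integer percent for
  class tables, one decimal for origin tables). Undefined percentages (zero
  denominator) are NaN, never 0.
* `compare_sizes` is a two-sided Mann–Whitney test: for
  min(n₁, n₂) ≤ 8 and n₁ + n₂ ≤ 25 the permutation null is enumerated over
  all C(n₁+n₂, n₁) assignments of the pooled values (ties contribute ½ to U,
  so the enumeration is tie-exact); larger samples use the tie-corrected
  normal approximation. All-tied input returns p = 1 with a warning.
* `compare_proportions` is Fisher's exact (hypergeometric) test on pooled
  counts, with the proportion difference and ratio. The original
  experimental design tested per-replicate fractions with t-tests;
  replicate-level fractions are not part of this package's inputs, so the
  pooled exact test is provided instead and its p-values are not numerically
  comparable to replicate-level ones.
* The large-insertion threshold is ≥ 45 bp by default (the comparator is
  exposed because published usage varies between ≥ and >); "coupled"
  insertions have `del_total > 0`, and the origin tables additionally count
  coupling to deletions > 100 bp.

## Problem sizes and numerical choices

Tests and the acceptance script use 300–1000 simulated reads per condition,
a 20-kb donor genome, 10,000 random flank pairs for the microhomology
oracle, and full enumeration for Mann–Whitney up to combined n = 10 and
Fisher tables up to n = 30 per arm — sizes at which every oracle is
exhaustive and a complete run stays in the minutes range on one core.
Percentages recompute exactly from emitted counts in every output table.

## Known limitations

* The anchored parser assumes one contiguous junction per read: multi-block
  rearrangements (two separate inserts, inversions) are folded into a single
  inserted segment.
* Origin search against a 20-bp/90 % threshold occasionally assigns a
  spurious origin to long runs of random (untemplated) sequence, at the rate
  expected for that threshold; lowering the false-assignment rate costs
  sensitivity for short templated cores flanked by N-additions.
* Border microhomology is exact-match only; mismatched ("imperfect")
  microhomology is not scored.
* Unalignable reads are excluded rather than rescued by split alignment, so
  heavily rearranged clones reduce the effective denominator.
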