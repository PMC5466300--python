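# Methods

This note records the models and procedures `cwgtscreen` implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic-data generator does and does not emulate.

## Scope and stance

The package covers the desk side of an expression-screening campaign:
homolog culling, sequence-feature annotation, phylogenetic binning,
library selection, truncation-construct design, design-matrix
enumeration, codon-frequency flagging, and hit identification /
summarization from electrophoresis peak tables. Wet-lab stages (cloning,
expression, lysis, pull-down, gels, mass spectrometry) are outside the
package; mass-spec confirmation is consumed as a per-sample boolean.
Running external search/alignment/prediction servers (BLAST variants,
multiple aligners, TM and disorder predictors) is also out of scope: the
pipeline consumes their tabular exports, or uses the self-contained
predictors described below.

## Homolog culling

Hits arrive as a header-bearing TSV (`query_id`, `subject_id`,
`subject_seq`, optional `identity_pct`); a converter from BLAST
`-outfmt "6 qseqid sseqid pident"` plus a subject FASTA is provided.
Filters, applied in order with single-valued rejection reasons:

* **identity** — keep iff identity ≥ `min_identity` (default 0.40,
  boundary inclusive). When the table has no identity column it is
  computed from a global alignment (below) as identical columns divided
  by total alignment columns, gaps included — a conservative,
  deterministic definition chosen because homology-search percent
  identity depends on the tool's alignment and denominator conventions.
* **length** — keep iff subject/query length ratio lies in
  [`min_len_ratio`, `max_len_ratio`] (defaults 0.85 and 1.15, inclusive).
  Ratios are computed on protein length. The lower bound biases toward
  full-length sequences; the upper bound excludes extra-domain
  architectures.
* **duplicate** — subjects with exactly identical residues collapse to
  the first occurrence. Near-duplicates are retained; the binning stage
  handles redundancy.

The filters are monotone (loosening any threshold never removes a kept
hit) and idempotent, and both properties are tested.

### Global alignment

Needleman–Wunsch with affine gaps (Gotoh's three-matrix recurrence)
under BLOSUM62. A gap of length L costs `gap_open + L * gap_extend`
(defaults 10 and 1). Traceback tie-breaking is fixed — substitution
move first, then gap-in-subject, then gap-in-query — so the reported
alignment, identity and culling decisions are reproducible across runs
and platforms. The aligner is written in the package precisely because
this tie-break is part of its contract; tests cross-check its scores
against an exhaustive enumeration oracle on all pairs up to length 5 and
against Biopython's independent `PairwiseAligner` on longer random
pairs.

## Sequence features

Coordinates are 1-based and inclusive throughout, matching the Δ-notation
used for constructs.

* **Sequons** — every position i with residue i = Asn, residue i+1 ≠ Pro
  and residue i+2 ∈ {Ser, Thr}. Overlapping sequons are each counted.
  No exclusion is applied after the Ser/Thr position; this is the
  standard consensus.
* **Cysteines** — literal count of C.
* **Transmembrane segments** — Kyte–Doolittle (1982) hydropathy averaged
  over a sliding window (default 19, odd, fully contained windows only).
  Maximal runs of window centres scoring ≥ 1.6 and at least 15 centres
  long are reported, extended by half a window on each side. The
  predictor is a deliberate, deterministic desk-scale stand-in for
  dedicated TM topology tools; its windows/thresholds are conventional
  hydropathy-plot values, exposed in `SelectionConfig`. Output segments
  are sorted and non-overlapping by construction, and lowering the
  threshold never removes covered residues (tested).
* **Disordered C-terminus** — TOP-IDP disorder propensities (Campen et
  al. 2008) averaged over a window (default 21). A disordered
  C-terminus is reported iff the terminal maximal run of non-negative
  centres reaches the last scored position and spans ≥ 30 centres; the
  segment is extended to the true C-terminus. Again a deterministic
  stand-in for dedicated disorder predictors.
* **Molecular weight** — sum of average (not monoisotopic) residue
  masses plus one water plus the tag mass, in kDa; average masses
  because the quantity is matched against electrophoretic estimates.
  The unknown residue X is assigned the unweighted mean of the 20
  standard residue masses. Additivity up to one water across
  concatenation is a tested invariant.

## Phylogenetic binning

* **Distances** — p-distance over aligned sequences: mismatches divided
  by columns where neither sequence is gapped; a pair with no comparable
  column is an error. When no alignment is available, 1 − pairwise
  global-alignment identity is an accepted fallback, with the caveat
  that such distances need not be additive.
* **Neighbor joining** — standard Saitou–Nei agglomeration. Two pinned
  behaviours make it deterministic: Q-matrix ties resolve to the
  smallest creation-order index pair, and a negative branch length is
  clamped to zero with the deficit moved to the sister branch (both
  following common NJ practice; the choice matters only off the additive
  regime). The result is returned as an unrooted tree whose root is the
  final three-way join. On additive matrices the implementation
  reproduces the generating tree's path-length matrix to 1e-9, and
  agrees with scikit-bio's independent `nj` — both are tested.
* **Tree cutting** — the manual step of eyeballing a tree into groups is
  replaced by a deterministic cut into `k` bins (default 10). Candidate
  edges form a fixed priority list — internal branches by decreasing
  length, then leaf branches by decreasing length, ties resolved by the
  lexicographically smallest leaf set under the edge — and an edge is
  cut only if it actually splits the current leaf partition, until `k`
  bins exist. Leaf edges must be eligible because an unrooted binary
  tree has only n − 3 internal edges, which cannot produce singleton
  bins as `k` approaches n. Because the accepted cut sequence is
  independent of `k`, increasing `k` always refines the partition
  (tested). Bins are numbered by their smallest leaf label.

Since the original groupings in this workflow were chosen by eye,
bin-for-bin agreement with any particular published tree figure is not a
meaningful target; the automated cut is valued for determinism and the
partition/refinement guarantees.

## Library selection and construct design

Within a bin, candidates lacking expression evidence are dropped and the
rest sort by (sequon count, cysteine count, id) ascending — fewer
unsatisfiable glycosylation sites and fewer potential aberrant
disulfides first; the id tie-break makes the order total. Across bins
(visited in index order, `per_bin` picks each) a greedy rule favours
candidates from organisms not yet represented, maximizing plant
coverage; bins with no eligible candidate are reported.

Construct design: the full-length construct is always emitted. An
N-terminal truncation Δ1–(tm_end + stalk_offset) is added when a TM
segment starts at or before residue 40 — the operational definition of
"N-terminal type II anchor", configurable, since no published rule pins
it. When a disordered C-terminus exists, each N-terminally truncated
variant is additionally emitted with the tail deleted too (tail-only
variants are not emitted; C-terminal trimming entered the published
workflow only on top of N-truncations). Expected MW is recomputed from
the retained residues plus tag for every construct (tested to 1e-6 kDa).
Actual published truncation junctions reflect unrecorded manual
judgement, so per-gene junction agreement is deliberately not a target;
the rule-based junction plus `stalk_offset` is the package's
reproducible counterpart.

The design matrix is the plain cross product construct × vector × host
in deterministic order: 38 × 3 × 6 = 684 samples for the test screen,
69 × 2 × 1 = 138 for the crop screen.

## Codon flagging

Usage tables are renormalized on read to relative synonymous
frequencies (fractions within each amino-acid family), accepting counts,
per-1000 or fraction dialects uniformly — normalization is idempotent,
so no dialect auto-detection is needed. The per-codon ratio is host
frequency / source frequency, with 0/0 → 1 and x/0 → ∞. A codon is
flagged when its ratio is strictly above `codon_fold` (default 5,
strict per "more than"). Flag counts are non-increasing in the fold and
invariant under synonymous recoding at ratio-1 positions (tested). The
optional harmonizer replaces each flagged codon with the synonymous
codon whose host frequency is nearest the original codon's source
frequency (ties alphabetical). Flag positions for any real gene depend
on the codon-usage table edition, so specific flagged positions are
treated as edition-annotated observations, not fixed expectations.

## Hit identification and summaries

A sample matches when a peak's observed MW lies within
expected × (1 ± `mw_tolerance`) (default 0.15), boundaries inclusive
(implemented with a 1e-9 relative epsilon so the inclusive boundary
survives float rounding). Among in-window peaks the smallest relative
deviation wins; ties go to the higher concentration (the multi-peak rule
is the package's choice; the published workflow is silent on it). The
follow-up cutoffs are strict: purity > 27 % OR concentration >
70 µg/mL. The expected MW includes the tag mass, on the reasoning that
the electrophoresed product carries the tag.

Summaries count hits by vector and by host condition, floor the
per-vector mean yields to integer µg/mL (floored means reproduce the
printed 52/3/68 from the transcribed yields), count full-length
(zero-deletion) versus truncated hits, and report hits as a one-decimal
percentage of total samples. All tallies are permutation-invariant
(tested). The published test-library average yield (28 µg/mL) is not
reproducible from the printed per-hit yields (their arithmetic mean is
≈24), so only the crop-library average (68), which the printed rows do
reproduce, is used as an expectation.

## Synthetic data

`make_protein` plants features exactly: a hydrophobic I/L/V/F block at
the TM interval, Asn–X–Ser/Thr at each requested sequon position, an
exact cysteine count, and a P/E/S/Q-repeat tail of the requested length.
Background residues are drawn from a hydrophilic, order-promoting
weighted alphabet (D/E/N/Q/G/S/T/K/R/H with Trp and Tyr enriched 6×; no
A/C/I/L/V/F/M/P) chosen so that un-planted regions stay far below the
TM threshold *and* below the disorder threshold — Trp and Tyr are the
only residues that are simultaneously hydropathy-negative and strongly
order-promoting, which is why they are over-weighted. Accidental sequons
are destroyed by editing their Ser/Thr position to Ala, which can
neither create a sequon nor break a planted one. Consequences, verified
by the generator/feature-agreement tests over 100 random specs:

* planted sequon lists and cysteine counts are recovered exactly;
* a planted TM block of ≥ 23 residues is recovered as exactly one
  segment covering it at the default window 19 / threshold 1.6 /
  min-run 15 (shorter blocks can fall below the minimum run length
  depending on flank composition — an analytical property of windowed
  means, so specs should plant ≥ 23-residue anchors);
* a planted tail of ≥ 45 residues is recovered at the default disorder
  settings; specs without a tail yield no disorder call.

Cysteines are placed ≥ 8 residues apart so their positive hydropathy
cannot accumulate into a spurious TM window.

`make_plate` gives planted samples a peak at expected MW × (1 + η) with
η normal (sd 0.03) truncated to the match tolerance, and hit-grade
purity/concentration; decoys get peaks offset beyond the tolerance
(default 0.30–0.50) with sub-cutoff purity/concentration. Planted truth
is therefore exactly recoverable by construction, which turns hit-caller
validation into a deterministic property despite stochastic generation;
the acceptance script reports 100 % precision/recall over 100 plates for
any seed. All randomness flows from explicit integer seeds; no function
reads global random state.

What the generator does **not** emulate: realistic amino-acid
composition or evolutionary structure (the W/Y-rich background is
compositionally artificial), borderline peaks near the MW window edge,
correlated purity/concentration noise, partially soluble samples, or
false mass-spec confirmations. Passing the planted-truth tests
demonstrates the decision logic is correct under its stated rules, not
that the rules themselves are optimal for real electropherograms.

## Numerical choices and degenerate inputs

* Windowed profiles require odd windows no longer than the sequence;
  positions whose full window does not fit get no score.
* Two-taxon NJ input returns a degenerate two-leaf tree with a warning
  rather than an error; three taxa use the closed-form branch lengths.
* An all-zero synonymous family in a usage table degenerates to the
  uniform distribution within that family.
* Deleting an entire protein in a construct is an error; a truncation
  junction computed past the C-terminus is clipped to it (and then
  errors as a full-span deletion).
* Empty peak tables, empty planted sets and header-only tables are
  valid empty inputs, not errors.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
alignment oracles at length ≤ 5 plus random pairs ≤ 40 residues, NJ on
4–12 taxa, 100 synthetic proteins of 200–400 residues, and 100
synthetic 96-well plates. These sizes exercise every code path and all
stated invariants; nothing in the implementation is specific to them.

## Known limitations

* The TM and disorder predictors are single-scale window methods; they
  will miss marginal or compositionally unusual membrane anchors that
  dedicated topology predictors catch, and the disorder call only
  reports C-terminal runs (by design — that is the construct-design
  question).
* Identity from one optimal global alignment can differ from
  search-tool identities computed on local alignments.
* Tree cutting by branch length is a proxy for expert clade judgement;
  with highly non-clock-like trees the longest internal branches need
  not separate the most meaningful groups.
* The organism-diversity rule in library assembly is greedy and
  order-dependent across bins; it maximizes coverage heuristically, not
  optimally.
* Sequence-level checks that require fetching real gene sequences from
  external databases (and codon-usage-edition-dependent flag positions)
  are outside the offline test surface.
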