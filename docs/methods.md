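# Methods

## Motif model and matching

Binding sequences are IUPAC degenerate consensus patterns (4–25 nt)
compiled from the melanocyte transcription literature, one or more per
factor.  Matching uses a uniform per-position mismatch fraction: for
pattern *p* and equal-length window *w*,

    d(p, w) = 100 · #{ i : w_i ∉ class(p_i) } / |p|,

accepted when `d ≤ max_dissimilarity_percent` (default **15**).  The
threshold's interaction with pattern length is deliberate and worth
stating: 6-mers must match exactly (1/6 ≈ 16.7% > 15), 7–13-mers may
miss one position, the 14-mer may miss two.  This is a license-free
stand-in for weighted-matrix dissimilarity scoring: it is exactly
reproducible and has no trained parameters, but it weights all positions
equally, so it is more permissive at degenerate positions' neighbours
and stricter at information-poor flanks than a true weight matrix.  An
`N` in the sequence never matches any pattern position (conservative
false-positive control; no wildcard credit).

Both strands are scanned at step 1 nt.  A span where a pattern matches
on both strands (palindromes such as the CRE `TGACGTCA`, and
near-palindromic E-boxes) is reported once, strand `+`, so cluster
counts are not doubled.  Coordinates are 1-based inclusive on the
forward strand, position 1 being the most distal base of the upstream
window; the orientation convention is recorded here because the
upstream-region sources do not state one, and all outputs can be
re-interpreted flipped if needed.

FOXD3 has no literature-transcribed binding sequence in the compiled
catalog, so it carries a forkhead-core placeholder (`TGTTTGT`,
`is_paper_sourced=False`, user-replaceable via
`MotifCatalog.replace_class`).  The placeholder was additionally chosen
so that no alignment of it against any other default plantable pattern
can match with at most one free background base — without this
property, a planted POU3F2 octamer (`ATGCAAAT`) would *always* carry an
unremovable FOXD3 match inside it (6 of 7 positions fixed, at most one
mismatch possible), and synthetic ground truth could not be made exact.
SOX10 patterns from the same literature are kept in the source for
completeness but excluded from the default catalog, which scans exactly
the six factors above.

## Collapsing

A factor is represented by several near-redundant patterns, so raw hits
are collapsed per factor: hits of one TF class are chained into
connected components by ≥ 1-base span overlap and each component keeps
its best hit (lowest dissimilarity, then leftmost, then longest).
Overlapping hits of different classes are never merged; a planted E-box
genuinely yields one MITF and one USF-1 site at the same span.  The
operation is idempotent and order-independent.

## Module detection

A candidate enhancer module is found greedily.  Over all 200-nt window
offsets, the window containing the most collapsed hits — a hit counts
only if its full span lies inside the window — and spanning at least 2
distinct TF classes is selected; ties break to the leftmost (most
distal) offset, which makes output deterministic.  The selected
interval is trimmed to the minimal span covering its member hits
(`trim_to_span`, default on), which is why reported module widths vary
(~125–300 nt) although the search window is fixed.  The trimmed
interval is added to the exclusion set and the search repeats, up to 3
modules per region; fewer is a valid outcome.

Exclusion granularity: a hit *overlapping* an excluded interval by even
one base is ineligible for later windows.  A weaker rule (only hits
fully inside an excluded interval removed) would allow a later trimmed
module to overlap an earlier one; the chosen rule makes pairwise module
non-overlap a structural invariant rather than a tendency.  Subsequent
windows may abut excluded intervals.

The window length is a single free parameter (default 200 nt) rather
than a set of variable window sizes; combined with trim-to-span
reporting this reproduces variable printed interval widths with one
parameter.  No enrichment p-value is computed for modules; the
qualification rule (≥ 2 distinct factors) is the selection criterion.

## Ortholog percent identity

`align_identity` wraps Biopython's `PairwiseAligner` with BLOSUM62 and
affine gaps (open 11, extend 1), the common protein-alignment default.
Identity is matches over alignment columns × 100; in local mode only
the locally aligned segment contributes (terminal gaps never enter the
count), in global mode every column counts.  For indel-free pairs the
optimal alignment is gapless and identity equals the fraction of
conserved positions, which is what the parameter-recovery tests exploit.
The original per-gene identities came from a BLAST best-hit web service;
exact reproduction of those numbers is out of scope, and the packaged
matrix fixture carries them as data instead.

The fixture is a 23-gene × 8-species-pair matrix.  Two garter-snake
cells (RAB38, SLC24A5) are printed as 0 in the source table but
represent absent sequences; they are loaded as *missing*, since 0%
identity is semantically wrong for a real ortholog pair.  Range
summaries (per-gene min–max over non-missing cells) reproduce the
narrative ranges that are arithmetically consistent with the matrix
(PAX3 96–99, RAB27A 90–95, TYR 71–87, PMEL min 39, KITLG max 85); for
five genes (ASIP, EDN3, MYO5A, OCA2, SLC2A9) the narrative ranges
disagree with the printed rows, and the package reports the computed
ranges and flags the discrepancy rather than matching prose to data.
The heat-map export writes `GENE (annotation)` row labels and literal
`NA` for missing cells; the annotation fixture shipped for this is
synthetic (short pleiotropy tags) and exists only to exercise the
formatting.

## Synthetic data

The generator emulates the study design the pipeline assumes: per
region, 1500 nt of i.i.d. background (default uniform base
composition), three 200-nt planted windows separated by gaps larger
than the window length, each carrying 2–5 sites of *distinct* TF
classes spread across the window (first site near the left edge, last
near the right, ≥ 3 nt apart), plus two single-factor decoy sites
centred in the inter-window gaps.  Decoys use cross-class-unambiguous
patterns and are placed so that no 200-nt interval can contain a decoy
together with a planted site; they exercise the ≥ 2-distinct-factors
rejection path without ever competing with a planted cluster.

Ground truth is the complete catalog annotation of the planted
material: every hit fully contained in a planted/decoy footprint
(a planted E-box truthfully carries both its MITF and USF-1 identity,
and a planted M-box contains its E-box core).  Background is
rejection-resampled — any scan hit extending outside the footprints has
its background bases redrawn, iterating until clean, with bounded
retries of the whole region — so `scan_region(region) == truth` holds
exactly, as an invariant rather than a probability.  A spec whose
planted material unavoidably creates out-of-footprint matches raises
`SimulationError` instead of returning approximate truth.

One integer seed drives the study; per-region sub-seeds are drawn from
the master stream, so regeneration is byte-identical across runs and
platforms.  Protein families are a random reference sequence per gene
(length 300) plus one diverged copy per species, each position
independently substituted with the species' rate to a uniformly chosen
different residue, no indels.

What the generator does **not** emulate: real squamate base
composition, repeats, CpG structure, weight-matrix score distributions,
overlapping or nested true modules, or indel evolution in proteins.
Passing tests therefore demonstrate algorithmic correctness (exact
recovery of known structure under the model's assumptions), not
predictive performance on real promoter sequence.

## Numerical and design choices

* Dissimilarity comparisons use exact rational arithmetic in effect
  (integer mismatch counts against `0.15·m`); the scanner's threshold
  test is `100·mm/m ≤ 15` with no epsilon, matching the oracle.
* Greedy tie-breaks: window selection → leftmost offset; collapse →
  lowest dissimilarity, then leftmost, then longest.
* Degenerate inputs: empty sequences are rejected; sequences shorter
  than every pattern scan to an empty hit list; an empty hit list
  yields no modules; an all-missing matrix row is an error for
  `range_summary`.
* The visualization deliberately omits strand, to-scale intra-module
  spacing, per-site length and nucleotide composition (equal-width
  glyphs packed in site order); it encodes factor identity by a fixed
  six-colour mapping (CREB green, FOXD3 magenta, LEF-1 orange, MITF
  blue, POU3F2 red, USF-1 purple), site count, linear order,
  cross-factor overlap (black outline / `*`), and module position and
  width proportional to the region.  SVG output is assembled
  deterministically so renders are byte-stable; a text renderer mirrors
  the layout for diff-friendly tests.
* Problem sizes in the test suite: oracle scans on ≤ 200-nt regions,
  exhaustive window enumeration on ≤ 30 hits, planted-cluster recovery
  over 20 seeds × 9 regions, identity recovery at length 300 × 12
  replicates — sizes chosen so the full suite completes in seconds
  while each property is exercised far past its edge cases.

## Known limitations

* Uniform mismatch scoring cannot reproduce weighted-matrix hit lists;
  real-data coordinates from matrix-based scans will differ.
* The FOXD3 placeholder is a generic forkhead core, not a validated
  FOXD3 site; results for FOXD3 should be treated as illustrative until
  a curated pattern is supplied.
* Greedy window selection is optimal per step, not globally; a
  configuration where two overlapping dense windows shadow a third is
  resolved greedily by design.
* The identity aligner reports one optimal alignment; tie alignments
  with different identities are theoretically possible under extreme
  gap configurations, though not for the indel-free families generated
  here.
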