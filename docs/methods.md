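# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators emulate, and what the tests do and
do not establish about real data.

## Discriminative motif discovery

**Model.** A motif is an exact, contiguous amino-acid substring.  The
discriminative predicate is presence in every binder and absence from
every non-binder; the shared (positives-only) predicate drops the
negative constraint.  The search substrate is the raw sequences, not
alignment columns: the predicate is pure substring membership, so the
complete answer for length k is the intersection of the binders'
k-mer sets filtered against the non-binders.  Because a shared
(k+1)-mer implies a shared k-mer, the scan over k stops at the first
empty intersection; the result provably equals exhaustive enumeration
of all substrings (the test suite checks this equivalence against a
brute-force oracle on hundreds of random instances).

**Reporting.** Motifs are grouped by length and sorted (length
descending, then lexicographic).  The headline subset is *maximal*
motifs — not contained in any other reported motif — because every
discriminative motif drags in its own discriminative substrings;
maximality reports each independent signature once.  Both views are
available (`MotifReport.motifs` vs `.maximal`; `--all` on the CLI).

**Parameters.** `min_len` defaults to 2 ("more than one residue").
Positions are 1-based inclusive.  Ambiguity codes (X/B/Z/U) are kept as
literal symbols that match only themselves, so exact-substring semantics
stay unambiguous.  Records labeled `excluded` are dropped from both
classes before the search.

## Conservation

**Alignment.** Pairwise global (Needleman-Wunsch) or local
(Smith-Waterman) alignment under BLOSUM62 with affine gap costs
`11 + 1·L` (blastp defaults), computed by Biopython's PairwiseAligner.
Co-optimal alignments are resolved deterministically by taking the
aligner's first enumerated alignment; scores are unaffected by the
tie-break and are validated against an independent recursive
dynamic-programming oracle on short sequences.

**Identity.** Default convention is matches / alignment columns (the
NCBI convention); matches / shorter-sequence is available.  Summary
statistics over ortholog panels use midpoint-of-central-pair medians
and sample (ddof = 1) standard deviations.

**Mann-Whitney U.** Two-tailed.  With pooled n <= 12 and no ties the
p-value is exact: the U null distribution is enumerated over all
C(n, nA) group assignments and the two-tailed p is the probability of a
U at least as extreme on either side.  Larger or tied samples use the
normal approximation with tie and continuity corrections
(scipy backend).  Degenerate input (all values identical) returns p = 1
with a warning.

**Trees.** Distances are `100 - identity` with no evolutionary
correction — the clustering is on conservation as measured, not on an
inferred substitution count.  Neighbor joining follows Saitou-Nei: at
each step join the pair minimizing
`Q(i,j) = (m-2)·d(i,j) - r(i) - r(j)`, ties broken by the lowest
label-index pair in row-major order; branch lengths
`l_i = d(i,j)/2 + (r_i - r_j)/(2(m-2))` with negative values clamped to
zero (deficit logged).  The result is an unrooted binary tree stored
with a trifurcating root.  On additive matrices this recovers the
generating topology and all path lengths exactly (tested to 1e-9);
an independent scikit-bio implementation serves as a cross-check in the
tests, never as the implementation.  `is_clade` asks whether some edge
bipartition of the unrooted topology separates exactly the query taxa;
singletons and the full leaf set are trivially clades.

## Binding quantification

Scanned blots are dark-on-light, so band quantities are pixel-inverted
against the image bit depth before background subtraction; the two
inversions cancel, giving `net = background_mean - raw_mean`
(negative when a band is below its local background).  Derived
quantities and their below-detection behavior:

| quantity | formula | below detection |
|---|---|---|
| percent prey recovered | prey_PD / prey_input | NaN + warning (input <= 0) |
| relative binding | (prey_PD/bait_PD) / (prey_PD/bait_PD) in reference lane | `BELOW_DETECTION` marker; rendered 0 + flag in matrices |
| bait-normalized recovery | (prey_PD/bait_PD) / same in WT lane | floor value (default 0.01) |

The floor rule guarantees no output strictly inside (0, floor): a
sub-background prey signal maps to the floor exactly and a tiny positive
ratio is clamped up to it, so plotted values never visually vanish.
Replicates aggregate by arithmetic mean over available cells; missing
lanes (NaN) are distinct from below-detection cells (0 + mask).
Linear-range eligibility of a blot is the user's call, not inferred.

## Cell-death kinetics

For frames t = 0..n with live-marker counts (mKate2+), dead-marker
counts (SG+) and double positives:

    live_n  = max(0, mKate2+_n - double+_n)
    SGmax_n = max over t<=n of SG+_t
    LF_n    = SGmax_n / (live_n + SGmax_n)

The running maximum makes LF robust to late disintegration of dead
cells; replacing the SG+ series by its own running maximum leaves LF
unchanged (idempotence, tested).  Frames where double+ exceeds mKate2+
(segmentation artifacts) clamp live at zero with a warning; frames with
zero denominator (empty field) are NaN, never silently 0, and are
omitted pointwise from the trapezoidal AUC.  The t = 0 SG+ baseline
participates in SGmax — no baseline subtraction.  Time is in hours;
the default frame interval is 4 h but arbitrary strictly-increasing
spacing is accepted.  Counts are accepted as non-negative reals rather
than strict integers so that noise-free model expectations flow through
the same code path as measured counts.

## Synthetic generators

All generators are pure functions of (spec, seed) and return ground
truth sufficient to score the downstream stage.

* **Motif families** — i.i.d. flank residues (default uniform over the
  20 standard amino acids) with the motif spliced into each positive
  exactly once (rejection-sampled) and excluded from every negative;
  decoy negatives carry a one-substitution variant.  No homology
  structure beyond the plant: chance shared flanks are possible and are
  exactly what the brute-force oracle also sees.  An impossible spec
  (e.g. a one-letter alphabet) exhausts the rejection budget and raises.
* **Ortholog pairs** — substitution-only (no indels): exactly
  `round(L·(1 - identity/100))` positions changed to a different
  residue, so measured identity equals the plant exactly.
* **Additive matrices** — random unrooted binary trees grown by
  sequential leaf attachment, branch lengths uniform (0.5, 5); the
  matrix is the exact tip-to-tip path-length table.
* **Co-IP panels** — band raw means are `background - signal` plus
  optional Gaussian noise, clipped to the bit range with a warning;
  prey pull-down signal is `occupancy x captured bait`, so with zero
  noise the normalization chain inverts exactly to the planted ratios.
* **Death model** — exponential growth at rate r until onset `t_on`,
  then constant death hazard λ with growth halted; a dead cell stays
  double positive for a dwell time τ.  Expected counts have the
  closed form `live(t) = N0·e^{r·t_on}·e^{-λ(t-t_on)}` after onset and
  analytic LF = dead/(live+dead).  Defaults (N0 = 500, r = 0.02/h,
  t_on = 24 h, λ = 0.08/h, τ = 4 h, 4-h frames to 96 h) give a
  realistic sigmoid course reaching LF ≈ 1.  The model is deliberately
  minimal: its only job is count streams with a known LF.  Poisson
  sampling is hierarchical (live, recently dead and older dead sampled
  separately, SG+ = recent + older, mKate2+ = live + recent) so the
  count-ordering invariants hold by construction.

## The synthetic stand-in panel

No sequence database is bundled, so the worked examples run on a
generated stand-in panel (`palmkit.synthetic_panel`, labelled synthetic
throughout).  Record ids reuse the real accession strings for drop-in
compatibility, but sequences are random backgrounds with planted
structure: RNYR spliced into the six binder stand-ins (position 144 in
the Zdhhc5 stand-in), RNFR at 152 in the Zdhhc19 stand-in, RDYS at
16/25 in the GOLGA7/GOLGA7B stand-ins with forced flanking mismatches
(so RDYS itself, not an extension, is the maximal shared motif), and
per-gene mouse-human identities fixed once so the panel reproduces the
published summary statistics (median 93, range 60-99, binder mean 94,
non-binder mean 89, Zdhhc5 pair 98, GOLGA7/GOLGA7B 79).  The GOLGA7B
stand-in adds a 9-residue N-terminal extension to reproduce the 16→25
motif offset.

What passing on the panel shows: the full computation path — alignment,
identity, rank test, k-mer search, maximality, position reporting —
recovers planted structure through the same code a user runs on real
FASTA input.  What it does not show: anything about real ZDHHC
sequences; random backgrounds lack the family's homology, so e.g. the
binder clade observed in the real conservation tree is reported by the
pipeline but asserted only on additive synthetic matrices, where tree
reconstruction is exact.

## Numerical choices and problem sizes

Fixed 6-decimal branch lengths and sorted-key JSON make every report
byte-stable.  Exhaustive-search equivalence is checked on 200 random
instances (<= 8 sequences, length <= 60, alphabets of 4 and 20 letters);
planted-motif recovery on 100 seeded families (length-5 motif, 6 vs 17
sequences of length 300); neighbor joining on 100 additive matrices of
4-8 taxa; Poisson lethal-fraction agreement on 100 seeded courses
(mean within 3 standard errors of the analytic curve per frame).  These
sizes give sub-minute, deterministic runs while leaving the checks
statistically meaningful.

## Known limitations

* Exact motifs only: no degenerate positions, PWMs, gaps or enrichment
  statistics — the discriminative predicate is presence/absence.
* Pairwise alignment only; no progressive MSA, bootstrap support or
  model-based phylogenetics.
* The binding module consumes intensity tables, not images; ROI drawing
  and segmentation happen upstream.
* The death model ignores cell-cycle structure, spatial effects and
  marker-expression variability; it is a scoring oracle, not a
  biological model.
* Local-alignment percent identity depends on the aligned region; for
  length-mismatched pairs the columns convention is sensitive to
  end-gap placement (the global default includes end gaps in the
  denominator).
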