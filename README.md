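# palmkit

Analysis toolkit for mapping the sequence determinants of
ZDHHC-family acyltransferase / GOLGA7 accessory-protein complexes, and
for quantifying the biochemical and cell-death readouts used to test
them.

## The scientific problem

Protein *S*-acylation (palmitoylation) is catalyzed by the 23-member
ZDHHC enzyme family, defined by an Asp-His-His-Cys (DHHC) active-site
motif.  Some ZDHHC enzymes require small accessory proteins — GOLGA7, its
paralog GOLGA7B, or the yeast counterpart Erf4 — to form functional
complexes; the ZDHHC5-GOLGA7 complex in particular drives a nonapoptotic
cell-death program.  Only a subset of the family binds GOLGA7, raising a
sharp sequence question: **what distinguishes the binders?**

palmkit implements the computational side of that question as four
reusable stages:

1. **Discriminative motif discovery** — given protein sequences labeled
   *binder* / *non-binder*, find every exact substring `m` with
   `|m| >= 2` such that `m` occurs in **all** binders and in **no**
   non-binder.  Motifs are grouped by length; the headline output is the
   *maximal* subset (motifs not contained in any other reported motif),
   so a family signature like RNYR is reported once rather than
   alongside its own substrings.  A positives-only mode finds motifs
   shared by a small family (e.g. GOLGA7 vs GOLGA7B) with no negative
   set — the mode that exposes the shared RDYS motif.
2. **Conservation statistics** — pairwise percent identity
   (`100 x matches / alignment columns` under BLOSUM62, affine gaps
   11/1, global or local), ortholog panel summaries, a two-tailed
   Mann-Whitney U test (exact by enumeration for pooled n <= 12 without
   ties, normal approximation with tie/continuity corrections
   otherwise), and a neighbor-joining tree (Saitou-Nei Q-criterion) on
   `d = 100 - identity` distances with clade queries on the unrooted
   topology.
3. **Co-IP binding quantification** — immunoblot densitometry with pixel
   inversion and background subtraction (`net = background - raw`),
   percent prey recovered (`prey_PD / prey_input`), reference-normalized
   relative binding `(prey_PD/bait_PD) / (prey_PD_ref/bait_PD_ref)`, and
   WT-relative bait-normalized recovery with a 0.01 floor for
   sub-background signals.
4. **Cell-death kinetics** — the lethal fraction from live (mKate2+),
   dead (SG+) and double-positive object counts,

   `LF_n = SGmax_n / (live_n + SGmax_n)`, `live_n = mKate2+_n - double+_n`,

   where `SGmax_n` is the running maximum of the SG+ count over frames
   0..n, plus an SG-only mode and endpoint summaries (max LF, time to
   LF >= 0.5, AUC).

A fifth module provides seeded **synthetic generators** with recorded
ground truth for every input class (motif families with near-miss
decoys, substitution-only ortholog pairs of controlled identity,
additive distance matrices, co-IP band tables, death time courses with a
closed-form LF), and a **synthetic stand-in panel**
(`palmkit.synthetic_panel`) that emulates the real 23-enzyme panel —
RNYR planted in the six binders (residues 144-147 of the Zdhhc5
stand-in), RNFR in the Zdhhc19 stand-in, RDYS at positions 16/25 of the
GOLGA7/GOLGA7B stand-ins, and per-pair mouse-human identities fixed to
the published summary statistics.  See `docs/methods.md` for what the
stand-ins do and do not establish.

## Worked example

```sh
python examples/02_panel_run.py
```

prints

```
binder-specific maximal motifs: ['RNYR']
  RNYR in Zdhhc5 stand-in at: (144,)
accessory shared motif RDYS at: {'Q7Z5G4': (16,), 'SYN-GOLGA7B': (25,)}
mouse-human identity: median 92.9% (range 60.0-99.0%)
binders 94.0% vs nonbinders 89.0%: Mann-Whitney p = 0.151
```

Reading the numbers: the motif search over the labeled panel finds
exactly one maximal binder-specific motif (RNYR), located at residues
144-147 of the Zdhhc5 stand-in; the accessory-protein comparison finds
RDYS at position 16 of GOLGA7 and 25 of GOLGA7B; and overall mouse-human
conservation does **not** separate binders from non-binders (p > 0.05) —
the discriminative motif does, which is the point of the analysis.

The other examples (`examples/01...05`) each demonstrate one stage:
motif discovery on a simulated family, identity/tree recovery on
controlled inputs, binding-matrix construction, and lethal-fraction
kinetics.

There is also a thin CLI:

```sh
palmkit run --out results/panel        # full sequence-stage run
palmkit motifs --fasta panel.fasta --labels labels.tsv --out report.json
palmkit lf --counts counts.csv --mode dual --out lf.tsv
palmkit simulate death --seed 3 --out sim/
```

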