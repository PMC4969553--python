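# Methods

## Scope and assumptions

`nonbscan` annotates linear DNA sequences with two non-B DNA motif classes
and provides the statistics used to relate them to genetic-instability
data. It is a *sequence-pattern* engine: it asserts nothing about whether a
motif actually adopts H-DNA or Z-DNA in a given cell (supercoiling, pH,
divalent cations and chromatin all matter in vivo and are out of scope), it
does not model triplex thermodynamics or B–Z transition energetics, and it
does not search for cruciform-forming inverted repeats or G-quadruplexes,
for which dedicated tools exist.

All internal coordinates are 0-based half-open; BED input and GFF3 output
are converted at the file boundary only. N bases are retained but never
match anything: they terminate purity runs and alternation runs alike.
Soft-masked (lowercase) input is uppercased by default; `respect_mask`
converts masked runs to N so they cannot seed or extend a tract.

## H-DNA: mirror repeats in homopurine/homopyrimidine context

A candidate is `arm1 + spacer + arm2` with `arm2[i] = arm1[L-1-i]` — the
arms are reversals of each other on the *same strand*, the geometry needed
for a strand to fold back and form Hoogsteen pairs in the major groove.
Both arms must be drawn from one purity class ({A,G} or {C,T}); the spacer
is the unpaired hinge and is unconstrained by default (`require_pure_spacer`
restricts it to the arm class for users who want conservative calls — the
hinge does not pair, so purity there is not mechanically required).

Parameters (defaults):

| parameter | default | units | role |
| --- | --- | --- | --- |
| `min_arm` | 6 | bp | shortest arm that can form a stable triplex stem |
| `min_spacer` / `max_spacer` | 1 / 12 | bp | hinge length; longer hinges destabilize the fold-back |
| `mismatch_arm_threshold` | 10 | bp | arm length from which one symmetry mismatch is tolerated |
| `max_mismatches` | 1 | — | mismatch budget for the whole arm pair |
| `require_pure_spacer` | false | — | restrict the hinge to the arm's purity class |

Mismatch accounting: one budget for the whole arm pair; a "mismatch" is a
symmetry violation between paired positions whose bases both still satisfy
the arm's purity class — an out-of-class base is not a mismatch, it
truncates the arm. The gate is applied to the *final* arm length, so a
10 bp arm may place its single mismatch anywhere, including the outermost
pair.

Maximality and redundancy: arms of a candidate grow symmetrically outward
from a fixed spacer placement, so for each (spacer position, spacer length)
exactly the longest admissible arm is a candidate hit (because the
admissible set along the growth path can be non-contiguous — a mismatch
consumed at arm 9 may become affordable at arm 10 — "longest admissible"
is evaluated against the budget at each final length). A hit wholly
contained in another hit with at least its arm length is then suppressed.
Without suppression a poly-purine run of length n yields O(n) nested
variants of the same physical motif; with it, planted and biological motifs
come out as discrete intervals.

The production scanner prunes using per-position purity-run lengths
(a candidate spacer needs a ≥ `min_arm` same-class run on each side), then
grows arms positionally; `brute_force_mirror_repeats` enumerates every
(spacer, arm) placement on raw string slices and applies the same rules
literally. The suite holds the two to exact equality on hundreds of seeded
random sequences, on near-homopolymer stress inputs, and on N-containing
sequences.

## Z-DNA: phased dinucleotide scoring

Within each maximal alternation run (adjacent bases always one purine, one
pyrimidine; runs shorter than `min_tract_len` = 6 are skipped, 6 being the
shortest fragment that can reach the default threshold), the run is
partitioned into non-overlapping dinucleotide steps at phase 0 or phase 1.
Step weights: GC/CG = 25, GT/TG/CA/AC = 3, AT/TA = 0, threshold 75.
Complementary/reversed step spellings share one weight because the two
strands of a step are chemically the same unit; AT steps are formally
alternating but are given zero weight by default (configurable via
`score_at`) since A/T alternation is a poor Z-former. Steps are
non-overlapping because the Z helix's syn/anti repeat unit is the
dinucleotide; overlapping counting would double-weight interior bases and
break the identity "(GC)₃ = 75 = threshold".

The better-scoring frame is reported, frame 0 on ties; the hit interval
covers exactly the scored steps (an unpaired flanking base is excluded).
All weights are non-negative, so the maximal-scoring segment of a frame is
its whole stepped span — one hit per tract at defaults;
`subsegments=True` emits every frame whose span passes the threshold.
One consequence of the deterministic frame-0 tie-break: when a tract's two
frames tie, the spans chosen on a sequence and on its reverse complement
are mirror images, so reflected coordinates can differ by the single
unpaired base (scores and step counts are always identical).

## Co-localization and permutation enrichment

`count_colocalized` counts breakpoints having ≥ 1 motif within ± `window`
bp (edge distance, half-open arithmetic; containment is distance 0). The
null repositions *breakpoints* uniformly within their region — motif
positions are intrinsic sequence properties and stay fixed — independently
per permutation; regions default to whole sequences and can be supplied
(e.g. gene bodies) to condition the null. The empirical p-value uses the
add-one rule `(1 + #{null ≥ obs}) / (1 + N)`, which is never exactly zero
and is mildly conservative for discrete counts. Joint analyses of several
windows (e.g. 100 and 200 bp) are Benjamini–Hochberg corrected;
single-window runs are not. Distances are measured to motif edges, not
centers, matching the "within ± N bp of the motif sequence" reading.

Calibration: the suite verifies type-I error at α = 0.05 over 500 null
datasets on a layout chosen so the count statistic has rich support — a
100 kb region, 200 motif intervals of 30 bp (windowed coverage ≈ 0.46),
400 breakpoints, 200 permutations. With sparse coverage or few breakpoints
the discrete statistic ties often and the add-one p becomes conservative
(observed rates drop toward 0.02–0.03); that regime is a property of the
estimator, not an error, but it cannot demonstrate near-nominal
calibration, so the calibration check runs where near-uniform p-values are
attainable. GC- or replication-timing-matched nulls are out of scope.

## Assay statistics

Mutation frequency is FOA-resistant colonies / total colonies (times an
optional dilution factor for differential plating volumes); no
Luria–Delbrück rate correction is applied — frequencies, not rates, are
the reported quantity, and an m-estimator is deliberately out of scope.
Fold induction is mean(structure) / mean(control). Its standard error uses
per-replicate structure:control ratios when replicates pair up (equal
counts, matching replicate ids, non-zero control frequencies) and the
delta method on the two group means otherwise; a zero control mean yields
NA with a warning rather than infinity. Pooled single-plating counts and
per-culture replicates are both supported.

## Synthetic data

`simulate.generate_sequence` plants motifs in an i.i.d. background of
chosen GC content. Each plant is flanked by two **guard bases** chosen to
break the relevant structure — opposite-class bases around mirror-repeat
arms, same-class bases at alternating-tract ends — so the planted geometry
is provably maximal and the scanners must report it at exact coordinates.
Mirror-repeat spacers are drawn from the opposite purity class so the arms
are exactly the purity runs. At default search parameters a planted mirror
repeat spans ≥ 13 bp, longer than any admissible spacer, so no
background-assisted hit can contain (and hence suppress) it.

`generate_breakpoints` places `round(association · n)` points uniformly
within ± window of a random planted motif and the rest uniformly;
`generate_assay_counts` draws binomial colony counts at a known fold.
Everything is deterministic per seed.

What the background does *not* emulate: higher-order composition
(CpG islands, isochores), repeat families, chromatin or replication-timing
structure. Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under a neutral background — not performance on
real promoter sequence, where motif density and clustering differ.

## Numerical and degenerate-input choices

- Sequences shorter than `2·min_arm + min_spacer` return no mirror hits
  without error; empty FASTA files parse to empty lists.
- Hit ordering is (start ascending, arm length descending, spacer
  ascending) for mirror repeats, (start, score descending) for Z hits;
  GFF3 emission orders (seq_id, start, longer-first).
- BED records wider than 1 bp are reduced to floor((start+end)/2) with a
  warning — breakpoints are points.
- Scores are plain floats; all default weights are small integers so no
  floating-point comparison tolerance is needed at the 75 threshold.
- Permutation draws iterate sequences in sorted order so results are
  reproducible across processes regardless of hash randomization.

## Problem sizes in the test suite

Oracle-equivalence runs use 500 random sequences of length 100–500 (both
scanners, exact equality); planted-recovery runs use 200 datasets of
2.5 kb with three plants each; the calibration study uses 500 datasets at
200 permutations; the throughput check scans 1 Mb with both engines
(≈ 1 s total on one core, asserted < 60 s).
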