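# nonbscan

Non-B DNA motif discovery and genetic-instability co-localization toolkit.

Repetitive DNA can leave the canonical right-handed B-form duplex:
homopurine·homopyrimidine **mirror repeats** can fold into intramolecular
triplexes (**H-DNA**), and alternating purine–pyrimidine tracts — above all
GC and GT/CA repeats — favor left-handed **Z-DNA**. Both structure classes
cluster at mutation and translocation hotspots, e.g. in the *c-MYC* and
*BCL-2* promoter/breakpoint regions, and both are mutagenic in reporter
assays. `nonbscan` is for researchers who want to (1) annotate sequences
with these two motif classes under a fixed, published parameterization,
(2) test whether mapped breakpoints cluster around the motifs, and (3)
summarize yeast-artificial-chromosome (YAC) fragility assays that measure
structure-induced breakage.

## The scanners

**H-DNA (mirror repeats).** A hit is `arm1 + spacer + arm2` where
`arm2 = reverse(arm1)` on the same strand (*mirror* symmetry — no
complementation; reverse-complement symmetry would be an inverted repeat,
a different structure), both arms are homopurine or both homopyrimidine,
and at defaults:

- arm length ≥ 6 bp,
- spacer length 1–12 bp (spacer composition unconstrained; `--pure-spacer`
  restricts it),
- one symmetry mismatch allowed only when the arms are ≥ 10 bp, and the
  mismatched base must still respect the arm's purity class.

For each spacer placement the longest admissible arm is reported, and hits
wholly contained in a hit with at least their arm length are suppressed, so
poly-purine runs yield discrete motifs rather than a combinatorial flood.

**Z-DNA.** Within each maximal alternating purine/pyrimidine tract the
sequence is partitioned into non-overlapping dinucleotide steps in the
better of the two phases; each GC/CG step scores 25, each GT/TG/CA/AC step
scores 3, AT/TA steps score 0. A tract is reported when its best-frame
total reaches 75 — so (GC)₃ is the shortest qualifying GC repeat and
(CA)₂₅ the shortest qualifying CA repeat.

Both scanners ship with brute-force reference implementations
(`brute_force_mirror_repeats`, `brute_force_zdna`) that the test suite
holds to exact agreement on hundreds of random sequences.

**Co-localization.** A breakpoint at position *p* co-localizes with a motif
when the motif overlaps *p* ± *w* bp (defaults offered: 100 and 200).
Enrichment is assessed by repositioning breakpoints uniformly within their
region; the empirical p-value uses the add-one rule
`p = (1 + #{null ≥ observed}) / (1 + N)`.

**Assay statistics.** Mutation frequency = FOA-resistant colonies / total
colonies; fold induction = structure frequency / control frequency, with a
paired-ratio or delta-method standard error across replicates.

## Worked example

Generate a 600 bp synthetic sequence with two planted motifs — a 10 bp-arm
mirror repeat with a 3 bp spacer and one symmetry mismatch, and a (GC)₅
tract — then scan it:

```python
from nonbscan import PlantSpec, PlantedMotif, generate_sequence
from nonbscan.seq_io import write_fasta

spec = PlantSpec(
    seq_len=600,
    motifs=(PlantedMotif("mirror_repeat", arm_len=10, spacer_len=3, mismatches=1),
            PlantedMotif("zdna_gc", n_steps=5)),
    seed=11,
)
rec, truth = generate_sequence(spec)
write_fasta([rec], "demo.fa")
```

```bash
nonbscan scan --fasta demo.fa --out demo_hits.gff3 --tsv demo_hits.tsv
cat demo_hits.tsv
```

```
seq_id	type	start	end	arm_len	spacer_len	mismatches	tract_type	score
sim	triplex_motif	188	211	10	3	1	purine	
sim	Z_DNA_motif	401	411					125.0
```

The mirror repeat is recovered at exactly its planted coordinates
(0-based [188, 211) = 10 + 3 + 10 bp) with its one mismatch, reportable
because the arms reach the 10 bp gate; the (GC)₅ tract scores
5 × 25 = 125 ≥ 75. The GFF3 output carries the same hits 1-based
(`triplex_motif` 189–211 with the arm sequences in the attributes;
`Z_DNA_motif` 402–411, score 125).

Enrichment of breakpoints around hits, and assay summaries:

```bash
nonbscan colocalize --motifs demo_hits.gff3 --breakpoints bp.bed \
    --window 100 --window 200 --n-perm 1000 --seed 17 --fasta demo.fa \
    --out enrichment.tsv
nonbscan assay-stats --counts counts.tsv --out screen.tsv
```

## Layout

| module | contents |
| --- | --- |
| `nonbscan.seq_io` | FASTA/BED/GFF3 I/O, `SequenceRecord`, coordinate conventions (0-based half-open internally) |
| `nonbscan.hdna` | mirror-repeat scanner + brute-force oracle |
| `nonbscan.zdna` | alternating-tract scanner, dinucleotide scoring + oracle |
| `nonbscan.colocalize` | window co-localization counts, permutation enrichment, distance profiles |
| `nonbscan.assay` | mutation frequency, fold induction, screen summaries |
| `nonbscan.simulate` | synthetic sequences with guard-protected planted truth |
| `nonbscan.cli` | `nonbscan` subcommands: `hdna`, `zdna`, `scan`, `colocalize`, `assay-stats`, `simulate` |

See `docs/methods.md` for the model assumptions, parameter rationale, and
known limitations.
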