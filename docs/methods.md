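# Methods

This note records the models, parameter choices and numerical conventions
behind `flavoscan`, and what the synthetic cohorts do and do not establish
about real genomes.

## Transcriptional-unit prediction

Genes on one replicon, sorted by start, are partitioned greedily: two
adjacent genes join the same unit iff they share a strand and either their
intergenic distance is ≤ `d_max` or their functional-linkage score is
≥ `link_min`. Published distance/linkage operon predictors do not agree on a
single numeric threshold, so both are explicit configuration: `d_max`
defaults to 50 bp (a conventional same-operon spacing bound) and `link_min`
to 0.8 on a [0, 1] STRING-like score. Overlapping same-strand genes are
treated as distance 0 and merge — overlap is stronger evidence of
co-transcription than a short gap. A strand change always breaks a unit.
Unit gene lists are stored in transcription order (reversed genomic order on
the − strand). The greedy pairwise rule makes two properties exact by
construction: units partition the gene set, and raising `d_max` can only
merge, never split (tested as monotonicity of the unit count).

Upstream windows default to 350 nt: generous for a ~120–160 nt riboswitch
plus spacer, and configurable. Windows truncate at linear replicon edges
(a unit at position 0 has an empty window, not an error) and wrap on
replicons flagged circular.

## Riboswitch scanning

A covariance model scores both sequence and secondary structure; that
machinery is out of scope here. What the pipeline actually consumes is the
*contract* of such a search — a bit score per upstream region and a fixed
acceptance cutoff — so the scanner is an ungapped position-wise log-odds
profile: `log2` of pseudocounted match frequency over background, summed
over the best placement in the window. Ties go to the smallest offset;
non-ACGT positions contribute 0 bits (their background expectation); a
window shorter than the profile is scored at the single truncated placement.
Profile building drops training columns with > 50% gaps and applies Laplace
pseudocounts (default 1.0) so small training sets stay finite; with
pseudocount 0 zero frequencies are floored at 1e-9 rather than −∞.

The default cutoff is 51.34 bits and is kept configurable.
`calibrate_cutoff` re-derives a cutoff as the minimum score over an anchor
set of riboswitches known to sit on biosynthesis operons — the same rule
that produced the default — and the pipeline reports this re-calibration on
every synthetic run without applying it. One hit (the best placement) is
reported per transcriptional unit, since the downstream tallies count
riboswitch-regulated units, not placements; multi-hit reporting is behind a
flag.

## Orthology

Candidates are compared to one prototype protein per transporter family by
exact affine-gap Smith–Waterman (BLOSUM62; a length-g gap costs
`11 + g`). With desk-scale proteomes, an exact aligner is affordable and
removes the external-binary dependency a heuristic search would impose; the
identity/coverage contract is unchanged. Determinism is pinned down
explicitly because identity depends on the traceback chosen among co-optimal
alignments: the end cell is the highest-scoring cell with smallest
(row, col), and traceback prefers diagonal, then vertical gap, then
horizontal, with gap closure preferred over extension. Identity is matches
over aligned columns (gap columns count); coverage is the fraction of the
*prototype* covered — "total sequence coverage" is ambiguous in the
literature, so the denominator is configurable (query/subject/mutual) with
subject as default, since the prototype is the calibrated reference.

Acceptance floors: identity strictly greater than 0.38 ("more than 38%")
and coverage at least 0.80 ("80% or more"); the RfnT family uses 0.42/0.90.
A candidate within `margin` (default 0.05) below the identity floor is
accepted only when its transcriptional unit carries a riboswitch hit,
mechanising the one evidence-adjustment that can be stated as a rule; such
calls carry a `threshold_override` flag and are logged, never silent. The
other manual adjustments (synteny, operon structure) are reported as
evidence fields, not applied. A gene passing two families keeps the
higher-identity family. Composite systems (RibXY, ECF-RibU, RfuABCD) are
represented by their substrate-binding component (RibY, RibU, RfuA) alone.

Supporting evidence per call: a bi-directional-best-hit flag (reciprocal
best scores between the genome's proteome and the prototype set) and a
Markov-cluster id. MCL runs on the candidate–prototype similarity graph
with edge weights = alignment score normalised by the prototype self-score —
a database-free substitute for e-value weighting — with expansion 2,
inflation 2.0 (configurable), pruning at 1e-5 and attractor-based cluster
extraction; disconnected components can never merge.

## Co-occurrence

A genome counts as a riboflavin producer only when both marker families
(COG0054-like lumazine synthase and COG0307-like riboflavin synthase, the
last two pathway steps) are annotated; a single-marker genome is reported
non-producer with a `partial_rbp` flag rather than silently rounded either
way. The four categories partition the cohort, and
`transporter_total = RBP+transporter + transporter-only` holds by
construction (property-tested). Counts are genome-level: the input taxonomy
table supplies phylum labels and nothing is deduplicated to species, because
mixing the two silently is worse than stating the unit. The distribution
matrix marks (or counts) phylum × (family, RBP±) cells only when a
supporting record exists.

## Phylogeny

Alignment columns with gap fraction ≥ 0.75 are removed (the boundary is
removal-inclusive, so a 4-taxon column with 3 gaps goes). Distances use the
Kimura protein correction `d = −ln(1 − p − 0.2p²)` on the mismatch fraction
over mutually ungapped columns — closed-form and dependency-free, adequate
for a display tree; the matrix backend is pluggable if a likelihood distance
is wanted. Saturated pairs (argument ≤ 0, p ≳ 0.854) are capped at a
configurable maximum (default 10.0) with a warning. Zero comparable columns
is an error for the base matrix but a skipped replicate during bootstrap.

Neighbor joining uses the Q criterion with branch lengths
`l_i = d_ij/2 + (r_i − r_j)/(2(n−2))`; ties on Q break lexicographically on
the (sorted) pair of tie labels, an internal node inheriting the smaller
child label, so the topology is deterministic. Negative branch lengths are
clamped to 0 with a warning. On additive matrices the algorithm is exact
(tested to 1e-9 on a 4-taxon matrix and cross-checked against an independent
NJ implementation on random matrices). Bootstrap resamples masked columns
with replacement under a fixed seed and maps bipartition frequencies onto
the full-data tree as percent supports.

## Synthetic cohorts

The generator emulates exactly the structure downstream stages assume, with
one random stream per genome derived from the master seed, so identical
configurations are byte-identical on disk.

* **Layout.** Each genome is one linear replicon of operon blocks: planted
  transporter monocistrons (sorted by family), a two-gene marker operon when
  the genome is a producer, then filler operons of 1–3 random genes.
  Same-operon gaps average 20 bp; between-operon gaps average 500 bp with a
  400 bp floor. The floor exceeds the 350 nt scan window so a planted motif
  can never fall inside a neighbouring unit's window, and the 20/400
  separation brackets `d_max = 50` so unit prediction can recover the
  planted operon structure exactly — the regime the recovery tests assume.
  Intergenic DNA is i.i.d. uniform over ACGT unless a GC fraction is set.
* **Sequences.** Proteins are i.i.d. uniform over the 20 residues; coding
  DNA is a fixed one-codon-per-residue back-translation plus a TAA stop
  (codon usage is a non-goal). Family prototypes are seeded synthetic
  stand-ins of 110–190 aa, stable across cohorts.
* **Identity control.** `mutate_to_identity` substitutes
  `round((1−t)·L)` distinct positions uniformly over the 19 alternatives,
  realising the global identity target exactly up to rounding (indels are
  available but default off, within the 5%-of-length budget). Note that
  *local*-alignment identity runs slightly above the substitution rate
  because optimal alignments trim mismatching ends; tests that exercise the
  acceptance floors therefore plant candidates at measured local identity.
* **Motif control.** The riboswitch training alignment draws per-column
  mutation rates from U(0.05, 0.4), giving the profile a graded score
  landscape; `sample_motif` walks from the consensus by greedy base swaps to
  within ±0.5 bits of the target (contract: ±2). Planted levels default to
  U(56.34, 76.34) bits — at least 5 bits above the cutoff — on every true
  transporter unit and (p = 0.8) on the marker operon, which provides the
  calibration anchors. Random windows score far below the cutoff (the
  expected per-position log-odds of background sequence is negative), giving
  the <1% false-hit regime the scan tests verify.
* **Decoys.** With probability 0.3 a genome carries a decoy transporter gene
  at identity 0.20, well below every floor, so ortholog evaluation has true
  negatives.
* **Markers for the tree.** A 120-aa root protein evolves along a star with
  per-genome rates U(0.05, 0.3) — enough signal for a display tree, with no
  indels, so the "alignment" is trivially correct.

What passing tests on these cohorts show: the pipeline's logic, thresholds,
coordinate arithmetic and bookkeeping are correct under the stated
generative assumptions. What they do not show: performance on real genomes,
where riboswitches diverge structurally from any profile, operon spacing
distributions overlap, homology is phylogenetically correlated rather than
i.i.d., and annotation is noisy. The generator deliberately omits codon
usage, correlated evolution and genuine covariance-model sampling.

## Problem sizes and defaults

End-to-end checks use 30-genome cohorts (12 genes/genome) and scan-level
checks 20 genomes at 50 genes/genome (≥ 500 riboswitch-free windows); these
sizes give stable 0/100% outcomes for the planted effect sizes while keeping
an exact aligner practical. All thresholds above (`d_max` 50, window 350,
cutoff 51.34, floors 0.38/0.80 and 0.42/0.90, margin 0.05, inflation 2.0)
are surfaced in one YAML config and echoed with file checksums in the run
manifest; reruns with an identical config are checksum-identical.

## Known limitations

* The profile scorer ignores secondary structure; its bit scores are not
  comparable to covariance-model scores in absolute terms — only the
  score-plus-cutoff mechanism is preserved.
* Coverage of the prototype is one of three defensible readings of "total
  sequence coverage"; switching the denominator changes borderline calls.
* The riboswitch-linked rescue is the only mechanised threshold adjustment;
  synteny- or experiment-based adjustments must be made by the caller.
* Category counts are genome-level; species-level tallies require
  deduplication upstream.
* NJ with Kimura distances is a display-quality tree, not an inference of
  evolutionary history.
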