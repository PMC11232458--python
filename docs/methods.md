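# Methods

This note documents the models and procedures implemented in `svlr`, the
parameters that matter, the numerical conventions, and what the synthetic
data does and does not emulate.

## Signature collection

Alignments are read from coordinate-sorted BAM through pysam; secondary and
unmapped records are dropped, supplementary records kept. Records with
mapping quality below a floor (default 20, the convention of comparable
long-read callers) are excluded uniformly — both as primary evidence and as
split-read partners.

**Intra-alignment signatures.** Each I/D CIGAR operation of at least
`min_size` (default 30 bp) becomes an INS/DEL signature at its reference
locus; for INS the span encodes the inserted length (e = s + length).
Adjacent same-type gaps of ≥ 20 bp separated by < 150 bp of matched sequence
are merged first, so fragmented evidence for one event survives clustering;
the 20 bp candidate floor keeps scattered 1–15 bp sequencing indels from
merging into phantom events. Signatures are collected down to 30 bp although
only ≥ 50 bp calls are reported, so borderline events with fragmented
evidence are not lost before clustering.

**Inter-alignment signatures.** The aligned segments of one read (primary +
supplementary records, with SA-tag entries filling gaps in regional fetches)
are ordered by query offset (hard clips converted; ties broken by reference
position). Every adjacent pair is classified by deliberately lenient rules:
different contigs → TRA; opposite strands → INV; a reference backtrack of
≥ min_size on the same strand → DUP; otherwise the sign of (reference gap −
read gap) separates DEL from INS, with the magnitude as the SV length.
No further heuristics are applied — separating noise from signal is the
random forest's job. Two conventions are worth noting:

* INV span: the pair's two read-order breakpoints (where the first segment
  stops and the second resumes on the reference) bracket the inverted
  interval exactly for reads entering, leaving or spanning an inversion, so
  the signature span is [min(bp), max(bp)]. This is exact in all three read
  geometries, unlike taking the inverted segment's own interval.
* A 100 kb ceiling on inter-signature spans. Chimeric alignments otherwise
  pair into megabase-scale pseudo-signatures whose span-relative similarity
  lets unrelated noise cluster into supported false calls. Comparable
  callers ship the same cap as `max_size`.

**Feature vectors.** 25 intra features (9 global-alignment: mapq, clip
lengths, indel-op counts, edit distance, read length, aligned fraction,
supplementary count; 6 CIGAR-local: gap offsets in read and reference, gap
length and type, distance to the nearest other large gap, large-gap count;
10 base-distribution: ACGT frequencies of the read and of a ±100 bp window
around the gap, plus the repeated-base frequency of each, where a position
counts as repeated when it lies in a homopolymer run of ≥ 5). 22 inter
features (8 global, 9 split-geometry, 5 base-distribution). The feature
name lists are part of the public schema; model bundles store a schema hash
and refuse to load against a different layout. Records without a sequence
get zero base-distribution features rather than failing.

## Adaptive clustering

Signatures of one type are sorted by (contig, start) — translocations by the
ordered contig pair — and swept into partitions: a new partition opens when
the spatial distance to the previous signature exceeds 1000 bp. For
interval-shaped types the spatial distance is the end-to-start gap clamped
at zero for overlapping spans (an absolute-value form would place all
signatures of any event longer than the partition gap into separate
partitions and make large events uncallable); for point-anchored types it is
the start-to-start distance.

Per type, the global depth GD is the mean partition size, computed
genome-wide. Within each partition of local depth LD, the scale

    λ = |GD − LD| / max(GD, LD) + GD,  clamped to ≥ 1,

balances locus distance against span distance in the similarity

    S(i, j) = (pos_dis/λ + span_dis) / max(span_i, span_j),

with pos_dis the midpoint distance and span_dis the span difference.
Average-linkage hierarchical clustering (scipy) merges while the linkage
distance stays strictly below 0.3. Consensus breakpoints and length are
lower medians (determinism for even counts); support is the count of
distinct read names.

Breakend evidence has no span, so Eq-form S is undefined for TRA. We use
S = pos_dis / (λ · 100): the 100 bp nominal span sets the breakpoint
resolution at which one junction's jittered signatures still merge. A raw
pos_dis/λ form (merge radius 0.3·λ bp ≈ 2–6 bp) fragments every junction
cluster below the support threshold once alignment jitter exceeds a few bp.
TRA pos_dis takes the worse of the two junction-side distances.

## Learned filters

**Random forest (before clustering).** Inter-signature vectors are min-max
normalized with bounds frozen at training time (inference clips to [0, 1]);
a grid over tree depth {2,4,6,8,10}, forest size {10,25,50,75,100} and
minimum split size {10,25,50,75,100} selects the model with the best
held-out macro-F1 (25% stratified hold-out, seeded). "false" predictions
are removed; a predicted type different from the rule-inferred one relabels
the signature (the INS/DUP boundary is genuinely fuzzy in read space), except
across the breakend/span divide, where coordinates are not convertible and
the rule-inferred geometry is kept.

**CNN (after clustering).** Intra-sourced DEL/INS clusters become (100, 25)
matrices: rows are member feature vectors ordered by start, zero-filled
beyond the cluster size; clusters above 100 keep the 100 members nearest the
consensus breakpoint. Clusters of depth 1–20 are augmented at training time:
each member serves as a window start with a wrap-around window smaller than
the depth. The network is three convolutions with kernels 3×25, 3×8 and
3×1, each followed by (2,1) max-pooling, then FC 256 → 64 → 3 with batch
normalization and dropout 0.5, softmax over {DEL, INS, false}; training uses
cross-entropy, Adam at 1e-3 with ×0.1 step decay every 5 epochs, batch 256,
15 epochs. Kernel geometry: the first convolution collapses the 25-feature
axis into 8 channels; those channels become the width of the second
convolution's input, so the 3×8 kernel mixes them while sliding along the
signature axis, and the 3×1 kernel is a plain multi-channel temporal
convolution. The network is implemented directly in numpy (im2col
convolutions with analytic gradients); training is deterministic under its
seed. DUP/INV/TRA clusters and clusters without intra evidence pass through
unfiltered — the class set forces this.

**Labels.** Training items are matched to truth SVs within 500 bp
(breakpoint distance; both junctions for TRA) and a 0.7–1.43 length ratio;
the label is the matched truth type, everything else is "false". Filter
bundles are trained at run time from seeded synthetic genomes (a few
minutes); shipping pretrained weights was rejected because the package's
fixtures are plain text and a trained CNN does not fit that budget.

## Genotyping

For each call, alt = distinct cluster reads; ref = mean count over the two
breakpoints of other reads spanning that breakpoint with ≥ 100 bp anchored
on both sides (reads ending inside a flank never reach the variant and are
uninformative; windows are clipped at contig bounds). Genotypes maximize
Binom(k; n, p) over allele fractions p ∈ {e, ½, 1 − e}; quality is the
phred-scaled gap to the runner-up. The error index e is platform- and
category-dependent: CLR/ONT 0.2 for insertion-like calls (INS, DUP), 0.1
otherwise; CCS 0.1 / 0.05. Translocations are genotyped with the "other"
index but the single-locus model makes those genotypes low-confidence.

At n = 20 informative reads the three-hypothesis rule is the exact Bayes
rule, whose per-class accuracy (by direct binomial enumeration) is ≥ 0.958
for e ≤ 0.1 but only 0.885–0.913 for e = 0.2 — an information limit of the
counts, not an implementation artifact; no decision rule does better at that
depth and error index.

## Pipeline

general mode: extract → RF filter (inter) → merge intra+inter per type,
deduplicating same-read same-type evidence within 200 bp (one vote per read;
intra wins because its breakpoints are exact) → partition → cluster → CNN
filter (intra DEL/INS clusters) → support filter → 50 bp length filter
(breakends exempt) → optional genotyping → VCF. sensitive mode skips both
learned filters and is otherwise identical. `min_support` defaults to
"auto": round(depth/10) + 2 clamped to [2, 10] (5 at 30×, where callers
typically peak). The output VCF body is a pure function of the input and
configuration; the thread setting never affects it (contigs are processed
and merged in deterministic order). TRA calls are emitted as paired VCF 4.2
BND records with MATEID/EVENT; internal coordinates are 0-based half-open
and convert to 1-based only in the writer. The `train` subcommand covers
filter fitting end to end (labels are generated internally against the
simulated truth), standing in for separate per-model training commands.

## Synthetic data

The generator builds a two-contig reference (uniform base composition plus
planted homopolymer runs of 5–12 every 1–2 kb, so repeat features see
signal), implants non-overlapping SVs spaced at least twice the mean read
length apart, and synthesizes alignment records directly from the donor
block map — no external aligner, so ground-truth CIGARs and split layouts
are exact. Defaults are the study conditions: 1 Mb + 200 kb contigs, 100
SVs (25 DEL, 25 INS, 20 DUP, 20 INV, 10 TRA), sizes log-uniform on
50–5000 bp (SV size distributions are heavy-tailed toward small events),
30× depth, log-normal read lengths with mean 4000 bp (σ = 0.45; the 1 Mb /
100-event geometry fixes the spacing budget, and the long tail still spans
multi-kb insertions), half the events homozygous.

Representation follows aligner behavior: DEL/INS up to 1000 bp appear as
CIGAR gaps, larger ones as split alignments; DUP as a reference backtrack;
INV as strand-flipped segments; TRA as a foreign block from the second
contig, whose two junctions are both recorded as truth breakends. Aligned
pieces shorter than `min_segment` (default 150 bp) are soft-clipped away.
Noise has three layers: platform small indels (1–15 bp, Poisson along the
alignment; rate 1/200 CLR, 1/250 ONT, 1/2000 CCS), and per read with
probability `noise_rate` a spurious 30–80 bp gap (with reduced mapq and
inflated NM) and with `noise_rate`/2 a spurious low-mapq split fragment —
exactly the regimes the two filters target. `platform_noise_scale=0`
produces byte-deterministic, exactly breakpoint-true alignments for oracle
tests.

What the generator does **not** emulate: base-level error profiles and
quality scores, chimeric-read artifacts beyond the simple split fragments,
nested or overlapping SVs, alignment ambiguity in repeats, and reference
bias. Passing tests therefore demonstrate the correctness of the calling
machinery under controlled evidence, not performance on real genomes.
Two systematic blind spots are inherent to the representation and shared
with real alignment-based calling: inversions shorter than the minimum
alignable segment leave no split evidence, and insertions approaching the
read length cannot be spanned with anchors on both sides; both bound
end-to-end recall below 100% by a few events per hundred.

## Problem sizes and determinism

Tests and the acceptance script use 300 kb–1 Mb genomes at 30×
(~7500 reads), 10 k/5 k-item filter training sets, and 1000-trial
genotype simulations — sizes chosen so a full run completes in minutes on
one CPU while every assertion still measures the intended property. All
randomness flows from explicit seeds (numpy Generator); repeated runs are
bit-reproducible, and the CNN's final loss is reproducible to < 1e-4 across
runs on one platform.
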