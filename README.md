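# svlr

Structural variant (SV) discovery and genotyping from long-read alignments.

Long reads (PacBio CLR/CCS, Oxford Nanopore) resolve SVs — deletions (DEL),
insertions (INS), duplications (DUP), inversions (INV) and translocations
(TRA) of ≥ 50 bp — far better than short reads, but their high error rate
scatters false SV-like signal through every alignment. `svlr` detects and
genotypes all five SV types from a coordinate-sorted BAM by combining:

1. **Lenient signature collection** — DEL/INS evidence from CIGAR gaps
   (*intra*-alignment) and DEL/INS/DUP/INV/TRA evidence from the geometry of
   split alignments (*inter*-alignment), each signature stored as a quadruple
   *(t, c, s, e)* with a feature vector (25 intra / 22 inter features).
2. **Two-step adaptive clustering** — a fast 1000 bp coordinate partition,
   then hierarchical (average-linkage) clustering under the similarity

   S(i,j) = (pos_dis/λ + span_dis) / max(span_i, span_j),  cut at 0.3,

   where pos_dis is the midpoint distance, span_dis the span difference, and
   λ = |GD − LD| / max(GD, LD) + GD (≥ 1) adapts to the partition's local
   depth LD and the per-type global depth GD = mean(LD). Consensus
   breakpoints are the medians of member coordinates.
3. **Learned false-positive filters** (general mode) — a grid-searched random
   forest classifies split-read signatures into {DEL, INS, DUP, INV, TRA,
   false} *before* clustering; a small CNN (conv kernels 3×25 / 3×8 / 3×1,
   three max-pools, FC 256→64→3, trained with Adam / cross-entropy, batch
   256, 15 epochs) classifies clustered CIGAR evidence into {DEL, INS, false}
   *after* clustering. A *sensitive* mode bypasses both filters for maximal
   recall (e.g. cancer genomes).
4. **Maximum-likelihood genotyping** — allele counts (k alt of n informative
   reads) compared under Binom(k; n, e), Binom(k; n, ½), Binom(k; n, 1−e)
   with platform error indices e: CLR/ONT 0.2 (insertion-like) / 0.1 (other),
   CCS 0.1 / 0.05.

Calls are written as VCF 4.2 (TRA as paired BND records). A deterministic
synthetic-data module generates references, implanted SVs and realistic noisy
alignments with exact truth, and powers both the tests and filter training.

## Worked example

Simulate a 300 kb sample with 25 SVs at 30× and call it in sensitive mode:

```sh
$ svlr simulate --out-dir demo --ref-length 300000 --depth 30 \
      --n-sv DEL=6,INS=6,DUP=5,INV=5,TRA=3 --noise-rate 0 --seed 3
wrote demo/reads.bam (28 truth records)

$ svlr call --bam demo/reads.bam --ref demo/ref.fa \
      --out demo/calls.vcf --mode sensitive
[svlr] intra_signatures: 217
[svlr] inter_signatures: 356
[svlr] merged_signatures: 573
[svlr] clusters: 28
[svlr] estimated_depth: 30
[svlr] min_support: 5
[svlr] calls: 27
wrote demo/calls.vcf
```

217 CIGAR-gap and 356 split-read signatures merge into 573 deduplicated
votes; clustering condenses them to 28 candidate clusters, and the support
filter (auto-derived: round(30/10)+2 = 5 reads at 30×) leaves 27 calls.
The VCF then reads, e.g.:

```text
chr1  22037  svlr.TRA.1_1  N  N[chr2:8001[  .  PASS  SVTYPE=TRA;SUPPORT=25;...  GT:DP:AD  1/1:25:0,25
chr1  45547  svlr.DEL.3    N  <DEL>         .  PASS  SVTYPE=DEL;SVLEN=-900;END=46446;SUPPORT=9   GT:DP:AD  0/1:27:18,9
chr1  69545  svlr.INS.5    N  <INS>         .  PASS  SVTYPE=INS;SVLEN=167;END=69544;SUPPORT=31   GT:DP:AD  1/1:31:0,31
```

The heterozygous deletion shows 9 of 27 informative reads supporting the
alternate allele (GT 0/1); the homozygous insertion shows 31 of 31 (GT 1/1).

General mode needs a trained filter bundle; one is fit in a few minutes from
seeded simulations:

```sh
svlr train --out bundle --seed 7
svlr call --bam demo/reads.bam --out demo/general.vcf --mode general --bundle bundle
```

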