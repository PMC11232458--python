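"""End-to-end orchestration of the four calling steps.

general mode: extract -> RF-filter split-read signatures -> merge evidence
-> partition -> adaptive clustering -> CNN-filter intra clusters -> support
and length filters -> optional genotyping -> VCF.

sensitive mode bypasses both learned filters and relies purely on the
lenient signature matching plus the two-step adaptive clustering — the
maximal-recall configuration for complex (e.g. cancer) genomes.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Optional

from . import alignment_io
from .alignment_io import DEFAULT_MAPQ_FLOOR, stream_alignments, write_vcf
from .clustering import (DEFAULT_CLUSTER_THRESHOLD, DEFAULT_PARTITION_GAP,
                         SignatureCluster, cluster_all)
from .genotyping import genotype_call
from .ml_filters import FilterModelBundle, cnn_filter, rf_filter
from .models import Signature, SVCall
from .signatures import (DEFAULT_MIN_SIZE, extract_inter_signatures,
                         extract_intra_signatures, group_reads)

logger = logging.getLogger("svlr")

DEFAULT_MIN_SV_SIZE_REPORT = 50
#: intra and inter evidence from one read within this distance is one vote
DEDUP_DISTANCE = 200


@dataclass
class RunConfig:
    mode: str = "general"  # "general" | "sensitive"
    platform: str = "ONT"
    min_support: object = "auto"  # int or "auto"
    min_sv_size: int = DEFAULT_MIN_SIZE
    min_sv_size_report: int = DEFAULT_MIN_SV_SIZE_REPORT
    partition_gap: int = DEFAULT_PARTITION_GAP
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    mapq_floor: int = DEFAULT_MAPQ_FLOOR
    genotype: bool = True
    threads: int = 1
    seed: int = 0
    bundle: Optional[FilterModelBundle] = None

    def __post_init__(self):
        if self.mode not in ("general", "sensitive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("min_sv_size", "min_sv_size_report", "partition_gap",
                     "mapq_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mode == "general" and self.bundle is None:
            raise ValueError("general mode requires a trained model bundle "
                             "(use sensitive mode to call without one)")


def auto_min_support(mean_depth: float) -> int:
    """Depth-adaptive minimum supporting reads: round(depth/10)+2 in [2, 10].

    Yields 5 at ~30x, the optimum most callers (and this one) show at that
    coverage.
    """
    if mean_depth <= 0:
        logger.warning("zero estimated depth; min_support falls back to 2")
        return 2
    # half-up rounding: depth 5 -> 3, depth 30 -> 5
    return int(min(10, max(2, int(mean_depth / 10 + 0.5) + 2)))


def collect_signatures(bam_path: str, min_size: int = DEFAULT_MIN_SIZE,
                       mapq_floor: int = DEFAULT_MAPQ_FLOOR,
                       region: Optional[tuple[str, int, int]] = None
                       ) -> tuple[list[Signature], list[Signature]]:
    """All intra and inter signatures of a BAM (or one region)."""
    records = list(stream_alignments(bam_path, region=region,
                                     mapq_floor=mapq_floor))
    intra: list[Signature] = []
    for rec in records:
        intra.extend(extract_intra_signatures(rec, min_size=min_size))
    inter: list[Signature] = []
    for _, recs in sorted(group_reads(records).items()):
        inter.extend(extract_inter_signatures(recs, min_size=min_size))
    return intra, inter


def merge_evidence(intra: list[Signature], inter: list[Signature]
                   ) -> dict[str, list[Signature]]:
    """One signature pool per SV type, deduplicating intra+inter evidence of
    the same read at the same locus (intra wins: its breakpoints are exact)."""
    by_type: dict[str, list[Signature]] = {}
    intra_index: dict[tuple[str, str, str], list[Signature]] = {}
    for sig in intra:
        by_type.setdefault(sig.t, []).append(sig)
        intra_index.setdefault((sig.read_name, sig.t, sig.c), []).append(sig)
    for sig in inter:
        twins = intra_index.get((sig.read_name, sig.t, sig.c), ())
        if any(abs(sig.s - tw.s) <= DEDUP_DISTANCE for tw in twins):
            continue
        by_type.setdefault(sig.t, []).append(sig)
    return by_type


def clusters_to_calls(clusters: list[SignatureCluster], min_support: int,
                      min_size_report: int) -> list[SVCall]:
    calls = []
    for cl in clusters:
        if cl.support < min_support:
            continue
        if cl.t != "TRA" and cl.length < min_size_report:
            continue
        if cl.t == "INS":
            svlen = cl.length
            pos = cl.consensus_s
            end = pos
        elif cl.t == "DEL":
            pos, end = cl.consensus_s, cl.consensus_e
            svlen = -(end - pos)
        elif cl.t == "TRA":
            pos = cl.consensus_s
            end = pos
            svlen = 0
        else:
            pos, end = cl.consensus_s, cl.consensus_e
            svlen = end - pos
        calls.append(SVCall(
            sv_type=cl.t, contig=cl.c, pos=pos, end=end, svlen=svlen,
            support=cl.support, alt_support=cl.support,
            mate_contig=cl.c2 if cl.t == "TRA" else None,
            mate_pos=cl.consensus_p2 if cl.t == "TRA" else None))
    return calls


def call_variants(bam_path: str, config: RunConfig
                  ) -> tuple[list[SVCall], dict]:
    """Run the pipeline in memory; returns calls plus per-stage counts."""
    counts: dict[str, int] = {}
    intra, inter = collect_signatures(bam_path, min_size=config.min_sv_size,
                                      mapq_floor=config.mapq_floor)
    counts["intra_signatures"] = len(intra)
    counts["inter_signatures"] = len(inter)

    if config.mode == "general" and config.bundle and config.bundle.rf:
        inter = rf_filter(inter, config.bundle.rf)
        counts["inter_after_rf"] = len(inter)

    by_type = merge_evidence(intra, inter)
    counts["merged_signatures"] = sum(len(v) for v in by_type.values())

    clusters, stats = cluster_all(by_type, partition_gap=config.partition_gap,
                                  threshold=config.cluster_threshold)
    counts["clusters"] = len(clusters)

    if config.mode == "general" and config.bundle and config.bundle.cnn:
        clusters = cnn_filter(clusters, config.bundle.cnn,
                              config.bundle.cnn_bounds)
        counts["clusters_after_cnn"] = len(clusters)

    contigs = alignment_io.bam_contigs(bam_path)
    if config.min_support == "auto":
        depth = alignment_io.estimate_mean_depth(bam_path, contigs,
                                                 mapq_floor=config.mapq_floor)
        min_support = auto_min_support(depth)
        counts["estimated_depth"] = int(round(depth))
    else:
        min_support = int(config.min_support)
    counts["min_support"] = min_support

    calls = clusters_to_calls(clusters, min_support, config.min_sv_size_report)
    cluster_reads = {
        (cl.t, cl.c, cl.consensus_s): {m.read_name for m in cl.members}
        for cl in clusters}
    order = {name: i for i, (name, _) in enumerate(contigs)}
    lengths = dict(contigs)
    calls.sort(key=lambda c: (order[c.contig], c.pos, c.sv_type))
    counts["calls"] = len(calls)

    if config.genotype:
        for call in calls:
            reads = cluster_reads.get((call.sv_type, call.contig, call.pos),
                                      set())
            genotype_call(call, bam_path, reads, lengths[call.contig],
                          platform=config.platform,
                          mapq_floor=config.mapq_floor)
    return calls, counts


def run_call(bam_path: str, ref_path: Optional[str], out_vcf: str,
             config: RunConfig, sample_name: str = "SAMPLE",
             command: str = "svlr call") -> str:
    """Call SVs on a BAM and write a VCF. Identical inputs + seed give a
    byte-identical VCF body regardless of the thread count."""
    contigs = alignment_io.bam_contigs(bam_path)
    if ref_path is not None:
        import pysam

        with pysam.FastaFile(ref_path) as fa:
            ref_contigs = dict(zip(fa.references, fa.lengths))
        for name, length in contigs:
            if name not in ref_contigs or ref_contigs[name] != length:
                raise ValueError(
                    f"contig {name!r} mismatch between BAM and reference")
    calls, counts = call_variants(bam_path, config)
    for stage, value in counts.items():
        logger.info("%s: %d", stage, value)
    return write_vcf(calls, contigs, out_vcf, sample_name=sample_name,
                     command=command)
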