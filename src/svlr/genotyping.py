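"""Maximum-likelihood genotyping of filtered SV calls.

Three genotype hypotheses are compared under a binomial model of the
alt-supporting read count k out of n informative reads, with allele fractions
{e, 1/2, 1 - e}: L(0/0) = Binom(k; n, e), L(0/1) = Binom(k; n, 1/2),
L(1/1) = Binom(k; n, 1 - e). The error index e is platform- and
category-specific: insertions are harder to support than other SV types, so
insertion-like calls (INS, DUP) use a larger e. Translocations are genotyped
with the "other" index but the single-locus model makes those genotypes
low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .models import SVCall

#: recalibrated error indices per (platform, category)
ERROR_INDEX = {
    ("CLR", "insertion"): 0.2,
    ("CLR", "other"): 0.1,
    ("ONT", "insertion"): 0.2,
    ("ONT", "other"): 0.1,
    ("CCS", "insertion"): 0.1,
    ("CCS", "other"): 0.05,
}

FLANK_WINDOW = 500

GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass
class AlleleSupport:
    ref_count: int
    alt_count: int
    region: tuple[int, int] = (0, 0)


def error_index(platform: str, sv_type: str) -> float:
    category = "insertion" if sv_type in ("INS", "DUP") else "other"
    try:
        return ERROR_INDEX[(platform, category)]
    except KeyError:
        raise ValueError(f"unknown platform {platform!r}") from None


def genotype_likelihoods(support: AlleleSupport, e: float
                         ) -> tuple[str, int, np.ndarray]:
    """Return (genotype, phred quality, log-likelihoods for 0/0, 0/1, 1/1).

    Quality is the phred-scaled gap between the best and second-best
    hypothesis. Zero informative reads give ./. with quality 0.
    """
    n = support.ref_count + support.alt_count
    k = support.alt_count
    if n == 0:
        return "./.", 0, np.full(3, -np.inf)
    ll = np.array([
        binom.logpmf(k, n, e),
        binom.logpmf(k, n, 0.5),
        binom.logpmf(k, n, 1.0 - e),
    ])
    order = np.argsort(ll)[::-1]
    best, second = order[0], order[1]
    qual = int(round(10.0 * (ll[best] - ll[second]) / np.log(10.0)))
    return GENOTYPES[best], qual, ll


def count_allele_support(call: SVCall, bam_path: str, alt_reads: set[str],
                         contig_length: int, mapq_floor: int = 20,
                         flank: int = FLANK_WINDOW) -> AlleleSupport:
    """Reference/alternate read counts around a call.

    alt = distinct cluster reads; ref = mean count, over the two breakpoint
    flanks, of other reads spanning the breakpoint with at least 100 bp of
    anchored alignment on both sides (reads ending inside a flank never reach
    the variant and are uninformative). Windows are clipped at contig bounds;
    if one vanishes the other alone counts.
    """
    import pysam

    margin = 100
    left_lo = max(0, call.pos - flank)
    right_hi = min(call.end + flank, contig_length)
    breakpoints = [bp for bp in (call.pos, call.end)
                   if margin <= bp <= contig_length - margin]
    counts = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for bp in breakpoints or [min(max(call.pos, margin),
                                      contig_length - margin)]:
            names = set()
            for seg in bam.fetch(call.contig, max(0, bp - 1), bp + 1):
                if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                    continue
                if seg.mapping_quality < mapq_floor:
                    continue
                if seg.query_name in alt_reads:
                    continue
                if seg.reference_start + margin <= bp <= seg.reference_end - margin:
                    names.add(seg.query_name)
            counts.append(len(names))
    ref = int(round(float(np.mean(counts)))) if counts else 0
    return AlleleSupport(ref_count=max(0, ref), alt_count=len(alt_reads),
                         region=(left_lo, right_hi))


def genotype_call(call: SVCall, bam_path: str, alt_reads: set[str],
                  contig_length: int, platform: str = "ONT",
                  mapq_floor: int = 20) -> SVCall:
    support = count_allele_support(call, bam_path, alt_reads, contig_length,
                                   mapq_floor=mapq_floor)
    e = error_index(platform, call.sv_type)
    gt, qual, _ = genotype_likelihoods(support, e)
    call.genotype = gt
    call.gt_quality = qual
    call.ref_support = support.ref_count
    call.alt_support = support.alt_count
    return call
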