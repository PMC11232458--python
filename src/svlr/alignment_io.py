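"""BAM reading and VCF writing.

Reading goes through pysam; secondary and unmapped records are dropped at the
source, supplementary records are kept because they carry split-read evidence.
Records below a configurable mapping-quality floor are excluded uniformly
(primary and supplementary alike).
"""

from __future__ import annotations

import os
from typing import Iterator, Optional, Sequence

import pysam

from . import __version__
from .models import AlignmentRecord, SAEntry, SVCall, cigar_query_length, parse_cigar

DEFAULT_MAPQ_FLOOR = 20


def _parse_sa_tag(tag: str) -> list[SAEntry]:
    entries = []
    for part in tag.rstrip(";").split(";"):
        if not part:
            continue
        rname, pos, strand, cig, mapq, nm = part.split(",")
        entries.append(
            SAEntry(contig=rname, pos=int(pos) - 1, strand=strand,
                    cigar=parse_cigar(cig), mapq=int(mapq), nm=int(nm))
        )
    return entries


def record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = list(seg.cigartuples or [])
    sa = _parse_sa_tag(seg.get_tag("SA")) if seg.has_tag("SA") else []
    return AlignmentRecord(
        read_name=seg.query_name,
        contig=seg.reference_name,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end if seg.reference_end is not None else seg.reference_start,
        mapq=seg.mapping_quality,
        strand="-" if seg.is_reverse else "+",
        is_primary=not (seg.is_supplementary or seg.is_secondary),
        is_supplementary=seg.is_supplementary,
        cigar=cigar,
        edit_distance=seg.get_tag("NM") if seg.has_tag("NM") else None,
        sa_entries=sa,
        read_sequence=seg.query_sequence,
        read_length=cigar_query_length(cigar) if cigar else (seg.query_length or 0),
    )


def stream_alignments(
    path: str,
    region: Optional[tuple[str, int, int]] = None,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> Iterator[AlignmentRecord]:
    """Yield mapped primary+supplementary records in coordinate order.

    ``region`` is a 0-based half-open (contig, start, end) interval; records
    merely overlapping it are included.
    """
    with pysam.AlignmentFile(path, "rb") as bam:
        if region is not None:
            contig, start, end = region
            it = bam.fetch(contig, start, end)
        else:
            it = bam.fetch()
        for seg in it:
            if seg.is_unmapped or seg.is_secondary:
                continue
            if seg.mapping_quality < mapq_floor:
                continue
            yield record_from_pysam(seg)


def bam_contigs(path: str) -> list[tuple[str, int]]:
    with pysam.AlignmentFile(path, "rb") as bam:
        return list(zip(bam.references, bam.lengths))


def estimate_mean_depth(path: str, contigs: Optional[Sequence[tuple[str, int]]] = None,
                        mapq_floor: int = DEFAULT_MAPQ_FLOOR) -> float:
    """Mean fold coverage estimated from total aligned bases / genome length."""
    if contigs is None:
        contigs = bam_contigs(path)
    genome = sum(length for _, length in contigs)
    if genome == 0:
        return 0.0
    aligned = 0
    for rec in stream_alignments(path, mapq_floor=mapq_floor):
        aligned += rec.aligned_length
    return aligned / genome


# ---------------------------------------------------------------------------
# VCF output


_VCF_HEADER_META = """\
##fileformat=VCFv4.2
##source=svlr-{version}
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of distinct supporting reads">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=EVENT,Number=1,Type=String,Description="ID of the breakend event">
##FILTER=<ID=low_support,Description="Fewer supporting reads than the configured minimum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at the locus">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reference and alternate supporting reads">
"""


class VCFOrderError(ValueError):
    pass


class VCFConsistencyError(ValueError):
    pass


def _format_fields(call: SVCall) -> str:
    dp = call.ref_support + call.alt_support
    return f"{call.genotype}:{dp}:{call.ref_support},{call.alt_support}"


def write_vcf(calls: Sequence[SVCall], contigs: Sequence[tuple[str, int]], out: str,
              sample_name: str = "SAMPLE", command: str = "svlr") -> str:
    """Write calls as VCF 4.2; TRA calls become a pair of BND records.

    ``calls`` must be sorted by (contig order as given, pos). Genotype fields
    for translocation breakends come from a single-locus model and are
    low-confidence by construction.
    """
    order = {name: i for i, (name, _) in enumerate(contigs)}
    known = set(order)
    last = (-1, -1)
    for call in calls:
        if call.contig not in known:
            raise VCFConsistencyError(f"call contig {call.contig!r} absent from header")
        if call.mate_contig is not None and call.mate_contig not in known:
            raise VCFConsistencyError(f"mate contig {call.mate_contig!r} absent from header")
        key = (order[call.contig], call.pos)
        if key < last:
            raise VCFOrderError("calls must be sorted by contig then position")
        last = key

    lines = [_VCF_HEADER_META.format(version=__version__)]
    lines.append(f"##svlrCommand={command}\n")
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")

    n = 0
    for call in calls:
        n += 1
        pos1 = call.pos + 1
        if call.sv_type == "TRA":
            mate1 = call.mate_pos + 1
            id_a, id_b = f"svlr.TRA.{n}_1", f"svlr.TRA.{n}_2"
            info_a = (f"SVTYPE=TRA;SUPPORT={call.support};MATEID={id_b};"
                      f"EVENT=svlr.TRA.{n}")
            info_b = (f"SVTYPE=TRA;SUPPORT={call.support};MATEID={id_a};"
                      f"EVENT=svlr.TRA.{n}")
            alt_a = f"N[{call.mate_contig}:{mate1}["
            alt_b = f"N]{call.contig}:{pos1}]"
            fmt = _format_fields(call)
            lines.append(f"{call.contig}\t{pos1}\t{id_a}\tN\t{alt_a}\t.\t"
                         f"{call.filter}\t{info_a}\tGT:DP:AD\t{fmt}\n")
            lines.append(f"{call.mate_contig}\t{mate1}\t{id_b}\tN\t{alt_b}\t.\t"
                         f"{call.filter}\t{info_b}\tGT:DP:AD\t{fmt}\n")
        else:
            info = (f"SVTYPE={call.sv_type};SVLEN={call.svlen};END={call.end};"
                    f"SUPPORT={call.support}")
            alt = f"<{call.sv_type}>"
            lines.append(f"{call.contig}\t{pos1}\tsvlr.{call.sv_type}.{n}\tN\t{alt}\t.\t"
                         f"{call.filter}\t{info}\tGT:DP:AD\t{_format_fields(call)}\n")
    with open(out, "w") as fh:
        fh.writelines(lines)
    return out


def read_vcf(path: str) -> list[SVCall]:
    """Parse a VCF written by :func:`write_vcf` back into SVCall objects.

    BND mate pairs are folded back into a single TRA call (the record whose ID
    ends in ``_1`` wins).
    """
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, pos, vid, _ref, alt, _qual, filt, info, _fmt, sample = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            gt, dp, ad = sample.split(":")
            ref_sup, alt_sup = (int(x) for x in ad.split(","))
            svtype = fields["SVTYPE"]
            if svtype == "TRA":
                if not vid.endswith("_1"):
                    continue
                mate_contig = alt.split("[")[1].split(":")[0]
                mate_pos = int(alt.split(":")[1].rstrip("[]")) - 1
                calls.append(SVCall(
                    sv_type="TRA", contig=contig, pos=int(pos) - 1,
                    end=int(pos) - 1, svlen=0,
                    support=int(fields["SUPPORT"]), genotype=gt,
                    ref_support=ref_sup, alt_support=alt_sup, filter=filt,
                    mate_contig=mate_contig, mate_pos=mate_pos))
            else:
                calls.append(SVCall(
                    sv_type=svtype, contig=contig, pos=int(pos) - 1,
                    end=int(fields["END"]), svlen=int(fields["SVLEN"]),
                    support=int(fields["SUPPORT"]), genotype=gt,
                    ref_support=ref_sup, alt_support=alt_sup, filter=filt))
    return calls


def vcf_body(path: str) -> str:
    """Record lines of a VCF (everything after the header), for determinism checks."""
    with open(path) as fh:
        return "".join(line for line in fh if not line.startswith("#"))
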