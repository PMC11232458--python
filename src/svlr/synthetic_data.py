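"""Deterministic synthetic references, implanted SVs and long-read alignments.

The generator emulates what an aligner would emit for long reads drawn from a
donor genome carrying structural variants, without shelling out to an
aligner: reads are literal donor substrings and their alignments are derived
from the exact donor-to-reference block map, so ground-truth CIGARs and split
alignments are available by construction. Platform-style noise is layered on
top: scattered 1-15 bp indels (below the SV-candidate gap size), occasional
spurious 30-80 bp gaps, and spurious low-quality split fragments — the false
signal regime the learned filters are trained to remove.

Donor model per haplotype (all events implanted on the first contig):

* DEL  — reference segment skipped;
* INS  — novel random sequence inserted;
* DUP  — tandem duplication (segment emitted twice);
* INV  — segment emitted reverse-complemented;
* TRA  — a foreign block from the second contig inserted, creating two
  breakend junctions; both junctions are recorded in the truth set.

Large deletions/insertions (beyond ``split_threshold``) surface as split
alignments rather than single CIGAR gaps, duplications as reference
backtracks, inversions as strand flips, translocations as cross-contig
splits — the alignment geometries the extraction rules consume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .alignment_io import write_vcf
from .models import SVCall

DEFAULT_N_SV = {"DEL": 25, "INS": 25, "DUP": 20, "INV": 20, "TRA": 10}

_COMP = str.maketrans("ACGTN", "TGCAN")

#: per-platform alignment noise: (small-indel rate per bp, base error fraction)
PLATFORM_PROFILES = {
    "CLR": (1 / 200, 0.10),
    "ONT": (1 / 250, 0.08),
    "CCS": (1 / 2000, 0.01),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic sample."""

    ref_length: int = 1_000_000
    second_contig_length: int = 200_000
    n_sv: dict = field(default_factory=lambda: dict(DEFAULT_N_SV))
    sv_size_range: tuple[int, int] = (50, 5000)
    depth: float = 30.0
    read_length: int = 4000  # mean; lengths are log-normal around this
    read_length_sigma: float = 0.45
    noise_rate: float = 0.1
    hom_fraction: float = 0.5
    platform: str = "ONT"
    platform_noise_scale: float = 1.0  # 0 disables small-indel CIGAR noise
    seed: int = 0
    split_threshold: int = 1000  # gaps beyond this surface as split alignments
    min_segment: int = 150  # shorter aligned pieces are soft-clipped away

    def validate(self) -> None:
        if not 0 <= self.noise_rate <= 1 or not 0 <= self.hom_fraction <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.platform not in PLATFORM_PROFILES:
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class TruthSV:
    id: str
    type: str
    contig: str
    s: int
    e: int
    length: int
    genotype: str
    c2: Optional[str] = None
    p2: Optional[int] = None


@dataclass
class TruthSet:
    spec: SimulationSpec
    contigs: list[tuple[str, int]]
    references: dict[str, str]
    svs: list[TruthSV]
    #: implanted events grouped by id (a TRA implant owns two junction records)
    n_events: int = 0


def _random_reference(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    # plant homopolymer runs >= 5 so repeat-aware features see real signal
    pos = 200
    while pos < length - 20:
        run = int(rng.integers(5, 13))
        seq[pos:pos + run] = bases[rng.integers(0, 4)]
        pos += int(rng.integers(1000, 2000))
    return "".join(seq)


def generate_truth(spec: SimulationSpec) -> TruthSet:
    """Reference contigs plus non-overlapping implanted SVs and their truth.

    Events are spaced at least twice the mean read length apart so no read
    spans two events. Raises when the requested events cannot fit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contigs = [("chr1", spec.ref_length), ("chr2", spec.second_contig_length)]
    refs = {"chr1": _random_reference(rng, spec.ref_length),
            "chr2": _random_reference(rng, spec.second_contig_length)}

    lo, hi = spec.sv_size_range
    events = []
    for t in ("DEL", "INS", "DUP", "INV", "TRA"):
        for _ in range(int(spec.n_sv.get(t, 0))):
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            events.append([t, size])
    order = rng.permutation(len(events))
    events = [events[i] for i in order]

    spacing = 2 * spec.read_length
    ref_consumed = {"DEL": lambda sz: sz, "INS": lambda sz: 0,
                    "DUP": lambda sz: sz, "INV": lambda sz: sz,
                    "TRA": lambda sz: 0}
    needed = spacing * (len(events) + 1) + sum(
        ref_consumed[t](sz) for t, sz in events)
    if needed > spec.ref_length:
        raise ValueError(
            f"cannot place {len(events)} events in {spec.ref_length} bp "
            f"(needs >= {needed} bp)")
    slack = spec.ref_length - needed
    extra = rng.multinomial(slack, np.full(len(events) + 1, 1 / (len(events) + 1)))

    svs: list[TruthSV] = []
    cursor = spacing + int(extra[0])
    tra_mate_cursor = 2 * spec.read_length
    n_events = 0
    for i, (t, size) in enumerate(events):
        n_events += 1
        sid = f"sv{i}"
        gt = "1/1" if rng.random() < spec.hom_fraction else "0/1"
        s = cursor
        if t == "DEL":
            svs.append(TruthSV(sid, "DEL", "chr1", s, s + size, size, gt))
        elif t == "INS":
            svs.append(TruthSV(sid, "INS", "chr1", s, s + size, size, gt))
        elif t == "DUP":
            svs.append(TruthSV(sid, "DUP", "chr1", s, s + size, size, gt))
        elif t == "INV":
            svs.append(TruthSV(sid, "INV", "chr1", s, s + size, size, gt))
        else:  # TRA: foreign block from chr2, two junctions share the id
            fsize = max(size, 2 * spec.min_segment)
            y = tra_mate_cursor
            tra_mate_cursor += fsize + 2 * spec.read_length
            if tra_mate_cursor > spec.second_contig_length:
                raise ValueError("second contig too short for TRA mates")
            svs.append(TruthSV(sid, "TRA", "chr1", s, s, fsize, gt,
                               c2="chr2", p2=y))
            svs.append(TruthSV(sid + "b", "TRA", "chr2", y + fsize, y + fsize,
                               fsize, gt, c2="chr1", p2=s))
        cursor += ref_consumed[t](size) + spacing + int(extra[i + 1])
    return TruthSet(spec=spec, contigs=contigs, references=refs, svs=svs,
                    n_events=n_events)


def truth_vcf(truth: TruthSet, out: str) -> str:
    calls = []
    for sv in truth.svs:
        if sv.type == "TRA":
            if sv.contig != "chr1":
                continue
            calls.append(SVCall(sv_type="TRA", contig=sv.contig, pos=sv.s,
                                end=sv.s, svlen=0, support=0,
                                genotype=sv.genotype, mate_contig=sv.c2,
                                mate_pos=sv.p2))
        else:
            svlen = -sv.length if sv.type == "DEL" else sv.length
            end = sv.s if sv.type == "INS" else sv.e
            calls.append(SVCall(sv_type=sv.type, contig=sv.contig, pos=sv.s,
                                end=end, svlen=svlen, support=0,
                                genotype=sv.genotype))
    order = {name: i for i, (name, _) in enumerate(truth.contigs)}
    calls.sort(key=lambda c: (order[c.contig], c.pos))
    return write_vcf(calls, truth.contigs, out, sample_name="TRUTH",
                     command="svlr simulate")


# ---------------------------------------------------------------------------
# donor construction


@dataclass
class _Block:
    kind: str  # "R" reference block | "I" novel insertion
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    seq: str = ""  # for "I"

    def __len__(self) -> int:
        return (self.end - self.start) if self.kind == "R" else len(self.seq)


def _donor_blocks(truth: TruthSet, hap: int, rng: np.random.Generator
                  ) -> list[_Block]:
    """Edit-script blocks of the chr1 donor haplotype."""
    events = [sv for sv in truth.svs
              if sv.contig == "chr1" and not sv.id.endswith("b")
              and (sv.genotype == "1/1" or hap == 0)]
    events.sort(key=lambda sv: sv.s)
    blocks: list[_Block] = []
    pos = 0
    bases = np.array(list("ACGT"))
    for sv in events:
        if sv.s > pos:
            blocks.append(_Block("R", "chr1", pos, sv.s))
        if sv.type == "DEL":
            pos = sv.e
        elif sv.type == "INS":
            ins = "".join(bases[rng.integers(0, 4, size=sv.length)])
            blocks.append(_Block("I", seq=ins))
            pos = sv.s
        elif sv.type == "DUP":
            blocks.append(_Block("R", "chr1", sv.s, sv.e))
            blocks.append(_Block("R", "chr1", sv.s, sv.e))
            pos = sv.e
        elif sv.type == "INV":
            blocks.append(_Block("R", "chr1", sv.s, sv.e, strand="-"))
            pos = sv.e
        elif sv.type == "TRA":
            blocks.append(_Block("R", "chr2", sv.p2, sv.p2 + sv.length))
            pos = sv.s
    if pos < truth.contigs[0][1]:
        blocks.append(_Block("R", "chr1", pos, truth.contigs[0][1]))
    return blocks


def _block_seq(block: _Block, refs: dict[str, str]) -> str:
    if block.kind == "I":
        return block.seq
    seq = refs[block.contig][block.start:block.end]
    return revcomp(seq) if block.strand == "-" else seq


@dataclass
class _Piece:
    """One read sub-interval mapped through a donor block."""

    q0: int
    q1: int
    is_insertion: bool
    contig: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"


def _read_pieces(blocks: list[_Block], offsets: list[int], a: int, b: int
                 ) -> list[_Piece]:
    """Map donor read interval [a, b) through the block structure."""
    pieces = []
    for block, off in zip(blocks, offsets):
        blen = len(block)
        lo, hi = max(a, off), min(b, off + blen)
        if hi <= lo:
            continue
        d0, d1 = lo - off, hi - off
        q0, q1 = lo - a, hi - a
        if block.kind == "I":
            pieces.append(_Piece(q0, q1, True))
        elif block.strand == "+":
            pieces.append(_Piece(q0, q1, False, block.contig,
                                 block.start + d0, block.start + d1, "+"))
        else:
            pieces.append(_Piece(q0, q1, False, block.contig,
                                 block.end - d1, block.end - d0, "-"))
    return pieces


@dataclass
class _Aln:
    """One alignment segment of a read in original-read orientation."""

    q0: int
    q1: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    ops: list[tuple[str, int]]  # read-orientation ops: M/I/D
    mapq: int = 60
    nm: int = 0


def _pieces_to_alignments(pieces: list[_Piece], split_threshold: int,
                          min_segment: int) -> list[_Aln]:
    alns: list[_Aln] = []
    cur: Optional[_Aln] = None
    pending_ins = 0

    def flush():
        nonlocal cur, pending_ins
        if cur is not None and cur.q1 - cur.q0 >= min_segment:
            alns.append(cur)
        cur = None
        pending_ins = 0

    for piece in pieces:
        if piece.is_insertion:
            if piece.q1 - piece.q0 > split_threshold:
                flush()
            else:
                pending_ins += piece.q1 - piece.q0
            continue
        plen = piece.q1 - piece.q0
        if cur is not None and piece.contig == cur.contig \
                and piece.strand == cur.strand:
            gap = (piece.ref_start - cur.ref_end if piece.strand == "+"
                   else cur.ref_start - piece.ref_end)
            if 0 <= gap <= split_threshold:
                if pending_ins:
                    cur.ops.append(("I", pending_ins))
                    pending_ins = 0
                if gap:
                    cur.ops.append(("D", gap))
                cur.ops.append(("M", plen))
                cur.q1 = piece.q1
                if piece.strand == "+":
                    cur.ref_end = piece.ref_end
                else:
                    cur.ref_start = piece.ref_start
                continue
        flush()
        # an unconsumed small insertion before a split lands in the clip
        cur = _Aln(piece.q0, piece.q1, piece.contig, piece.ref_start,
                   piece.ref_end, piece.strand, [("M", plen)])
        pending_ins = 0
    flush()
    return alns


# ---------------------------------------------------------------------------
# noise


def _inject_indel_noise(aln: _Aln, rng: np.random.Generator, rate: float,
                        spurious: bool) -> None:
    """Scatter small indels through M runs; optionally one SV-sized gap.

    Small indels are 1-15 bp (below the extractor's candidate gap size);
    a spurious gap is 30-80 bp and is exactly the false signal the CNN
    filter is trained on. Reference span and NM are updated in place.
    """
    aligned = sum(ln for op, ln in aln.ops if op == "M")
    n_small = rng.poisson(aligned * rate)
    sizes = [min(15, 1 + int(rng.geometric(0.5))) for _ in range(n_small)]
    kinds = ["D" if rng.random() < 0.5 else "I" for _ in range(n_small)]
    if spurious:
        sizes.append(int(rng.integers(30, 81)))
        kinds.append("D" if rng.random() < 0.5 else "I")
    for size, kind in zip(sizes, kinds):
        m_idx = [i for i, (op, ln) in enumerate(aln.ops)
                 if op == "M" and ln > size + 2]
        if not m_idx:
            break
        i = int(m_idx[rng.integers(0, len(m_idx))])
        mlen = aln.ops[i][1]
        if kind == "I":
            k = int(rng.integers(1, mlen - size))
            aln.ops[i:i + 1] = [("M", k), ("I", size), ("M", mlen - size - k)]
        else:
            k = int(rng.integers(1, mlen - 1))
            aln.ops[i:i + 1] = [("M", k), ("D", size), ("M", mlen - k)]
            if aln.strand == "+":
                aln.ref_end += size
            else:
                aln.ref_start -= size
        aln.nm += size


# ---------------------------------------------------------------------------
# BAM emission


def _stored_cigar(aln: _Aln, read_len: int, hard: bool) -> list[tuple[int, int]]:
    """CIGAR in reference orientation with clips (soft or hard)."""
    from .models import OP_CODE

    left = aln.q0
    right = read_len - aln.q1
    ops = aln.ops
    if aln.strand == "-":
        left, right = right, left
        ops = ops[::-1]
    clip = OP_CODE["H"] if hard else OP_CODE["S"]
    cig = []
    if left:
        cig.append((clip, left))
    cig.extend((OP_CODE[o], ln) for o, ln in ops)
    if right:
        cig.append((clip, right))
    return cig


def _cigar_str(cig: list[tuple[int, int]]) -> str:
    from .models import cigar_to_string
    return cigar_to_string(cig)


def simulate_alignments(truth: TruthSet, out_bam: str,
                        manifest_path: Optional[str] = None) -> str:
    """Sample reads from the donor haplotypes and write a sorted indexed BAM.

    Reads are donor substrings; alignment segments follow from the donor
    block map, platform noise perturbs CIGARs, and ``noise_rate`` controls
    spurious gaps and split fragments. Deterministic under the spec seed.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1)
    indel_rate, base_error = PLATFORM_PROFILES[spec.platform]
    indel_rate *= spec.platform_noise_scale

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in truth.contigs],
    }

    sources = []
    for hap in (0, 1):
        blocks = _donor_blocks(truth, hap, rng)
        offsets = list(np.cumsum([0] + [len(b) for b in blocks[:-1]]))
        donor_len = offsets[-1] + len(blocks[-1])
        seq = "".join(_block_seq(b, truth.references) for b in blocks)
        sources.append((f"h{hap}", blocks, offsets, donor_len, seq))
    for name, length in truth.contigs[1:]:
        block = [_Block("R", name, 0, length)]
        sources.append((f"{name}r0", block, [0], length, truth.references[name]))
        sources.append((f"{name}r1", block, [0], length, truth.references[name]))

    mu = np.log(spec.read_length) - spec.read_length_sigma ** 2 / 2
    records = []
    manifest_rows = []
    read_no = 0
    for src_name, blocks, offsets, donor_len, donor_seq in sources:
        n_reads = int(round(spec.depth / 2 * donor_len / spec.read_length))
        for _ in range(n_reads):
            read_no += 1
            length = int(np.clip(rng.lognormal(mu, spec.read_length_sigma),
                                 500, donor_len))
            a = int(rng.integers(0, max(1, donor_len - length + 1)))
            b = a + length
            name = f"read{read_no}_{src_name}"
            pieces = _read_pieces(blocks, offsets, a, b)
            alns = _pieces_to_alignments(pieces, spec.split_threshold,
                                         spec.min_segment)
            if not alns:
                continue
            read_seq = donor_seq[a:b]

            noisy_gap = rng.random() < spec.noise_rate
            noisy_split = rng.random() < spec.noise_rate / 2
            for k, aln in enumerate(alns):
                _inject_indel_noise(aln, rng, indel_rate,
                                    spurious=(noisy_gap and k == 0))
                aln.nm += int((aln.q1 - aln.q0) * base_error)
                aln.mapq = int(rng.integers(20, 46)) if noisy_gap else 60
            if noisy_split:
                frag = int(rng.integers(300, 601))
                if length > frag + 100:
                    q0 = int(rng.integers(0, length - frag))
                    contig, clen = truth.contigs[int(rng.integers(0, 2))]
                    pos = int(rng.integers(0, clen - frag))
                    alns.append(_Aln(q0, q0 + frag, contig, pos, pos + frag,
                                     "+" if rng.random() < 0.5 else "-",
                                     [("M", frag)],
                                     mapq=int(rng.integers(10, 41)),
                                     nm=int(frag * 0.15)))
                    alns.sort(key=lambda x: x.q0)

            primary_idx = max(range(len(alns)),
                              key=lambda i: alns[i].q1 - alns[i].q0)
            sa_strings = []
            for aln in alns:
                cig = _stored_cigar(aln, length, hard=False)
                sa_strings.append(
                    f"{aln.contig},{aln.ref_start + 1},{aln.strand},"
                    f"{_cigar_str(cig)},{aln.mapq},{aln.nm}")
            for i, aln in enumerate(alns):
                is_primary = i == primary_idx
                seg = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                seg.query_name = name
                seg.flag = (0 if is_primary else 2048) | \
                    (16 if aln.strand == "-" else 0)
                seg.reference_id = 0 if aln.contig == "chr1" else 1
                seg.reference_start = aln.ref_start
                seg.mapping_quality = aln.mapq
                if is_primary:
                    seg.cigartuples = _stored_cigar(aln, length, hard=False)
                    sseq = read_seq
                else:
                    seg.cigartuples = _stored_cigar(aln, length, hard=True)
                    sseq = read_seq[aln.q0:aln.q1]
                if aln.strand == "-":
                    sseq = revcomp(sseq)
                seg.query_sequence = sseq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(sseq))
                others = [sa for j, sa in enumerate(sa_strings) if j != i]
                tags = [("NM", int(aln.nm))]
                if others:
                    tags.append(("SA", ";".join(others) + ";"))
                seg.set_tags(tags)
                records.append(seg)
            manifest_rows.append(
                (name, src_name, a, b, len(alns),
                 int(noisy_gap), int(noisy_split)))

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                r.flag))
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(out_bam)

    if manifest_path:
        with open(manifest_path, "w") as fh:
            fh.write("read\tsource\tdonor_start\tdonor_end\tn_segments\t"
                     "noisy_gap\tnoisy_split\n")
            for row in manifest_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return out_bam


def write_reference(truth: TruthSet, out_fasta: str) -> str:
    with open(out_fasta, "w") as fh:
        for name, _ in truth.contigs:
            fh.write(f">{name}\n")
            seq = truth.references[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(out_fasta)
    return out_fasta


def simulate_to_files(spec: SimulationSpec, outdir: str
                      ) -> tuple[str, str, TruthSet]:
    """Full fixture: (bam, fasta, truth); truth VCF and manifest sit alongside."""
    os.makedirs(outdir, exist_ok=True)
    truth = generate_truth(spec)
    fasta = write_reference(truth, os.path.join(outdir, "ref.fa"))
    bam = simulate_alignments(truth, os.path.join(outdir, "reads.bam"),
                              manifest_path=os.path.join(outdir, "manifest.tsv"))
    truth_vcf(truth, os.path.join(outdir, "truth.vcf"))
    return bam, fasta, truth


# ---------------------------------------------------------------------------
# separable labeled feature sets for filter training checks


def separable_inter_vectors(n_per_class: int, seed: int = 0,
                            separation: float = 4.0
                            ) -> tuple[np.ndarray, list[str]]:
    """Class-conditional Gaussian 22-feature vectors, means >= 3 sigma apart.

    Six classes (DEL/INS/DUP/INV/TRA/false); each class elevates two of the
    feature coordinates by ``separation`` standard deviations.
    """
    from .ml_filters.rf import RF_CLASSES
    from .signatures import INTER_FEATURES

    rng = np.random.default_rng(seed)
    d = len(INTER_FEATURES)
    base = rng.uniform(0, 10, size=d)
    xs, ys = [], []
    for ci, cls in enumerate(RF_CLASSES):
        mean = base.copy()
        mean[ci] += separation
        mean[(ci + 8) % d] += separation
        xs.append(rng.normal(mean, 1.0, size=(n_per_class, d)))
        ys.extend([cls] * n_per_class)
    return np.vstack(xs), ys


def separable_cluster_matrices(n_per_class: int, seed: int = 0,
                               separation: float = 4.0):
    """Separable labeled (100, 25) cluster matrices for the CNN classes."""
    from .ml_filters.cnn import CNN_CLASSES
    from .ml_filters.matrix import CLUSTER_MATRIX_ROWS, ClusterFeatureMatrix
    from .signatures import INTRA_FEATURES

    rng = np.random.default_rng(seed)
    d = len(INTRA_FEATURES)
    base = rng.uniform(0, 10, size=d)
    out = []
    for ci, cls in enumerate(CNN_CLASSES):
        mean = base.copy()
        mean[ci] += separation
        mean[(ci + 9) % d] += separation
        for _ in range(n_per_class):
            depth = int(rng.integers(5, CLUSTER_MATRIX_ROWS + 1))
            rows = rng.normal(mean, 1.0, size=(depth, d))
            values = np.zeros((CLUSTER_MATRIX_ROWS, d))
            values[:depth] = 1.0 / (1.0 + np.exp(-(rows - base) / 4.0))
            out.append(ClusterFeatureMatrix(values=values, depth=depth,
                                            label=cls))
    order = rng.permutation(len(out))
    return [out[i] for i in order]
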