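"""Reference-vs-draft nucleotide comparison and divergence contrasts.

Whole-genome comparison proceeds by anchor chaining: maximal exact
matches that are unique in both sequences (>= ``min_anchor`` bp) are
chained colinearly by a maximum-weight increasing-subsequence DP (weight
= anchor length); inter-anchor gaps are closed by direct column pairing
when the ref and query gaps have equal length, by unit-cost global
alignment (edlib) when both are <= ``max_gap``, and flagged unaligned
otherwise. SNPs are mismatched aligned columns with unambiguous bases.

The island-vs-backbone contrast asks whether the island is depleted of
SNPs relative to the genome backbone: a one-sided exact binomial test of
the island SNP count at the backbone rate, combined with the island /
backbone frequency ratio, classifies the island's history as
``recent_independent`` (strong depletion), ``ancestral_vertical``
(ratio within [0.5, 2]) or ``indeterminate``.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.stats import binom

from .genome import Feature, Genome

_ACGT = set("ACGT")


@dataclass
class Block:
    """One colinear aligned block (gapped rows over ref/query intervals)."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    ref_aln: str
    qry_aln: str


@dataclass
class SegmentMap:
    """Ordered colinear blocks plus unaligned ref intervals."""

    ref_id: str
    qry_id: str
    contig: str
    blocks: list[Block] = field(default_factory=list)
    unaligned_ref: list[tuple[int, int]] = field(default_factory=list)

    def aligned_ref_length(self, region: tuple[int, int] | None = None) -> int:
        total = 0
        for b in self.blocks:
            s, e = b.ref_start, b.ref_end
            if region is not None:
                s, e = max(s, region[0]), min(e, region[1])
            total += max(0, e - s)
        return total


@dataclass
class SnpRecord:
    contig: str
    position: int  # 0-based on the reference
    ref_base: str
    alt_base: str
    region: str = "backbone"  # island | backbone | unaligned-adjacent

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if self.ref_base not in _ACGT or self.alt_base not in _ACGT:
            raise ValueError("SNP bases must be unambiguous A/C/G/T")


# ---------------------------------------------------------------------------
# Anchors


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return {
        seq[i : i + k]: i
        for i in range(len(seq) - k + 1)
        if counts[seq[i : i + k]] == 1
    }


def find_anchors(ref: str, qry: str, min_anchor: int = 20) -> list[tuple[int, int, int]]:
    """Maximal exact matches unique in both sequences.

    Seeds are ``min_anchor``-mers unique in ref and in query; runs of
    seeds on the same diagonal merge into one anchor ``(ref_start,
    qry_start, length)``. Sorted by ref position.
    """
    k = min_anchor
    ru = _unique_kmer_positions(ref, k)
    qu = _unique_kmer_positions(qry, k)
    seeds = sorted(
        (rpos, qu[kmer]) for kmer, rpos in ru.items() if kmer in qu
    )
    anchors: list[tuple[int, int, int]] = []
    for rpos, qpos in seeds:
        if anchors:
            pr, pq, pl = anchors[-1]
            if rpos - pr == qpos - pq and rpos <= pr + pl:
                anchors[-1] = (pr, pq, rpos + k - pr)
                continue
        anchors.append((rpos, qpos, k))
    return anchors


@njit(cache=True)
def _chain_dp(rs: np.ndarray, qs: np.ndarray, ln: np.ndarray):
    """Maximum-weight colinear non-overlapping chain (O(n^2) DP)."""
    n = rs.size
    best = ln.astype(np.float64).copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        for j in range(i):
            if rs[j] + ln[j] <= rs[i] and qs[j] + ln[j] <= qs[i]:
                cand = best[j] + ln[i]
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = np.argmax(best)
    return best[end], prev, end


def chain_anchors(
    anchors: list[tuple[int, int, int]]
) -> tuple[list[tuple[int, int, int]], float]:
    """Heaviest colinear non-overlapping subset of anchors."""
    if not anchors:
        return [], 0.0
    anchors = sorted(anchors)
    rs = np.array([a[0] for a in anchors], dtype=np.int64)
    qs = np.array([a[1] for a in anchors], dtype=np.int64)
    ln = np.array([a[2] for a in anchors], dtype=np.int64)
    weight, prev, end = _chain_dp(rs, qs, ln)
    chain = []
    i = int(end)
    while i >= 0:
        chain.append(anchors[i])
        i = int(prev[i])
    return chain[::-1], float(weight)


# ---------------------------------------------------------------------------
# Gap closure / segment map


def _cigar_to_rows(cigar: str, ref_gap: str, qry_gap: str) -> tuple[str, str]:
    r_out, q_out = [], []
    ri = qi = 0
    for num, op in re.findall(r"(\d+)([=XMIDN])", cigar):
        num = int(num)
        if op in "=XM":
            r_out.append(ref_gap[ri : ri + num])
            q_out.append(qry_gap[qi : qi + num])
            ri += num
            qi += num
        elif op == "I":  # insertion in query
            r_out.append("-" * num)
            q_out.append(qry_gap[qi : qi + num])
            qi += num
        else:  # deletion from query
            r_out.append(ref_gap[ri : ri + num])
            q_out.append("-" * num)
            ri += num
    return "".join(r_out), "".join(q_out)


def anchor_chain_align(
    ref: Genome | str,
    qry: Genome | str,
    min_anchor: int = 20,
    max_gap: int = 5_000,
    contig: str | None = None,
    ref_id: str = "ref",
    qry_id: str = "query",
) -> SegmentMap:
    """Colinear whole-sequence alignment via unique-anchor chaining.

    Every reference base is assigned to exactly one aligned block or one
    unaligned interval. With no anchors at all the map is empty (all of
    the reference unaligned).
    """
    if isinstance(ref, Genome):
        contig = contig or next(iter(ref.contigs))
        ref_id, ref_seq = ref.genome_id, ref.contigs[contig]
    else:
        ref_seq = ref
        contig = contig or "chr"
    if isinstance(qry, Genome):
        qry_id, qry_seq = qry.genome_id, qry.contigs[contig if contig in qry.contigs else next(iter(qry.contigs))]
    else:
        qry_seq = qry
    if not ref_seq or not qry_seq:
        raise ValueError("sequences must be non-empty")

    anchors = find_anchors(ref_seq, qry_seq, min_anchor)
    chain, _ = chain_anchors(anchors)
    smap = SegmentMap(ref_id=ref_id, qry_id=qry_id, contig=contig)
    if not chain:
        smap.unaligned_ref.append((0, len(ref_seq)))
        return smap

    def add_block(rs: int, re_: int, qs: int, qe: int) -> None:
        """Align ref[rs:re_] against qry[qs:qe] (possibly via edlib)."""
        if re_ == rs and qe == qs:
            return
        rgap, qgap = ref_seq[rs:re_], qry_seq[qs:qe]
        if len(rgap) == len(qgap):
            smap.blocks.append(Block(rs, re_, qs, qe, rgap, qgap))
        elif len(rgap) <= max_gap and len(qgap) <= max_gap and rgap and qgap:
            import edlib

            aln = edlib.align(qgap, rgap, mode="NW", task="path")
            r_aln, q_aln = _cigar_to_rows(aln["cigar"], rgap, qgap)
            smap.blocks.append(Block(rs, re_, qs, qe, r_aln, q_aln))
        else:
            if re_ > rs:
                smap.unaligned_ref.append((rs, re_))

    first = chain[0]
    add_block(max(0, first[0] - first[1]), first[0], max(0, first[1] - first[0]), first[1])
    if first[0] - first[1] > 0:
        # Query starts inside the ref: leading ref overhang unaligned.
        smap.unaligned_ref.insert(0, (0, first[0] - first[1]))
    prev = None
    for rs, qs, ln in chain:
        if prev is not None:
            add_block(prev[0] + prev[2], rs, prev[1] + prev[2], qs)
        smap.blocks.append(
            Block(rs, rs + ln, qs, qs + ln, ref_seq[rs : rs + ln], qry_seq[qs : qs + ln])
        )
        prev = (rs, qs, ln)
    # Trailing segment.
    last_r, last_q = prev[0] + prev[2], prev[1] + prev[2]
    rtail, qtail = len(ref_seq) - last_r, len(qry_seq) - last_q
    if rtail or qtail:
        if rtail == qtail or (rtail <= max_gap and qtail <= max_gap and rtail and qtail):
            add_block(last_r, len(ref_seq), last_q, len(qry_seq))
        elif rtail:
            smap.unaligned_ref.append((last_r, len(ref_seq)))
    smap.blocks.sort(key=lambda b: b.ref_start)
    # Merge adjacent equal-length ungapped blocks for compactness.
    merged: list[Block] = []
    for b in smap.blocks:
        if (
            merged
            and "-" not in merged[-1].ref_aln[-1:]
            and merged[-1].ref_end == b.ref_start
            and merged[-1].qry_end == b.qry_start
            and "-" not in b.ref_aln
            and "-" not in b.qry_aln
            and "-" not in merged[-1].ref_aln
            and "-" not in merged[-1].qry_aln
        ):
            m = merged[-1]
            merged[-1] = Block(
                m.ref_start, b.ref_end, m.qry_start, b.qry_end,
                m.ref_aln + b.ref_aln, m.qry_aln + b.qry_aln,
            )
        else:
            merged.append(b)
    smap.blocks = merged
    smap.unaligned_ref.sort()
    return smap


# ---------------------------------------------------------------------------
# SNP calling


def call_snps(smap: SegmentMap) -> list[SnpRecord]:
    """One record per mismatched aligned column with unambiguous bases.

    Indel columns and columns containing N are skipped; records are
    sorted by reference position.
    """
    out: list[SnpRecord] = []
    for b in smap.blocks:
        if len(b.ref_aln) == len(b.ref_aln.replace("-", "")) == len(b.qry_aln):
            # Ungapped block: vectorized compare.
            r = np.frombuffer(b.ref_aln.encode(), dtype=np.uint8)
            q = np.frombuffer(b.qry_aln.encode(), dtype=np.uint8)
            for off in np.nonzero(r != q)[0]:
                rb, qb = b.ref_aln[off], b.qry_aln[off]
                if rb in _ACGT and qb in _ACGT:
                    out.append(SnpRecord(smap.contig, b.ref_start + int(off), rb, qb))
        else:
            rpos = b.ref_start
            for rb, qb in zip(b.ref_aln, b.qry_aln):
                if rb != "-":
                    if qb != "-" and rb != qb and rb in _ACGT and qb in _ACGT:
                        out.append(SnpRecord(smap.contig, rpos, rb, qb))
                    rpos += 1
    out.sort(key=lambda s: s.position)
    return out


def label_snp_regions(
    snps: list[SnpRecord],
    island_intervals: list[tuple[int, int]],
    smap: SegmentMap | None = None,
    adjacency: int = 100,
) -> list[SnpRecord]:
    """Assign island / backbone / unaligned-adjacent labels in place."""
    edges: list[int] = []
    if smap is not None:
        for s, e in smap.unaligned_ref:
            edges.extend((s, e))
    for snp in snps:
        if any(s <= snp.position < e for s, e in island_intervals):
            snp.region = "island"
        elif any(abs(snp.position - x) <= adjacency for x in edges):
            snp.region = "unaligned-adjacent"
        else:
            snp.region = "backbone"
    return snps


# ---------------------------------------------------------------------------
# Windows and frequencies


@dataclass
class WindowTrack:
    window: int
    region: tuple[int, int]
    starts: list[int]
    effective_lengths: list[int]
    counts: list[int]


def window_snp_histogram(
    snps: list[SnpRecord],
    region: tuple[int, int],
    window: int = 500,
    smap: SegmentMap | None = None,
) -> WindowTrack:
    """Tile *region* with fixed windows and count SNPs per window.

    The last partial window keeps its true (shorter) span; when a
    segment map is given, effective lengths count aligned ref bp only.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    start, end = region
    starts, lengths, counts = [], [], []
    pos = start
    while pos < end:
        wend = min(pos + window, end)
        starts.append(pos)
        if smap is not None:
            lengths.append(smap.aligned_ref_length((pos, wend)))
        else:
            lengths.append(wend - pos)
        counts.append(sum(1 for s in snps if pos <= s.position < wend))
        pos = wend
    return WindowTrack(window, region, starts, lengths, counts)


def region_snp_frequency(
    snps: list[SnpRecord],
    region: tuple[int, int],
    smap: SegmentMap,
    denominator: str = "aligned",
) -> tuple[int, int, float]:
    """(count, denominator bp, frequency) for SNPs inside *region*.

    ``denominator='aligned'`` uses aligned reference bp in the region
    (the default: draft-genome comparisons leave unaligned holes);
    ``'total'`` uses the raw region length.
    """
    count = sum(1 for s in snps if region[0] <= s.position < region[1])
    if denominator == "aligned":
        denom = smap.aligned_ref_length(region)
    elif denominator == "total":
        denom = region[1] - region[0]
    else:
        raise ValueError("denominator must be 'aligned' or 'total'")
    if denom == 0:
        raise ValueError("zero-length denominator: frequency undefined")
    return count, denom, count / denom


# ---------------------------------------------------------------------------
# Acquisition contrast


@dataclass
class ContrastResult:
    island_snps: int
    island_bp: int
    island_freq: float
    backbone_snps: int
    backbone_bp: int
    backbone_freq: float
    ratio: float
    p_value: float
    call: str  # recent_independent | ancestral_vertical | indeterminate


def acquisition_contrast_test(
    island: tuple[int, int],
    backbone: tuple[int, int],
    alpha: float = 0.01,
    ratio_cut: float = 0.1,
    two_sided: bool = False,
) -> ContrastResult:
    """Island-vs-backbone SNP frequency contrast.

    ``island=(k1, n1)`` and ``backbone=(k2, n2)`` are SNP counts over
    aligned bp. The one-sided exact binomial tail
    ``p = P(X <= k1), X ~ Binomial(n1, k2/n2)`` measures depletion of
    island SNPs at the backbone rate. Classification: recent_independent
    when ``p < alpha`` and ratio < ``ratio_cut``; ancestral_vertical when
    the ratio lies in [0.5, 2]; otherwise indeterminate.
    """
    k1, n1 = island
    k2, n2 = backbone
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if k2 == 0:
        raise ValueError("backbone SNP rate is zero: contrast undefined")
    rate = k2 / n2
    p = float(binom.cdf(k1, n1, rate))
    if two_sided:
        p = float(min(1.0, 2.0 * min(p, 1.0 - binom.cdf(k1 - 1, n1, rate))))
    f1, f2 = k1 / n1, k2 / n2
    ratio = f1 / f2
    if p < alpha and ratio < ratio_cut:
        call = "recent_independent"
    elif 0.5 <= ratio <= 2.0:
        call = "ancestral_vertical"
    else:
        call = "indeterminate"
    return ContrastResult(k1, n1, f1, k2, n2, f2, ratio, p, call)


# ---------------------------------------------------------------------------
# Coding effects


_START_CODONS = {"ATG", "GTG", "TTG"}


@dataclass
class CodingEffect:
    snp: SnpRecord
    gene_id: str
    classification: str  # synonymous | nonsynonymous | nonsense | start_loss
    substitution: str | None = None  # "X<pos>Y", 1-based residue


def annotate_coding_effect(
    snp: SnpRecord, feature: Feature, genome: Genome
) -> CodingEffect:
    """Classify a SNP inside a CDS by its codon-level effect.

    Translation is strand-aware under the standard code. A change that
    destroys the start codon (ATG/GTG/TTG) is ``start_loss``; a change
    producing an internal stop is ``nonsense``; otherwise synonymous or
    nonsynonymous, the latter with an ``X<pos>Y`` string (1-based residue
    index).
    """
    if not (feature.start <= snp.position < feature.end):
        raise ValueError("SNP not inside the CDS feature")
    if feature.length % 3 != 0:
        raise ValueError(f"CDS {feature.feature_id} length not divisible by 3")
    from Bio.Seq import Seq

    from .genome import revcomp

    cds = genome.feature_seq(feature)
    if feature.strand == "+":
        cpos = snp.position - feature.start
        alt = snp.alt_base
    else:
        cpos = feature.end - 1 - snp.position
        alt = revcomp(snp.alt_base)
    if cds[cpos] != (snp.ref_base if feature.strand == "+" else revcomp(snp.ref_base)):
        raise ValueError("reference base disagrees with the CDS sequence")
    ci = cpos // 3
    codon = cds[3 * ci : 3 * ci + 3]
    new_codon = codon[: cpos % 3] + alt + codon[cpos % 3 + 1 :]
    if ci == 0:
        if codon in _START_CODONS and new_codon not in _START_CODONS:
            return CodingEffect(snp, feature.feature_id, "start_loss")
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if aa_new == "*" and aa_old != "*" and ci < feature.length // 3 - 1:
        return CodingEffect(snp, feature.feature_id, "nonsense")
    if aa_old == aa_new:
        return CodingEffect(snp, feature.feature_id, "synonymous")
    return CodingEffect(
        snp, feature.feature_id, "nonsynonymous", f"{aa_old}{ci + 1}{aa_new}"
    )


def annotate_snps(
    snps: list[SnpRecord], genome: Genome
) -> list[CodingEffect]:
    """Annotate every SNP falling inside an annotated CDS."""
    cds = genome.features_of_type("CDS")
    out = []
    for snp in snps:
        for f in cds:
            if f.contig == snp.contig and f.start <= snp.position < f.end:
                try:
                    out.append(annotate_coding_effect(snp, f, genome))
                except ValueError:
                    out.append(CodingEffect(snp, f.feature_id, "unclassified"))
                break
    return out


# ---------------------------------------------------------------------------
# Writers (minimal VCF / bedGraph / contrast JSON)


def write_vcf(path: str | Path, snps: list[SnpRecord], ref_id: str, qry_id: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={ref_id}\n")
        fh.write(f"##source=islekit query={qry_id}\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="island|backbone|unaligned-adjacent">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.contig}\t{s.position + 1}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\tREGION={s.region}\n"
            )


def read_vcf(path: str | Path) -> list[SnpRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            region = "backbone"
            for item in info.split(";"):
                if item.startswith("REGION="):
                    region = item.split("=", 1)[1]
            out.append(SnpRecord(c, int(pos) - 1, ref, alt, region))
    return out


def write_bedgraph(path: str | Path, contig: str, track: WindowTrack) -> None:
    with open(path, "w") as fh:
        for start, eff, count in zip(track.starts, track.effective_lengths, track.counts):
            end = min(start + track.window, track.region[1])
            fh.write(f"{contig}\t{start}\t{end}\t{count}\n")
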