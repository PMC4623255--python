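"""Genomic-island delineation and mobility characterization.

The delineation chain mirrors how tRNA-integrated islands are recognized
in finished genomes: find long flanking direct repeats (the target-site
duplication), require one copy to overlap a tRNA, call the island span
from the end of the proximal repeat copy to the end of the distal copy
(leaving the intact tRNA outside the island), verify that the island's
flanking genes form a contiguous block in a non-carrier relative, expand
a shared "core" gene set outward from the ``pcrA``/``cld`` anchors, and
classify the island's mobility mechanism from marker annotations.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome import Feature, Genome
from .orthology import OrthologCluster

DEFAULT_MIN_REPEAT = 40
DEFAULT_SEED_K = 16


@dataclass
class RepeatPair:
    """Two same-orientation repeat copies on one contig (copy1 first)."""

    contig: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    length: int
    mismatches: int
    orientation: str = "direct"

    def __post_init__(self) -> None:
        if self.copy1[0] > self.copy2[0]:
            raise ValueError("copy1 must precede copy2")
        if self.copy1[1] - self.copy1[0] != self.copy2[1] - self.copy2[0]:
            raise ValueError("repeat copies must have equal length")

    @property
    def separation(self) -> int:
        """Inner distance between the copies (copy2 start − copy1 end)."""
        return self.copy2[0] - self.copy1[1]


@dataclass
class IslandCall:
    genome_id: str
    contig: str
    start: int
    end: int
    repeat: RepeatPair | None = None
    integration_feature: str | None = None
    gene_ids: list[str] = field(default_factory=list)
    evidence: dict[str, bool] = field(default_factory=dict)
    alternates: list[RepeatPair] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_direct_repeats(
    contig_seq: str,
    min_len: int = DEFAULT_MIN_REPEAT,
    max_mismatch: int = 0,
    min_sep: int = 5_000,
    max_sep: int = 200_000,
    seed_k: int = DEFAULT_SEED_K,
    max_kmer_occurrences: int = 100,
    contig: str = "chr",
) -> list[RepeatPair]:
    """All maximal direct repeat pairs with the given length/separation.

    Exact ``seed_k``-mer seeding followed by maximal extension (greedy,
    rightward then leftward, spending at most ``max_mismatch`` Hamming
    mismatches). Separation is the inner distance between the copies.
    Pairs fully contained in a longer reported pair are suppressed;
    k-mers occurring more than ``max_kmer_occurrences`` times are skipped
    as low-complexity guards.
    """
    if min_len < seed_k:
        raise ValueError(f"min_len ({min_len}) must be >= seed_k ({seed_k})")
    n = len(contig_seq)
    if n < min_len:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        index[contig_seq[i : i + seed_k]].append(i)

    seen: set[tuple[int, int, int]] = set()
    pairs: list[RepeatPair] = []
    for positions in index.values():
        if len(positions) < 2 or len(positions) > max_kmer_occurrences:
            continue
        for ai, a in enumerate(positions):
            for b in positions[ai + 1 :]:
                s1, s2, length, mm = _extend_pair(
                    contig_seq, a, b, seed_k, max_mismatch
                )
                key = (s1, s2, length)
                if key in seen:
                    continue
                seen.add(key)
                if length < min_len:
                    continue
                sep = s2 - (s1 + length)
                if sep < min_sep or sep > max_sep:
                    continue
                pairs.append(
                    RepeatPair(contig, (s1, s1 + length), (s2, s2 + length), length, mm)
                )
    # Suppress pairs contained in longer ones.
    pairs.sort(key=lambda p: (-p.length, p.copy1[0], p.copy2[0]))
    kept: list[RepeatPair] = []
    for p in pairs:
        contained = any(
            p.copy1[0] >= q.copy1[0]
            and p.copy1[1] <= q.copy1[1]
            and p.copy2[0] >= q.copy2[0]
            and p.copy2[1] <= q.copy2[1]
            for q in kept
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.copy1[0], p.copy2[0]))
    return kept


def _extend_pair(
    seq: str, a: int, b: int, k: int, max_mismatch: int
) -> tuple[int, int, int, int]:
    """Greedily extend an exact seed at (a, b) right then left."""
    mm = 0
    # Right.
    ea, eb = a + k, b + k
    while eb < len(seq) and ea < b:
        if seq[ea] == seq[eb]:
            ea += 1
            eb += 1
        elif mm < max_mismatch:
            mm += 1
            ea += 1
            eb += 1
        else:
            break
    # Trim trailing mismatches.
    while ea > a + k and seq[ea - 1] != seq[eb - 1]:
        ea -= 1
        eb -= 1
        mm -= 1
    # Left.
    sa, sb = a, b
    while sa > 0 and sb > ea:
        if seq[sa - 1] == seq[sb - 1]:
            sa -= 1
            sb -= 1
        elif mm < max_mismatch:
            mm += 1
            sa -= 1
            sb -= 1
        else:
            break
    while sa < a and seq[sa] != seq[sb]:
        sa += 1
        sb += 1
        mm -= 1
    return sa, sb, ea - sa, mm


def locate_integration_sites(
    genome: Genome, repeats: list[RepeatPair]
) -> list[IslandCall]:
    """Island calls from repeat pairs anchored at tRNA features.

    A repeat pair qualifies when at least one copy overlaps a tRNA; the
    island span runs from the end of the proximal copy to the end of the
    distal copy (the island carries the distal repeat copy and the tRNA
    stays intact). When several qualifying pairs share a tRNA copy the
    longest span wins; the others are kept as alternates.
    """
    trnas = genome.features_of_type("tRNA")
    by_trna: dict[str, list[RepeatPair]] = defaultdict(list)
    for rp in repeats:
        for t in trnas:
            if t.contig != rp.contig:
                continue
            if _overlaps(t, rp.copy1) or _overlaps(t, rp.copy2):
                by_trna[t.feature_id].append(rp)
                break
    calls: list[IslandCall] = []
    for tid, cands in sorted(by_trna.items()):
        cands = sorted(cands, key=lambda p: (p.copy2[1] - p.copy1[1]), reverse=True)
        best, rest = cands[0], cands[1:]
        start, end = best.copy1[1], best.copy2[1]
        genes = [
            f.feature_id
            for f in genome.features_of_type("CDS")
            if f.contig == best.contig and f.start >= start and f.end <= end
        ]
        gene_labels = {genome.get_feature(g).gene for g in genes}
        calls.append(
            IslandCall(
                genome_id=genome.genome_id,
                contig=best.contig,
                start=start,
                end=end,
                repeat=best,
                integration_feature=tid,
                gene_ids=genes,
                evidence={
                    "repeat": True,
                    "trna": True,
                    "anchors": {"pcrA", "cld"} <= gene_labels,
                    "synteny": False,
                },
                alternates=rest,
            )
        )
    calls.sort(key=lambda c: (c.contig, c.start))
    return calls


def _overlaps(feat: Feature, interval: tuple[int, int]) -> bool:
    return feat.start < interval[1] and interval[0] < feat.end


def delineate_islands(genome: Genome, **repeat_kwargs) -> list[IslandCall]:
    """Repeat scan + tRNA anchoring over every contig of a genome."""
    calls: list[IslandCall] = []
    for contig, seq in genome.contigs.items():
        reps = find_direct_repeats(seq, contig=contig, **repeat_kwargs)
        calls.extend(
            c for c in locate_integration_sites(genome, reps) if c.contig == contig
        )
    return calls


# ---------------------------------------------------------------------------
# Flanking synteny


def flanking_synteny_score(
    carrier: Genome,
    island: IslandCall,
    noncarrier: Genome,
    clusters: list[OrthologCluster],
    m_flank: int = 5,
    gap_tolerance: int = 1,
) -> tuple[bool, int]:
    """Do the island's flanking genes form a contiguous run in a relative?

    Takes ``m_flank`` CDS on each side of the island in the carrier, maps
    them through the ortholog clusters into the non-carrier's gene order,
    and reports ``(contiguous, intervening_gene_count)``: contiguous when
    the mapped upstream and downstream blocks are adjacent up to
    ``gap_tolerance`` intervening genes (orientation-agnostic).
    """
    to_cluster: dict[tuple[str, str], str] = {}
    for c in clusters:
        for member in c.members:
            to_cluster[member] = c.cluster_id
    car_genes = [
        f for f in carrier.features_of_type("CDS") if f.contig == island.contig
    ]
    upstream = [f for f in car_genes if f.end <= island.start][-m_flank:]
    downstream = [f for f in car_genes if f.start >= island.end][:m_flank]

    non_genes = noncarrier.features_of_type("CDS")
    order = {f.feature_id: i for i, f in enumerate(non_genes)}
    non_by_cluster: dict[str, list[int]] = defaultdict(list)
    for f in non_genes:
        cid = to_cluster.get((noncarrier.genome_id, f.feature_id))
        if cid:
            non_by_cluster[cid].append(order[f.feature_id])

    def mapped(feats: list[Feature]) -> list[int]:
        out = []
        for f in feats:
            cid = to_cluster.get((carrier.genome_id, f.feature_id))
            hits = non_by_cluster.get(cid, []) if cid else []
            if len(hits) == 1:
                out.append(hits[0])
        return out

    up_idx, down_idx = mapped(upstream), mapped(downstream)
    if not up_idx or not down_idx:
        return False, -1
    if max(up_idx) < min(down_idx):
        intervening = min(down_idx) - max(up_idx) - 1
    elif max(down_idx) < min(up_idx):
        intervening = min(up_idx) - max(down_idx) - 1
    else:  # interleaved blocks: not colinear
        return False, -1
    return intervening <= gap_tolerance, intervening


# ---------------------------------------------------------------------------
# Anchor-based core expansion


@dataclass
class CoreGeneSet:
    core: set[str]  # cluster ids shared by >= 2 islands, anchor-reachable
    accessory: dict[str, set[str]]  # island id -> island-specific cluster ids
    anchors: set[str]


def anchor_core_expansion(
    island_genes: dict[str, list[tuple[str, str]]],
    anchors: set[str],
    stop_run: int = 3,
) -> CoreGeneSet:
    """Expand the island core outward from the anchor loci.

    ``island_genes`` maps an island id to its ordered (gene_id,
    cluster_id) list. Starting at each anchor cluster, the walk moves
    gene by gene in both directions; a gene joins the core when its
    cluster occurs in >= 2 islands, and each direction stops after
    ``stop_run`` consecutive island-specific genes. Remaining island
    genes are accessory.
    """
    if len(island_genes) < 2:
        raise ValueError("core/accessory partition needs >= 2 islands")
    occurrence: dict[str, int] = defaultdict(int)
    for genes in island_genes.values():
        for cid in {cid for _, cid in genes}:
            occurrence[cid] += 1
    if not any(
        cid in anchors for genes in island_genes.values() for _, cid in genes
    ):
        raise ValueError("no anchor cluster present in any island")

    core: set[str] = set()
    accessory: dict[str, set[str]] = {}
    for iid, genes in island_genes.items():
        clusters = [cid for _, cid in genes]
        in_core = [False] * len(clusters)
        for pos, cid in enumerate(clusters):
            if cid not in anchors:
                continue
            in_core[pos] = True
            for direction in (-1, 1):
                run = 0
                p = pos + direction
                while 0 <= p < len(clusters) and run < stop_run:
                    if occurrence[clusters[p]] >= 2:
                        in_core[p] = True
                        run = 0
                    else:
                        run += 1
                    p += direction
        island_core = {c for c, flag in zip(clusters, in_core) if flag}
        core |= island_core
        accessory[iid] = set(clusters) - island_core
    # A cluster in the core anywhere is core everywhere.
    for iid in accessory:
        accessory[iid] -= core
    return CoreGeneSet(core=core, accessory=accessory, anchors=anchors & core)


# ---------------------------------------------------------------------------
# Mobility classification


DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "recombinase": ("recombinase", "integrase", "xerd"),
    "conjugation": ("conjugal", "conjugation", "tra", "trb", "virb", "type iv secretion"),
    "replication": ("replication", "repa", "replicase"),
    "insertion_sequence": ("transposase", "insertion sequence", "is element"),
}


def _marker_match(text: str, key: str) -> bool:
    """Multi-word keys match as substrings; single words as token prefixes.

    Token-prefix matching keeps ``tra`` from firing on e.g. "tetraheme"
    while still catching TraB/transfer/transposase-style names.
    """
    if " " in key:
        return key in text
    return any(tok.startswith(key) for tok in text.replace("-", " ").split())


@dataclass
class MobilityClass:
    label: str  # trna_integrative | ice | composite_transposon | unknown
    markers: dict[str, list[str]]
    all_matches: list[str] = field(default_factory=list)


def _identity_equal_or_edlib(a: str, b: str) -> float:
    if a == b:
        return 1.0
    import edlib

    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def classify_mobility(
    island: IslandCall,
    genome: Genome,
    markers: dict[str, tuple[str, ...]] | None = None,
    is_min_len: int = 500,
    is_min_identity: float = 0.95,
    is_window: int = 2_000,
) -> MobilityClass:
    """Assign a mobility class from marker annotations.

    * ``trna_integrative``: tRNA-anchored repeat pair plus a recombinase
      marker inside the span;
    * ``ice``: conjugation and replication markers inside the span;
    * ``composite_transposon``: the span is flanked (within
      ``is_window`` of each end, ends included) by two insertion-sequence
      features >= ``is_min_len`` bp and >= ``is_min_identity`` identical;
    * ``unknown`` otherwise.

    Multiple matching classes report in priority order trna_integrative >
    ice > composite_transposon, with all evidence listed. Always returns
    a class (total and deterministic).
    """
    markers = markers or DEFAULT_MARKERS
    found: dict[str, list[str]] = {k: [] for k in markers}
    for gid in island.gene_ids:
        f = genome.get_feature(gid)
        text = f"{f.gene} {f.product}".lower()
        for cls, keys in markers.items():
            if any(_marker_match(text, k) for k in keys):
                found[cls].append(gid)

    matches: list[str] = []
    if (
        island.evidence.get("repeat")
        and island.evidence.get("trna")
        and found["recombinase"]
    ):
        matches.append("trna_integrative")
    if found["conjugation"] and found["replication"]:
        matches.append("ice")

    # Flanking IS copies (inside the span termini or just outside).
    is_feats = []
    for f in genome.features_of_type("CDS"):
        if f.contig != island.contig:
            continue
        text = f"{f.gene} {f.product}".lower()
        if not any(_marker_match(text, k) for k in markers["insertion_sequence"]):
            continue
        if f.length < is_min_len:
            continue
        if (
            island.start - is_window <= f.start
            and f.end <= island.end + is_window
        ):
            is_feats.append(f)
    left = [f for f in is_feats if f.start - island.start <= is_window]
    right = [f for f in is_feats if island.end - f.end <= is_window]
    for fl in left:
        for fr in right:
            if fl is fr:
                continue
            ident = _identity_equal_or_edlib(
                genome.feature_seq(fl), genome.feature_seq(fr)
            )
            if ident >= is_min_identity:
                matches.append("composite_transposon")
                found["insertion_sequence"] = sorted(
                    {fl.feature_id, fr.feature_id}
                )
                break
        if "composite_transposon" in matches:
            break

    label = matches[0] if matches else "unknown"
    return MobilityClass(label=label, markers=found, all_matches=matches)
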