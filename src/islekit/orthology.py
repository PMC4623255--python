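"""Homology detection and ortholog clustering across proteomes.

The locus-selection logic mirrors standard MLSA practice: all-vs-all
pairwise local protein alignment, reciprocal best hits (RBH) per genome
pair, clustering as connected components of the RBH graph, and a
single-copy-complete filter that keeps only clusters with exactly one
member in every genome — the loci that enter the supermatrix.

Scoring uses Smith–Waterman local alignment with BLOSUM62 and affine gaps
(open 11, extend 1, applied as −11 for the first gap position and −1 for
each additional one). A k-mer prefilter (shared 5-mers) skips obviously
unrelated pairs before alignment; it can be disabled by setting
``min_shared_kmers=0``.

Best-hit ties are resolved conservatively: a query whose two best subjects
score identically is excluded from RBH for that genome pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import Genome

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class ProteinRecord:
    """A protein with its genomic provenance."""

    genome_id: str
    gene_id: str
    sequence: str
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty protein sequence for {self.gene_id}")


def proteome_from_genome(
    genome: Genome, min_length: int = 30, to_stop: bool = False
) -> list[ProteinRecord]:
    """Translate every CDS into a protein record.

    By default the full annotated CDS is translated and internal stops
    become ``X``, so pseudogenes stay full-length and alignable (the
    alphabet is the 20 amino acids plus X). With ``to_stop=True``
    translation truncates at the first stop instead. Products shorter
    than ``min_length`` residues are dropped.
    """
    out = []
    for f in genome.features_of_type("CDS"):
        aa = genome.translate_cds(f, to_stop=to_stop).replace("*", "X")
        if len(aa) >= min_length:
            out.append(
                ProteinRecord(genome.genome_id, f.feature_id, aa, f.contig, f.start, f.end, f.strand)
            )
    return out


def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def score_local_alignment(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> tuple[float, float, int]:
    """Optimal local affine-gap alignment of two proteins.

    Returns ``(score, identity, aln_length)`` where identity is
    matches / alignment columns of the optimal traceback (gap columns
    count) and ``aln_length`` is the number of traceback columns. An
    empty optimal alignment (score 0 between unrelated sequences) yields
    identity 0 and length 0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0.0, 0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aln_length = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / aln_length if aln_length else 0.0
    return float(score), identity, int(aln_length)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    proteomes: dict[str, list[ProteinRecord]],
    min_score: float = DEFAULT_MIN_SCORE,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
    seed_kmer: int = 5,
    min_shared_kmers: int = 2,
) -> pd.DataFrame:
    """All-vs-all protein hits between every pair of proteomes.

    Coverage is aligned residue pairs / length of the shorter sequence.
    Both hit directions are emitted (scores are symmetric). Rows are
    ordered deterministically by (query genome, subject genome, query,
    subject).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    kmers: dict[tuple[str, str], set[str]] = {}
    if min_shared_kmers > 0:
        for gid, prots in proteomes.items():
            for p in prots:
                kmers[(gid, p.gene_id)] = _kmer_set(p.sequence, seed_kmer)
    rows = []
    gids = sorted(proteomes)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            for pa in proteomes[ga]:
                for pb in proteomes[gb]:
                    if min_shared_kmers > 0 and (
                        len(kmers[(ga, pa.gene_id)] & kmers[(gb, pb.gene_id)])
                        < min_shared_kmers
                    ):
                        continue
                    score = aligner.score(pa.sequence, pb.sequence)
                    if score < min_score or score <= 0:
                        continue
                    aln = aligner.align(pa.sequence, pb.sequence)[0]
                    counts = aln.counts()
                    aln_length = counts.gaps + counts.identities + counts.mismatches
                    aligned_pairs = counts.identities + counts.mismatches
                    shorter = min(len(pa.sequence), len(pb.sequence))
                    if aligned_pairs / shorter < min_coverage:
                        continue
                    identity = counts.identities / aln_length if aln_length else 0.0
                    rows.append((ga, pa.gene_id, gb, pb.gene_id, float(score), identity, int(aln_length)))
    hits = pd.DataFrame(
        rows,
        columns=[
            "query_genome", "query_id", "subject_genome", "subject_id",
            "score", "identity", "aln_length",
        ],
    )
    # Mirror to get both directions explicitly.
    mirror = hits.rename(
        columns={
            "query_genome": "subject_genome", "query_id": "subject_id",
            "subject_genome": "query_genome", "subject_id": "query_id",
        }
    )
    hits = pd.concat([hits, mirror], ignore_index=True)
    return hits.sort_values(
        ["query_genome", "subject_genome", "query_id", "subject_id"],
        ignore_index=True,
    )


def reciprocal_best_hits(
    hits: pd.DataFrame, genome_a: str, genome_b: str
) -> list[tuple[str, str]]:
    """RBH pairs between two genomes; ties exclude the tied query."""

    def best_map(qg: str, sg: str) -> dict[str, str]:
        sub = hits[(hits.query_genome == qg) & (hits.subject_genome == sg)]
        best: dict[str, str] = {}
        for qid, grp in sub.groupby("query_id"):
            top = grp.score.max()
            winners = grp[grp.score == top].subject_id.tolist()
            if len(winners) == 1:
                best[qid] = winners[0]
        return best

    ab = best_map(genome_a, genome_b)
    ba = best_map(genome_b, genome_a)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


@dataclass
class OrthologCluster:
    """A homology group across genomes."""

    cluster_id: str
    members: set[tuple[str, str]] = field(default_factory=set)  # (genome, gene)

    def genomes(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g, _ in self.members:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def is_single_copy_complete(self, genome_set: set[str]) -> bool:
        counts = self.genomes()
        return set(counts) == set(genome_set) and all(v == 1 for v in counts.values())


def cluster_rbh_graph(
    rbh_pairs: dict[tuple[str, str], list[tuple[str, str]]]
) -> list[OrthologCluster]:
    """Connected components of the union of all pairwise RBH graphs.

    ``rbh_pairs`` maps a (genome_a, genome_b) pair to its RBH gene pairs.
    Cluster ids are stable: components are sorted by their smallest
    member.
    """
    graph: nx.Graph = nx.Graph()
    for (ga, gb), pairs in rbh_pairs.items():
        for a, b in pairs:
            graph.add_edge((ga, a), (gb, b))
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    return [
        OrthologCluster(cluster_id=f"CL{i:05d}", members=set(comp))
        for i, comp in enumerate(comps, start=1)
    ]


def filter_single_copy_complete(
    clusters: list[OrthologCluster], genome_set: set[str]
) -> list[OrthologCluster]:
    """Clusters with exactly one member per genome of *genome_set*."""
    return [c for c in clusters if c.is_single_copy_complete(genome_set)]


def build_clusters(
    proteomes: dict[str, list[ProteinRecord]], **hit_kwargs
) -> tuple[list[OrthologCluster], pd.DataFrame]:
    """Hits → pairwise RBH → clusters, in one call."""
    hits = all_vs_all_hits(proteomes, **hit_kwargs)
    gids = sorted(proteomes)
    rbh = {}
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            rbh[(ga, gb)] = reciprocal_best_hits(hits, ga, gb)
    return cluster_rbh_graph(rbh), hits


def greedy_identity_cluster(
    sequences: dict[str, str],
    threshold: float = 0.90,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first identity clustering (CD-HIT style).

    Sequences are processed longest first; each becomes a new
    representative unless it is ≥ ``threshold`` identical (matches /
    global-alignment columns) to an existing representative. Returns the
    representative ids and a member → representative map.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for sid in order:
        placed = False
        for rid in reps:
            aln = aligner.align(sequences[sid], sequences[rid])[0]
            counts = aln.counts()
            cols = counts.gaps + counts.identities + counts.mismatches
            if cols and counts.identities / cols >= threshold:
                assign[sid] = rid
                placed = True
                break
        if not placed:
            reps.append(sid)
            assign[sid] = sid
    return reps, assign


# ---------------------------------------------------------------------------
# TSV export / import

def write_clusters_tsv(path: str | Path, clusters: list[OrthologCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome_id\tgene_id\n")
        for c in clusters:
            for genome_id, gene_id in sorted(c.members):
                fh.write(f"{c.cluster_id}\t{genome_id}\t{gene_id}\n")


def read_clusters_tsv(path: str | Path) -> list[OrthologCluster]:
    by_id: dict[str, OrthologCluster] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, genome_id, gene_id = line.split()
            by_id.setdefault(cid, OrthologCluster(cid)).members.add((genome_id, gene_id))
    return [by_id[k] for k in sorted(by_id)]
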