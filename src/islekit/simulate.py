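"""Forward simulator of bacterial genomes evolving along a species tree.

The simulator produces the study conditions for every downstream stage: a
small clade of genomes diverging under Jukes–Cantor substitutions, an
island (a contiguous cassette of genes, anchored by a perchlorate-
reductase-like ``pcrA`` and a chlorite-dismutase-like ``cld``) integrated
3' of a tRNA with a target-site duplication, horizontal transfer of that
island with a known residual divergence, and optional pseudogenization of
island genes. Everything the simulator plants is recorded in a
:class:`TruthBundle` so downstream inferences can be scored exactly.

Model notes
-----------
* Substitutions only (no indels): sequence length is conserved along every
  branch, and planted differences can be compared to called SNPs base by
  base.
* Branch lengths are expected substitutions per site. Each branch draws a
  Poisson number of events (``rate * length``), each event picks a uniform
  site and jumps to one of the three other bases uniformly — exactly the
  Jukes–Cantor process, so the observed difference fraction at path
  distance ``d`` is ``(3/4)(1 - exp(-4 d / 3))``.
* Island integration geometry: the island is inserted immediately 3' of
  the target tRNA, and the tRNA's terminal ``repeat_length`` bases are
  duplicated at the island's distal end, leaving the tRNA intact and the
  island flanked by two identical direct repeats.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .genome import Feature, Genome, revcomp

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_STARTS = ("ATG", "GTG", "TTG")


def _seq_to_idx(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return arr


def _idx_to_seq(arr: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# Species tree


def sample_species_tree(n_taxa: int, total_depth: float, seed: int) -> dendropy.Tree:
    """Sample a Yule (pure-birth) tree and rescale it to a fixed depth.

    The process starts with two lineages at the root; with ``k`` lineages
    the next speciation waits ``Exp(k)``, a uniformly chosen lineage
    splits, and after reaching ``n_taxa`` lineages a final ``Exp(n_taxa)``
    waiting time separates the last split from the present — so pendant
    branches are never zero. Branch lengths are then rescaled so that
    every root-to-tip path length equals ``total_depth`` (expected
    substitutions per site) exactly. Leaves are labelled ``T1..Tn`` in a
    canonical traversal order, so trees are reproducible given a seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if total_depth < 0:
        raise ValueError("total_depth must be >= 0")
    rng = random.Random(int(seed))
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    # Active lineages: (node, birth_time).
    active: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append((ch, 0.0))
    while len(active) < n_taxa:
        t += rng.expovariate(len(active))
        node, birth = active.pop(rng.randrange(len(active)))
        node.edge.length = t - birth
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            active.append((ch, t))
    t += rng.expovariate(len(active))
    for node, birth in active:
        node.edge.length = t - birth
    # Rescale to the requested depth (exact for every tip: ultrametric by
    # construction).
    factor = 0.0 if t == 0 else total_depth / t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    ns = tree.taxon_namespace
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon = ns.new_taxon(label=f"T{i}")
    ns.sort(key=lambda tx: tx.label)
    return tree


# ---------------------------------------------------------------------------
# Ancestral genome


@dataclass
class AncestralGenomeSpec:
    """Layout parameters for the simulated ancestral genome."""

    genome_length: int = 200_000
    n_genes: int = 150
    gene_length: int = 900
    n_trna: int = 4
    trna_length: int = 76
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_genes, self.n_trna) < 0:
            raise ValueError("counts and lengths must be >= 0")
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise ValueError("gene_length must be a multiple of 3 and >= 9")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        total = self.n_genes * self.gene_length + self.n_trna * self.trna_length
        if total > self.genome_length:
            raise ValueError(
                f"features ({total} bp) do not fit in genome_length "
                f"({self.genome_length} bp)"
            )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _idx_to_seq(rng.choice(4, size=n, p=p).astype(np.uint8))


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + random non-stop codons + one stop codon, total ``length`` bp."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def build_ancestral_genome(
    spec: AncestralGenomeSpec, genome_id: str = "ancestor", contig: str = "chr"
) -> Genome:
    """Build a single-contig ancestral genome with non-overlapping features.

    tRNAs are interleaved evenly among the genes; intergenic slack is
    distributed randomly; both strands are used.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_bases(rng, spec.genome_length, spec.gc_content))

    # Feature order: tRNAs spread evenly through the gene list.
    kinds: list[str] = ["CDS"] * spec.n_genes
    if spec.n_trna:
        step = max(1, (spec.n_genes + spec.n_trna) // (spec.n_trna + 1))
        for i in range(spec.n_trna):
            kinds.insert(min(len(kinds), (i + 1) * step + i), "tRNA")
    total_feat = spec.n_genes * spec.gene_length + spec.n_trna * spec.trna_length
    slack = spec.genome_length - total_feat
    n_gaps = len(kinds) + 1
    gaps = rng.multinomial(slack, np.ones(n_gaps) / n_gaps) if n_gaps else []

    features: list[Feature] = []
    pos = int(gaps[0]) if len(kinds) else 0
    gene_i = trna_i = 0
    for k, kind in enumerate(kinds):
        if kind == "CDS":
            gene_i += 1
            fid = f"gene_{gene_i:04d}"
            body = _random_cds(rng, spec.gene_length, spec.gc_content)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            placed = body if strand == "+" else revcomp(body)
            end = pos + spec.gene_length
            features.append(
                Feature(fid, "CDS", contig, pos, end, strand, gene=fid,
                        product=f"hypothetical protein {fid}")
            )
        else:
            trna_i += 1
            fid = f"trna_{trna_i:02d}"
            placed = _random_bases(rng, spec.trna_length, spec.gc_content)
            end = pos + spec.trna_length
            features.append(
                Feature(fid, "tRNA", contig, pos, end, "+", gene=fid,
                        product="tRNA-Pro" if trna_i == 2 else f"tRNA-{trna_i}")
            )
        seq[pos:end] = placed
        pos = end + int(gaps[k + 1])
    return Genome(genome_id, {contig: "".join(seq)}, features)


# ---------------------------------------------------------------------------
# Jukes–Cantor evolution


def jc_expected_difference(d: float) -> float:
    """Expected observed difference fraction at JC path distance *d*."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _mutate_idx(
    arr: np.ndarray, branch_length: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Apply a JC branch to an index array; returns (new array, n events)."""
    L = arr.size
    n = int(rng.poisson(branch_length * L)) if L else 0
    out = arr.copy()
    if n:
        pos = rng.integers(0, L, size=n)
        step = rng.integers(1, 4, size=n)
        for p, s in zip(pos.tolist(), step.tolist()):
            out[p] = (out[p] + s) % 4
    return out, n


def evolve_arr_along_tree(
    tree: dendropy.Tree, root_arr: np.ndarray, seed: int
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Evolve an index array down every branch of *tree*.

    Returns per-leaf arrays and per-branch realized event counts keyed by
    the child node (taxon label for leaves, ``N<i>`` preorder index for
    internal nodes). Traversal order is deterministic, so a fixed seed
    reproduces the run bit for bit.
    """
    rng = np.random.default_rng(seed)
    leaf_arrs: dict[str, np.ndarray] = {}
    branch_events: dict[str, int] = {}
    counter = [0]

    def label_of(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        counter[0] += 1
        return f"N{counter[0]}"

    def walk(node: dendropy.Node, arr: np.ndarray) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            child_arr, n = _mutate_idx(arr, b, rng)
            branch_events[label_of(child)] = n
            if child.is_leaf():
                leaf_arrs[child.taxon.label] = child_arr
            else:
                walk(child, child_arr)

    walk(tree.seed_node, root_arr)
    return leaf_arrs, branch_events


def evolve_sequences(
    tree: dendropy.Tree, root: Genome, seed: int
) -> tuple[dict[str, Genome], dict[str, int], dict[str, dict[int, tuple[str, str]]]]:
    """Evolve a whole genome along *tree* (substitutions only).

    Returns per-leaf genomes (feature tables copied from the root), the
    realized per-branch substitution-event counts, and per-leaf difference
    maps ``{position: (root_base, leaf_base)}`` computed against the root.
    """
    if len(root.contigs) != 1:
        raise ValueError("evolve_sequences expects a single-contig root genome")
    (contig, seq), = root.contigs.items()
    root_arr = _seq_to_idx(seq)
    leaf_arrs, branch_events = evolve_arr_along_tree(tree, root_arr, seed)
    leaves: dict[str, Genome] = {}
    diffs: dict[str, dict[int, tuple[str, str]]] = {}
    for label, arr in leaf_arrs.items():
        leaves[label] = Genome(
            label, {contig: _idx_to_seq(arr)}, [replace(f) for f in root.features]
        )
        where = np.nonzero(arr != root_arr)[0]
        diffs[label] = {
            int(p): (_BASES[root_arr[p]], _BASES[arr[p]]) for p in where
        }
    return leaves, branch_events, diffs


# ---------------------------------------------------------------------------
# Island template and insertion


@dataclass
class IslandGene:
    label: str
    rel_start: int
    rel_end: int
    strand: str
    product: str


@dataclass
class IslandTemplate:
    """A genomic-island cassette: sequence plus its gene roster.

    The roster always contains the two anchor genes ``pcrA`` and ``cld``
    exactly once each; depending on ``kind`` it additionally carries a
    site-specific recombinase (tRNA-integrative islands), conjugation and
    replication genes (ICEs), or terminal insertion-sequence copies
    (composite transposons).
    """

    length: int
    genes: list[IslandGene]
    sequence: str
    repeat_length: int = 48
    mobility_markers: tuple[str, ...] = ("recombinase",)
    kind: str = "trna_integrative"

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with declared length")
        if self.repeat_length < 1:
            raise ValueError("repeat_length must be >= 1")
        for anchor in ("pcrA", "cld"):
            if sum(g.label == anchor for g in self.genes) != 1:
                raise ValueError(f"anchor {anchor} must occur exactly once")


_CORE_PRODUCTS = [
    ("pcrA", "perchlorate reductase alpha subunit"),
    ("pcrB", "perchlorate reductase beta subunit"),
    ("cld", "chlorite dismutase"),
    ("pcrC", "tetraheme cytochrome c PcrC"),
    ("pcrD", "perchlorate reductase chaperone"),
    ("moaA", "molybdenum cofactor biosynthesis protein MoaA"),
]

_KIND_EXTRAS = {
    "trna_integrative": [("xerD", "site-specific tyrosine recombinase XerD")],
    "ice": [
        ("traB", "conjugal transfer protein TraB"),
        ("trbE", "conjugal transfer protein TrbE"),
        ("repA", "plasmid replication initiator protein RepA"),
    ],
    "composite_transposon": [],
}

_KIND_MARKERS = {
    "trna_integrative": ("recombinase",),
    "ice": ("conjugation", "replication"),
    "composite_transposon": ("insertion_sequence",),
}


def build_island_template(
    seed: int,
    length: int = 30_000,
    n_genes: int = 25,
    gene_length: int = 900,
    repeat_length: int = 48,
    kind: str = "trna_integrative",
    gc_content: float = 0.5,
    is_element_length: int = 800,
) -> IslandTemplate:
    """Build a random island cassette of ``n_genes`` labelled genes.

    Accessory filler genes are labelled ``acc_NN``; composite-transposon
    islands get two identical insertion-sequence copies at their termini.
    """
    if kind not in _KIND_EXTRAS:
        raise ValueError(f"unknown island kind {kind!r}")
    rng = np.random.default_rng(seed)
    roster = list(_CORE_PRODUCTS) + list(_KIND_EXTRAS[kind])
    if n_genes < len(roster):
        raise ValueError(f"n_genes must be >= {len(roster)} for kind {kind!r}")
    roster += [
        (f"acc_{i:02d}", f"island accessory protein {i}")
        for i in range(1, n_genes - len(roster) + 1)
    ]

    seq = list(_random_bases(rng, length, gc_content))
    genes: list[IslandGene] = []
    reserved = 0
    is_copy = ""
    if kind == "composite_transposon":
        # Two identical IS copies (a transposase CDS) at the termini.
        is_copy = _random_cds(rng, is_element_length - is_element_length % 3, gc_content)
        reserved = len(is_copy)
        for rel, lab in ((0, "IS_left"), (length - reserved, "IS_right")):
            seq[rel : rel + reserved] = is_copy
            genes.append(
                IslandGene(lab, rel, rel + reserved, "+", "IS family transposase")
            )
    inner_start, inner_end = reserved, length - reserved
    total_gene_bp = len(roster) * gene_length
    avail = inner_end - inner_start
    if total_gene_bp > avail:
        raise ValueError("island genes do not fit in island length")
    gaps = rng.multinomial(avail - total_gene_bp, np.ones(len(roster) + 1) / (len(roster) + 1))
    pos = inner_start + int(gaps[0])
    for k, (label, product) in enumerate(roster):
        body = _random_cds(rng, gene_length, gc_content)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq[pos : pos + gene_length] = body if strand == "+" else revcomp(body)
        genes.append(IslandGene(label, pos, pos + gene_length, strand, product))
        pos += gene_length + int(gaps[k + 1])
    return IslandTemplate(
        length=length,
        genes=sorted(genes, key=lambda g: g.rel_start),
        sequence="".join(seq),
        repeat_length=repeat_length,
        mobility_markers=_KIND_MARKERS[kind],
        kind=kind,
    )


def insert_island(
    genome: Genome,
    island: IslandTemplate,
    trna_index: int,
    island_sequence: str | None = None,
) -> tuple[Genome, tuple[str, int, int]]:
    """Integrate an island immediately 3' of the ``trna_index``-th tRNA.

    The terminal ``repeat_length`` bases of the target tRNA are duplicated
    at the island's distal end (target-site duplication), so the output
    grows by ``island.length + repeat_length`` and the island interval —
    end of the intact tRNA through the end of the distal repeat copy — is
    returned alongside the new genome.

    ``island_sequence`` overrides the template sequence (used to insert a
    lineage-specific, partially diverged island copy).
    """
    trnas = genome.features_of_type("tRNA")
    if trna_index < 0 or trna_index >= len(trnas):
        raise ValueError(
            f"genome {genome.genome_id} has no tRNA at index {trna_index}"
        )
    t = trnas[trna_index]
    if t.length < island.repeat_length:
        raise ValueError("target tRNA shorter than the direct repeat")
    iseq = island.sequence if island_sequence is None else island_sequence
    if len(iseq) != island.length:
        raise ValueError("island sequence length disagrees with template")
    contig = t.contig
    seq = genome.contigs[contig]
    ins = t.end
    repeat = seq[ins - island.repeat_length : ins]
    inserted = iseq + repeat
    new_seq = seq[:ins] + inserted + seq[ins:]
    shift = len(inserted)

    feats: list[Feature] = []
    for f in genome.features:
        if f.contig != contig or f.end <= ins:
            feats.append(replace(f))
        else:
            feats.append(f.shifted(shift))
    for g in island.genes:
        feats.append(
            Feature(
                feature_id=g.label,
                ftype="CDS",
                contig=contig,
                start=ins + g.rel_start,
                end=ins + g.rel_end,
                strand=g.strand,
                gene=g.label,
                product=g.product,
            )
        )
    span = (contig, ins, ins + shift)
    feats.append(
        Feature(
            feature_id=f"island_{genome.genome_id}",
            ftype="mobile_genetic_element",
            contig=contig,
            start=span[1],
            end=span[2],
            strand="+",
            gene="island",
            product=f"genomic island ({island.kind})",
        )
    )
    new_contigs = dict(genome.contigs)
    new_contigs[contig] = new_seq
    return Genome(genome.genome_id, new_contigs, feats), span


# ---------------------------------------------------------------------------
# Horizontal transfer and pseudogenization


@dataclass
class Event:
    etype: str  # insertion | transfer | pseudogenization
    time: float  # residual branch length (subs/site) before the recipient tip
    donor: str
    recipient: str
    payload: str


def apply_hgt_event(
    recipient: Genome,
    island: IslandTemplate,
    donor_island_seq: str,
    residual_divergence: float,
    trna_index: int,
    seed: int,
    event_log: list[Event],
    donor: str = "donor",
) -> tuple[Genome, tuple[str, int, int], dict[int, tuple[str, str]], int]:
    """Transfer an island copy into *recipient*.

    The recipient's island copy diverges from the donor sequence only by
    the substitutions accrued on the residual branch (``residual_divergence``
    expected subs/site). Returns the updated genome, the island interval,
    the island-relative difference map vs the donor sequence, and the
    number of planted island events. Raises if the recipient already
    carries an island.
    """
    if any(f.ftype == "mobile_genetic_element" for f in recipient.features):
        raise ValueError(f"recipient {recipient.genome_id} already carries an island")
    rng = np.random.default_rng(seed)
    arr = _seq_to_idx(donor_island_seq)
    leaf_arr, n_events = _mutate_idx(arr, residual_divergence, rng)
    where = np.nonzero(leaf_arr != arr)[0]
    diff = {int(p): (_BASES[arr[p]], _BASES[leaf_arr[p]]) for p in where}
    new_genome, span = insert_island(
        recipient, island, trna_index, island_sequence=_idx_to_seq(leaf_arr)
    )
    event_log.append(
        Event("transfer", residual_divergence, donor, recipient.genome_id, "island")
    )
    return new_genome, span, diff, n_events


def apply_pseudogenization(
    genome: Genome, gene_id: str, mode: str, seed: int
) -> tuple[Genome, tuple[int, str, str]]:
    """Inactivate a CDS by a single base change.

    ``mode='start_loss'`` mutates the start codon so it is no longer one
    of ATG/GTG/TTG; ``mode='nonsense'`` turns an internal codon into a
    stop. Exactly one base changes; the (genome position, old base, new
    base) record is returned for the truth bundle.
    """
    feat = genome.get_feature(gene_id)
    if feat.ftype != "CDS":
        raise ValueError(f"{gene_id} is not a CDS")
    cds = genome.feature_seq(feat)
    rng = np.random.default_rng(seed)

    def candidates_start() -> list[tuple[int, str]]:
        out = []
        for i in range(3):
            for b in _BASES:
                if b == cds[i]:
                    continue
                codon = cds[:i] + b + cds[i + 1 : 3]
                if codon not in _STARTS:
                    out.append((i, b))
        return out

    def candidates_nonsense() -> list[tuple[int, str]]:
        n_codons = len(cds) // 3
        out = []
        for ci in range(1, n_codons - 1):
            codon = cds[3 * ci : 3 * ci + 3]
            if codon in _STOPS:
                continue
            for i in range(3):
                for b in _BASES:
                    if b == codon[i]:
                        continue
                    cand = codon[:i] + b + codon[i + 1 :]
                    if cand in _STOPS:
                        out.append((3 * ci + i, b))
        return out

    if mode == "start_loss":
        cands = candidates_start()
    elif mode == "nonsense":
        cands = candidates_nonsense()
        if not cands:
            raise ValueError(f"{gene_id}: no internal codon available for a nonsense change")
    else:
        raise ValueError(f"unknown pseudogenization mode {mode!r}")
    cds_pos, new_base = cands[int(rng.integers(0, len(cands)))]

    # Map the CDS-relative position back to genome coordinates.
    if feat.strand == "+":
        gpos = feat.start + cds_pos
        planted = new_base
    else:
        gpos = feat.end - 1 - cds_pos
        planted = revcomp(new_base)
    seq = genome.contigs[feat.contig]
    old = seq[gpos]
    new_seq = seq[:gpos] + planted + seq[gpos + 1 :]
    contigs = dict(genome.contigs)
    contigs[feat.contig] = new_seq
    return (
        Genome(genome.genome_id, contigs, [replace(f) for f in genome.features]),
        (gpos, old, planted),
    )
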