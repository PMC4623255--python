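"""Supermatrix construction and distance-based tree inference.

Per-locus alignments (one row per taxon, guaranteed by the single-copy-
complete filter) are concatenated into a supermatrix with a partition
map. Pairwise evolutionary distances use the Poisson correction
``d = -ln(1 - p)`` with ``p`` the mismatch fraction over ungapped shared
columns; trees come from neighbor joining with a documented tie rule
(smallest (i, j) index pair on equal Q scores) and negative branch
lengths clamped to zero with the deficit moved to the sister edge so the
joined pair's path length is preserved. Branch support is the percentage
of column-bootstrap replicate NJ trees containing each bipartition.

The supermatrix can be exported as relaxed PHYLIP plus a RAxML-style
partition file, so external maximum-likelihood tools can refine the tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .align import GAP, Alignment


@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: dict[str, tuple[int, int]]  # locus -> [start, end) columns

    def __post_init__(self) -> None:
        spans = sorted(self.partitions.values())
        pos = 0
        for s, e in spans:
            if s != pos or e <= s:
                raise ValueError("partitions must be contiguous, disjoint and cover all columns")
            pos = e
        if self.alignment.rows and pos != self.alignment.ncols:
            raise ValueError("partitions do not cover the alignment")

    def locus_alignment(self, locus: str) -> Alignment:
        s, e = self.partitions[locus]
        return Alignment(list(self.alignment.ids), [r[s:e] for r in self.alignment.rows])


def concatenate_supermatrix(
    alignments: dict[str, Alignment], taxa: list[str] | None = None
) -> Supermatrix:
    """Concatenate per-locus alignments; every locus must cover every taxon."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    loci = sorted(alignments)
    if taxa is None:
        taxa = sorted(alignments[loci[0]].ids)
    parts: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    pos = 0
    for locus in loci:
        aln = alignments[locus]
        missing = set(taxa) - set(aln.ids)
        if missing:
            raise ValueError(f"locus {locus}: missing taxa {sorted(missing)}")
        for t in taxa:
            rows[t].append(aln.row(t))
        parts[locus] = (pos, pos + aln.ncols)
        pos += aln.ncols
    return Supermatrix(Alignment(list(taxa), ["".join(rows[t]) for t in taxa]), parts)


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape disagrees with taxa")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distance matrix must be symmetric, >= 0, zero diagonal")


SATURATION_P = 1.0 - 1.0 / 20.0


def _rows_to_arrays(aln: Alignment) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    )


def poisson_distance_matrix(sm: Supermatrix | Alignment) -> DistanceMatrix:
    """Poisson-corrected protein distances ``d = -ln(1 - p)``.

    ``p`` is the mismatch fraction over columns where both rows are
    ungapped. Pairs at or beyond ``p = 0.95`` are flagged saturated and
    capped there; a pair with no shared ungapped columns is an error.
    """
    aln = sm.alignment if isinstance(sm, Supermatrix) else sm
    arr = _rows_to_arrays(aln)
    gap = ord(GAP)
    n = len(aln.ids)
    D = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] != gap) & (arr[j] != gap)
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"no shared ungapped columns between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / total
            if p >= SATURATION_P:
                saturated.add((aln.ids[i], aln.ids[j]))
                p = SATURATION_P
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(list(aln.ids), D, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class SupportTree:
    """An (unrooted) tree with optional integer percent supports."""

    tree: dendropy.Tree

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def taxa(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())


def nj_tree(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> SupportTree:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (row, col) index pair
    in the current working order (original taxon order, join products
    appended), so permuting input taxa yields the same tree up to
    relabeling. Requires >= 3 taxa.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("nj_tree requires >= 3 taxa")
    ns = taxon_namespace or dendropy.TaxonNamespace(sorted(dm.taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        if node.taxon is None:
            raise ValueError(f"taxon {t} missing from namespace")
        nodes.append(node)
    D = dm.matrix.astype(np.float64).copy()
    active = list(range(n))

    def join(i: int, j: int) -> None:
        nonlocal D
        r = len(active)
        ri = D[np.ix_([i], active)].sum()
        rj = D[np.ix_([j], active)].sum()
        li = 0.5 * D[i, j] + (ri - rj) / (2.0 * (r - 2))
        lj = D[i, j] - li
        # Clamp negatives, moving the deficit to the sister edge so the
        # i--j path length is preserved.
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = li if li > 0 else 0.0
        lj = lj if lj > 0 else 0.0
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # Distances from the new node to the remaining actives.
        knew = D.shape[0]
        Dn = np.zeros((knew + 1, knew + 1))
        Dn[:knew, :knew] = D
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            Dn[knew, k] = Dn[k, knew] = max(dk, 0.0)
        D = Dn
        nodes.append(parent)
        active.remove(i)
        active.remove(j)
        active.append(knew)

    while len(active) > 3:
        r = len(active)
        sums = {a: D[np.ix_([a], active)].sum() for a in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        join(i, j)

    # Final three-node star: three-point formulas.
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    center = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = ln if ln > 0 else 0.0
    tree.seed_node = center
    tree.update_bipartitions(suppress_unifurcations=False)
    return SupportTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap support


def _bipartitions(tree: dendropy.Tree, taxa: list[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions as canonical leaf-label sets."""
    all_taxa = frozenset(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def robinson_foulds(a: SupportTree, b: SupportTree) -> int:
    """Unrooted symmetric (Robinson–Foulds) distance."""
    taxa = a.taxa()
    if taxa != b.taxa():
        raise ValueError("trees are on different taxon sets")
    ba = _bipartitions(a.tree, taxa)
    bb = _bipartitions(b.tree, taxa)
    return len(ba ^ bb)


def bootstrap_supports(
    sm: Supermatrix, n_reps: int, seed: int
) -> SupportTree:
    """NJ tree on the full supermatrix with column-bootstrap supports.

    Support of an internal edge is the rounded percentage of replicate
    trees containing the same bipartition, attached as the internal node
    label. Zero-divergence data (an all-zero distance matrix) cannot
    resolve any edge: supports are defined as 0 there.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = poisson_distance_matrix(sm)
    full = nj_tree(dm)
    taxa = full.taxa()
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(full.tree, taxa)}
    degenerate = not np.any(dm.matrix)
    if not degenerate:
        arr = _rows_to_arrays(sm.alignment)
        gap = ord(GAP)
        rng = np.random.default_rng(seed)
        ncols = arr.shape[1]
        ids = list(sm.alignment.ids)
        for _ in range(n_reps):
            cols = rng.integers(0, ncols, size=ncols)
            sub = arr[:, cols]
            n = len(ids)
            D = np.zeros((n, n))
            ok = True
            for i in range(n):
                for j in range(i + 1, n):
                    shared = (sub[i] != gap) & (sub[j] != gap)
                    tot = int(shared.sum())
                    if tot == 0:
                        ok = False
                        break
                    p = min(float((sub[i][shared] != sub[j][shared]).sum()) / tot, SATURATION_P)
                    D[i, j] = D[j, i] = -np.log(1.0 - p)
                if not ok:
                    break
            if not ok:
                continue
            rep = nj_tree(DistanceMatrix(ids, D))
            for bp in _bipartitions(rep.tree, taxa):
                if bp in counts:
                    counts[bp] += 1
    # Attach supports (round half up to integer percent).
    for node in full.tree.preorder_node_iter():
        if node is full.tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = frozenset(taxa) - side
        if len(side) < 2 or len(other) < 2:
            continue
        bp = min(side, other, key=lambda s: (len(s), sorted(s)))
        if degenerate:
            pct = 0
        else:
            pct = int(np.floor(100.0 * counts.get(bp, 0) / n_reps + 0.5))
        node.label = str(pct)
    return full


# ---------------------------------------------------------------------------
# Export


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, a space, then the full row."""
    aln = sm.alignment
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {aln.ncols}\n")
        for t, r in zip(aln.ids, aln.rows):
            fh.write(f"{t[:250]} {r}\n")


def write_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file (1-based inclusive column ranges)."""
    with open(path, "w") as fh:
        for locus, (s, e) in sorted(sm.partitions.items(), key=lambda kv: kv[1]):
            fh.write(f"PROT, {locus} = {s + 1}-{e}\n")


def write_newick(tree: SupportTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
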