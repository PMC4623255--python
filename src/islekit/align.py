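"""Multiple protein alignment and conserved-block trimming.

The aligner is a classic progressive scheme: a k-mer-distance guide tree
(UPGMA over shared 3-mer fractions) ordering profile–profile global
alignments with BLOSUM62 scores and affine gap penalties. Input residues
are never altered — only gap columns are inserted — so ungapping any
output row reproduces its input sequence verbatim.

``conserved_block_filter`` trims alignments to well-conserved blocks with
a relaxed, fully specified rule set (see the function docstring); the
defaults favour retaining informative sites over aggressive trimming.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

GAP = "-"
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # 20 AA + X; gap handled separately
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_GAP_IDX = len(_ALPHABET)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


def _blosum62_dense() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    dense = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            dense[i, j] = mat[a, b]
    return dense


_B62 = _blosum62_dense()


@dataclass
class Alignment:
    """Equal-length gapped rows over an ordered taxon list."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def select_columns(self, cols: list[int]) -> "Alignment":
        return Alignment(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])


@njit(cache=True)
def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed column-score matrix.

    The first gap column costs ``gap_open``, each further one
    ``gap_extend``. Returns (score, path) with path entries 0=diagonal,
    1=gap in B (consume A), 2=gap in A (consume B), ordered from the
    start of the alignment.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptrY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal step from best previous state.
            best = M[i - 1, j - 1]
            src = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                src = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            ptrM[i, j] = src
            # Ix: gap in B.
            best = M[i - 1, j] - gap_open
            src = 0
            if Ix[i - 1, j] - gap_extend > best:
                best = Ix[i - 1, j] - gap_extend
                src = 1
            if Iy[i - 1, j] - gap_open > best:
                best = Iy[i - 1, j] - gap_open
                src = 2
            Ix[i, j] = best
            ptrX[i, j] = src
            # Iy: gap in A.
            best = M[i, j - 1] - gap_open
            src = 0
            if Ix[i, j - 1] - gap_open > best:
                best = Ix[i, j - 1] - gap_open
                src = 1
            if Iy[i, j - 1] - gap_extend > best:
                best = Iy[i, j - 1] - gap_extend
                src = 2
            Iy[i, j] = best
            ptrY[i, j] = src
    # Traceback.
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    path = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            path[k] = 0
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            path[k] = 1
            state = ptrX[i, j]
            i -= 1
        else:
            path[k] = 2
            state = ptrY[i, j]
            j -= 1
    return score, path[k:]


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 21-letter alphabet (gaps excluded)."""
    L = len(rows[0])
    prof = np.zeros((L, len(_ALPHABET)), dtype=np.float64)
    for r in rows:
        for c, ch in enumerate(r):
            if ch != GAP:
                prof[c, _AA_INDEX[ch]] += 1.0
    return prof / len(rows)


def _merge(
    a: tuple[list[str], list[str]],
    b: tuple[list[str], list[str]],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    ids_a, rows_a = a
    ids_b, rows_b = b
    S = _profile(rows_a) @ _B62 @ _profile(rows_b).T
    _, path = _affine_dp(S, gap_open, gap_extend)
    out_a = []
    out_b = []
    ia = ib = 0
    cols_a: list[int] = []  # source column or -1 for gap
    cols_b: list[int] = []
    for step in path:
        if step == 0:
            cols_a.append(ia)
            cols_b.append(ib)
            ia += 1
            ib += 1
        elif step == 1:
            cols_a.append(ia)
            cols_b.append(-1)
            ia += 1
        else:
            cols_a.append(-1)
            cols_b.append(ib)
            ib += 1
    for r in rows_a:
        out_a.append("".join(GAP if c < 0 else r[c] for c in cols_a))
    for r in rows_b:
        out_b.append("".join(GAP if c < 0 else r[c] for c in cols_b))
    return ids_a + ids_b, out_a + out_b


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [{s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = max(1, min(len(seqs[i]), len(seqs[j])) - k + 1)
            d = 1.0 - len(sets[i] & sets[j]) / denom
            D[i, j] = D[j, i] = max(0.0, d)
    return D


def progressive_align(
    sequences: dict[str, str] | list[tuple[str, str]],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Progressively align proteins; deterministic for a fixed input.

    A single sequence is returned as a one-row alignment. Rows come back
    in the input order.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if not items:
        raise ValueError("no sequences to align")
    ids = [k for k, _ in items]
    seqs = [v for _, v in items]
    for k, v in items:
        if not v:
            raise ValueError(f"empty sequence {k!r}")
    if len(items) == 1:
        return Alignment([ids[0]], [seqs[0]])
    if len(items) == 2:
        merged = _merge(([ids[0]], [seqs[0]]), ([ids[1]], [seqs[1]]), gap_open, gap_extend)
        return Alignment(*merged)
    D = _kmer_distance(seqs)
    Z = linkage(squareform(D, checks=False), method="average")
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(len(items))
    }
    nxt = len(items)
    for za, zb, _, _ in Z:
        nodes[nxt] = _merge(nodes.pop(int(za)), nodes.pop(int(zb)), gap_open, gap_extend)
        nxt += 1
    merged_ids, merged_rows = nodes[nxt - 1]
    order = [merged_ids.index(i) for i in ids]
    return Alignment(ids, [merged_rows[i] for i in order])


# ---------------------------------------------------------------------------
# Conserved-block trimming


@dataclass
class BlockFilterParams:
    """Relaxed conserved-block parameters.

    ``min_conserved_frac``: a column is *conserved* when its most frequent
    residue reaches this fraction of the taxa (just over half by default)
    and its gap fraction is within ``max_gap_frac``. ``min_flank_frac``
    marks *highly conserved* columns. Runs of more than
    ``max_nonconserved_run`` consecutive non-conserved columns are
    removed and break blocks; surviving blocks shorter than
    ``min_block_len`` are kept only when both flanking columns are highly
    conserved.
    """

    min_conserved_frac: float = 0.501
    min_flank_frac: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 5
    max_gap_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_conserved_frac", "min_flank_frac", "max_gap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _column_status(aln: Alignment, params: BlockFilterParams) -> list[str]:
    """Classify columns: 'g' over-gapped, 'n' nonconserved, 'c' conserved,
    'h' highly conserved."""
    n = len(aln.rows)
    status = []
    for c in range(aln.ncols):
        col = [r[c] for r in aln.rows]
        gaps = col.count(GAP)
        if gaps / n > params.max_gap_frac:
            status.append("g")
            continue
        residues = [x for x in col if x != GAP]
        top = max(residues.count(x) for x in set(residues))
        frac = top / n
        if frac >= params.min_flank_frac:
            status.append("h")
        elif frac >= params.min_conserved_frac:
            status.append("c")
        else:
            status.append("n")
    return status


def conserved_block_filter(
    aln: Alignment, params: BlockFilterParams | None = None
) -> tuple[Alignment, list[int]]:
    """Trim an alignment to its conserved blocks.

    Returns the trimmed alignment and the kept column indices (into the
    input alignment). Rules, applied column by column:

    1. classify columns (see :class:`BlockFilterParams`);
    2. runs of **more than** ``max_nonconserved_run`` consecutive
       non-conserved columns (including over-gapped ones) are removed and
       split the alignment into candidate blocks; shorter noisy runs stay
       — this is what "maximize retention of informative sites" means;
    3. over-gapped columns are always removed (without breaking a block
       on their own);
    4. a surviving block shorter than ``min_block_len`` is dropped unless
       both its first and last columns are highly conserved.
    """
    params = params or BlockFilterParams()
    status = _column_status(aln, params)
    # Long nonconserved runs (block breakers).
    breaker = [False] * len(status)
    i = 0
    while i < len(status):
        if status[i] in "ng":
            j = i
            while j < len(status) and status[j] in "ng":
                j += 1
            if j - i > params.max_nonconserved_run:
                for k in range(i, j):
                    breaker[k] = True
            i = j
        else:
            i += 1
    kept: list[int] = []
    block: list[int] = []

    def flush(block: list[int]) -> None:
        if not block:
            return
        ok = len(block) >= params.min_block_len or (
            status[block[0]] == "h" and status[block[-1]] == "h"
        )
        if ok:
            kept.extend(block)

    for c in range(len(status)):
        if breaker[c]:
            flush(block)
            block = []
        elif status[c] != "g":
            block.append(c)
        # over-gapped columns inside a block are dropped but do not break
    flush(block)
    return aln.select_columns(kept), kept
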