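"""Orthology: local alignment scores, RBH, clustering and the
single-copy-complete locus filter, each against an independent oracle."""
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from islekit.orthology import (
    OrthologCluster,
    ProteinRecord,
    all_vs_all_hits,
    build_clusters,
    cluster_rbh_graph,
    filter_single_copy_complete,
    greedy_identity_cluster,
    proteome_from_genome,
    reciprocal_best_hits,
    score_local_alignment,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Exhaustive affine Smith–Waterman DP, written independently.

    First gap residue costs gap_open, each additional one gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i, j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i, j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestLocalAlignment:
    def test_self_alignment_is_identity_with_diagonal_score(self):
        seq = "MKVAWQNRLLEYGTPSKDFHIC" * 2
        score, ident, length = score_local_alignment(seq, seq)
        assert ident == 1.0
        assert length == len(seq)
        assert score == sum(_B62[c, c] for c in seq)

    def test_no_positive_pair_scores_means_empty_alignment(self):
        # All A/C pair scores are 0 in BLOSUM62, so the optimal local
        # alignment is empty with score 0.
        score, ident, length = score_local_alignment("AAAA", "CCCC")
        assert (score, ident, length) == (0.0, 0.0, 0)
        assert sw_oracle("AAAA", "CCCC") == 0.0

    def test_matches_exhaustive_dp_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(25):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 18)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 18)))
            score, _, _ = score_local_alignment(a, b)
            assert score == pytest.approx(sw_oracle(a, b))

    def test_score_is_symmetric(self):
        rng = random.Random(1)
        for _ in range(100):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            assert score_local_alignment(a, b)[0] == score_local_alignment(b, a)[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            score_local_alignment("", "MKV")


def _proteome(gid: str, seqs: dict[str, str]) -> list[ProteinRecord]:
    return [ProteinRecord(gid, k, v) for k, v in seqs.items()]


class TestAllVsAll:
    def test_identical_proteomes_hit_their_twins_at_identity_one(self):
        rng = random.Random(0)
        seqs = {f"g{i}": "".join(rng.choice(AA) for _ in range(60)) for i in range(4)}
        hits = all_vs_all_hits({"A": _proteome("A", seqs), "B": _proteome("B", seqs)})
        twins = hits[(hits.query_genome == "A") & (hits.query_id == hits.subject_id)]
        assert len(twins) == 4
        assert (twins.identity == 1.0).all()

    def test_infinite_threshold_empties_table(self):
        seqs = {"g": "MKVAWQNRLLEYGTPSKDFHIC"}
        hits = all_vs_all_hits(
            {"A": _proteome("A", seqs), "B": _proteome("B", seqs)},
            min_score=float("inf"),
        )
        assert hits.empty

    def test_hit_count_matches_brute_force_on_toy_proteomes(self):
        rng = random.Random(2)
        base = ["".join(rng.choice(AA) for _ in range(40)) for _ in range(5)]
        # Proteome B: mutated copies of A's proteins (still above threshold).
        def mutate(s, k):
            s = list(s)
            for i in rng.sample(range(len(s)), k):
                s[i] = rng.choice(AA)
            return "".join(s)

        pa = {f"a{i}": s for i, s in enumerate(base)}
        pb = {f"b{i}": mutate(s, 4) for i, s in enumerate(base)}
        min_score, min_cov = 50.0, 0.5
        hits = all_vs_all_hits(
            {"A": _proteome("A", pa), "B": _proteome("B", pb)},
            min_score=min_score, min_coverage=min_cov, min_shared_kmers=0,
        )
        forward = hits[hits.query_genome == "A"]
        expected = 0
        for qa in pa.values():
            for qb in pb.values():
                score, _, _ = score_local_alignment(qa, qb)
                if score >= min_score:
                    expected += 1  # coverage always passes for these toys
        assert len(forward) == expected > 0


class TestRBH:
    def test_identical_one_to_one_proteomes_fully_paired(self):
        rng = random.Random(10)
        seqs = {f"g{i}": "".join(rng.choice(AA) for _ in range(50)) for i in range(5)}
        hits = all_vs_all_hits({"A": _proteome("A", seqs), "B": _proteome("B", seqs)})
        pairs = reciprocal_best_hits(hits, "A", "B")
        assert pairs == sorted((g, g) for g in seqs)

    def test_tied_best_hits_exclude_the_query(self):
        seq = "".join(random.Random(3).choice(AA) for _ in range(50))
        pa = {"a1": seq}
        pb = {"b1": seq, "b2": seq}  # exact tie for a1's best hit
        hits = all_vs_all_hits({"A": _proteome("A", pa), "B": _proteome("B", pb)})
        assert reciprocal_best_hits(hits, "A", "B") == []

    def test_matches_double_argmax_oracle_on_random_tables(self):
        import pandas as pd

        rng = random.Random(4)
        for _ in range(10):
            rows = []
            for qa in range(6):
                for qb in range(6):
                    rows.append(("A", f"a{qa}", "B", f"b{qb}", rng.randint(10, 99), 0.9, 40))
                    rows.append(("B", f"b{qb}", "A", f"a{qa}", rows[-1][4], 0.9, 40))
            hits = pd.DataFrame(
                rows,
                columns=["query_genome", "query_id", "subject_genome", "subject_id",
                         "score", "identity", "aln_length"],
            )
            got = set(reciprocal_best_hits(hits, "A", "B"))
            # Oracle: literal double argmax with tie exclusion.
            score = {(r.query_id, r.subject_id): r.score
                     for r in hits[hits.query_genome == "A"].itertuples()}
            expected = set()
            for a in {k[0] for k in score}:
                arow = {b: s for (x, b), s in score.items() if x == a}
                btop = max(arow.values())
                bbest = [b for b, s in arow.items() if s == btop]
                if len(bbest) != 1:
                    continue
                b = bbest[0]
                bcol = {x: s for (x, bb), s in score.items() if bb == b}
                atop = max(bcol.values())
                abest = [x for x, s in bcol.items() if s == atop]
                if abest == [a]:
                    expected.add((a, b))
            assert got == expected


class TestClustering:
    def test_perfect_orthology_gives_three_member_clusters(self):
        rbh = {
            ("A", "B"): [("g1", "g1"), ("g2", "g2")],
            ("A", "C"): [("g1", "g1"), ("g2", "g2")],
            ("B", "C"): [("g1", "g1"), ("g2", "g2")],
        }
        clusters = cluster_rbh_graph(rbh)
        assert sorted(len(c.members) for c in clusters) == [3, 3]

    def test_chain_closes_transitively(self):
        rbh = {("A", "B"): [("x", "y")], ("B", "C"): [("y", "z")], ("A", "C"): []}
        clusters = cluster_rbh_graph(rbh)
        assert len(clusters) == 1
        assert clusters[0].members == {("A", "x"), ("B", "y"), ("C", "z")}

    def test_component_count_matches_union_find_oracle(self):
        rng = random.Random(5)
        genomes = ["A", "B", "C", "D"]
        edges = []
        for _ in range(20):
            ga, gb = rng.sample(genomes, 2)
            edges.append(((ga, f"g{rng.randint(0, 5)}"), (gb, f"g{rng.randint(0, 5)}")))
        rbh = {("A", "B"): []}
        for (ga, a), (gb, b) in edges:
            rbh.setdefault((ga, gb), []).append((a, b))
        clusters = cluster_rbh_graph(rbh)
        # Union-find oracle.
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in edges:
            parent[find(u)] = find(v)
        n_components = len({find(x) for x in parent})
        assert len(clusters) == n_components

    def test_rbh_symmetry_within_clusters(self, small_proteomes):
        clusters, hits = build_clusters(small_proteomes)
        a, b = sorted(small_proteomes)[:2]
        ab = set(reciprocal_best_hits(hits, a, b))
        ba = {(y, x) for x, y in reciprocal_best_hits(hits, b, a)}
        assert ab == ba


class TestSingleCopyComplete:
    def _cluster(self, members):
        return OrthologCluster("CL", set(members))

    def test_one_member_per_genome_kept(self):
        c = self._cluster([("A", "1"), ("B", "1"), ("C", "1")])
        assert filter_single_copy_complete([c], {"A", "B", "C"}) == [c]

    def test_paralogous_cluster_dropped(self):
        c = self._cluster([("A", "1"), ("A", "2"), ("B", "1"), ("C", "1")])
        assert filter_single_copy_complete([c], {"A", "B", "C"}) == []

    def test_incomplete_cluster_dropped(self):
        c = self._cluster([("A", "1"), ("B", "1")])
        assert filter_single_copy_complete([c], {"A", "B", "C"}) == []

    def test_filter_is_idempotent_and_subsetting(self):
        clusters = [
            self._cluster([("A", "1"), ("B", "1")]),
            self._cluster([("A", "2"), ("B", "2")]),
            self._cluster([("A", "3")]),
        ]
        once = filter_single_copy_complete(clusters, {"A", "B"})
        assert set(map(id, once)) <= set(map(id, clusters))
        assert filter_single_copy_complete(once, {"A", "B"}) == once

    def test_adding_a_genome_never_grows_the_set(self):
        clusters = [
            self._cluster([("A", "1"), ("B", "1"), ("C", "1")]),
            self._cluster([("A", "2"), ("B", "2")]),
        ]
        small = filter_single_copy_complete(clusters, {"A", "B"})
        large = filter_single_copy_complete(clusters, {"A", "B", "C"})
        assert {c.cluster_id for c in large} <= {c.cluster_id for c in small} | {
            c.cluster_id for c in clusters
        }
        assert len(large) <= len(small)


class TestGreedyIdentity:
    def test_identical_sequences_merge(self):
        reps, assign = greedy_identity_cluster({"a": "MKVLW" * 10, "b": "MKVLW" * 10})
        assert len(reps) == 1

    def test_distant_sequences_stay_apart(self):
        rng = random.Random(6)
        a = "".join(rng.choice(AA) for _ in range(60))
        b = "".join(rng.choice(AA) for _ in range(60))
        reps, _ = greedy_identity_cluster({"a": a, "b": b}, threshold=0.9)
        assert len(reps) == 2

    def test_ninety_percent_threshold_arithmetic(self):
        # 100-residue base; 8 substitutions = 92% identity (merges),
        # 15 substitutions = 85% (stays separate).
        rng = random.Random(7)
        base = "".join(rng.choice(AA) for _ in range(100))

        def mutate(s, k):
            s = list(s)
            for i in rng.sample(range(len(s)), k):
                s[i] = rng.choice([c for c in AA if c != s[i]])
            return "".join(s)

        seqs = {"base": base, "close": mutate(base, 8), "far": mutate(base, 15)}
        reps, assign = greedy_identity_cluster(seqs, threshold=0.90)
        assert len(reps) == 2
        assert assign["close"] == assign["base"]
        assert assign["far"] == "far"


def test_simulated_paralog_free_clusters_match_gene_labels(small_cohort, small_proteomes):
    """On simulator output without paralogs, every cluster is exactly one
    gene label across its carrier genomes (adjusted Rand index 1)."""
    clusters, _ = build_clusters(small_proteomes)
    for c in clusters:
        labels = {gene for _, gene in c.members}
        assert len(labels) == 1  # one locus per cluster
        genomes = [g for g, _ in c.members]
        assert len(genomes) == len(set(genomes))  # no paralogs
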