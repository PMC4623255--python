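"""Island delineation: repeats, integration sites, synteny, core genes,
mobility classes."""
import numpy as np
import pytest

from islekit.genome import Feature, Genome
from islekit.islands import (
    IslandCall,
    RepeatPair,
    anchor_core_expansion,
    classify_mobility,
    delineate_islands,
    find_direct_repeats,
    flanking_synteny_score,
    locate_integration_sites,
)
from islekit.orthology import OrthologCluster


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def repeat_oracle(seq, min_len, min_sep, max_sep):
    """Quadratic offset-scan oracle for exact direct repeats.

    For every offset, maximal equal runs of length >= min_len whose inner
    separation lies in [min_sep, max_sep]; contained pairs suppressed by
    the same declared rule as the implementation.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairs = []
    for off in range(min_sep + min_len, min(len(seq), max_sep + 2 * min_len + 1)):
        eq = arr[:-off] == arr[off:]
        # maximal runs of True
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            L = e - s
            sep = off - L
            if L >= min_len and min_sep <= sep <= max_sep:
                pairs.append((int(s), int(s) + L, int(s) + off, int(s) + off + L, L))
    pairs.sort(key=lambda p: (-p[4], p[0], p[2]))
    kept = []
    for p in pairs:
        if not any(
            p[0] >= q[0] and p[1] <= q[1] and p[2] >= q[2] and p[3] <= q[3]
            for q in kept
        ):
            kept.append(p)
    return sorted((p[0], p[2], p[4]) for p in kept)


class TestFindDirectRepeats:
    def test_planted_48mer_found_with_exact_coordinates(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 100_000)
        unit = seq[10_000 : 10_048]
        seq = seq[:40_000] + unit + seq[40_048:]
        reps = find_direct_repeats(seq, min_len=40, min_sep=5_000, max_sep=200_000)
        assert [(r.copy1, r.copy2, r.length) for r in reps] == [
            ((10_000, 10_048), (40_000, 40_048), 48)
        ]

    def test_no_long_repeat_returns_empty(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 20_000)
        assert find_direct_repeats(seq, min_len=40, min_sep=100, max_sep=20_000) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadratic_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, 3_000)
        # plant a couple of short repeats to guarantee signal
        seq = seq[:500] + seq[1000:1016] + seq[516:]
        got = find_direct_repeats(
            seq, min_len=16, seed_k=16, min_sep=100, max_sep=2_500
        )
        got_t = sorted((r.copy1[0], r.copy2[0], r.length) for r in got)
        assert got_t == repeat_oracle(seq, 16, 100, 2_500)

    def test_min_len_below_seed_k_rejected(self):
        with pytest.raises(ValueError):
            find_direct_repeats("ACGT" * 100, min_len=8, seed_k=16)


class TestIntegrationSites:
    def test_simulated_island_boundaries_exact(self, small_cohort):
        truth = small_cohort.truth
        for c in truth.carriers:
            calls = delineate_islands(small_cohort.genomes[c])
            assert len(calls) == 1
            contig, s, e = truth.island_coords[c]
            assert (calls[0].start, calls[0].end) == (s, e)
            assert calls[0].evidence["trna"] and calls[0].evidence["repeat"]
            assert calls[0].evidence["anchors"]

    def test_noncarrier_yields_no_call(self, small_cohort):
        assert delineate_islands(small_cohort.genomes[small_cohort.truth.noncarrier]) == []

    def test_repeat_without_trna_not_called(self):
        g = Genome("g", {"c": "A" * 1000}, [])
        rp = RepeatPair("c", (10, 60), (500, 550), 50, 0)
        assert locate_integration_sites(g, [rp]) == []

    def test_two_pairs_sharing_a_trna_prefer_longer_span(self):
        g = Genome(
            "g",
            {"c": "A" * 3000},
            [Feature("t1", "tRNA", "c", 40, 116, "+", gene="t1")],
        )
        short = RepeatPair("c", (68, 116), (1_000, 1_048), 48, 0)
        long = RepeatPair("c", (68, 116), (2_000, 2_048), 48, 0)
        calls = locate_integration_sites(g, [short, long])
        assert len(calls) == 1
        assert calls[0].end == 2_048
        assert calls[0].alternates == [short]


def _toy_pair_for_synteny(n_upstream_insert=0):
    """Carrier with an island between g5 and g6; relative optionally has
    a different element (extra genes) at the same spot."""
    feats_car = []
    pos = 0
    for i in range(1, 11):
        feats_car.append(Feature(f"g{i}", "CDS", "c", pos, pos + 90, "+", gene=f"g{i}"))
        pos += 100
        if i == 5:
            pos += 5_000  # island occupies this span
    car = Genome("car", {"c": "A" * (pos + 100)}, feats_car)
    island = IslandCall("car", "c", 500, 5_500, gene_ids=[])

    feats_non = []
    pos = 0
    for i in range(1, 11):
        feats_non.append(Feature(f"h{i}", "CDS", "c", pos, pos + 90, "+", gene=f"g{i}"))
        pos += 100
        if i == 5:
            for j in range(n_upstream_insert):
                feats_non.append(
                    Feature(f"x{j}", "CDS", "c", pos, pos + 90, "+", gene=f"x{j}")
                )
                pos += 100
    non = Genome("non", {"c": "A" * (pos + 100)}, feats_non)
    clusters = [
        OrthologCluster(f"CL{i}", {("car", f"g{i}"), ("non", f"h{i}")})
        for i in range(1, 11)
    ]
    return car, island, non, clusters


class TestFlankingSynteny:
    def test_clean_relative_is_contiguous_with_zero_intervening(self):
        car, island, non, clusters = _toy_pair_for_synteny(0)
        contiguous, intervening = flanking_synteny_score(car, island, non, clusters)
        assert contiguous and intervening == 0

    def test_relative_with_ten_gene_element_is_not_contiguous(self):
        car, island, non, clusters = _toy_pair_for_synteny(10)
        contiguous, intervening = flanking_synteny_score(car, island, non, clusters)
        assert not contiguous and intervening == 10

    def test_gap_tolerance_monotonicity(self):
        car, island, non, clusters = _toy_pair_for_synteny(10)
        assert flanking_synteny_score(car, island, non, clusters, gap_tolerance=10)[0]
        # contiguous flag is monotone non-decreasing in gap_tolerance
        results = [
            flanking_synteny_score(car, island, non, clusters, gap_tolerance=g)[0]
            for g in (0, 5, 9, 10, 20)
        ]
        assert results == sorted(results)

    def test_simulated_noncarrier_sibling_contiguous(self, small_cohort):
        from islekit.orthology import build_clusters

        truth = small_cohort.truth
        carrier = truth.carriers[0]
        clusters, _ = build_clusters(
            {
                g: __import__("islekit.orthology", fromlist=["x"]).proteome_from_genome(G)
                for g, G in small_cohort.genomes.items()
            }
        )
        call = delineate_islands(small_cohort.genomes[carrier])[0]
        contiguous, intervening = flanking_synteny_score(
            small_cohort.genomes[carrier],
            call,
            small_cohort.genomes[truth.noncarrier],
            clusters,
        )
        assert contiguous and intervening == 0


class TestAnchorCoreExpansion:
    def test_definitional_two_island_case(self):
        islands = {
            "i1": [("pcrA", "pcrA"), ("cld", "cld"), ("x", "x"), ("y", "y")],
            "i2": [("pcrA", "pcrA"), ("cld", "cld"), ("x", "x"), ("z", "z")],
        }
        cgs = anchor_core_expansion(islands, anchors={"pcrA", "cld"})
        assert cgs.core == {"pcrA", "cld", "x"}
        assert cgs.accessory == {"i1": {"y"}, "i2": {"z"}}

    def test_single_island_is_an_error(self):
        with pytest.raises(ValueError):
            anchor_core_expansion({"i1": [("pcrA", "pcrA")]}, anchors={"pcrA"})

    def test_missing_anchors_is_an_error(self):
        islands = {"i1": [("a", "a")], "i2": [("a", "a")]}
        with pytest.raises(ValueError, match="anchor"):
            anchor_core_expansion(islands, anchors={"pcrA"})

    def test_interior_specific_run_shorter_than_stop_run_is_crossed(self):
        # 12-gene constructed case: an interior island-specific run of
        # length 2 (< stop_run 3) between shared genes; brute-force
        # expectation: all shared clusters reachable from the anchors.
        i1 = [("g%d" % k, c) for k, c in enumerate(
            ["pcrA", "s1", "u1", "u2", "s2", "s3", "cld", "u3", "s4", "s5", "u4", "s6"]
        )]
        i2 = [("h%d" % k, c) for k, c in enumerate(
            ["pcrA", "s1", "s2", "s3", "cld", "s4", "s5", "s6"]
        )]
        cgs = anchor_core_expansion({"i1": i1, "i2": i2}, anchors={"pcrA", "cld"})
        shared = {"pcrA", "s1", "s2", "s3", "cld", "s4", "s5", "s6"}
        assert cgs.core == shared
        assert cgs.accessory["i1"] == {"u1", "u2", "u3", "u4"}


class TestMobility:
    def test_simulated_trna_island_with_recombinase(self, small_cohort):
        truth = small_cohort.truth
        c = truth.carriers[0]
        call = delineate_islands(small_cohort.genomes[c])[0]
        mc = classify_mobility(call, small_cohort.genomes[c])
        assert mc.label == "trna_integrative"
        assert mc.markers["recombinase"]

    def test_conjugation_plus_replication_markers_mean_ice(self):
        feats = [
            Feature("tra1", "CDS", "c", 100, 400, "+", product="conjugal transfer protein TraB"),
            Feature("rep1", "CDS", "c", 500, 800, "+", product="plasmid replication initiator RepA"),
        ]
        g = Genome("g", {"c": "A" * 2_000}, feats)
        call = IslandCall("g", "c", 0, 1_000, gene_ids=["tra1", "rep1"],
                          evidence={"repeat": False, "trna": False})
        assert classify_mobility(call, g).label == "ice"

    def test_flanking_identical_is_copies_mean_composite_transposon(self):
        rng = np.random.default_rng(3)
        is_seq = _random_seq(rng, 800)
        middle = _random_seq(rng, 3_000)
        seq = _random_seq(rng, 200) + is_seq + middle + is_seq + _random_seq(rng, 200)
        feats = [
            Feature("isL", "CDS", "c", 200, 1_000, "+", product="IS family transposase"),
            Feature("isR", "CDS", "c", 4_000, 4_800, "+", product="IS family transposase"),
        ]
        g = Genome("g", {"c": seq}, feats)
        call = IslandCall("g", "c", 200, 4_800, gene_ids=[],
                          evidence={"repeat": False, "trna": False})
        mc = classify_mobility(call, g)
        assert mc.label == "composite_transposon"

    def test_no_markers_is_unknown_and_total(self):
        g = Genome("g", {"c": "A" * 1_000},
                   [Feature("x", "CDS", "c", 10, 100, "+", product="hypothetical")])
        call = IslandCall("g", "c", 0, 500, gene_ids=["x"],
                          evidence={"repeat": False, "trna": False})
        a = classify_mobility(call, g)
        b = classify_mobility(call, g)
        assert a.label == "unknown" and b.label == "unknown"
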