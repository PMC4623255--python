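"""Study-condition evaluation runs: simulate, infer, score against truth.

These routines execute the full inference chain on simulator output at
the package's documented study conditions and score the results against
the truth bundle. They back both the validation test suite and the
reproduction script.

Problem sizes: island recovery runs at the default 200 kb backbone /
30 kb island; the classification and SNP-exactness batteries run many
replicates and therefore use a 60 kb backbone / 9 kb island with the
divergence conditions unchanged (backbone ~2 % pairwise, island ~0.01 %
for recent transfer); tree recovery uses 10 taxa x 60 loci at depth
0.05 substitutions/site — enough aligned columns that an internal
branch of typical Yule shortness still carries several expected
substitutions, the floor below which no distance method can resolve it.
"""
from __future__ import annotations

from dataclasses import replace

import dendropy
import numpy as np

from .align import conserved_block_filter, progressive_align
from .cohort import CohortConfig, simulate_cohort
from .islands import delineate_islands
from .orthology import (
    build_clusters,
    filter_single_copy_complete,
    proteome_from_genome,
)
from .phylo import (
    SupportTree,
    concatenate_supermatrix,
    nj_tree,
    poisson_distance_matrix,
    robinson_foulds,
    DistanceMatrix,
)
from .snp import (
    acquisition_contrast_test,
    anchor_chain_align,
    call_snps,
    label_snp_regions,
    region_snp_frequency,
    window_snp_histogram,
)

#: Scaled-down replicate conditions (divergences match the defaults).
SMALL = dict(genome_length=60_000, n_genes=40, island_length=9_000, island_genes=8)


def _seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Island recovery (default 200 kb / 30 kb conditions)


def island_recovery(n_genomes: int = 20, base_seed: int = 20_001) -> dict:
    """Delineate islands on carrier genomes; score vs planted truth.

    Runs cohorts of four carriers at the default conditions until
    ``n_genomes`` carrier genomes have been scored. Precision counts
    called islands matching a planted island (any overlap); exactness
    requires base-exact boundaries.
    """
    tp = fp = fn = exact = scored = 0
    for seed in _seeds(base_seed, (n_genomes + 3) // 4):
        res = simulate_cohort(CohortConfig(seed=seed, n_carriers=4))
        for c in res.truth.carriers:
            if scored >= n_genomes:
                break
            scored += 1
            truth = res.truth.island_coords[c][1:]
            calls = delineate_islands(res.genomes[c])
            matched = False
            for call in calls:
                if call.start < truth[1] and truth[0] < call.end:
                    matched = True
                    tp += 1
                    if (call.start, call.end) == truth:
                        exact += 1
                else:
                    fp += 1
            if not matched:
                fn += 1
    return {
        "n": scored,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "boundary_exact_fraction": exact / scored,
    }


# ---------------------------------------------------------------------------
# Acquisition classification (scaled replicates)


def classify_one(res) -> tuple[str, float]:
    """Contrast one cohort's reference/query carrier pair."""
    t = res.truth
    ref_id, qry_id = t.contrast_pair
    ref, qry = res.genomes[ref_id], res.genomes[qry_id]
    smap = anchor_chain_align(ref, qry)
    snps = call_snps(smap)
    isl = (t.insert_pos, t.insert_pos + t.island_span_length)
    label_snp_regions(snps, [isl], smap)
    glen = len(ref.contigs["chr"])
    k1, n1, _ = region_snp_frequency(snps, isl, smap)
    k2 = sum(1 for s in snps if s.region == "backbone")
    n2 = smap.aligned_ref_length((0, glen)) - smap.aligned_ref_length(isl)
    cr = acquisition_contrast_test((k1, n1), (k2, n2))
    return cr.call, cr.ratio


def classification_rates(
    scenario: str, n_runs: int = 100, base_seed: int = 30_001
) -> dict:
    """Fraction of replicate cohorts assigned each acquisition call."""
    calls = []
    ratios = []
    for seed in _seeds(base_seed + (0 if scenario == "recent" else 1), n_runs):
        res = simulate_cohort(CohortConfig(seed=seed, scenario=scenario, **SMALL))
        call, ratio = classify_one(res)
        calls.append(call)
        ratios.append(ratio)
    return {
        "n": n_runs,
        "recent_independent_rate": calls.count("recent_independent") / n_runs,
        "ancestral_vertical_rate": calls.count("ancestral_vertical") / n_runs,
        "ratio_below_cut_rate": sum(r < 0.1 for r in ratios) / n_runs,
        "median_ratio": float(np.median(ratios)),
    }


# ---------------------------------------------------------------------------
# SNP exactness


def snp_exactness(n_runs: int = 5, base_seed: int = 40_001) -> dict:
    """Called SNPs vs planted substitutions, plus window conservation."""
    exact_runs = 0
    window_ok = 0
    for seed in _seeds(base_seed, n_runs):
        res = simulate_cohort(CohortConfig(seed=seed, **SMALL))
        t = res.truth
        ref_id, qry_id = t.contrast_pair
        smap = anchor_chain_align(res.genomes[ref_id], res.genomes[qry_id])
        snps = call_snps(smap)
        called = [(s.position, s.ref_base, s.alt_base) for s in snps]
        if called == t.pair_planted_snps(ref_id, qry_id):
            exact_runs += 1
        glen = len(res.genomes[ref_id].contigs["chr"])
        track = window_snp_histogram(snps, (0, glen), 500, smap)
        if sum(track.counts) == len(snps):
            window_ok += 1
    return {
        "n": n_runs,
        "exact_rate": exact_runs / n_runs,
        "window_conservation_rate": window_ok / n_runs,
    }


# ---------------------------------------------------------------------------
# Orthology recovery


def orthology_recovery(base_seed: int = 50_001) -> dict:
    """Cluster recovery on paralog-free proteomes + duplication exclusion."""
    res = simulate_cohort(
        CohortConfig(seed=base_seed, scenario="none", n_carriers=0, **SMALL)
    )
    prots = {g: proteome_from_genome(G) for g, G in res.genomes.items()}
    clusters, _ = build_clusters(prots)
    scc = filter_single_copy_complete(clusters, set(prots))
    n_genes = res.config.n_genes
    label_exact = all(
        len({gene for _, gene in c.members}) == 1 and len(c.members) == len(prots)
        for c in clusters
    ) and len(clusters) == n_genes

    # Plant an exact duplication of one gene in one genome and re-cluster:
    # the duplicated locus (and exactly that locus) must leave the
    # single-copy-complete set.
    gid = sorted(prots)[0]
    victim = prots[gid][0]
    dup = replace(victim, gene_id=victim.gene_id + "_dup")
    prots_dup = {g: list(ps) for g, ps in prots.items()}
    prots_dup[gid] = prots_dup[gid] + [dup]
    clusters2, _ = build_clusters(prots_dup)
    scc2 = filter_single_copy_complete(clusters2, set(prots_dup))
    kept_loci = {next(iter({gene for _, gene in c.members})) for c in scc2}
    expected = {f"gene_{i:04d}" for i in range(1, n_genes + 1)} - {victim.gene_id}
    return {
        "paralog_free_exact": bool(label_exact),
        "n_single_copy_complete": len(scc),
        "duplicated_locus_excluded": victim.gene_id not in kept_loci,
        "exactly_one_locus_excluded": kept_loci == expected,
    }


# ---------------------------------------------------------------------------
# Tree recovery


def infer_mlsa_tree(res) -> tuple[SupportTree, int]:
    """Orthology → single-copy loci → align/trim → supermatrix → NJ."""
    prots = {g: proteome_from_genome(G) for g, G in res.genomes.items()}
    clusters, _ = build_clusters(prots)
    scc = filter_single_copy_complete(clusters, set(prots))
    seq_by = {g: {p.gene_id: p.sequence for p in ps} for g, ps in prots.items()}
    alns = {}
    for c in scc:
        aln = progressive_align({g: seq_by[g][gene] for g, gene in sorted(c.members)})
        trimmed, _ = conserved_block_filter(aln)
        if trimmed.ncols:
            alns[c.cluster_id] = trimmed
    sm = concatenate_supermatrix(alns, sorted(res.genomes))
    return nj_tree(poisson_distance_matrix(sm)), len(alns)


def tree_recovery(n_seeds: int = 20, base_seed: int = 60_001) -> dict:
    """RF distance between inferred and true topologies over seeds."""
    rf_zero = 0
    loci_counts = []
    for seed in _seeds(base_seed, n_seeds):
        res = simulate_cohort(
            CohortConfig(
                seed=seed, n_taxa=10, tree_depth=0.05, genome_length=60_000,
                n_genes=60, n_trna=2, scenario="none", n_carriers=0,
            )
        )
        inferred, n_loci = infer_mlsa_tree(res)
        loci_counts.append(n_loci)
        true = dendropy.Tree.get(data=res.truth.tree_newick, schema="newick")
        true.is_rooted = False
        if robinson_foulds(inferred, SupportTree(true)) == 0:
            rf_zero += 1
    return {
        "n": n_seeds,
        "rf_zero_count": rf_zero,
        "rf_zero_rate": rf_zero / n_seeds,
        "min_loci": min(loci_counts),
    }


def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, SupportTree]:
    """A random binary unrooted tree and its exact path-distance matrix."""
    ns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    center = tree.seed_node
    leaves = []
    for i in range(3):
        node = dendropy.Node()
        node.taxon = ns.get_taxon(f"T{i}")
        center.add_child(node)
        node.edge.length = float(rng.uniform(0.1, 1.0))
        leaves.append(node)
    internal_edges = []
    for i in range(3, n_taxa):
        # Attach the new leaf to a random existing edge.
        candidates = leaves + internal_edges
        target = candidates[int(rng.integers(0, len(candidates)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        old_len = target.edge.length
        split = float(rng.uniform(0.2, 0.8))
        mid.edge.length = old_len * split
        mid.add_child(target)
        target.edge.length = old_len * (1 - split)
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(f"T{i}")
        leaf.edge.length = float(rng.uniform(0.1, 1.0))
        mid.add_child(leaf)
        leaves.append(leaf)
        internal_edges.append(mid)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [f"T{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = pdm.distance(ns.get_taxon(taxa[i]), ns.get_taxon(taxa[j]))
    return DistanceMatrix(taxa, D), SupportTree(tree)


def nj_additive_exactness(
    n_matrices: int = 20, base_seed: int = 70_001, max_taxa: int = 6
) -> dict:
    """NJ on random additive matrices: topology and distances exact?"""
    exact = 0
    for seed in _seeds(base_seed, n_matrices):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, max_taxa + 1))
        dm, true = random_additive_matrix(n_taxa, rng)
        inferred = nj_tree(dm)
        if robinson_foulds(inferred, true) != 0:
            continue
        pdm = inferred.tree.phylogenetic_distance_matrix()
        ns = inferred.tree.taxon_namespace
        ok = all(
            abs(pdm.distance(ns.get_taxon(dm.taxa[i]), ns.get_taxon(dm.taxa[j]))
                - dm.matrix[i, j]) < 1e-9
            for i in range(n_taxa)
            for j in range(i + 1, n_taxa)
        )
        exact += ok
    return {"n": n_matrices, "exact_rate": exact / n_matrices}
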