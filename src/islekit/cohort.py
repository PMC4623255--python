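"""Cohort-level simulation scenarios and the machine-readable truth bundle.

A *cohort* is a small clade of genomes (by default three island carriers
plus one non-carrier relative) evolved along a sampled species tree. Two
island histories are supported:

``recent``
    The island is acquired independently and recently by each carrier: all
    carrier island copies descend from one donor sequence and accrue only a
    small residual divergence (default 5e-5 subs/site per carrier, i.e.
    ~0.01% pairwise), while the genome backbones diverge normally (~2%
    pairwise at the default tree depth of 0.01).

``vertical``
    The island was present in the cohort ancestor and is inherited
    vertically, so island divergence matches the backbone.

Everything planted — tree, branch substitution counts, island coordinates,
per-leaf difference maps, transfer events, pseudogene edits — is stored in
a :class:`TruthBundle` and can be written to / reloaded from plain-text
files, so downstream stages can be scored base-exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genome import Genome, read_genome, write_bed6, write_genome
from .simulate import (
    AncestralGenomeSpec,
    Event,
    IslandTemplate,
    _BASES,
    _idx_to_seq,
    _seq_to_idx,
    apply_pseudogenization,
    build_ancestral_genome,
    build_island_template,
    evolve_arr_along_tree,
    evolve_sequences,
    insert_island,
    sample_species_tree,
    _mutate_idx,
)

DiffMap = dict[int, tuple[str, str]]


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    seed: int
    n_taxa: int = 4
    tree_depth: float = 0.01
    genome_length: int = 200_000
    n_genes: int = 150
    gene_length: int = 900
    n_trna: int = 4
    trna_length: int = 76
    gc_content: float = 0.5
    island_length: int = 30_000
    island_genes: int = 25
    repeat_length: int = 48
    island_kind: str = "trna_integrative"
    scenario: str = "recent"  # recent | vertical | none
    residual_divergence: float = 5e-5
    n_carriers: int = 3
    trna_index: int = 1
    n_pseudogenes: int = 1


@dataclass
class TruthBundle:
    """Ground truth for one simulated cohort."""

    tree_newick: str
    island_coords: dict[str, tuple[str, int, int] | None]
    insert_pos: int | None
    island_span_length: int
    island_length: int
    repeat_length: int
    branch_events: dict[str, int]
    island_events: dict[str, int]
    backbone_diffs: dict[str, DiffMap]
    island_diffs: dict[str, DiffMap]
    event_log: list[Event]
    pseudogenes: list[tuple[str, str, str]]
    carriers: list[str]
    noncarrier: str | None
    contrast_pair: tuple[str, str] | None
    scenario: str = "recent"

    # -- coordinate helpers -------------------------------------------------

    def to_leaf_coord(self, genome_id: str, backbone_pos: int) -> int:
        """Map a backbone (root) coordinate into a leaf genome coordinate."""
        if genome_id in self.carriers and self.insert_pos is not None:
            if backbone_pos >= self.insert_pos:
                return backbone_pos + self.island_span_length
        return backbone_pos

    def island_interval(self, genome_id: str) -> tuple[int, int] | None:
        coords = self.island_coords.get(genome_id)
        return None if coords is None else (coords[1], coords[2])

    def pair_planted_snps(
        self, ref_id: str, query_id: str
    ) -> list[tuple[int, str, str]]:
        """Planted differences between two leaves, in *ref* coordinates.

        Backbone differences come from composing each leaf's diff-vs-root;
        island differences (carrier pairs only) from the diff-vs-donor maps
        plus the target-site-duplication copy, whose bases track each
        genome's own tRNA suffix.
        """
        out: list[tuple[int, str, str]] = []
        dref = self.backbone_diffs[ref_id]
        dqry = self.backbone_diffs[query_id]
        for pos in set(dref) | set(dqry):
            root = (dref.get(pos) or dqry.get(pos))[0]
            rb = dref.get(pos, (root, root))[1]
            qb = dqry.get(pos, (root, root))[1]
            if rb != qb:
                out.append((self.to_leaf_coord(ref_id, pos), rb, qb))
        if ref_id in self.carriers and query_id in self.carriers:
            iref = self.island_diffs[ref_id]
            iqry = self.island_diffs[query_id]
            assert self.insert_pos is not None
            for rel in set(iref) | set(iqry):
                anc = (iref.get(rel) or iqry.get(rel))[0]
                rb = iref.get(rel, (anc, anc))[1]
                qb = iqry.get(rel, (anc, anc))[1]
                if rb != qb:
                    out.append((self.insert_pos + rel, rb, qb))
            # Distal repeat copy: duplicated from each genome's tRNA suffix.
            for i in range(self.repeat_length):
                bpos = self.insert_pos - self.repeat_length + i
                root = None
                for d in (dref, dqry):
                    if bpos in d:
                        root = d[bpos][0]
                if root is None:
                    continue
                rb = dref.get(bpos, (root, root))[1]
                qb = dqry.get(bpos, (root, root))[1]
                if rb != qb:
                    out.append((self.insert_pos + self.island_length + i, rb, qb))
        return sorted(out)


@dataclass
class SimulationResult:
    config: CohortConfig
    tree: dendropy.Tree
    genomes: dict[str, Genome]
    truth: TruthBundle
    island: IslandTemplate | None = None


def _pick_contrast_pair(tree: dendropy.Tree) -> tuple[str, str]:
    """Two leaves on opposite sides of the root (maximal path ~ 2*depth)."""
    children = tree.seed_node.child_nodes()
    sides = []
    for ch in children[:2]:
        labels = sorted(lf.taxon.label for lf in ch.leaf_iter())
        sides.append(labels[0])
    return sides[0], sides[1]


def simulate_cohort(cfg: CohortConfig) -> SimulationResult:
    """Run one cohort simulation end to end."""
    rng = np.random.default_rng(cfg.seed)
    sub = rng.integers(0, 2**31 - 1, size=16)

    tree = sample_species_tree(cfg.n_taxa, cfg.tree_depth, int(sub[0]))
    root = build_ancestral_genome(
        AncestralGenomeSpec(
            genome_length=cfg.genome_length,
            n_genes=cfg.n_genes,
            gene_length=cfg.gene_length,
            n_trna=cfg.n_trna,
            trna_length=cfg.trna_length,
            gc_content=cfg.gc_content,
            seed=int(sub[1]),
        )
    )
    leaves, branch_events, backbone_diffs = evolve_sequences(tree, root, int(sub[2]))
    labels = sorted(leaves)

    event_log: list[Event] = []
    island_coords: dict[str, tuple[str, int, int] | None] = {g: None for g in labels}
    island_diffs: dict[str, DiffMap] = {}
    island_events: dict[str, int] = {}
    pseudogenes: list[tuple[str, str, str]] = []
    island = None
    insert_pos: int | None = None
    span_len = 0
    contrast_pair = _pick_contrast_pair(tree) if cfg.n_taxa >= 2 else None

    carriers: list[str] = []
    noncarrier: str | None = None
    if cfg.scenario != "none" and cfg.n_carriers > 0:
        if cfg.n_carriers >= cfg.n_taxa:
            carriers = list(labels)
        else:
            pool = [g for g in labels if contrast_pair is None or g not in contrast_pair]
            noncarrier = pool[-1]
            carriers = [g for g in labels if g != noncarrier][: cfg.n_carriers]
        # The planted direct repeat must be maximal at exactly
        # repeat_length: if the island's terminal bases coincided with the
        # backbone bases flanking the insertion site, the repeat would
        # extend by chance and the island boundary would become
        # ambiguous. Resample the template until both termini differ.
        trna_end = root.features_of_type("tRNA")[cfg.trna_index].end
        root_seq = root.contigs["chr"]
        after = root_seq[trna_end] if trna_end < len(root_seq) else ""
        before = root_seq[trna_end - cfg.repeat_length - 1]
        for attempt in range(64):
            island = build_island_template(
                seed=int((sub[3] + attempt) % (2**31 - 1)),
                length=cfg.island_length,
                n_genes=cfg.island_genes,
                gene_length=cfg.gene_length,
                repeat_length=cfg.repeat_length,
                kind=cfg.island_kind,
                gc_content=cfg.gc_content,
            )
            if island.sequence[0] != after and island.sequence[-1] != before:
                break
        donor = carriers[0]
        event_log.append(Event("insertion", cfg.residual_divergence, "environment", donor, "island"))

        if cfg.scenario == "recent":
            per_carrier_seeds = {c: int(sub[4 + i]) for i, c in enumerate(carriers)}
            for c in carriers:
                crng = np.random.default_rng(per_carrier_seeds[c])
                arr = _seq_to_idx(island.sequence)
                leaf_arr, n_ev = _mutate_idx(arr, cfg.residual_divergence, crng)
                where = np.nonzero(leaf_arr != arr)[0]
                island_diffs[c] = {
                    int(p): (_BASES[arr[p]], _BASES[leaf_arr[p]]) for p in where
                }
                island_events[c] = n_ev
                leaves[c], span = insert_island(
                    leaves[c], island, cfg.trna_index, island_sequence=_idx_to_seq(leaf_arr)
                )
                island_coords[c] = span
                if c != donor:
                    event_log.append(
                        Event("transfer", cfg.residual_divergence, donor, c, "island")
                    )
        elif cfg.scenario == "vertical":
            arr = _seq_to_idx(island.sequence)
            leaf_arrs, isl_branch = evolve_arr_along_tree(tree, arr, int(sub[4]))
            for c in carriers:
                leaf_arr = leaf_arrs[c]
                where = np.nonzero(leaf_arr != arr)[0]
                island_diffs[c] = {
                    int(p): (_BASES[arr[p]], _BASES[leaf_arr[p]]) for p in where
                }
                island_events[c] = int(sum(isl_branch.values()))
                leaves[c], span = insert_island(
                    leaves[c], island, cfg.trna_index, island_sequence=_idx_to_seq(leaf_arr)
                )
                island_coords[c] = span
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        insert_pos = island_coords[carriers[0]][1]
        span_len = island.length + island.repeat_length

        # Pseudogenize island accessory genes in (cyclically chosen) carriers.
        acc_labels = [g.label for g in island.genes if g.label.startswith("acc_")]
        prng = np.random.default_rng(int(sub[10]))
        for i in range(cfg.n_pseudogenes):
            if not acc_labels:
                break
            c = carriers[i % len(carriers)]
            gene = acc_labels[int(prng.integers(0, len(acc_labels)))]
            mode = "start_loss" if i % 2 == 0 else "nonsense"
            leaves[c], (gpos, old, new) = apply_pseudogenization(
                leaves[c], gene, mode, int(prng.integers(0, 2**31 - 1))
            )
            pseudogenes.append((c, gene, mode))
            rel = gpos - insert_pos
            if 0 <= rel < island.length:
                anc = island.sequence[rel]
                if anc == new:
                    island_diffs[c].pop(rel, None)
                else:
                    island_diffs[c][rel] = (anc, new)
            event_log.append(Event("pseudogenization", 0.0, c, c, gene))

    truth = TruthBundle(
        tree_newick=tree.as_string(schema="newick").strip(),
        island_coords=island_coords,
        insert_pos=insert_pos,
        island_span_length=span_len,
        island_length=island.length if island else 0,
        repeat_length=island.repeat_length if island else 0,
        branch_events=branch_events,
        island_events=island_events,
        backbone_diffs=backbone_diffs,
        island_diffs=island_diffs,
        event_log=event_log,
        pseudogenes=pseudogenes,
        carriers=carriers,
        noncarrier=noncarrier,
        contrast_pair=contrast_pair,
        scenario=cfg.scenario,
    )
    return SimulationResult(cfg, tree, leaves, truth, island)


# ---------------------------------------------------------------------------
# Emission / reload


def write_simulation(result: SimulationResult, outdir: str | Path) -> Path:
    """Write genomes + truth bundle as plain-text files; returns outdir."""
    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "diffs").mkdir(exist_ok=True)
    for g in result.genomes.values():
        write_genome(g, out / "genomes")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(result.truth.tree_newick + "\n")
    bed_rows = [
        (c, s, e, f"island_{gid}", 0.0, "+")
        for gid, coords in sorted(result.truth.island_coords.items())
        if coords is not None
        for (c, s, e) in [coords]
    ]
    write_bed6(out / "islands.bed", bed_rows)
    with open(out / "events.tsv", "w") as fh:
        fh.write("type\ttime\tdonor\trecipient\tpayload\n")
        for ev in result.truth.event_log:
            fh.write(f"{ev.etype}\t{ev.time}\t{ev.donor}\t{ev.recipient}\t{ev.payload}\n")
    with open(out / "planted_snps.tsv", "w") as fh:
        fh.write("scope\tkey\tevents\n")
        for k, v in sorted(result.truth.branch_events.items()):
            fh.write(f"branch\t{k}\t{v}\n")
        for k, v in sorted(result.truth.island_events.items()):
            fh.write(f"island\t{k}\t{v}\n")
    with open(out / "pseudogenes.tsv", "w") as fh:
        fh.write("genome\tgene\tmode\n")
        for g, gene, mode in result.truth.pseudogenes:
            fh.write(f"{g}\t{gene}\t{mode}\n")
    for gid, dmap in result.truth.backbone_diffs.items():
        _write_diff(out / "diffs" / f"{gid}.backbone.tsv", dmap)
    for gid, dmap in result.truth.island_diffs.items():
        _write_diff(out / "diffs" / f"{gid}.island.tsv", dmap)
    meta = {
        "scenario": result.truth.scenario,
        "carriers": result.truth.carriers,
        "noncarrier": result.truth.noncarrier,
        "contrast_pair": result.truth.contrast_pair,
        "insert_pos": result.truth.insert_pos,
        "island_span_length": result.truth.island_span_length,
        "island_length": result.truth.island_length,
        "repeat_length": result.truth.repeat_length,
        "island_coords": result.truth.island_coords,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return out


def _write_diff(path: Path, dmap: DiffMap) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tancestral\tderived\n")
        for pos in sorted(dmap):
            a, b = dmap[pos]
            fh.write(f"{pos}\t{a}\t{b}\n")


def _read_diff(path: Path) -> DiffMap:
    out: DiffMap = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            pos, a, b = line.split()
            out[int(pos)] = (a, b)
    return out


def load_simulation(outdir: str | Path) -> tuple[dict[str, Genome], TruthBundle]:
    """Reload an emitted simulation; inverse of :func:`write_simulation`."""
    out = Path(outdir)
    genomes: dict[str, Genome] = {}
    for fasta in sorted((out / "genomes").glob("*.fasta")):
        genomes[fasta.stem] = read_genome(fasta, fasta.with_suffix(".gff3"))
    with open(out / "truth.json") as fh:
        meta = json.load(fh)
    with open(out / "tree.nwk") as fh:
        newick = fh.read().strip()
    events: list[Event] = []
    with open(out / "events.tsv") as fh:
        next(fh)
        for line in fh:
            et, t, d, r, p = line.rstrip("\n").split("\t")
            events.append(Event(et, float(t), d, r, p))
    branch_events: dict[str, int] = {}
    island_events: dict[str, int] = {}
    with open(out / "planted_snps.tsv") as fh:
        next(fh)
        for line in fh:
            scope, key, v = line.split()
            (branch_events if scope == "branch" else island_events)[key] = int(v)
    pseudogenes: list[tuple[str, str, str]] = []
    with open(out / "pseudogenes.tsv") as fh:
        next(fh)
        for line in fh:
            g, gene, mode = line.split()
            pseudogenes.append((g, gene, mode))
    backbone_diffs = {}
    island_diffs = {}
    for p in sorted((out / "diffs").glob("*.backbone.tsv")):
        backbone_diffs[p.name.removesuffix(".backbone.tsv")] = _read_diff(p)
    for p in sorted((out / "diffs").glob("*.island.tsv")):
        island_diffs[p.name.removesuffix(".island.tsv")] = _read_diff(p)
    truth = TruthBundle(
        tree_newick=newick,
        island_coords={
            k: (tuple(v) if v is not None else None)
            for k, v in meta["island_coords"].items()
        },
        insert_pos=meta["insert_pos"],
        island_span_length=meta["island_span_length"],
        island_length=meta["island_length"],
        repeat_length=meta["repeat_length"],
        branch_events=branch_events,
        island_events=island_events,
        backbone_diffs=backbone_diffs,
        island_diffs=island_diffs,
        event_log=events,
        pseudogenes=pseudogenes,
        carriers=list(meta["carriers"]),
        noncarrier=meta["noncarrier"],
        contrast_pair=tuple(meta["contrast_pair"]) if meta["contrast_pair"] else None,
        scenario=meta["scenario"],
    )
    return genomes, truth
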