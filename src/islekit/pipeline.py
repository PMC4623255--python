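"""Pipeline orchestration: simulate → orthologs → tree → delineate → snp-scan.

Every stage reads and writes plain standard-format files on disk, so any
stage can be run (or replaced by an external tool) standalone. A run
manifest records the config hash, per-stage output checksums and
wall-clock times; re-running with identical config and seed reproduces
identical checksums, and completed stages are skipped on resume.
"""
from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import BlockFilterParams, conserved_block_filter, progressive_align
from .cohort import CohortConfig, simulate_cohort, write_simulation
from .config import PipelineConfig
from .genome import Genome, load_genome_dir, write_bed6
from .islands import (
    IslandCall,
    anchor_core_expansion,
    classify_mobility,
    delineate_islands,
    find_direct_repeats,
    flanking_synteny_score,
)
from .orthology import (
    OrthologCluster,
    build_clusters,
    filter_single_copy_complete,
    proteome_from_genome,
    read_clusters_tsv,
    write_clusters_tsv,
)
from .phylo import (
    bootstrap_supports,
    concatenate_supermatrix,
    poisson_distance_matrix,
    write_newick,
    write_partitions,
    write_phylip,
)
from .snp import (
    acquisition_contrast_test,
    anchor_chain_align,
    annotate_snps,
    call_snps,
    label_snp_regions,
    region_snp_frequency,
    window_snp_histogram,
    write_bedgraph,
    write_vcf,
)

STAGES = ("simulate", "orthologs", "mlsa_tree", "delineate", "snp_scan", "report")


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    python: str = sys.version.split()[0]
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "python": self.python,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=1,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _derive_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class StageRunner:
    """Runs stages with checksum manifests and resumable skip markers."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config_hash=_config_hash(cfg))

    def _marker(self, stage: str) -> Path:
        return self.out / f".{stage}.done"

    def completed(self, stage: str) -> bool:
        m = self._marker(stage)
        if not m.exists():
            return False
        try:
            info = json.loads(m.read_text())
        except json.JSONDecodeError:
            return False
        if info.get("config_hash") != self.manifest.config_hash:
            return False
        return all(Path(p).exists() and _sha256(Path(p)) == h for p, h in info["files"].items())

    def run_stage(self, stage: str, fn) -> None:
        if self.completed(stage):
            info = json.loads(self._marker(stage).read_text())
            info["skipped"] = True
            self.manifest.stages[stage] = info
            return
        t0 = time.time()
        try:
            outputs, warnings = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        info = {
            "config_hash": self.manifest.config_hash,
            "files": {str(p): _sha256(Path(p)) for p in sorted(map(str, outputs))},
            "seconds": round(time.time() - t0, 3),
            "warnings": warnings,
        }
        self.manifest.stages[stage] = info
        self.manifest.warnings.extend(f"{stage}: {w}" for w in warnings)
        self._marker(stage).write_text(json.dumps(info))


# ---------------------------------------------------------------------------
# Stage implementations


def stage_simulate(cfg: PipelineConfig, out: Path) -> tuple[list[Path], list[str]]:
    sim = cfg.simulate
    assert sim is not None
    cohort = CohortConfig(seed=_derive_seed(cfg.seed, "simulate"), **sim.model_dump())
    result = simulate_cohort(cohort)
    simdir = out / "sim"
    write_simulation(result, simdir)
    return sorted(p for p in simdir.rglob("*") if p.is_file()), []


def genomes_dir_for(cfg: PipelineConfig, out: Path) -> Path:
    return Path(cfg.genomes_dir) if cfg.genomes_dir else out / "sim" / "genomes"


def stage_orthologs(
    cfg: PipelineConfig, out: Path, genomes: dict[str, Genome]
) -> tuple[list[Path], list[str]]:
    prots = {g: proteome_from_genome(G) for g, G in genomes.items()}
    o = cfg.orthology
    clusters, _ = build_clusters(
        prots,
        min_score=o.min_score,
        min_coverage=o.min_coverage,
        matrix=o.matrix,
        gap_open=o.gap_open,
        gap_extend=o.gap_extend,
        seed_kmer=o.seed_kmer,
        min_shared_kmers=o.min_shared_kmers,
    )
    path = out / "clusters.tsv"
    write_clusters_tsv(path, clusters)
    return [path], []


def stage_mlsa_tree(
    cfg: PipelineConfig, out: Path, genomes: dict[str, Genome]
) -> tuple[list[Path], list[str]]:
    warnings: list[str] = []
    clusters = read_clusters_tsv(out / "clusters.tsv")
    scc = filter_single_copy_complete(clusters, set(genomes))
    if len(scc) < 3:
        warnings.append(f"only {len(scc)} single-copy-complete loci")
    prots = {
        g: {p.gene_id: p.sequence for p in proteome_from_genome(G)}
        for g, G in genomes.items()
    }
    m = cfg.mlsa
    params = BlockFilterParams(
        min_conserved_frac=m.min_conserved_frac,
        min_flank_frac=m.min_flank_frac,
        max_nonconserved_run=m.max_nonconserved_run,
        min_block_len=m.min_block_len,
        max_gap_frac=m.max_gap_frac,
    )
    alns = {}
    for c in scc:
        seqs = {g: prots[g][gene] for g, gene in sorted(c.members)}
        aln = progressive_align(seqs, gap_open=m.gap_open, gap_extend=m.gap_extend)
        trimmed, _ = conserved_block_filter(aln, params)
        if trimmed.ncols:
            alns[c.cluster_id] = trimmed
    sm = concatenate_supermatrix(alns, sorted(genomes))
    tree = bootstrap_supports(sm, m.bootstrap_reps, _derive_seed(cfg.seed, "bootstrap"))
    paths = [out / "supermatrix.phy", out / "partitions.txt", out / "tree.nwk"]
    write_phylip(sm, paths[0])
    write_partitions(sm, paths[1])
    write_newick(tree, paths[2])
    return paths, warnings


def stage_delineate(
    cfg: PipelineConfig, out: Path, genomes: dict[str, Genome]
) -> tuple[list[Path], list[str]]:
    warnings: list[str] = []
    isl = cfg.island
    clusters = read_clusters_tsv(out / "clusters.tsv")
    calls: dict[str, list[IslandCall]] = {}
    repeat_only: dict[str, list] = {}
    for gid, G in sorted(genomes.items()):
        if not G.features_of_type("tRNA"):
            reps = []
            for contig, seq in G.contigs.items():
                reps.extend(
                    find_direct_repeats(
                        seq,
                        min_len=isl.min_repeat_len,
                        max_mismatch=isl.max_mismatch,
                        min_sep=isl.min_sep,
                        max_sep=isl.max_sep,
                        contig=contig,
                    )
                )
            repeat_only[gid] = [
                {"copy1": r.copy1, "copy2": r.copy2, "length": r.length} for r in reps
            ]
            warnings.append(f"{gid}: no tRNA annotations; repeat-only evidence")
            calls[gid] = []
            continue
        calls[gid] = delineate_islands(
            G,
            min_len=isl.min_repeat_len,
            max_mismatch=isl.max_mismatch,
            min_sep=isl.min_sep,
            max_sep=isl.max_sep,
        )
    noncarriers = [g for g, c in calls.items() if not c and genomes[g].features_of_type("tRNA")]
    report: dict[str, list[dict]] = {}
    bed_rows = []
    for gid, gcalls in calls.items():
        report[gid] = []
        for call in gcalls:
            if noncarriers:
                contiguous, intervening = flanking_synteny_score(
                    genomes[gid], call, genomes[noncarriers[0]], clusters,
                    m_flank=isl.m_flank, gap_tolerance=isl.gap_tolerance,
                )
                call.evidence["synteny"] = contiguous
            mob = classify_mobility(call, genomes[gid])
            bed_rows.append(
                (call.contig, call.start, call.end, f"island_{gid}", 0.0, "+")
            )
            report[gid].append(
                {
                    "contig": call.contig,
                    "start": call.start,
                    "end": call.end,
                    "integration_feature": call.integration_feature,
                    "repeat": {
                        "copy1": call.repeat.copy1,
                        "copy2": call.repeat.copy2,
                        "length": call.repeat.length,
                        "mismatches": call.repeat.mismatches,
                    }
                    if call.repeat
                    else None,
                    "evidence": call.evidence,
                    "mobility": mob.label,
                    "mobility_markers": mob.markers,
                    "n_genes": len(call.gene_ids),
                }
            )

    # Core/accessory partition across islands sharing anchors.
    gene_to_cluster = {}
    for c in clusters:
        for member in c.members:
            gene_to_cluster[member] = c.cluster_id
    island_genes = {}
    for gid, gcalls in calls.items():
        for call in gcalls:
            ordered = [
                (g, gene_to_cluster.get((gid, g), f"unclustered:{g}"))
                for g in call.gene_ids
            ]
            island_genes[f"{gid}:{call.start}"] = ordered
    core_info = None
    if len(island_genes) >= 2:
        anchor_clusters = {
            cid
            for (g, gene), cid in gene_to_cluster.items()
            for G in [genomes.get(g)]
            if G is not None
            for f in [next((f for f in G.features if f.feature_id == gene), None)]
            if f is not None and f.gene in set(isl.anchor_genes)
        }
        if anchor_clusters:
            cgs = anchor_core_expansion(island_genes, anchor_clusters)
            core_info = {
                "core": sorted(cgs.core),
                "accessory": {k: sorted(v) for k, v in cgs.accessory.items()},
                "anchors": sorted(cgs.anchors),
            }
    paths = [out / "islands.bed", out / "islands.json"]
    write_bed6(paths[0], bed_rows)
    with open(paths[1], "w") as fh:
        json.dump(
            {"islands": report, "repeat_only": repeat_only, "core": core_info},
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths, warnings


def stage_snp_scan(
    cfg: PipelineConfig, out: Path, genomes: dict[str, Genome]
) -> tuple[list[Path], list[str]]:
    warnings: list[str] = []
    with open(out / "islands.json") as fh:
        islands = json.load(fh)["islands"]
    carriers = sorted(g for g, calls in islands.items() if calls)
    ref_id = cfg.reference or (carriers[0] if carriers else sorted(genomes)[0])
    if ref_id not in genomes:
        raise ValueError(f"reference genome {ref_id!r} not found")
    ref = genomes[ref_id]
    island_intervals = [
        (c["start"], c["end"]) for c in islands.get(ref_id, [])
    ]
    if not island_intervals:
        warnings.append(f"reference {ref_id} carries no island; backbone-only scan")
    s = cfg.snp
    paths = []
    contrasts = {}
    snpdir = out / "snps"
    snpdir.mkdir(exist_ok=True)
    for qid in sorted(genomes):
        if qid == ref_id:
            continue
        smap = anchor_chain_align(
            ref, genomes[qid], min_anchor=s.min_anchor, max_gap=s.max_gap
        )
        snps = call_snps(smap)
        label_snp_regions(snps, island_intervals, smap)
        vcf = snpdir / f"{qid}.vcf"
        write_vcf(vcf, snps, ref_id, qid)
        paths.append(vcf)
        (contig, glen), = [(c, len(seq)) for c, seq in ref.contigs.items()][:1]
        track = window_snp_histogram(snps, (0, glen), s.window, smap)
        bg = snpdir / f"{qid}.bedgraph"
        write_bedgraph(bg, contig, track)
        paths.append(bg)
        if island_intervals:
            isl = island_intervals[0]
            try:
                k1, n1, f1 = region_snp_frequency(snps, isl, smap, s.denominator)
                backbone_snps = [x for x in snps if x.region == "backbone"]
                n2 = smap.aligned_ref_length((0, glen)) - smap.aligned_ref_length(isl)
                if s.denominator == "total":
                    n2 = glen - (isl[1] - isl[0])
                k2 = len(backbone_snps)
                cr = acquisition_contrast_test(
                    (k1, n1), (k2, n2), alpha=s.alpha, ratio_cut=s.ratio_cut
                )
                effects = [
                    e
                    for e in annotate_snps(
                        [x for x in snps if x.region == "island"], ref
                    )
                ]
                contrasts[qid] = {
                    "island": {"snps": k1, "aligned_bp": n1, "frequency": f1},
                    "backbone": {
                        "snps": k2,
                        "aligned_bp": n2,
                        "frequency": k2 / n2 if n2 else None,
                    },
                    "ratio": cr.ratio,
                    "p_value": cr.p_value,
                    "call": cr.call,
                    "island_coding_effects": [
                        {
                            "gene": e.gene_id,
                            "classification": e.classification,
                            "substitution": e.substitution,
                        }
                        for e in effects
                    ],
                }
            except ValueError as exc:
                warnings.append(f"{qid}: contrast undefined ({exc})")
    cpath = out / "contrast.json"
    with open(cpath, "w") as fh:
        json.dump({"reference": ref_id, "queries": contrasts}, fh, indent=1, sort_keys=True)
    paths.append(cpath)
    return paths, warnings


def stage_report(cfg: PipelineConfig, out: Path) -> tuple[list[Path], list[str]]:
    with open(out / "contrast.json") as fh:
        data = json.load(fh)
    path = out / "report.tsv"
    with open(path, "w") as fh:
        fh.write(
            "query\tregion\tsnps\taligned_bp\tfrequency_pct\tratio\tp_value\tcall\n"
        )
        for qid, c in sorted(data["queries"].items()):
            for region in ("island", "backbone"):
                r = c[region]
                freq = r["frequency"]
                fh.write(
                    f"{qid}\t{region}\t{r['snps']}\t{r['aligned_bp']}\t"
                    f"{100 * freq:.4f}\t{c['ratio']:.6g}\t{c['p_value']:.6g}\t{c['call']}\n"
                )
    return [path], []


# ---------------------------------------------------------------------------


def run_full_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage in order; returns the manifest (also written)."""
    runner = StageRunner(cfg)
    out = runner.out
    if cfg.simulate is not None:
        runner.run_stage("simulate", lambda: stage_simulate(cfg, out))
    genomes = load_genome_dir(genomes_dir_for(cfg, out))
    if not genomes:
        raise RuntimeError("no genomes found (need <id>.fasta + <id>.gff3 pairs)")
    runner.run_stage("orthologs", lambda: stage_orthologs(cfg, out, genomes))
    runner.run_stage("mlsa_tree", lambda: stage_mlsa_tree(cfg, out, genomes))
    runner.run_stage("delineate", lambda: stage_delineate(cfg, out, genomes))
    runner.run_stage("snp_scan", lambda: stage_snp_scan(cfg, out, genomes))
    runner.run_stage("report", lambda: stage_report(cfg, out))
    (out / "manifest.json").write_text(runner.manifest.to_json())
    return runner.manifest
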