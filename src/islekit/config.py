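"""Run configuration: schema-validated YAML with explicit seeds.

Unknown keys are rejected (typos fail loudly), defaults mirror the
module-level defaults, and every random stage derives its seed from the
single mandatory top-level ``seed`` — no hidden global randomness.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationBlock(_Block):
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
    scenario: str = "recent"
    residual_divergence: float = 5e-5
    n_carriers: int = 3
    trna_index: int = 1
    n_pseudogenes: int = 1


class OrthologyBlock(_Block):
    matrix: str = "BLOSUM62"
    gap_open: float = 11
    gap_extend: float = 1
    min_score: float = 50.0
    min_coverage: float = 0.5
    seed_kmer: int = 5
    min_shared_kmers: int = 2
    identity_threshold: float = 0.90


class MlsaBlock(_Block):
    gap_open: float = 11
    gap_extend: float = 1
    min_conserved_frac: float = 0.501
    min_flank_frac: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 5
    max_gap_frac: float = 0.5
    bootstrap_reps: int = 100


class IslandBlock(_Block):
    min_repeat_len: int = 40
    max_mismatch: int = 0
    min_sep: int = 5_000
    max_sep: int = 200_000
    m_flank: int = 5
    gap_tolerance: int = 1
    anchor_genes: tuple[str, str] = ("pcrA", "cld")


class SnpBlock(_Block):
    window: int = 500
    min_anchor: int = 20
    max_gap: int = 5_000
    alpha: float = 0.01
    ratio_cut: float = 0.1
    denominator: str = "aligned"


class PipelineConfig(_Block):
    out_dir: str
    seed: int
    genomes_dir: str | None = None
    reference: str | None = None
    simulate: SimulationBlock | None = None
    orthology: OrthologyBlock = Field(default_factory=OrthologyBlock)
    mlsa: MlsaBlock = Field(default_factory=MlsaBlock)
    island: IslandBlock = Field(default_factory=IslandBlock)
    snp: SnpBlock = Field(default_factory=SnpBlock)

    @model_validator(mode="after")
    def _one_input_mode(self) -> "PipelineConfig":
        if (self.genomes_dir is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of 'genomes_dir' (real-genome mode) or "
                "'simulate' (simulation mode) must be given"
            )
        return self


def validate_config(text: str) -> PipelineConfig:
    """Parse and validate a YAML config string."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    return PipelineConfig.model_validate(raw)


def load_config(path: str | Path) -> PipelineConfig:
    return validate_config(Path(path).read_text())
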