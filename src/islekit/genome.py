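"""Sequence and feature containers with plain-text genomics I/O.

All coordinates are 0-based half-open on the forward strand of a contig.
GFF3 files are written 1-based inclusive (per the format); BED stays
0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature types understood by the toolkit.
FEATURE_TYPES = ("CDS", "tRNA", "mobile_genetic_element")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """A typed genomic feature.

    ``start``/``end`` are 0-based half-open; ``gene`` is a human-readable
    locus label (stable across simulated genomes), ``product`` a free-text
    functional annotation used for mobility-marker matching.
    """

    feature_id: str
    ftype: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    gene: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"bad interval for {self.feature_id}: [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.feature_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class Genome:
    """A genome: named contig sequences plus typed features."""

    genome_id: str
    contigs: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def feature_seq(self, feat: Feature) -> str:
        s = self.contigs[feat.contig][feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def translate_cds(self, feat: Feature, to_stop: bool = False) -> str:
        """Translate a CDS feature (standard code), trailing stop removed.

        With ``to_stop=True`` translation halts at the first stop codon,
        which truncates pseudogenes carrying a premature stop.
        """
        aa = str(Seq(self.feature_seq(feat)).translate(to_stop=to_stop))
        return aa.rstrip("*")

    def features_of_type(self, ftype: str) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.ftype == ftype),
            key=lambda f: (f.contig, f.start),
        )

    def get_feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature {feature_id!r} in genome {self.genome_id}")

    def sorted_features(self, contig: str | None = None) -> list[Feature]:
        feats = self.features if contig is None else [
            f for f in self.features if f.contig == contig
        ]
        return sorted(feats, key=lambda f: (f.contig, f.start))


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str | Path, seqs: dict[str, str], wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (minimal subset: CDS / tRNA / mobile_genetic_element rows with
# ID, gene and product attributes)

_GFF_SAFE = " :/_().|-"


def write_gff3(path: str | Path, genome: Genome, source: str = "islekit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for f in genome.sorted_features():
            attrs = [f"ID={quote(f.feature_id, safe=_GFF_SAFE)}"]
            if f.gene:
                attrs.append(f"gene={quote(f.gene, safe=_GFF_SAFE)}")
            if f.product:
                attrs.append(f"product={quote(f.product, safe=_GFF_SAFE)}")
            phase = "0" if f.ftype == "CDS" else "."
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        phase,
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 row: {line!r}")
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = unquote(v)
            feats.append(
                Feature(
                    feature_id=attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                    ftype=cols[2],
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    gene=attrs.get("gene", ""),
                    product=attrs.get("product", ""),
                )
            )
    return feats


def write_genome(genome: Genome, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``<id>.fasta`` + ``<id>.gff3`` into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{genome.genome_id}.fasta"
    gff = outdir / f"{genome.genome_id}.gff3"
    write_fasta(fasta, genome.contigs)
    write_gff3(gff, genome)
    return fasta, gff


def read_genome(fasta: str | Path, gff: str | Path, genome_id: str | None = None) -> Genome:
    contigs = read_fasta(fasta)
    feats = read_gff3(gff)
    gid = genome_id or Path(fasta).stem
    return Genome(genome_id=gid, contigs=contigs, features=feats)


def load_genome_dir(path: str | Path) -> dict[str, Genome]:
    """Load every ``<id>.fasta`` / ``<id>.gff3`` pair in a directory."""
    path = Path(path)
    genomes: dict[str, Genome] = {}
    for fasta in sorted(path.glob("*.fasta")):
        gff = fasta.with_suffix(".gff3")
        if gff.exists():
            genomes[fasta.stem] = read_genome(fasta, gff)
    return genomes


# ---------------------------------------------------------------------------
# BED6

def write_bed6(path: str | Path, rows: list[tuple[str, int, int, str, float, str]]) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, n, sc, st = line.rstrip("\n").split("\t")[:6]
            rows.append((c, int(s), int(e), n, float(sc), st))
    return rows
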