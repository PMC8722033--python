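"""Synthetic genome model and ground-truth containers.

The genome model is deliberately small: a handful of chromosomes (one of
which must be named ``X``), genes with regularly spaced exons, and a toy
phenotype ontology annotating those genes. It fixes the coordinate frame for
every simulator — read-depth bins (20 kb by default, the shallow-WGS
convention this toolkit is built around), exon-depth matrices, and trio
variant tables. All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np

from .ontology import ToyOntology, build_toy_ontology

__all__ = [
    "Exon",
    "Gene",
    "GenomeModel",
    "SimulationConfig",
    "PlantedCnv",
    "PlantedVariant",
    "TruthFinding",
    "TruthSet",
    "build_genome_model",
]

INHERITANCE_MODES = ("AD", "AR", "XL")
CNV_ORIGINS = ("denovo", "pat", "mat")
MECHANISMS = (
    "ad_denovo_cnv",
    "ad_denovo_snv",
    "xl_maternal",
    "ar_homozygous",
    "ar_comphet_snv",
    "ar_comphet_cnv_snv",
    "none",
)


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    inheritance_mode: str
    hpo_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise ValueError(f"invalid inheritance mode {self.inheritance_mode!r}")


@dataclass(frozen=True)
class GenomeModel:
    """Chromosomes, bins, genes/exons and the annotating ontology."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    exons: tuple[Exon, ...]
    genes: tuple[Gene, ...]
    ontology: ToyOntology

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if "X" not in names:
            raise ValueError("chromosome set must include one designated 'X'")
        by_gene: dict[str, list[Exon]] = {}
        for ex in self.exons:
            by_gene.setdefault(ex.gene_id, []).append(ex)
        for gene in self.genes:
            exs = by_gene.get(gene.gene_id, [])
            if not exs:
                raise ValueError(f"gene {gene.gene_id} has no exons")
            exs = sorted(exs, key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping exons in gene {gene.gene_id}")
            if not gene.hpo_terms:
                raise ValueError(f"gene {gene.gene_id} has no ontology terms")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c, _ in self.chromosomes)

    def bin_table(self) -> list[tuple[str, int, int]]:
        """(chrom, start, end) for every bin; the terminal bin may be short."""
        out: list[tuple[str, int, int]] = []
        for chrom, length in self.chromosomes:
            for start in range(0, length, self.bin_size):
                out.append((chrom, start, min(start + self.bin_size, length)))
        return out

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    def gene_exons(self, gene_id: str) -> list[Exon]:
        return sorted(
            (e for e in self.exons if e.gene_id == gene_id), key=lambda e: e.start
        )

    def to_dict(self) -> dict:
        return {
            "chromosomes": [list(c) for c in self.chromosomes],
            "bin_size": self.bin_size,
            "exons": [list(astuple_exon(e)) for e in self.exons],
            "genes": [
                [g.gene_id, g.chrom, g.start, g.end, g.inheritance_mode, list(g.hpo_terms)]
                for g in self.genes
            ],
            "ontology": self.ontology.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, data: dict) -> "GenomeModel":
        return cls(
            chromosomes=tuple((c, int(n)) for c, n in data["chromosomes"]),
            bin_size=int(data["bin_size"]),
            exons=tuple(Exon(c, int(s), int(e), g) for c, s, e, g in data["exons"]),
            genes=tuple(
                Gene(gid, c, int(s), int(e), mode, tuple(terms))
                for gid, c, s, e, mode, terms in data["genes"]
            ),
            ontology=ToyOntology.from_dict(data["ontology"]),
        )


def astuple_exon(e: Exon) -> tuple[str, int, int, str]:
    return (e.chrom, e.start, e.end, e.gene_id)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for :func:`build_genome_model`.

    Defaults give three chromosomes (two 10 Mb autosomes plus a 5 Mb X),
    eight genes per chromosome with eight ~200 bp exons spaced 3 kb apart,
    and a 3-level / branching-3 toy ontology.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("1", 10_000_000),
        ("2", 10_000_000),
        ("X", 5_000_000),
    )
    bin_size: int = 20_000
    genes_per_chromosome: int = 8
    exons_per_gene: int = 8
    exon_length: int = 200
    exon_spacing: int = 3_000
    ontology_levels: int = 3
    ontology_branching: int = 3
    extra_terms_per_gene: int = 2

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        if self.genes_per_chromosome < 1 or self.exons_per_gene < 1:
            raise ValueError("need at least one gene per chromosome and exon per gene")
        if "X" not in {c for c, _ in self.chromosomes}:
            raise ValueError("chromosome set must include one designated 'X'")


@dataclass(frozen=True)
class PlantedCnv:
    """A ground-truth copy-number event carried by one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copies: int  # 0, 1, 3 or 4 — never the diploid 2
    parental_origin: str | None = None  # denovo | pat | mat; None for parents
    gene_id: str | None = None
    channel: str = "lowpass"  # lowpass | exonic

    def __post_init__(self) -> None:
        if self.copies == 2 or not 0 <= self.copies <= 4:
            raise ValueError(f"planted CNV copies must be in {{0,1,3,4}}, got {self.copies}")
        if self.end <= self.start:
            raise ValueError("empty CNV interval")
        if self.parental_origin is not None and self.parental_origin not in CNV_ORIGINS:
            raise ValueError(f"invalid parental origin {self.parental_origin!r}")


@dataclass(frozen=True)
class PlantedVariant:
    sample_id: str
    chrom: str
    pos: int  # 1-based, matching the VCF records it materializes in
    ref: str
    alt: str
    genotype: str
    origin: str  # denovo | pat | mat | both
    gene_id: str | None = None


@dataclass(frozen=True)
class TruthFinding:
    """The designated causal mechanism for one trio."""

    trio_id: str
    mechanism: str
    gene_id: str | None = None
    cnv: PlantedCnv | None = None
    variants: tuple[PlantedVariant, ...] = ()

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "ar_comphet_cnv_snv":
            if self.cnv is None or len(self.variants) != 1:
                raise ValueError("CNV+SNV compound het needs one CNV and one variant")
            origins = {self.cnv.parental_origin, self.variants[0].origin}
            if origins != {"pat", "mat"}:
                raise ValueError("compound het pair must have opposite parental origins")
        if self.mechanism == "ar_comphet_snv":
            origins = {v.origin for v in self.variants}
            if len(self.variants) != 2 or origins != {"pat", "mat"}:
                raise ValueError("compound het pair must have opposite parental origins")

    @property
    def is_double_diagnosis(self) -> bool:
        return self.cnv is not None and len(self.variants) > 0


@dataclass
class TruthSet:
    """Everything the simulators planted, serializable and lossless."""

    planted_cnvs: list[PlantedCnv] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    causal_findings: list[TruthFinding] = field(default_factory=list)

    def cnvs_for(self, sample_id: str, channel: str | None = None) -> list[PlantedCnv]:
        return [
            c
            for c in self.planted_cnvs
            if c.sample_id == sample_id and (channel is None or c.channel == channel)
        ]

    def to_dict(self) -> dict:
        return {
            "planted_cnvs": [asdict(c) for c in self.planted_cnvs],
            "planted_variants": [asdict(v) for v in self.planted_variants],
            "causal_findings": [
                {
                    "trio_id": f.trio_id,
                    "mechanism": f.mechanism,
                    "gene_id": f.gene_id,
                    "cnv": asdict(f.cnv) if f.cnv else None,
                    "variants": [asdict(v) for v in f.variants],
                }
                for f in self.causal_findings
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TruthSet":
        return cls(
            planted_cnvs=[PlantedCnv(**c) for c in data["planted_cnvs"]],
            planted_variants=[PlantedVariant(**v) for v in data["planted_variants"]],
            causal_findings=[
                TruthFinding(
                    trio_id=f["trio_id"],
                    mechanism=f["mechanism"],
                    gene_id=f["gene_id"],
                    cnv=PlantedCnv(**f["cnv"]) if f["cnv"] else None,
                    variants=tuple(PlantedVariant(**v) for v in f["variants"]),
                )
                for f in data["causal_findings"]
            ],
        )


def build_genome_model(config: SimulationConfig, seed: int) -> GenomeModel:
    """Deterministically lay out genes, exons and ontology annotations.

    Genes are placed in equal-width slots along each chromosome with a
    seed-jittered offset; exons are evenly spaced within the gene body.
    Autosomal genes draw AD/AR inheritance at random; X genes are XL.
    Each gene is annotated with leaf terms (every leaf covered round-robin)
    plus a few random extra terms.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    for chrom, _ in config.chromosomes:
        for i in range(config.genes_per_chromosome):
            gene_ids.append(f"GENE_{chrom}_{i + 1:02d}")
    ontology = build_toy_ontology(
        levels=config.ontology_levels,
        branching=config.ontology_branching,
        gene_ids=gene_ids,
    )
    non_root = sorted(ontology.terms - {ontology.root})
    annotations = {g: set(t) for g, t in ontology.gene_annotations.items()}

    genes: list[Gene] = []
    exons: list[Exon] = []
    gene_len = config.exons_per_gene * config.exon_spacing
    for chrom, length in config.chromosomes:
        slot = length // config.genes_per_chromosome
        if gene_len >= slot:
            raise ValueError(
                f"gene body ({gene_len} bp) does not fit the per-gene slot "
                f"({slot} bp) on chromosome {chrom}"
            )
        for i in range(config.genes_per_chromosome):
            gene_id = f"GENE_{chrom}_{i + 1:02d}"
            offset = int(rng.integers(0, slot - gene_len))
            start = i * slot + offset
            mode = "XL" if chrom == "X" else ("AD" if rng.random() < 0.5 else "AR")
            for k in range(config.extra_terms_per_gene):
                annotations[gene_id].add(non_root[int(rng.integers(len(non_root)))])
            genes.append(
                Gene(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=start + gene_len,
                    inheritance_mode=mode,
                    hpo_terms=tuple(sorted(annotations[gene_id])),
                )
            )
            for k in range(config.exons_per_gene):
                ex_start = start + k * config.exon_spacing
                exons.append(Exon(chrom, ex_start, ex_start + config.exon_length, gene_id))

    ontology = ToyOntology(
        root=ontology.root,
        parents=ontology.parents,
        gene_annotations={g: frozenset(t) for g, t in annotations.items()},
    )
    return GenomeModel(
        chromosomes=tuple(config.chromosomes),
        bin_size=config.bin_size,
        exons=tuple(exons),
        genes=tuple(genes),
        ontology=ontology,
    )
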