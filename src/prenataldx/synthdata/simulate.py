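"""Simulators for low-pass bin counts, exon depths and trio genotype cohorts.

The generators emulate the data a simultaneous shallow-WGS + trio-exome
pipeline consumes:

* **Low-pass counts** — ~5M reads per sample dropped into 20 kb bins as a
  Poisson draw with multiplicative log-normal bin bias (shared within a
  batch, standing in for mappability/GC structure) and a per-sample scale
  factor; planted CNVs rescale the mean by copies/2.
* **Exon depths** — rank-1 sample x exon expectation (library size x capture
  efficiency) times planted-CNV dosage, configurable low-rank latent factors
  (PCA-removable batch structure) and log-normal noise. Planted events span
  whole exons with genomic sizes of a few to tens of kb.
* **Trio cohorts** — parental genotypes in Hardy–Weinberg proportions,
  Mendelian transmission to the fetus, background de novo injection, and
  designated causal mechanisms per trio: autosomal-dominant de novo (CNV or
  SNV), X-linked maternal in a male fetus, recessive homozygous, and
  SNV+SNV or CNV+SNV compound heterozygotes in trans. Fetal phenotype
  profiles are the causal gene's ontology terms with per-term dropout plus
  decoy terms.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..wes_filter import MemberCall, VariantRecord
from ..trio import Trio
from .genome import (
    GenomeModel,
    PlantedCnv,
    PlantedVariant,
    TruthFinding,
    TruthSet,
)

__all__ = [
    "LowpassNoise",
    "ExonNoise",
    "CohortRates",
    "simulate_lowpass_counts",
    "simulate_exon_depths",
    "simulate_trio_cohort",
    "TrioCohort",
]


# ---------------------------------------------------------------- low-pass


@dataclass(frozen=True)
class LowpassNoise:
    bias_sigma: float = 0.1  # log-normal sd of per-bin bias (shared in batch)
    batch_sigma: float = 0.05  # log-normal sd of per-sample scale


def _snap_cnv(cnv: PlantedCnv, bin_size: int) -> PlantedCnv:
    start = (cnv.start // bin_size) * bin_size
    end = math.ceil(cnv.end / bin_size) * bin_size
    if (start, end) == (cnv.start, cnv.end):
        return cnv
    return PlantedCnv(
        sample_id=cnv.sample_id,
        chrom=cnv.chrom,
        start=start,
        end=end,
        copies=cnv.copies,
        parental_origin=cnv.parental_origin,
        gene_id=cnv.gene_id,
        channel=cnv.channel,
    )


def simulate_lowpass_counts(
    model: GenomeModel,
    truth: TruthSet,
    sample_ids: Sequence[str],
    depth: float = 5_000_000,
    seed: int = 0,
    noise: LowpassNoise = LowpassNoise(),
) -> tuple[pd.DataFrame, TruthSet]:
    """Poisson bin counts for one batch of samples.

    Mean for sample i, bin j: depth x (width_j / genome_size) x bias_j x
    batch_i x copies_ij / 2. Returns a (chrom, start, end, samples...) table
    plus a truth set whose low-pass CNV coordinates are snapped to bin
    boundaries.
    """
    lengths = model.chrom_lengths
    for cnv in truth.planted_cnvs:
        if cnv.channel != "lowpass":
            continue
        if cnv.chrom not in lengths:
            raise ValueError(f"planted CNV on unknown chromosome {cnv.chrom}")
        if cnv.start < 0 or cnv.end > lengths[cnv.chrom]:
            raise ValueError(
                f"planted CNV {cnv.chrom}:{cnv.start}-{cnv.end} outside chromosome bounds"
            )
    rng = np.random.default_rng(seed)
    bins = model.bin_table()
    widths = np.array([e - s for _, s, e in bins], dtype=float)
    genome = float(model.genome_size)
    bias = np.exp(rng.normal(0.0, noise.bias_sigma, size=len(bins))) if noise.bias_sigma > 0 else np.ones(len(bins))
    frame = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    bin_lookup: dict[str, np.ndarray] = {}
    for chrom in lengths:
        bin_lookup[chrom] = np.where(frame["chrom"].to_numpy() == chrom)[0]

    snapped: list[PlantedCnv] = []
    copies_by_sample: dict[str, np.ndarray] = {
        s: np.full(len(bins), 2.0) for s in sample_ids
    }
    for cnv in truth.planted_cnvs:
        if cnv.channel != "lowpass":
            snapped.append(cnv)
            continue
        s_cnv = _snap_cnv(cnv, model.bin_size)
        snapped.append(s_cnv)
        if s_cnv.sample_id in copies_by_sample:
            idx = bin_lookup[s_cnv.chrom]
            starts = frame["start"].to_numpy()[idx]
            inside = (starts >= s_cnv.start) & (starts < s_cnv.end)
            copies_by_sample[s_cnv.sample_id][idx[inside]] = float(s_cnv.copies)

    batch = (
        np.exp(rng.normal(0.0, noise.batch_sigma, size=len(sample_ids)))
        if noise.batch_sigma > 0
        else np.ones(len(sample_ids))
    )
    for i, sample in enumerate(sample_ids):
        lam = depth * (widths / genome) * bias * batch[i] * (copies_by_sample[sample] / 2.0)
        frame[sample] = rng.poisson(lam)
    new_truth = TruthSet(
        planted_cnvs=snapped,
        planted_variants=list(truth.planted_variants),
        causal_findings=list(truth.causal_findings),
    )
    return frame, new_truth


# -------------------------------------------------------------- exon depth


@dataclass(frozen=True)
class ExonNoise:
    noise_sigma: float = 0.1  # log-normal depth noise
    n_latent: int = 2  # PCA-removable structured factors
    latent_sigma: float = 0.08
    base_depth: float = 100.0  # mean exon depth
    base_sigma: float = 0.2  # spread of per-sample library size
    exon_sigma: float = 0.3  # spread of per-exon capture efficiency


def simulate_exon_depths(
    model: GenomeModel,
    truth: TruthSet,
    sample_ids: Sequence[str],
    seed: int = 0,
    noise: ExonNoise = ExonNoise(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x exons depth matrix with planted exonic CNVs.

    depth_ij = base_i x eff_j x (copies_ij / 2) x exp(latent_ij) x noise_ij.
    Returns (depths indexed by sample id, exon table chrom/start/end/gene_id).
    """
    if len(sample_ids) < 10:
        raise ValueError("exon-depth normalization needs a cohort of >= 10 samples")
    rng = np.random.default_rng(seed)
    exons = pd.DataFrame(
        [(e.chrom, e.start, e.end, e.gene_id) for e in model.exons],
        columns=["chrom", "start", "end", "gene_id"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    n_s, n_e = len(sample_ids), len(exons)
    base = (
        noise.base_depth * np.exp(rng.normal(0.0, noise.base_sigma, n_s))
        if noise.base_sigma > 0
        else np.full(n_s, noise.base_depth)
    )
    eff = (
        np.exp(rng.normal(0.0, noise.exon_sigma, n_e))
        if noise.exon_sigma > 0
        else np.ones(n_e)
    )
    copies = np.full((n_s, n_e), 2.0)
    starts = exons["start"].to_numpy()
    chroms = exons["chrom"].to_numpy()
    index = {s: i for i, s in enumerate(sample_ids)}
    for cnv in truth.planted_cnvs:
        if cnv.channel != "exonic" or cnv.sample_id not in index:
            continue
        inside = (chroms == cnv.chrom) & (starts >= cnv.start) & (starts < cnv.end)
        copies[index[cnv.sample_id], inside] = float(cnv.copies)
    expectation = base[:, None] * eff[None, :] * (copies / 2.0)
    if noise.n_latent > 0 and noise.latent_sigma > 0:
        u = rng.normal(0.0, 1.0, (n_s, noise.n_latent))
        v = rng.normal(0.0, noise.latent_sigma, (noise.n_latent, n_e))
        expectation = expectation * np.exp(u @ v)
    if noise.noise_sigma > 0:
        expectation = expectation * np.exp(
            rng.normal(0.0, noise.noise_sigma, (n_s, n_e))
        )
    depths = pd.DataFrame(expectation, index=list(sample_ids))
    return depths, exons


# ------------------------------------------------------------ trio cohort


@dataclass(frozen=True)
class CohortRates:
    """Mechanism mix and background rates for the simulated cohort.

    Defaults follow the diagnostic spectrum of a 959-trio prenatal cohort:
    roughly 20% of trios carry an autosomal-dominant de novo finding (split
    ~52:48 between CNVs and sequence variants), ~1% are X-linked maternal,
    ~0.8% recessive homozygous and ~0.2% each SNV+SNV and CNV+SNV compound
    heterozygotes.
    """

    denovo_rate: float = 0.0005  # background per-site fetal de novo probability
    causal_fraction: float = 213 / 959
    ad_fraction: float = 191 / 213  # of causal trios: AD de novo
    ad_cnv_fraction: float = 99 / 191  # of AD de novo: CNV rather than SNV
    xl_fraction: float = 10 / 213
    ar_hom_fraction: float = 8 / 213
    ar_comphet_snv_fraction: float = 2 / 213
    ar_comphet_cnv_snv_fraction: float = 2 / 213
    male_fraction: float = 0.58
    phenotype_dropout: float = 0.2
    n_decoy_terms: int = 2
    background_af_range: tuple[float, float] = (0.05, 0.3)
    background_sites_per_gene: int = 2

    def validate(self) -> None:
        fracs = [
            self.denovo_rate,
            self.causal_fraction,
            self.ad_fraction,
            self.ad_cnv_fraction,
            self.xl_fraction,
            self.ar_hom_fraction,
            self.ar_comphet_snv_fraction,
            self.ar_comphet_cnv_snv_fraction,
            self.male_fraction,
            self.phenotype_dropout,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all rates must lie in [0, 1]")
        total = (
            self.ad_fraction
            + self.xl_fraction
            + self.ar_hom_fraction
            + self.ar_comphet_snv_fraction
            + self.ar_comphet_cnv_snv_fraction
        )
        if total > 1.0 + 1e-9:
            raise ValueError("causal mechanism fractions sum above 1")


@dataclass
class TrioCohort:
    """Everything one simulated cohort produced, keyed by trio."""

    trios: list[Trio]
    records: dict[str, list[VariantRecord]]  # trio_id -> records
    phenotypes: dict[str, frozenset[str]]  # trio_id -> profile terms
    truth: TruthSet


def _hwe_genotype(rng: np.random.Generator, af: float) -> str:
    alleles = rng.random(2) < af
    return f"{int(alleles[0])}/{int(alleles[1])}" if alleles[0] <= alleles[1] else "0/1"


def _transmit(rng: np.random.Generator, genotype: str) -> str:
    alleles = genotype.split("/")
    return alleles[int(rng.integers(2))]


def _clean_call(genotype: str) -> MemberCall:
    return MemberCall(genotype=genotype, gq=99, dp=50, lowq_frac=0.01)


def _noisy_call(rng: np.random.Generator, genotype: str) -> MemberCall:
    gq = int(np.clip(rng.normal(60, 20), 0, 99))
    dp = int(max(rng.poisson(40), 0))
    lowq = round(float(np.clip(rng.beta(1, 30), 0.0, 1.0)), 4)
    return MemberCall(genotype=genotype, gq=gq, dp=dp, lowq_frac=lowq)


def _site_pos(model: GenomeModel, gene_id: str, slot: int) -> tuple[str, int]:
    exons = model.gene_exons(gene_id)
    ex = exons[slot % len(exons)]
    return ex.chrom, ex.start + 10 + (slot // len(exons))  # 0-based


def _mechanism_for(rng: np.random.Generator, rates: CohortRates) -> str:
    if rng.random() >= rates.causal_fraction:
        return "none"
    u = rng.random()
    edges = np.cumsum(
        [
            rates.ad_fraction,
            rates.xl_fraction,
            rates.ar_hom_fraction,
            rates.ar_comphet_snv_fraction,
            rates.ar_comphet_cnv_snv_fraction,
        ]
    )
    names = ["ad", "xl_maternal", "ar_homozygous", "ar_comphet_snv", "ar_comphet_cnv_snv"]
    for name, edge in zip(names, edges):
        if u < edge:
            if name == "ad":
                return (
                    "ad_denovo_cnv"
                    if rng.random() < rates.ad_cnv_fraction
                    else "ad_denovo_snv"
                )
            return name
    return "none"


def simulate_trio_cohort(
    model: GenomeModel,
    n_trios: int,
    rates: CohortRates = CohortRates(),
    seed: int = 0,
) -> TrioCohort:
    """Simulate genotype records, causal mechanisms and phenotypes for trios.

    Background sites follow Hardy–Weinberg parental genotypes with Mendelian
    transmission and optional background de novo injection; causal sites
    realize the designated mechanism with clean quality fields (causal
    findings, by construction, survive quality screening). Phenotype
    profiles derive from the causal gene's terms with dropout plus decoys;
    non-causal trios get random decoy-only profiles.
    """
    rates.validate()
    rng = np.random.default_rng(seed)
    autosomal = [g for g in model.genes if g.chrom != "X"]
    ad_genes = [g for g in autosomal if g.inheritance_mode == "AD"] or autosomal
    ar_genes = [g for g in autosomal if g.inheritance_mode == "AR"] or autosomal
    xl_genes = [g for g in model.genes if g.chrom == "X"]
    non_root_terms = sorted(model.ontology.terms - {model.ontology.root})

    # the background site panel (positions, frequencies, consequences) is a
    # population property drawn once and shared by every trio
    panel: list[tuple[str, str, int, float, str]] = []
    for gene in model.genes:
        for s in range(rates.background_sites_per_gene):
            af = round(float(rng.uniform(*rates.background_af_range)), 4)
            chrom, pos0 = _site_pos(model, gene.gene_id, s)
            csq = str(rng.choice(["synonymous", "intronic", "missense"]))
            panel.append((gene.gene_id, chrom, pos0 + 1, af, csq))

    cohort = TrioCohort(trios=[], records={}, phenotypes={}, truth=TruthSet())
    for t in range(n_trios):
        trio_id = f"TRIO{t + 1:04d}"
        trio = Trio(
            trio_id=trio_id,
            father_id=f"{trio_id}-F",
            mother_id=f"{trio_id}-M",
            fetus_id=f"{trio_id}-C",
            fetal_sex="male" if rng.random() < rates.male_fraction else "female",
        )
        mechanism = _mechanism_for(rng, rates)
        if mechanism == "xl_maternal" and not xl_genes:
            mechanism = "ad_denovo_snv"
        if mechanism == "xl_maternal":
            trio = Trio(
                trio_id=trio.trio_id,
                father_id=trio.father_id,
                mother_id=trio.mother_id,
                fetus_id=trio.fetus_id,
                fetal_sex="male",
            )
        records: list[VariantRecord] = []

        # background polymorphic sites
        for gene_id, chrom, pos1, af, csq in panel:
            on_x = chrom == "X"
            father_gt = _hwe_genotype(rng, af)
            mother_gt = _hwe_genotype(rng, af)
            if on_x:
                father_gt = str(int(rng.random() < af))  # hemizygous father
            if on_x and trio.fetal_sex == "male":
                fetus_gt = _transmit(rng, mother_gt)
            else:
                pat = father_gt if on_x else _transmit(rng, father_gt)
                mat = _transmit(rng, mother_gt)
                a, b = sorted([pat, mat])
                fetus_gt = f"{a}/{b}"
            if rates.denovo_rate > 0 and rng.random() < rates.denovo_rate:
                if fetus_gt == "0/0":
                    fetus_gt = "0/1"
                elif fetus_gt == "0":
                    fetus_gt = "1"
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos1,
                    ref="A",
                    alt="G",
                    gene_id=gene_id,
                    consequence=csq,
                    population_af=af,
                    father=_noisy_call(rng, father_gt),
                    mother=_noisy_call(rng, mother_gt),
                    fetus=_noisy_call(rng, fetus_gt),
                )
            )

        # causal mechanism
        causal_gene = None
        finding_cnv: PlantedCnv | None = None
        finding_vars: list[PlantedVariant] = []
        if mechanism == "ad_denovo_snv":
            causal_gene = ad_genes[int(rng.integers(len(ad_genes)))]
            chrom, pos0 = _site_pos(model, causal_gene.gene_id, 5)
            gt = "0/1"
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    gene_id=causal_gene.gene_id,
                    consequence="truncating",
                    population_af=1e-4,
                    father=_clean_call("0/0"),
                    mother=_clean_call("0/0"),
                    fetus=_clean_call(gt),
                )
            )
            finding_vars.append(
                PlantedVariant(
                    sample_id=trio.fetus_id,
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    genotype=gt,
                    origin="denovo",
                    gene_id=causal_gene.gene_id,
                )
            )
        elif mechanism == "ad_denovo_cnv":
            causal_gene = ad_genes[int(rng.integers(len(ad_genes)))]
            # a large genome-wide event (1–3 Mb) covering the causal gene
            lengths = model.chrom_lengths
            span = int(rng.integers(50, 150)) * model.bin_size
            chrom = causal_gene.chrom
            center = (causal_gene.start + causal_gene.end) // 2
            start = max(0, min(center - span // 2, lengths[chrom] - span))
            copies = 1 if rng.random() < 0.5 else 3
            finding_cnv = PlantedCnv(
                sample_id=trio.fetus_id,
                chrom=chrom,
                start=start,
                end=start + span,
                copies=copies,
                parental_origin="denovo",
                gene_id=causal_gene.gene_id,
                channel="lowpass",
            )
            cohort.truth.planted_cnvs.append(finding_cnv)
        elif mechanism == "xl_maternal":
            causal_gene = xl_genes[int(rng.integers(len(xl_genes)))]
            chrom, pos0 = _site_pos(model, causal_gene.gene_id, 5)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    gene_id=causal_gene.gene_id,
                    consequence="missense",
                    population_af=1e-4,
                    father=_clean_call("0"),
                    mother=_clean_call("0/1"),
                    fetus=_clean_call("1"),
                )
            )
            finding_vars.append(
                PlantedVariant(
                    sample_id=trio.fetus_id,
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    genotype="1",
                    origin="mat",
                    gene_id=causal_gene.gene_id,
                )
            )
        elif mechanism == "ar_homozygous":
            causal_gene = ar_genes[int(rng.integers(len(ar_genes)))]
            chrom, pos0 = _site_pos(model, causal_gene.gene_id, 6)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    gene_id=causal_gene.gene_id,
                    consequence="missense",
                    population_af=5e-3,
                    father=_clean_call("0/1"),
                    mother=_clean_call("0/1"),
                    fetus=_clean_call("1/1"),
                )
            )
            finding_vars.append(
                PlantedVariant(
                    sample_id=trio.fetus_id,
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    genotype="1/1",
                    origin="both",
                    gene_id=causal_gene.gene_id,
                )
            )
        elif mechanism == "ar_comphet_snv":
            causal_gene = ar_genes[int(rng.integers(len(ar_genes)))]
            for slot, (origin, f_gt, m_gt) in enumerate(
                [("pat", "0/1", "0/0"), ("mat", "0/0", "0/1")]
            ):
                chrom, pos0 = _site_pos(model, causal_gene.gene_id, 5 + slot)
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos0 + 1,
                        ref="C",
                        alt="T",
                        gene_id=causal_gene.gene_id,
                        consequence="missense" if slot else "truncating",
                        population_af=5e-3,
                        father=_clean_call(f_gt),
                        mother=_clean_call(m_gt),
                        fetus=_clean_call("0/1"),
                    )
                )
                finding_vars.append(
                    PlantedVariant(
                        sample_id=trio.fetus_id,
                        chrom=chrom,
                        pos=pos0 + 1,
                        ref="C",
                        alt="T",
                        genotype="0/1",
                        origin=origin,
                        gene_id=causal_gene.gene_id,
                    )
                )
        elif mechanism == "ar_comphet_cnv_snv":
            causal_gene = ar_genes[int(rng.integers(len(ar_genes)))]
            exons = model.gene_exons(causal_gene.gene_id)
            n_ex = int(rng.integers(3, min(6, len(exons)) + 1))
            first = int(rng.integers(0, len(exons) - n_ex + 1))
            cnv_origin = "pat" if rng.random() < 0.5 else "mat"
            snv_origin = "mat" if cnv_origin == "pat" else "pat"
            carrier_parent = trio.father_id if cnv_origin == "pat" else trio.mother_id
            cnv_start, cnv_end = exons[first].start, exons[first + n_ex - 1].end
            finding_cnv = PlantedCnv(
                sample_id=trio.fetus_id,
                chrom=causal_gene.chrom,
                start=cnv_start,
                end=cnv_end,
                copies=1,
                parental_origin=cnv_origin,
                gene_id=causal_gene.gene_id,
                channel="exonic",
            )
            cohort.truth.planted_cnvs.append(finding_cnv)
            cohort.truth.planted_cnvs.append(
                PlantedCnv(
                    sample_id=carrier_parent,
                    chrom=causal_gene.chrom,
                    start=cnv_start,
                    end=cnv_end,
                    copies=1,
                    parental_origin=None,
                    gene_id=causal_gene.gene_id,
                    channel="exonic",
                )
            )
            chrom, pos0 = _site_pos(model, causal_gene.gene_id, 7)
            f_gt, m_gt = ("0/0", "0/1") if snv_origin == "mat" else ("0/1", "0/0")
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    gene_id=causal_gene.gene_id,
                    consequence="missense",
                    population_af=5e-3,
                    father=_clean_call(f_gt),
                    mother=_clean_call(m_gt),
                    fetus=_clean_call("0/1"),
                )
            )
            finding_vars.append(
                PlantedVariant(
                    sample_id=trio.fetus_id,
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref="C",
                    alt="T",
                    genotype="0/1",
                    origin=snv_origin,
                    gene_id=causal_gene.gene_id,
                )
            )

        cohort.truth.planted_variants.extend(finding_vars)
        cohort.truth.causal_findings.append(
            TruthFinding(
                trio_id=trio_id,
                mechanism=mechanism,
                gene_id=causal_gene.gene_id if causal_gene else None,
                cnv=finding_cnv,
                variants=tuple(finding_vars),
            )
        )

        # phenotype profile
        if causal_gene is not None:
            kept = {
                term
                for term in causal_gene.hpo_terms
                if rng.random() >= rates.phenotype_dropout
            }
            if not kept:
                kept = {causal_gene.hpo_terms[int(rng.integers(len(causal_gene.hpo_terms)))]}
        else:
            kept = set()
        n_decoys = rates.n_decoy_terms if causal_gene is not None else 3
        for _ in range(n_decoys):
            kept.add(non_root_terms[int(rng.integers(len(non_root_terms)))])

        records.sort(key=lambda r: (r.chrom, r.pos))
        cohort.trios.append(trio)
        cohort.records[trio_id] = records
        cohort.phenotypes[trio_id] = frozenset(kept)
    return cohort
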