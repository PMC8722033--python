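"""Phenotype-driven candidate prioritization and simplified report tiering.

Gene–phenotype matching uses an information-content score in the style of
Phrank: for each ontology term t let n(t) be the number of genes whose
annotation closure contains t, and n_pa(t) the number of genes whose closure
contains *all parents* of t (the whole annotated gene set for the root). The
marginal information of t is

    Φ(t) = −log2( n(t) / n_pa(t) )   [bits]

and a gene's score against a patient profile is the sum of Φ over the
intersection of the two ancestor closures. Rare, specific terms carry many
bits; the root carries none.

Candidates then pass allele-frequency and consequence filters and receive a
simplified tier (labelled "ACMG-lite" in outputs — it deliberately collapses
the full ACMG evidence framework to a small rule table). Only P/LP findings
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .synthdata.ontology import ToyOntology
from .trio import Candidate, InheritanceLabel

__all__ = [
    "PhenotypeProfile",
    "ScoredCandidate",
    "AfThresholds",
    "term_closure",
    "phrank_score",
    "score_candidates",
    "filter_and_rank",
    "assign_report_tier",
    "prioritize_trio",
]

#: consequence severity for ranking ties (higher = more severe)
CONSEQUENCE_SEVERITY = {
    "truncating": 3,
    "splice_region": 2,
    "missense": 1,
    "synonymous": 0,
    "intronic": 0,
    "other": 0,
}

LOF_CONSEQUENCES = {"truncating", "splice_region"}

RECESSIVE_LABELS = {
    InheritanceLabel.BIPARENTAL_HOMOZYGOUS,
    InheritanceLabel.COMPOUND_HETEROZYGOUS,
    InheritanceLabel.X_LINKED_MATERNAL,
}


@dataclass(frozen=True)
class PhenotypeProfile:
    trio_id: str
    terms: frozenset[str]

    def validated(self, ontology: ToyOntology) -> "PhenotypeProfile":
        unknown = self.terms - ontology.terms
        if unknown:
            raise ValueError(f"profile {self.trio_id} has unknown terms {sorted(unknown)}")
        return self


@dataclass
class ScoredCandidate:
    candidate: Candidate
    phrank_score: float = 0.0
    passed_af: bool = True
    passed_consequence: bool = True
    inheritance_consistent: bool = True
    tier: str = "not_reported"  # P | LP | VUS | not_reported

    @property
    def all_filters_passed(self) -> bool:
        return self.passed_af and self.passed_consequence and self.inheritance_consistent


@dataclass(frozen=True)
class AfThresholds:
    max_af_dominant: float = 0.001
    max_af_recessive: float = 0.01


def term_closure(terms: Iterable[str], ontology: ToyOntology) -> frozenset[str]:
    """Union of the terms with all their ancestors up to the root; idempotent."""
    return ontology.closure(terms)


def _gene_term_counts(ontology: ToyOntology) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for gene in ontology.gene_annotations:
        for t in ontology.gene_closure(gene):
            counts[t] += 1
    return counts, len(ontology.gene_annotations)


def term_information(ontology: ToyOntology) -> dict[str, float]:
    """Marginal information Φ(t) = −log2(n(t)/n_pa(t)) for every term."""
    counts, n_genes = _gene_term_counts(ontology)
    if n_genes == 0:
        raise ValueError("ontology has no annotated genes")
    info: dict[str, float] = {}
    for t in ontology.terms:
        parents = ontology.parents[t]
        if not parents:
            n_pa = n_genes
        else:
            n_pa = sum(
                1
                for g in ontology.gene_annotations
                if parents <= ontology.gene_closure(g)
            )
        n_t = counts[t]
        info[t] = -math.log2(n_t / n_pa) if n_t > 0 and n_pa > 0 else 0.0
    return info


def phrank_score(
    profile: PhenotypeProfile,
    gene_id: str,
    ontology: ToyOntology,
    information: Mapping[str, float] | None = None,
) -> float:
    """Sum of Φ over the shared ancestor closure of profile and gene."""
    profile.validated(ontology)
    gene_terms = ontology.gene_closure(gene_id)  # raises on unannotated gene
    if information is None:
        information = term_information(ontology)
    shared = term_closure(profile.terms, ontology) & gene_terms
    return float(sum(information[t] for t in shared))


def score_candidates(
    candidates: Sequence[Candidate],
    profile: PhenotypeProfile,
    ontology: ToyOntology,
) -> list[ScoredCandidate]:
    """Score each candidate by its best gene match to the profile."""
    information = term_information(ontology)
    scored = []
    for c in candidates:
        score = max(
            (
                phrank_score(profile, g, ontology, information)
                for g in c.gene_ids
                if g in ontology.gene_annotations
            ),
            default=0.0,
        )
        scored.append(ScoredCandidate(candidate=c, phrank_score=score))
    return scored


def _af_limit(candidate: Candidate, thresholds: AfThresholds) -> float:
    if candidate.inheritance in RECESSIVE_LABELS:
        return thresholds.max_af_recessive
    return thresholds.max_af_dominant


def filter_and_rank(
    scored: Sequence[ScoredCandidate],
    thresholds: AfThresholds = AfThresholds(),
) -> list[ScoredCandidate]:
    """Apply AF filters and order by (score desc, severity desc, position asc).

    CNV candidates carry no population AF and always pass the AF filter.
    The genomic-position tie-break makes the order a deterministic total
    order. Filter-failing candidates are kept (flagged) at the tail.
    """
    for s in scored:
        c = s.candidate
        if c.kind == "variant" and c.payload.population_af is not None:
            s.passed_af = c.payload.population_af <= _af_limit(c, thresholds)

    def sort_key(s: ScoredCandidate):
        c = s.candidate
        severity = (
            CONSEQUENCE_SEVERITY.get(c.payload.consequence, 0)
            if c.kind == "variant"
            else 2  # a called multi-bin/multi-exon CNV is treated as disruptive
        )
        return (
            not s.all_filters_passed,
            -s.phrank_score,
            -severity,
            c.position_key,
        )

    return sorted(scored, key=sort_key)


def _is_lof(candidate: Candidate) -> bool:
    if candidate.kind == "cnv":
        return True  # whole-exon/multi-bin dosage change
    return candidate.payload.consequence in LOF_CONSEQUENCES


def _overlaps_known_region(
    candidate: Candidate, regions: Sequence[tuple[str, int, int]]
) -> bool:
    if candidate.kind != "cnv":
        return False
    call = candidate.payload
    return any(
        chrom == call.chrom and start < call.end and call.start < end
        for chrom, start, end in regions
    )


def assign_report_tier(
    scored: ScoredCandidate,
    phenotype_match: bool,
    known_mms_regions: Sequence[tuple[str, int, int]] = (),
) -> str:
    """Simplified "ACMG-lite" tier table; only P/LP are reportable.

    P: de novo loss-of-function with phenotype match, or a CNV hitting a
    configured known-microdeletion/duplication-syndrome region.
    LP: any two of {de novo, LoF, phenotype match}, or a recessive genotype
    (compound het, biparental homozygous, X-linked hemizygous) in a
    phenotype-matched gene.
    """
    if not scored.all_filters_passed:
        return "not_reported"
    c = scored.candidate
    is_de_novo = c.inheritance == InheritanceLabel.DE_NOVO
    is_lof = _is_lof(c)
    if (is_de_novo and is_lof and phenotype_match) or _overlaps_known_region(
        c, known_mms_regions
    ):
        return "P"
    recessive_matched = (
        c.inheritance
        in (
            InheritanceLabel.COMPOUND_HETEROZYGOUS,
            InheritanceLabel.BIPARENTAL_HOMOZYGOUS,
            InheritanceLabel.X_LINKED_MATERNAL,
        )
        and phenotype_match
    )
    if sum((is_de_novo, is_lof, phenotype_match)) >= 2 or recessive_matched:
        return "LP"
    return "VUS"


def prioritize_trio(
    candidates: Sequence[Candidate],
    profile: PhenotypeProfile,
    ontology: ToyOntology,
    thresholds: AfThresholds = AfThresholds(),
    known_mms_regions: Sequence[tuple[str, int, int]] = (),
    secondary_findings_genes: frozenset[str] = frozenset(),
    top_k: int = 3,
) -> list[ScoredCandidate]:
    """Score, filter, rank and tier one trio's candidates.

    ``phenotype_match`` for tiering means a positive score within the top
    ``top_k`` ranks. Candidates in the configured secondary-findings gene
    list are withheld from the report (tier forced to ``not_reported``)
    regardless of evidence, mirroring an opt-in incidental-findings policy.
    """
    ranked = filter_and_rank(score_candidates(candidates, profile, ontology), thresholds)
    for rank, s in enumerate(ranked):
        match = s.phrank_score > 0 and rank < top_k
        s.tier = assign_report_tier(s, match, known_mms_regions)
        if set(s.candidate.gene_ids) & secondary_findings_genes:
            s.tier = "not_reported"
        s.candidate.tier = s.tier
    return ranked
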