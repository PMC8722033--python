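"""Trio-level integration: inheritance classification and compound-het phasing.

Fetal variants and CNVs (genome-wide low-pass calls and exonic calls, for all
three family members) are merged into unified candidates. Each candidate gets
exactly one inheritance label:

* ``de_novo`` — fetus carries, neither parent does;
* ``x_linked_maternal`` — male fetus hemizygous on X, mother heterozygous,
  father non-carrier;
* ``biparental_homozygous`` — fetus homozygous alternate, both parents het;
* ``paternal`` / ``maternal`` — exactly one parent carries;
* ``compound_heterozygous`` — assigned by pairing, below;
* ``unclassified`` — anything unresolvable.

Compound heterozygosity is detected gene by gene: two heterozygous-carrier
candidates (sequence variants or gene-overlapping CNVs) with opposite
parental origins are in trans with certain phase; a de novo allele paired
with a single inherited one is in trans only *possibly*, since trio
genotypes alone cannot phase a de novo event. A fetus whose reported
findings include both a CNV and a sequence variant is a double diagnosis.

CNV parental presence uses 50% reciprocal-overlap matching of same-state
calls between fetus and parent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, Union

from typing import TYPE_CHECKING

from .cnv_exonic import ExonicCnvCall
from .cnv_lowpass import CnvCall
from .wes_filter import VariantRecord

if TYPE_CHECKING:  # gene intervals are duck-typed to avoid a synthdata cycle
    from .synthdata.genome import Gene

logger = logging.getLogger(__name__)

__all__ = [
    "Trio",
    "InheritanceLabel",
    "Candidate",
    "Diagnosis",
    "integrate_trio_candidates",
    "classify_inheritance",
    "detect_compound_het",
    "summarize_diagnosis",
    "reciprocal_overlap",
]

AnyCnv = Union[CnvCall, ExonicCnvCall]


class InheritanceLabel(str, Enum):
    DE_NOVO = "de_novo"
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    BIPARENTAL_HOMOZYGOUS = "biparental_homozygous"
    X_LINKED_MATERNAL = "x_linked_maternal"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Trio:
    trio_id: str
    father_id: str
    mother_id: str
    fetus_id: str
    fetal_sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        ids = {self.father_id, self.mother_id, self.fetus_id}
        if len(ids) != 3:
            raise ValueError("trio requires three distinct sample ids")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError(f"invalid fetal sex {self.fetal_sex!r}")

    @property
    def member_ids(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.fetus_id)


@dataclass
class Candidate:
    """One fetal variant or CNV with trio context."""

    trio_id: str
    kind: str  # "variant" | "cnv"
    payload: Union[VariantRecord, AnyCnv]
    gene_ids: tuple[str, ...]
    presence: dict  # member -> bool (CNV) or genotype string (variant)
    inheritance: InheritanceLabel = InheritanceLabel.UNCLASSIFIED
    phase_confidence: str | None = None  # set on compound-het members
    tier: str | None = None  # filled by the prioritizer

    @property
    def chrom(self) -> str:
        return self.payload.chrom

    @property
    def start(self) -> int:
        if self.kind == "variant":
            return self.payload.pos
        return self.payload.start

    @property
    def position_key(self) -> tuple[str, int]:
        return (self.chrom, self.start)

    @property
    def is_fetal_het(self) -> bool:
        """Carries exactly one affected allele copy (SNV het or single-dose CNV)."""
        if self.kind == "variant":
            return self.payload.fetus.is_het or self.payload.fetus.is_hemi_alt
        return True  # a called CNV contributes one structural allele to a gene


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def _cnv_state(call: AnyCnv) -> str:
    state = call.state
    return {"DEL": "loss", "DUP": "gain"}.get(state, state)


def _cnv_present_in(call: AnyCnv, others: Sequence[AnyCnv], min_overlap: float = 0.5) -> bool:
    return any(
        other.chrom == call.chrom
        and _cnv_state(other) == _cnv_state(call)
        and reciprocal_overlap(call.start, call.end, other.start, other.end) >= min_overlap
        for other in others
    )


def _genes_touched(call: AnyCnv, genes: Sequence["Gene"]) -> tuple[str, ...]:
    if isinstance(call, ExonicCnvCall):
        return call.gene_ids
    return tuple(
        g.gene_id
        for g in genes
        if g.chrom == call.chrom and g.start < call.end and call.start < g.end
    )


def integrate_trio_candidates(
    variants: Sequence[VariantRecord],
    cnvs: Mapping[str, Sequence[AnyCnv]],
    trio: Trio,
    genes: Sequence["Gene"] = (),
    min_overlap: float = 0.5,
) -> list[Candidate]:
    """Merge fetal variants and CNVs into candidates with parental presence.

    ``cnvs`` maps each member's sample id to its call list; only fetal events
    become candidates, parents contribute presence. Output is sorted by
    (chrom, start).
    """
    unknown = set(cnvs) - set(trio.member_ids)
    if unknown:
        raise ValueError(f"CNV sample ids {sorted(unknown)} are not members of trio {trio.trio_id}")
    candidates: list[Candidate] = []
    for rec in variants:
        if not rec.fetus.carries_alt:
            continue
        candidates.append(
            Candidate(
                trio_id=trio.trio_id,
                kind="variant",
                payload=rec,
                gene_ids=(rec.gene_id,) if rec.gene_id else (),
                presence={
                    "father": rec.father.genotype,
                    "mother": rec.mother.genotype,
                    "fetus": rec.fetus.genotype,
                },
            )
        )
    father_cnvs = list(cnvs.get(trio.father_id, ()))
    mother_cnvs = list(cnvs.get(trio.mother_id, ()))
    for call in cnvs.get(trio.fetus_id, ()):
        candidates.append(
            Candidate(
                trio_id=trio.trio_id,
                kind="cnv",
                payload=call,
                gene_ids=_genes_touched(call, genes),
                presence={
                    "father": _cnv_present_in(call, father_cnvs, min_overlap),
                    "mother": _cnv_present_in(call, mother_cnvs, min_overlap),
                    "fetus": True,
                },
            )
        )
    candidates.sort(key=lambda c: c.position_key)
    return candidates


def _is_x(chrom: str) -> bool:
    return chrom.removeprefix("chr") == "X"


def classify_inheritance(candidate: Candidate, trio: Trio) -> InheritanceLabel:
    """Apply the ordered inheritance rules to one candidate."""
    if candidate.kind == "variant":
        rec: VariantRecord = candidate.payload
        father_carries = rec.father.carries_alt
        mother_carries = rec.mother.carries_alt
        if not father_carries and not mother_carries:
            return InheritanceLabel.DE_NOVO
        if (
            _is_x(rec.chrom)
            and trio.fetal_sex == "male"
            and (rec.fetus.is_hemi_alt or rec.fetus.is_hom_alt)
            and rec.mother.is_het
            and not father_carries
        ):
            return InheritanceLabel.X_LINKED_MATERNAL
        if rec.fetus.is_hom_alt and rec.father.is_het and rec.mother.is_het:
            return InheritanceLabel.BIPARENTAL_HOMOZYGOUS
        if father_carries != mother_carries:
            return InheritanceLabel.PATERNAL if father_carries else InheritanceLabel.MATERNAL
        return InheritanceLabel.UNCLASSIFIED
    father = bool(candidate.presence.get("father"))
    mother = bool(candidate.presence.get("mother"))
    if not father and not mother:
        return InheritanceLabel.DE_NOVO
    if father != mother:
        return InheritanceLabel.PATERNAL if father else InheritanceLabel.MATERNAL
    return InheritanceLabel.UNCLASSIFIED


def classify_all(candidates: Iterable[Candidate], trio: Trio) -> None:
    for c in candidates:
        c.inheritance = classify_inheritance(c, trio)


_PARENTAL = {InheritanceLabel.PATERNAL, InheritanceLabel.MATERNAL}


def _comphet_eligible(candidate: Candidate, max_af: float) -> bool:
    """Only rare, potentially damaging alleles form compound-het pairs.

    Common polymorphisms and silent changes carried in trans are ubiquitous
    and diagnostically meaningless; without this rarity gate every gene with
    two inherited SNPs would pair.
    """
    if not candidate.is_fetal_het:
        return False
    if candidate.kind == "cnv":
        return True
    rec: VariantRecord = candidate.payload
    if rec.consequence in ("synonymous", "intronic"):
        return False
    return rec.population_af is None or rec.population_af <= max_af


def detect_compound_het(
    candidates: Sequence[Candidate],
    trio: Trio,
    max_af: float = 0.01,
) -> list[tuple[Candidate, Candidate]]:
    """Pair trans-configured heterozygous candidates within each gene.

    Opposite parental origins give certain phase; de novo paired with one
    inherited allele gives possible phase. Same-origin pairs are rejected as
    cis, and only rare non-silent alleles (``population_af <= max_af``) are
    eligible. Pair members get the compound-heterozygous label; each pair is
    reported once, ordered by genomic position.
    """
    by_gene: dict[str, list[Candidate]] = {}
    for c in candidates:
        if not _comphet_eligible(c, max_af):
            continue
        for g in c.gene_ids:
            by_gene.setdefault(g, []).append(c)
    pairs: list[tuple[Candidate, Candidate]] = []
    seen: set[tuple[int, int]] = set()
    for gene, members in sorted(by_gene.items()):
        members = sorted(members, key=lambda c: c.position_key)
        for a, b in itertools.combinations(members, 2):
            labels = {a.inheritance, b.inheritance}
            if labels == _PARENTAL:
                confidence = "certain"
            elif InheritanceLabel.DE_NOVO in labels and labels & _PARENTAL:
                confidence = "possible"
            else:
                continue
            key = (min(id(a), id(b)), max(id(a), id(b)))
            if key in seen:
                continue
            seen.add(key)
            a.inheritance = b.inheritance = InheritanceLabel.COMPOUND_HETEROZYGOUS
            a.phase_confidence = a.phase_confidence or confidence
            b.phase_confidence = b.phase_confidence or confidence
            pairs.append((a, b))
    pairs.sort(key=lambda p: p[0].position_key)
    return pairs


@dataclass
class Diagnosis:
    trio_id: str
    findings: list[Candidate] = field(default_factory=list)
    double_diagnosis: bool = False
    comphet_pairs: list[tuple[Candidate, Candidate]] = field(default_factory=list)

    @property
    def diagnosed(self) -> bool:
        return bool(self.findings)


def summarize_diagnosis(
    reported: Sequence[Candidate],
    trio: Trio,
    comphet_pairs: Sequence[tuple[Candidate, Candidate]] = (),
) -> Diagnosis:
    """Fold reported (P/LP) candidates into a per-trio diagnosis.

    A double diagnosis means at least one reported CNV *and* one reported
    sequence variant; only pairs whose two members are both reported are kept.
    """
    findings = list(reported)
    kinds = {c.kind for c in findings}
    kept_pairs = [
        (a, b) for a, b in comphet_pairs if a in findings and b in findings
    ]
    return Diagnosis(
        trio_id=trio.trio_id,
        findings=findings,
        double_diagnosis=("cnv" in kinds and "variant" in kinds),
        comphet_pairs=kept_pairs,
    )


def mendelian_error_rate(variants: Sequence[VariantRecord], trio: Trio) -> float:
    """Fraction of complete-genotype autosomal sites violating transmission.

    Used as a contamination / sample-swap warning (logged above 5%), not as
    a filter.
    """
    checked = errors = 0
    for rec in variants:
        if _is_x(rec.chrom):
            continue
        calls = (rec.father, rec.mother, rec.fetus)
        if any(c.is_missing or "/" not in c.genotype for c in calls):
            continue
        checked += 1
        f, m, k = (set(c.genotype.split("/")) for c in calls)
        possible = {frozenset({a, b}) for a in f for b in m}
        if frozenset(k) not in {frozenset(p) for p in possible}:
            errors += 1
    if checked == 0:
        return 0.0
    rate = errors / checked
    if rate > 0.05:
        logger.warning(
            "trio %s: Mendelian error rate %.1f%% exceeds 5%% — possible "
            "contamination or sample swap",
            trio.trio_id,
            100 * rate,
        )
    return rate
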