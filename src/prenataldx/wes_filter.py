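"""Variant-level quality screening for trio exome records.

Each variant site carries per-member (father / mother / fetus) genotype and
quality fields. A member's record passes the screen iff

* genotype quality ``GQ >= min_gq`` (default 15),
* variant read depth ``DP >= min_dp`` (default 3), and
* the fraction of low-quality bases at the site is *below*
  ``max_lowq_frac`` (default 0.4) — a site dominated by low-quality bases
  is excluded, and the 0.4 boundary itself fails.

Missing quality fields fail closed: a diagnostic screen should never pass a
record it cannot evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "MemberCall",
    "VariantRecord",
    "QualityThresholds",
    "FilterFailure",
    "filter_variant_records",
]

MEMBERS = ("father", "mother", "fetus")

CONSEQUENCES = (
    "missense",
    "truncating",
    "splice_region",
    "synonymous",
    "intronic",
    "other",
)

_VALID_GENOTYPES = {"0/0", "0/1", "1/1", "0", "1", "./.", "."}


@dataclass(frozen=True)
class MemberCall:
    """Genotype and site-quality fields for one trio member at one site."""

    genotype: str = "./."
    gq: int | None = None
    dp: int | None = None
    lowq_frac: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in _VALID_GENOTYPES:
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if self.lowq_frac is not None and not 0.0 <= self.lowq_frac <= 1.0:
            raise ValueError(f"lowq_frac {self.lowq_frac} outside [0, 1]")

    @property
    def is_missing(self) -> bool:
        return self.genotype in (".", "./.")

    @property
    def n_alt(self) -> int:
        """Count of alternate alleles (hemizygous '1' counts one)."""
        if self.is_missing:
            return 0
        return sum(a == "1" for a in self.genotype.split("/"))

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_het(self) -> bool:
        return self.genotype == "0/1"

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype == "1/1"

    @property
    def is_hemi_alt(self) -> bool:
        return self.genotype == "1"


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-member calls for a single trio.

    Coordinates are 1-based (VCF convention); ``population_af`` is the
    population allele frequency, ``None`` when unobserved.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None = None
    consequence: str = "other"
    population_af: float | None = None
    father: MemberCall = field(default_factory=MemberCall)
    mother: MemberCall = field(default_factory=MemberCall)
    fetus: MemberCall = field(default_factory=MemberCall)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af {self.population_af} outside [0, 1]")

    def member(self, name: str) -> MemberCall:
        if name not in MEMBERS:
            raise ValueError(f"unknown trio member {name!r}; expected one of {MEMBERS}")
        return getattr(self, name)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_member(self, name: str, call: MemberCall) -> "VariantRecord":
        if name not in MEMBERS:
            raise ValueError(f"unknown trio member {name!r}")
        return replace(self, **{name: call})


@dataclass(frozen=True)
class QualityThresholds:
    """Screen thresholds; defaults are the pipeline's stated criteria."""

    min_gq: int = 15
    min_dp: int = 3
    max_lowq_frac: float = 0.4


@dataclass(frozen=True)
class FilterFailure:
    record: VariantRecord
    reasons: tuple[str, ...]


def _failure_reasons(call: MemberCall, thresholds: QualityThresholds) -> tuple[str, ...]:
    reasons: list[str] = []
    if call.gq is None or call.dp is None or call.lowq_frac is None:
        reasons.append("missing_field")
    if call.gq is not None and call.gq < thresholds.min_gq:
        reasons.append(f"GQ<{thresholds.min_gq}")
    if call.dp is not None and call.dp < thresholds.min_dp:
        reasons.append(f"DP<{thresholds.min_dp}")
    # >= is an exclusion: the boundary itself fails.
    if call.lowq_frac is not None and call.lowq_frac >= thresholds.max_lowq_frac:
        reasons.append(f"lowq_frac>={thresholds.max_lowq_frac}")
    return tuple(reasons)


def filter_variant_records(
    records: Iterable[VariantRecord],
    member: str = "fetus",
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[list[VariantRecord], list[FilterFailure]]:
    """Partition ``records`` into (pass, fail) on one member's quality fields.

    Every input record lands in exactly one of the two outputs; each failure
    lists all violated criteria. Input order is preserved.
    """
    if member not in MEMBERS:
        raise ValueError(f"unknown trio member {member!r}; expected one of {MEMBERS}")
    passed: list[VariantRecord] = []
    failed: list[FilterFailure] = []
    for record in records:
        reasons = _failure_reasons(record.member(member), thresholds)
        if reasons:
            failed.append(FilterFailure(record, reasons))
        else:
            passed.append(record)
    return passed, failed
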