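"""Cohort-level diagnostic statistics.

Works on a per-phenotypic-class count table (cases, double-diagnosis,
CNV-only and variant-only fetuses, each fetus counted once) and on finalized
per-trio diagnoses: diagnostic yields, exact two-tailed Fisher tests on 2x2
tables, the de novo fraction among single diagnoses, and recurrence tables
keyed by cytoband interval or gene symbol.

Percentages are half-up rounded to 2 decimal places and p-values to 4, the
display precision used throughout the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .trio import Diagnosis, InheritanceLabel

__all__ = [
    "CohortTable",
    "TwoByTwo",
    "diagnostic_yield",
    "fisher_exact_two_tailed",
    "cohort_summary",
    "load_cohort_table",
    "bundled_cohort_table",
    "round_half_up",
]

COUNT_COLUMNS = ("cases", "double", "cnv_only", "variant_only")


def round_half_up(value: float, places: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching printed tables."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortTable:
    """Per-phenotypic-class diagnosis counts; one row per class plus a total."""

    frame: pd.DataFrame  # index: class name; columns: COUNT_COLUMNS

    def __post_init__(self) -> None:
        missing = set(COUNT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if (self.frame[list(COUNT_COLUMNS)] < 0).any().any():
            raise ValueError("cohort table counts must be non-negative")
        diagnosed = self.frame[["double", "cnv_only", "variant_only"]].sum(axis=1)
        if (diagnosed > self.frame["cases"]).any():
            raise ValueError("diagnosed counts exceed cases in some row")

    def row(self, name: str) -> pd.Series:
        return self.frame.loc[name]

    def diagnosed(self, name: str) -> int:
        r = self.row(name)
        return int(r["double"] + r["cnv_only"] + r["variant_only"])

    def yields(self) -> dict[str, float]:
        return {str(name): diagnostic_yield(self.frame.loc[name]) for name in self.frame.index}


def diagnostic_yield(row: Mapping[str, int]) -> float:
    """100 x diagnosed / cases, half-up rounded to 2 dp."""
    cases = int(row["cases"])
    if cases == 0:
        raise ValueError("diagnostic yield undefined for zero cases")
    diagnosed = int(row["double"]) + int(row["cnv_only"]) + int(row["variant_only"])
    return round_half_up(100.0 * diagnosed / cases, 2)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table must have a positive margin")


def fisher_exact_two_tailed(table: TwoByTwo, rel_tol: float = 1e-7) -> float:
    """Exact two-sided Fisher p: sum of all same-margin tables whose point
    probability does not exceed the observed one (relative tie tolerance
    ``rel_tol``).

    With row margin r1 = a+b, column margin c1 = a+c and total n, cell ``a``
    follows Hypergeometric(n, r1, c1) under independence.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    observed = hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= observed * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def cohort_summary(
    diagnoses: Sequence[Diagnosis],
    cohort_size: int,
    recurrence_keys: Mapping[str, str] | None = None,
) -> dict:
    """De novo fraction, double-diagnosis count and recurrence table.

    The de novo fraction is computed over diagnosed trios whose single
    diagnosis is de novo, as a percent of all diagnosed trios (2 dp; ``None``
    when nothing is diagnosed). ``recurrence_keys`` maps a finding to its
    recurrence label (cytoband interval or gene symbol); by default the
    finding's first gene id (CNVs fall back to their interval).
    """
    diagnosed = [d for d in diagnoses if d.diagnosed]
    n_diag = len(diagnosed)
    double_count = sum(d.double_diagnosis for d in diagnosed)
    de_novo = 0
    for d in diagnosed:
        if d.double_diagnosis:
            continue
        labels = {c.inheritance for c in d.findings}
        if labels == {InheritanceLabel.DE_NOVO}:
            de_novo += 1
    fraction = round_half_up(100.0 * de_novo / n_diag, 2) if n_diag else None

    counts: dict[str, set[str]] = {}
    for d in diagnosed:
        for c in d.findings:
            if recurrence_keys is not None:
                key = recurrence_keys.get(d.trio_id + "/" + c.chrom, "")
            else:
                key = ""
            if not key:
                if c.gene_ids:
                    key = c.gene_ids[0]
                else:
                    key = f"{c.chrom}:{c.start}"
            counts.setdefault(key, set()).add(d.trio_id)
    recurrence = {
        key: (len(trios), round_half_up(100.0 * len(trios) / cohort_size, 2))
        for key, trios in sorted(counts.items())
        if cohort_size > 0
    }
    return {
        "n_diagnosed": n_diag,
        "de_novo_fraction": fraction,
        "double_count": int(double_count),
        "recurrence": recurrence,
    }


def recurrence_percent(carriers: int, cohort_size: int) -> float:
    """Percent of the cohort carrying one recurrent alteration (2 dp)."""
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    return round_half_up(100.0 * carriers / cohort_size, 2)


def de_novo_fraction(n_de_novo: int, n_diagnosed: int) -> float:
    """Percent of diagnosed trios whose finding is de novo (2 dp)."""
    if n_diagnosed <= 0:
        raise ValueError("no diagnosed trios")
    return round_half_up(100.0 * n_de_novo / n_diagnosed, 2)


def load_cohort_table(path) -> CohortTable:
    """Read a class/cases/double/cnv_only/variant_only TSV."""
    frame = pd.read_csv(path, sep="\t").set_index("class")
    return CohortTable(frame=frame)


def bundled_cohort_table() -> CohortTable:
    """The anatomical-system diagnosis count table shipped with the package."""
    ref = resources.files("prenataldx") / "fixtures" / "cohort_classes.tsv"
    with resources.as_file(ref) as path:
        return load_cohort_table(path)
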