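"""A miniature phenotype ontology: a rooted DAG of terms with gene annotations.

Shaped like the Human Phenotype Ontology at toy scale — terms point at parent
terms, every term reaches a single root, and genes are annotated with term
sets. The information-content gene scoring in :mod:`prenataldx.prioritizer`
operates on this structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

__all__ = ["ToyOntology", "build_toy_ontology"]


@dataclass(frozen=True)
class ToyOntology:
    """Rooted DAG of phenotype terms plus gene → term annotations.

    ``parents`` maps each non-root term to its parent term set; the root has
    an empty entry. ``gene_annotations`` holds each gene's *direct* terms;
    ancestor closures are computed on demand and cached.
    """

    root: str
    parents: Mapping[str, frozenset[str]]
    gene_annotations: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_ancestor_cache", {})
        self._validate()

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def _validate(self) -> None:
        if self.root not in self.parents:
            raise ValueError("root term missing from parent map")
        if self.parents[self.root]:
            raise ValueError("root term must have no parents")
        for term, pars in self.parents.items():
            for p in pars:
                if p not in self.parents:
                    raise ValueError(f"term {term!r} has unknown parent {p!r}")
        # acyclicity + root reachability: every term's ancestor walk must
        # terminate at the root without revisiting itself
        for term in self.parents:
            if self.root not in self.ancestors_or_self(term):
                raise ValueError(f"term {term!r} does not reach the root")
        for gene, terms in self.gene_annotations.items():
            unknown = terms - self.terms
            if unknown:
                raise ValueError(f"gene {gene!r} annotated with unknown terms {sorted(unknown)}")

    def ancestors_or_self(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` (transitively) plus the term itself."""
        cache: dict[str, frozenset[str]] = self._ancestor_cache  # type: ignore[attr-defined]
        if term in cache:
            return cache[term]
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            if len(seen) > len(self.parents):
                raise ValueError("cycle detected in ontology")
            stack.extend(self.parents[t])
        result = frozenset(seen)
        cache[term] = result
        return result

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        """Union of ``terms`` with all their ancestors; idempotent."""
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors_or_self(t)
        return frozenset(out)

    def gene_closure(self, gene_id: str) -> frozenset[str]:
        if gene_id not in self.gene_annotations:
            raise KeyError(f"gene {gene_id!r} has no ontology annotations")
        return self.closure(self.gene_annotations[gene_id])

    def leaves(self) -> list[str]:
        """Terms that are nobody's parent, in sorted order."""
        has_child: set[str] = set()
        for pars in self.parents.values():
            has_child |= pars
        return sorted(self.terms - has_child)

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "parents": {t: sorted(p) for t, p in sorted(self.parents.items())},
            "gene_annotations": {
                g: sorted(t) for g, t in sorted(self.gene_annotations.items())
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ToyOntology":
        return cls(
            root=data["root"],
            parents={t: frozenset(p) for t, p in data["parents"].items()},
            gene_annotations={
                g: frozenset(t) for g, t in data["gene_annotations"].items()
            },
        )


def build_toy_ontology(
    levels: int = 3,
    branching: int = 3,
    gene_ids: Iterable[str] = (),
    prefix: str = "TP",
) -> ToyOntology:
    """Build a complete ``branching``-ary term tree.

    ``levels`` counts levels including the root, so 3 levels with branching 3
    yield 1 + 3 + 9 = 13 terms. Gene annotations, when ``gene_ids`` are given,
    cover every leaf (round-robin) so each term is reachable from at least one
    annotated gene through its descendants.
    """
    if levels < 1 or branching < 1:
        raise ValueError("levels and branching must be >= 1")
    root = f"{prefix}:0000001"
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    level = [root]
    counter = 1
    for _ in range(levels - 1):
        nxt: list[str] = []
        for parent in level:
            for _ in range(branching):
                counter += 1
                term = f"{prefix}:{counter:07d}"
                parents[term] = frozenset({parent})
                nxt.append(term)
        level = nxt
    leaves = level
    genes = list(gene_ids)
    annotations: dict[str, frozenset[str]] = {}
    if genes:
        per_gene: dict[str, set[str]] = {g: set() for g in genes}
        # round-robin both ways so every leaf is annotated and every gene
        # carries at least one term
        n = max(len(genes), len(leaves))
        for i in range(n):
            per_gene[genes[i % len(genes)]].add(leaves[i % len(leaves)])
        annotations = {g: frozenset(t) for g, t in per_gene.items()}
    return ToyOntology(root=root, parents=parents, gene_annotations=annotations)
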