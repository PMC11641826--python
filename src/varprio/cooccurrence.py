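"""Gene-level co-occurrence aggregation of case-exclusive variants.

Models additive impairment of a gene: several distinct case-exclusive
variants on the same gene are pooled by summing their case
alternate-allele counts.  Genes carrying >= 2 variants with a summed
count >= 10 form the multi-variant route into the genes-of-interest
(GOI) set; significant single variants form the other route.  The two
routes must be disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .case_exclusive import CaseExclusiveVariant

__all__ = [
    "GeneAggregate",
    "GeneOfInterestSet",
    "aggregate_by_gene",
    "multi_variant_genes",
    "genes_of_interest",
]


@dataclass(frozen=True)
class GeneAggregate:
    """Per-gene summary of its case-exclusive variants (one Table-4-style row)."""

    gene: str
    n_variants: int
    allele_counts: tuple[int, ...]  # per-variant C_A
    terms: tuple[str, ...]  # per-variant most-severe term

    def __post_init__(self) -> None:
        if not (self.n_variants == len(self.allele_counts) == len(self.terms)):
            raise ValueError(f"inconsistent aggregate for {self.gene}")

    @property
    def allele_sum(self) -> int:
        return sum(self.allele_counts)


def aggregate_by_gene(
    variants: Sequence[CaseExclusiveVariant],
) -> list[GeneAggregate]:
    """One aggregate per gene, sorted by allele_sum descending then name.

    A variant annotated to several genes contributes to each; within a
    gene each variant site counts once (no double counting).
    """
    per_gene: dict[str, dict[tuple, CaseExclusiveVariant]] = {}
    for v in variants:
        per_gene.setdefault(v.gene, {})[v.variant.key] = v
    aggregates = []
    for gene, by_site in per_gene.items():
        rows = sorted(by_site.values(), key=lambda v: (-v.c_a, v.variant.key))
        aggregates.append(
            GeneAggregate(
                gene=gene,
                n_variants=len(rows),
                allele_counts=tuple(v.c_a for v in rows),
                terms=tuple(v.most_severe_term for v in rows),
            )
        )
    aggregates.sort(key=lambda g: (-g.allele_sum, g.gene))
    return aggregates


def multi_variant_genes(
    aggregates: Iterable[GeneAggregate],
    min_variants: int = 2,
    min_allele_sum: int = 10,
) -> list[GeneAggregate]:
    """Genes with >= min_variants variants and allele_sum >= min_allele_sum.

    The default sum threshold is 10; a stricter preset of 14 (for genes
    with three or more variants) can be requested explicitly.
    """
    return [
        g
        for g in aggregates
        if g.n_variants >= min_variants and g.allele_sum >= min_allele_sum
    ]


@dataclass(frozen=True)
class GeneOfInterestSet:
    single_variant_genes: tuple[str, ...]
    multi_variant_genes: tuple[str, ...]

    @property
    def union(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.single_variant_genes) | set(self.multi_variant_genes)))


def genes_of_interest(
    single_route: Iterable[str],
    multi_route: Iterable[GeneAggregate | str],
) -> GeneOfInterestSet:
    """Union of the two GOI routes; overlap between routes is an error."""
    single = tuple(dict.fromkeys(single_route))
    multi = tuple(
        dict.fromkeys(g.gene if isinstance(g, GeneAggregate) else g for g in multi_route)
    )
    overlap = sorted(set(single) & set(multi))
    if overlap:
        raise ValueError(
            f"genes present in both GOI routes (must be disjoint): {overlap}"
        )
    return GeneOfInterestSet(single, multi)
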