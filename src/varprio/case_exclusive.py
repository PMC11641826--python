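"""Case-exclusive variant filtering and prioritization.

A variant is *case-exclusive* when every non-missing control call is
homozygous reference and at least one case carries the alternate
allele.  Such variants are the pipeline's headline signal: rare alleles
present only in affected individuals.  Missing control genotypes are
not treated as evidence of carriage — exclusivity is judged on the
observed calls, with the number of missing controls logged per variant.

Prioritization joins the filter output with consequence annotations and
association results, keeps variants significant at a raw-p threshold,
and sorts by (severity rank, p) — severity first, as the headline
ranking is consequence-driven.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .association import AssociationResult
from .cohort_io import MISSING, GenotypeTable, PhenotypeMap, VariantSite
from .consequence import ConsequenceAnnotation, load_severity_table, most_severe

__all__ = [
    "CaseExclusiveVariant",
    "CaseExclusiveCall",
    "case_exclusive_variants",
    "prioritize",
    "top_per_variant",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseExclusiveCall:
    """Filter output: one variant with its case alt-allele count."""

    variant: VariantSite
    c_a: int  # alternate-allele count among cases
    n_missing_controls: int


@dataclass(frozen=True)
class CaseExclusiveVariant:
    """Prioritized case-exclusive variant on one annotated gene."""

    variant: VariantSite
    gene: str
    c_a: int
    most_severe_term: str
    severity_rank: int
    chi2: float
    p: float

    def __post_init__(self) -> None:
        if self.c_a < 1:
            raise ValueError(f"case-exclusive variant with C_A={self.c_a}")


def case_exclusive_variants(
    gt: GenotypeTable, ph: PhenotypeMap
) -> list[CaseExclusiveCall]:
    """Variants where all non-missing controls are hom-ref and >= 1 case carries alt."""
    case_mask, control_mask = ph.mask(gt)
    out: list[CaseExclusiveCall] = []
    for j, variant in enumerate(gt.variants):
        col = gt.dosages(j)
        controls = col[control_mask]
        cases = col[case_mask]
        controls_ok = controls != MISSING
        if (controls[controls_ok] != 0).any():
            continue
        cases_ok = cases != MISSING
        c_a = int(cases[cases_ok].sum())
        if c_a < 1:
            continue
        n_missing = int((~controls_ok).sum())
        if n_missing:
            logger.info(
                "%s: %d missing control genotypes at exclusivity decision",
                variant.id,
                n_missing,
            )
        out.append(CaseExclusiveCall(variant, c_a, n_missing))
    return out


def prioritize(
    calls: Sequence[CaseExclusiveCall],
    annotations: Mapping[str, Sequence[ConsequenceAnnotation]],
    results: Sequence[AssociationResult],
    alpha: float = 0.05,
) -> list[CaseExclusiveVariant]:
    """Join with annotations and association, filter at raw p < alpha.

    ``annotations`` maps variant identifier -> annotations; a variant
    annotated on several genes yields one row per gene (so downstream
    gene aggregation credits each gene).  Variants lacking any
    annotation are retained with an ``unknown`` term at the
    least-severe rank, and logged.  Output is sorted by
    (severity rank, p, variant key).
    """
    table = load_severity_table()
    by_key = {r.variant.key: r for r in results}
    out: list[CaseExclusiveVariant] = []
    for call in calls:
        res = by_key.get(call.variant.key)
        if res is None or math.isnan(res.p) or res.p >= alpha:
            continue
        anns = annotations.get(call.variant.id, ())
        if not anns:
            logger.warning("variant %s has no annotation", call.variant.id)
            out.append(
                CaseExclusiveVariant(
                    call.variant,
                    gene="-",
                    c_a=call.c_a,
                    most_severe_term="unknown",
                    severity_rank=table.unknown_rank,
                    chi2=res.chi2,
                    p=res.p,
                )
            )
            continue
        for ann in anns:
            term = most_severe([ann])
            out.append(
                CaseExclusiveVariant(
                    call.variant,
                    gene=ann.gene,
                    c_a=call.c_a,
                    most_severe_term=term,
                    severity_rank=table.rank(term),
                    chi2=res.chi2,
                    p=res.p,
                )
            )
    out.sort(key=lambda v: (v.severity_rank, v.p, v.variant.key, v.gene))
    return out


def top_per_variant(
    variants: Sequence[CaseExclusiveVariant],
) -> list[CaseExclusiveVariant]:
    """One row per variant site: its most severe gene annotation.

    Used for Table-3-style listings where each variant appears once;
    the full per-gene rows remain available for aggregation.
    """
    best: dict[tuple, CaseExclusiveVariant] = {}
    for v in variants:
        prev = best.get(v.variant.key)
        if prev is None or (v.severity_rank, v.gene) < (prev.severity_rank, prev.gene):
            best[v.variant.key] = v
    out = list(best.values())
    out.sort(key=lambda v: (v.severity_rank, v.p, v.variant.key))
    return out
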