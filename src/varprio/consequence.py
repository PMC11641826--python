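"""Variant consequence annotations and severity ranking.

Consumes VEP-style tab-delimited annotation tables (one row per
variant/gene pair, comma-separated sequence-ontology terms) and ranks
terms by a packaged severity table mirroring the canonical VEP ordering
(rank 1 = most severe).  The ten top-ranked structural/truncating terms
form the "most severe" block used for prioritization:
transcript_ablation, splice_acceptor_variant, splice_donor_variant,
stop_gained, frameshift_variant, stop_lost, start_lost,
transcript_amplification, feature_elongation, feature_truncation.

Unknown terms are retained and flagged, sorting after every known term,
so unrecognized ontology releases degrade gracefully instead of
breaking the pipeline.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ConsequenceAnnotation",
    "SeverityTable",
    "load_severity_table",
    "normalize_term",
    "read_vep_table",
    "most_severe",
    "is_coding",
    "MOST_SEVERE_BLOCK",
    "CODING_TERMS",
]

logger = logging.getLogger(__name__)

MOST_SEVERE_BLOCK: frozenset[str] = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "transcript_amplification",
        "feature_elongation",
        "feature_truncation",
    }
)

#: Terms with a direct coding consequence on the protein product.
CODING_TERMS: frozenset[str] = MOST_SEVERE_BLOCK | {
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "synonymous_variant",
    "protein_altering_variant",
}


def normalize_term(term: str) -> str:
    """Normalize a consequence term to lower_snake_case."""
    return term.strip().replace(" ", "_").lower()


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Annotation of one variant on one gene."""

    variant_id: str
    gene: str
    terms: tuple[str, ...]
    unknown_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(
                f"annotation for {self.variant_id}/{self.gene} has no terms"
            )


class SeverityTable:
    """Ordered consequence terms, rank 1 = most severe."""

    def __init__(self, ranks: dict[str, int]) -> None:
        if len(set(ranks.values())) != len(ranks):
            raise ValueError("severity ranks must be unique")
        self._ranks = dict(ranks)
        self.unknown_rank = max(ranks.values()) + 1

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._ranks

    def rank(self, term: str) -> int:
        """Severity rank; unknown terms share the least-severe rank."""
        return self._ranks.get(normalize_term(term), self.unknown_rank)

    @property
    def terms(self) -> list[str]:
        return sorted(self._ranks, key=self._ranks.get)


@lru_cache(maxsize=1)
def load_severity_table() -> SeverityTable:
    resource = importlib.resources.files("varprio.data") / "consequence_severity.tsv"
    with importlib.resources.as_file(resource) as path:
        df = pd.read_csv(path, sep="\t")
    return SeverityTable(dict(zip(df["term"], df["rank"].astype(int))))


# Column aliases accepted in VEP-style tables.
_VARIANT_COLS = ("Uploaded_variation", "#Uploaded_variation")
_GENE_COLS = ("SYMBOL", "Gene")
_CONSEQUENCE_COLS = ("Consequence",)


def read_vep_table(path: str | Path) -> list[ConsequenceAnnotation]:
    """Read a VEP-style tab-delimited annotation table.

    Requires an uploaded-variant column, a gene column (``SYMBOL`` or
    ``Gene``), and a ``Consequence`` column whose cells may hold several
    comma-separated terms.  Rows are merged per (variant, gene) pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]

    def pick(candidates: tuple[str, ...]) -> str:
        for c in candidates:
            name = c.lstrip("#")
            if name in df.columns:
                return name
        raise ValueError(
            f"{path}: missing required column (one of {candidates})"
        )

    var_col = pick(_VARIANT_COLS)
    gene_col = pick(_GENE_COLS)
    cons_col = pick(_CONSEQUENCE_COLS)

    if df.empty:
        logger.warning("%s: empty annotation table", path)
        return []

    table = load_severity_table()
    merged: dict[tuple[str, str], list[str]] = {}
    for _, row in df.iterrows():
        key = (str(row[var_col]), str(row[gene_col]))
        terms = [normalize_term(t) for t in str(row[cons_col]).split(",") if t.strip()]
        merged.setdefault(key, []).extend(terms)

    annotations = []
    for (variant_id, gene), terms in merged.items():
        seen = list(dict.fromkeys(terms))  # dedupe, order-preserving
        unknown = tuple(t for t in seen if t not in table)
        if unknown:
            logger.warning(
                "unknown consequence terms %s for %s/%s", unknown, variant_id, gene
            )
        annotations.append(
            ConsequenceAnnotation(variant_id, gene, tuple(seen), unknown)
        )
    return annotations


def most_severe(annotations: Iterable[ConsequenceAnnotation] | Iterable[str]) -> str:
    """The most severe term over annotations (or raw terms) of one variant.

    Ties at equal rank break lexicographically, making the result
    deterministic and independent of input order.
    """
    items = list(annotations)
    if not items:
        raise ValueError("no annotations supplied")
    terms: list[str] = []
    for item in items:
        if isinstance(item, ConsequenceAnnotation):
            terms.extend(item.terms)
        else:
            terms.append(normalize_term(item))
    table = load_severity_table()
    return min(terms, key=lambda t: (table.rank(t), t))


def is_coding(term: str) -> bool:
    """True for terms with a direct coding consequence."""
    return normalize_term(term) in CODING_TERMS
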