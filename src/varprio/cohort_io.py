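"""Cohort ingestion: genotypes, phenotypes, gene regions, allele counts.

This module turns the raw inputs of a small diploid case-control cohort
into the in-memory containers every downstream stage consumes:

* a :class:`GenotypeTable` of per-sample alternate-allele dosages
  (``0``/``1``/``2`` or missing) over an ordered list of biallelic
  :class:`VariantSite` records,
* a :class:`PhenotypeMap` assigning each sample to ``case`` or ``control``,
* per-variant 2x2 :class:`AlleleCountTable` objects (case/control x
  alt/ref allele counts), the unit of every association statistic.

File formats
------------
* **VCF 4.x** (plain or bgzipped), read through :mod:`cyvcf2`.
  Multi-allelic records are split into one biallelic variant per
  alternate allele, with genotypes recoded against that allele.
  Any call containing a missing allele (``./.`` and half-calls such as
  ``./1``) is treated as missing.
* **Phenotype TSV** — two columns, ``sample_id<TAB>status`` with the
  PLINK-style convention ``1`` = control, ``2`` = case.
* **Gene-region TSV** — header ``gene chrom start end``; coordinates are
  1-based inclusive.  A curated panel of opioid-use-disorder candidate
  genes (OPRM1, OPRD1, DRD2, BDNF, APBB2, KCNG2, KCNC1, CNIH3, RGMA,
  DRD3, DRD4, NRXN3 with GRCh38 coordinates) ships with the package and
  is available through :func:`load_gene_panel`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "CohortError",
    "VariantSite",
    "GenotypeTable",
    "PhenotypeMap",
    "AlleleCountTable",
    "GeneRegion",
    "read_vcf",
    "read_phenotypes",
    "read_gene_regions",
    "load_gene_panel",
    "allele_counts",
    "allele_count_arrays",
    "extract_gene_loci",
]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

CASE = "case"
CONTROL = "control"


class CohortError(ValueError):
    """Raised for malformed cohort inputs (VCF, phenotype, region files)."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site.

    The identifier falls back to the ``"REF > ALT"`` convention when the
    source record carries no rsID, so every site has a printable label.
    Sites are keyed by ``(chrom, pos, ref, alt)``, not by the identifier,
    because identifiers are not guaranteed unique.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CohortError(
                f"ref and alt alleles are identical ({self.ref}) at "
                f"{self.chrom}:{self.pos}"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.ref} > {self.alt}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class GenotypeTable:
    """Samples x variants matrix of alternate-allele dosages.

    ``calls[i, j]`` is the dosage of sample ``i`` at variant ``j``:
    0, 1, 2, or :data:`MISSING`.  The model is diploid autosomal
    throughout.
    """

    def __init__(
        self,
        variants: Sequence[VariantSite],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(variants)):
            raise CohortError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"invalid dosage {calls[i, j]} for sample {samples[i]!r} "
                f"at variant index {j}"
            )
        if len(set(samples)) != len(samples):
            raise CohortError("duplicate sample identifiers in genotype table")
        self.variants: list[VariantSite] = list(variants)
        self.samples: list[str] = list(samples)
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self, variant_index: int) -> np.ndarray:
        """Dosage column for one variant (length ``n_samples``)."""
        return self.calls[:, variant_index]

    def subset_variants(self, indices: Iterable[int]) -> "GenotypeTable":
        idx = list(indices)
        return GenotypeTable(
            [self.variants[j] for j in idx], self.samples, self.calls[:, idx]
        )

    def variant_index(self, site: VariantSite) -> int:
        for j, v in enumerate(self.variants):
            if v.key == site.key:
                return j
        raise KeyError(site.key)


@dataclass
class PhenotypeMap:
    """Sample -> case/control assignment; both classes must be non-empty."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s, v in self.assignments.items() if v not in (CASE, CONTROL)}
        if bad:
            raise CohortError(f"invalid phenotype status for samples: {sorted(bad)}")
        if not self.cases or not self.controls:
            raise CohortError("both case and control classes must be non-empty")

    @property
    def cases(self) -> list[str]:
        return [s for s, v in self.assignments.items() if v == CASE]

    @property
    def controls(self) -> list[str]:
        return [s for s, v in self.assignments.items() if v == CONTROL]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def swapped(self) -> "PhenotypeMap":
        """Label-swapped copy (cases become controls and vice versa)."""
        flip = {CASE: CONTROL, CONTROL: CASE}
        return PhenotypeMap({s: flip[v] for s, v in self.assignments.items()})

    def mask(self, gt: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (case_mask, control_mask) aligned to ``gt.samples``."""
        missing = [s for s in gt.samples if s not in self.assignments]
        if missing:
            raise CohortError(f"samples without phenotype: {missing}")
        status = np.array([self.assignments[s] for s in gt.samples])
        return status == CASE, status == CONTROL


@dataclass(frozen=True)
class AlleleCountTable:
    """2x2 allele-count table: cases (a alt, b ref), controls (c alt, d ref)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortError(f"negative allele count in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CohortError(
                f"region start > end for {self.gene}: {self.start} > {self.end}"
            )


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF 4.x file into a :class:`GenotypeTable`.

    Multi-allelic records are split into one biallelic variant per
    alternate allele; the dosage against alternate ``k`` counts how many
    of the sample's two alleles equal ``k``.  Calls with any missing
    allele are recorded as :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise CohortError(f"VCF file not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports the offending line in its message
        raise CohortError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise CohortError(f"VCF {path} contains no samples")

    variants: list[VariantSite] = []
    columns: list[np.ndarray] = []
    try:
        for rec in vcf:
            genotypes = rec.genotypes  # [allele1, allele2, phased] per sample
            for k, alt in enumerate(rec.ALT, start=1):
                col = np.empty(len(samples), dtype=np.int8)
                for i, g in enumerate(genotypes):
                    alleles = g[:-1]
                    if len(alleles) != 2 or any(a < 0 for a in alleles):
                        col[i] = MISSING
                    else:
                        col[i] = sum(a == k for a in alleles)
                variants.append(
                    VariantSite(rec.CHROM, rec.POS, rec.REF, alt, rec.ID or "")
                )
                columns.append(col)
    except CohortError:
        raise
    except Exception as exc:
        raise CohortError(f"malformed VCF record in {path}: {exc}") from exc

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeTable(variants, samples, calls)


def read_phenotypes(path: str | Path) -> PhenotypeMap:
    """Read a two-column phenotype table (``1`` = control, ``2`` = case)."""
    path = Path(path)
    codes = {"1": CONTROL, "2": CASE}
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise CohortError(
                    f"{path}:{lineno}: expected 'sample_id status', got {line!r}"
                )
            sample, code = fields
            if sample in assignments:
                raise CohortError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            if code not in codes:
                raise CohortError(
                    f"{path}:{lineno}: sample {sample!r} has status code {code!r}; "
                    "expected 1 (control) or 2 (case)"
                )
            assignments[sample] = codes[code]
    if not assignments:
        raise CohortError(f"{path}: no samples")
    return PhenotypeMap(assignments)


def read_gene_regions(path: str | Path) -> list[GeneRegion]:
    """Read a ``gene chrom start end`` region table (1-based inclusive)."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        header = fh.readline().split()
        expected = ["gene", "chrom", "start", "end"]
        if [h.lower() for h in header] != expected:
            raise CohortError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise CohortError(f"{path}:{lineno}: expected 4 columns")
            gene, chrom, start, end = fields
            regions.append(GeneRegion(gene, chrom, int(start), int(end)))
    return regions


def load_gene_panel() -> list[GeneRegion]:
    """The packaged candidate-gene panel (GRCh38 coordinates)."""
    resource = importlib.resources.files("varprio.data") / "gene_panel.tsv"
    with importlib.resources.as_file(resource) as path:
        return read_gene_regions(path)


def allele_counts(
    gt: GenotypeTable, ph: PhenotypeMap, variant_index: int
) -> AlleleCountTable:
    """2x2 allele-count table for one variant.

    Missing genotypes contribute zero alleles: ``a + b`` equals twice the
    number of non-missing case calls, likewise for controls.
    """
    if not 0 <= variant_index < gt.n_variants:
        raise IndexError(
            f"variant index {variant_index} out of range [0, {gt.n_variants})"
        )
    case_mask, control_mask = ph.mask(gt)
    col = gt.dosages(variant_index)
    a, b = _group_counts(col[case_mask])
    c, d = _group_counts(col[control_mask])
    return AlleleCountTable(a, b, c, d)


def _group_counts(dosages: np.ndarray) -> tuple[int, int]:
    ok = dosages != MISSING
    alt = int(dosages[ok].sum())
    return alt, int(2 * ok.sum() - alt)


def allele_count_arrays(
    gt: GenotypeTable, ph: PhenotypeMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (a, b, c, d) arrays over all variants.

    Equivalent to calling :func:`allele_counts` per variant; used on
    large simulated cohorts where the per-variant loop would dominate.
    """
    case_mask, control_mask = ph.mask(gt)
    calls = gt.calls

    def group(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = calls[mask]
        ok = sub != MISSING
        alt = np.where(ok, sub, 0).sum(axis=0)
        return alt.astype(np.int64), (2 * ok.sum(axis=0) - alt).astype(np.int64)

    a, b = group(case_mask)
    c, d = group(control_mask)
    return a, b, c, d


def extract_gene_loci(
    gt: GenotypeTable, regions: Sequence[GeneRegion], flank: int = 5000
) -> GenotypeTable:
    """Restrict to variants inside any region extended by ``flank`` bp.

    A variant is retained when ``start - flank <= pos <= end + flank`` on
    the matching chromosome for at least one region; overlapping regions
    never duplicate a variant.  The result is independent of region
    order.
    """
    keep: list[int] = []
    for j, v in enumerate(gt.variants):
        for r in regions:
            if v.chrom == r.chrom and r.start - flank <= v.pos <= r.end + flank:
                keep.append(j)
                break
    return gt.subset_variants(keep)
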