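"""Allelic case-control association with QC, in the PLINK idiom.

The statistic is the basic allelic chi-square on the 2x2 table of
alternate/reference allele counts in cases versus controls,

    chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)],    N = a+b+c+d,

with one degree of freedom and **no** Yates continuity correction (the
uncorrected form is what reproduces published allelic-test values).
Alongside it:

* group allele frequencies ``F_A = a/(a+b)``, ``F_U = c/(c+d)`` for the
  alternate allele, *without* minor-allele flipping (keep-allele-order
  semantics);
* the allelic odds ratio ``OR = ad/bc``, reported as undefined ("NA")
  when ``bc = 0`` and as 0 when ``ad = 0`` with ``bc > 0``;
* the exact conditional Hardy-Weinberg test (two-sided, summing the
  probabilities of all heterozygote counts no more likely than the one
  observed, given the allele totals);
* per-variant QC: missing-call fraction, pooled minor-allele frequency,
  and the HWE exact p-value, with PLINK-style default thresholds
  (0.1 / 0.05 / 1e-7);
* Bonferroni and Benjamini-Hochberg multiple-testing adjustment.

Two frequency conventions coexist deliberately: QC uses the pooled
*minor*-allele frequency ``min(f, 1-f)``, while association output
reports unflipped alternate-allele frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.multitest import multipletests

from .cohort_io import (
    MISSING,
    AlleleCountTable,
    GenotypeTable,
    PhenotypeMap,
    VariantSite,
    allele_count_arrays,
)

__all__ = [
    "QCParams",
    "QCFailure",
    "AssociationResult",
    "allelic_chi_square",
    "allelic_chi_square_arrays",
    "allelic_odds_ratio",
    "allele_frequencies",
    "hwe_exact_test",
    "qc_filter",
    "adjust_pvalues",
    "run_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    """Per-variant QC thresholds (PLINK-style defaults)."""

    max_missing_per_variant: float = 0.1
    min_maf: float = 0.05
    hwe_p_threshold: float = 1e-7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "max_missing_per_variant",
            "min_maf",
            "hwe_p_threshold",
            "alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class QCFailure:
    variant: VariantSite
    rule: str  # "missingness" | "maf" | "hwe"
    value: float


@dataclass
class AssociationResult:
    """Per-variant association summary (one Table-2/3-style row)."""

    variant: VariantSite
    counts: AlleleCountTable
    f_a: float
    f_u: float
    chi2: float
    p: float
    odds_ratio: float | None  # None renders as "NA"
    p_adj_bh: float = math.nan
    p_adj_bonferroni: float = math.nan
    qc_pass: bool = True
    qc_reason: str = ""

    @property
    def p_adj(self) -> float:
        """Default adjusted p-value (Benjamini-Hochberg)."""
        return self.p_adj_bh


def allelic_chi_square(t: AlleleCountTable) -> tuple[float, float]:
    """Uncorrected 1-df allelic chi-square and its upper-tail p-value.

    Returns ``(nan, nan)`` when a table margin is zero (the statistic is
    undefined; callers flag the variant instead of crashing).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if n == 0 or denom == 0:
        return (math.nan, math.nan)
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(_chi2_dist.sf(chi2, df=1))


def allelic_chi_square_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`allelic_chi_square` over parallel count arrays."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    p = np.full_like(chi2, np.nan)
    ok = ~np.isnan(chi2)
    p[ok] = _chi2_dist.sf(chi2[ok], df=1)
    return chi2, p


def allelic_odds_ratio(t: AlleleCountTable) -> float | None:
    """Allelic odds ratio ``ad/bc``; ``None`` (NA) exactly when ``bc = 0``."""
    if t.b * t.c == 0:
        return None
    return (t.a * t.d) / (t.b * t.c)


def allele_frequencies(t: AlleleCountTable) -> tuple[float, float]:
    """Alternate-allele frequencies ``(F_A, F_U)``, unflipped.

    A zero denominator (all calls missing in a group) yields ``nan``.
    """
    f_a = t.a / (t.a + t.b) if (t.a + t.b) > 0 else math.nan
    f_u = t.c / (t.c + t.d) if (t.c + t.d) > 0 else math.nan
    return f_a, f_u


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele totals, the number of
    heterozygotes follows a known discrete distribution; the p-value is
    the total probability of all heterozygote counts whose probability
    does not exceed that of the observed count.  Computed with the
    standard stable recurrence, seeded at the distribution's mode.
    Degenerate (all-zero or monomorphic) input returns 1.
    """
    for name, v in (
        ("n_hom_ref", n_hom_ref),
        ("n_het", n_het),
        ("n_hom_alt", n_hom_alt),
    ):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0

    # Heterozygote counts share the parity of the rare-allele total.
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    h, hr, hc = mid, hom_r, hom_c
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h, hr, hc = h - 2, hr + 1, hc + 1
    h, hr, hc = mid, hom_r, hom_c
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hr * hc / ((h + 1) * (h + 2))
        h, hr, hc = h + 2, hr - 1, hc - 1
    probs /= probs.sum()
    observed = probs[n_het]
    p = probs[probs <= observed * (1 + 1e-12)].sum()
    return min(1.0, float(p))


def qc_filter(
    gt: GenotypeTable, ph: PhenotypeMap, params: QCParams = QCParams()
) -> tuple[GenotypeTable, list[QCFailure]]:
    """Drop variants failing missingness, pooled-MAF, or HWE thresholds.

    Rules are checked in that order and the first failing rule is
    logged per variant.  HWE is computed on all samples pooled (the
    cohort is unrelated, so no founder restriction applies), and MAF is
    the pooled ``min(f, 1 - f)`` over non-missing alleles.
    """
    keep: list[int] = []
    failures: list[QCFailure] = []
    n_samples = gt.n_samples
    for j, variant in enumerate(gt.variants):
        col = gt.dosages(j)
        ok = col != MISSING
        missing_frac = 1.0 - ok.sum() / n_samples
        if missing_frac > params.max_missing_per_variant:
            failures.append(QCFailure(variant, "missingness", missing_frac))
            continue
        n_called = int(ok.sum())
        if n_called == 0:
            failures.append(QCFailure(variant, "missingness", 1.0))
            continue
        alt = int(col[ok].sum())
        freq = alt / (2 * n_called)
        maf = min(freq, 1.0 - freq)
        if maf < params.min_maf:
            failures.append(QCFailure(variant, "maf", maf))
            continue
        called = col[ok]
        p_hwe = hwe_exact_test(
            int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
        )
        if p_hwe < params.hwe_p_threshold:
            failures.append(QCFailure(variant, "hwe", p_hwe))
            continue
        keep.append(j)
    return gt.subset_variants(keep), failures


def adjust_pvalues(pvalues, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, order-preserving.

    ``method`` is ``"bonferroni"`` (``min(1, m p)``) or ``"bh"``
    (Benjamini-Hochberg step-up with enforced monotonicity).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    methods = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    if method not in methods:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adjusted, _, _ = multipletests(p, alpha=0.05, method=methods[method])
    return [float(x) for x in adjusted]


def run_association(
    gt: GenotypeTable,
    ph: PhenotypeMap,
    params: QCParams = QCParams(),
    apply_qc: bool = True,
) -> list[AssociationResult]:
    """QC, per-variant allelic test, and adjusted p-values, sorted by p.

    Both Bonferroni and Benjamini-Hochberg adjusted values are attached
    to every result (BH is the default ``p_adj``).  Variants whose
    statistic is undefined (zero margin) are flagged and excluded from
    the adjustment family.
    """
    if apply_qc:
        gt, failures = qc_filter(gt, ph, params)
        if failures:
            logger.info("QC removed %d variants", len(failures))
    if gt.n_variants == 0:
        logger.warning("no variants left to test after QC")
        return []

    a, b, c, d = allele_count_arrays(gt, ph)
    chi2, p = allelic_chi_square_arrays(a, b, c, d)

    results: list[AssociationResult] = []
    for j, variant in enumerate(gt.variants):
        t = AlleleCountTable(int(a[j]), int(b[j]), int(c[j]), int(d[j]))
        f_a, f_u = allele_frequencies(t)
        res = AssociationResult(
            variant=variant,
            counts=t,
            f_a=f_a,
            f_u=f_u,
            chi2=float(chi2[j]),
            p=float(p[j]),
            odds_ratio=allelic_odds_ratio(t),
        )
        if math.isnan(res.chi2):
            res.qc_pass = False
            res.qc_reason = "degenerate margin: statistic undefined"
        results.append(res)

    tested = [r for r in results if not math.isnan(r.p)]
    if tested:
        for attr, method in (("p_adj_bh", "bh"), ("p_adj_bonferroni", "bonferroni")):
            adjusted = adjust_pvalues([r.p for r in tested], method=method)
            for r, padj in zip(tested, adjusted):
                setattr(r, attr, padj)
    results.sort(key=lambda r: (math.isnan(r.p), r.p, r.variant.key))
    return results
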