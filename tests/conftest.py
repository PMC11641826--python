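"""Shared fixtures: tiny cohorts built directly from dosage vectors."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from varprio.cohort_io import (
    CASE,
    CONTROL,
    GenotypeTable,
    PhenotypeMap,
    VariantSite,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def cohort_from_dosages(
    case_cols: list[list[int]],
    control_cols: list[list[int]],
    chrom: str = "chr1",
) -> tuple[GenotypeTable, PhenotypeMap]:
    """Build a cohort where column ``j`` stacks case then control dosages.

    ``case_cols[j]`` / ``control_cols[j]`` list per-sample dosages
    (use -1 for missing) for variant ``j``.
    """
    n_cases = len(case_cols[0])
    n_controls = len(control_cols[0])
    samples = [f"CASE{i:02d}" for i in range(n_cases)] + [
        f"CTRL{i:02d}" for i in range(n_controls)
    ]
    ph = PhenotypeMap(
        {s: CASE if s.startswith("CASE") else CONTROL for s in samples}
    )
    calls = np.array(
        [list(cc) + list(tc) for cc, tc in zip(case_cols, control_cols)],
        dtype=np.int8,
    ).T
    variants = [
        VariantSite(chrom, 1000 + 100 * j, "A", "T", f"rsV{j:03d}")
        for j in range(len(case_cols))
    ]
    return GenotypeTable(variants, samples, calls), ph


def dosages_for_count(alt_count: int, n_samples: int, n_missing: int = 0) -> list[int]:
    """Dosage vector with the given alt-allele total over called samples.

    Alt alleles are packed as homozygotes then one heterozygote;
    ``n_missing`` trailing samples are set missing.
    """
    called = n_samples - n_missing
    assert alt_count <= 2 * called
    col = [0] * n_samples
    i = 0
    remaining = alt_count
    while remaining >= 2:
        col[i] = 2
        remaining -= 2
        i += 1
    if remaining:
        col[i] = 1
    for k in range(n_missing):
        col[called + k] = -1
    return col


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
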