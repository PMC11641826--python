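"""Synthetic cohorts, annotations, and PPI graphs with known ground truth.

Every stage of the pipeline is testable offline because this module
emits the exact formats the readers consume (VCF, phenotype TSV,
VEP-style annotation TSV, STRING-style links) together with truth
manifests listing what was planted.

The default emulation target is a small surgical-exposure cohort:
12 cases and 11 controls, background (null) variants drawn at the same
allele frequency in both groups, and planted case-exclusive variants
whose alternate alleles appear only in cases at counts between 4 and
11.  :func:`study_cohort_spec` reproduces that structure, including a
set of single-variant genes (case allele counts 11, 10, 9, 8) and
multi-variant genes whose per-variant counts sum to >= 10.

Allele sampling is per-chromosome binomial — no linkage disequilibrium
and no population structure — because the association model under test
treats variants independently.  Planted alternate alleles are spread as
heterozygotes first (hom-alt only when the count exceeds the number of
cases), and planted carrier calls are protected from missingness
erasure by default so the observable case allele count equals the
specified one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import (
    MISSING,
    CASE,
    CONTROL,
    GenotypeTable,
    PhenotypeMap,
    VariantSite,
)

__all__ = [
    "PlantedVariant",
    "CohortSpec",
    "SimulatedCohort",
    "study_cohort_spec",
    "simulate_cohort",
    "simulate_annotations",
    "write_vep_table",
    "ScoreDist",
    "GraphSpec",
    "simulate_ppi",
]


@dataclass(frozen=True)
class PlantedVariant:
    """Specification of one case-exclusive variant to plant."""

    gene: str
    c_a: int
    term: str = "missense_variant"


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 12
    n_controls: int = 11
    n_null_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: tuple[PlantedVariant, ...] = ()
    missing_rate: float = 0.0
    protect_planted: bool = True
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"invalid missing_rate {self.missing_rate}")
        for p in self.planted:
            if p.c_a < 1 or p.c_a > 2 * self.n_cases:
                raise ValueError(
                    f"planted C_A={p.c_a} on {p.gene} infeasible for "
                    f"{self.n_cases} diploid cases"
                )


def study_cohort_spec(
    seed: int = 0,
    n_null_variants: int = 200,
    missing_rate: float = 0.0,
) -> CohortSpec:
    """The default study-like cohort: 12 v 11 with planted structure.

    Four single-variant genes at case allele counts 11, 10, 9, 8 (all
    strong enough to clear a raw p < 0.005 listing under full
    genotyping) and eight multi-variant genes whose counts sum to 10 or
    more, mirroring the co-occurrence structure the pipeline is meant
    to recover.
    """
    singles = [
        PlantedVariant("FAM186A", 11, "frameshift_variant"),
        PlantedVariant("SCUBE2", 10, "missense_variant"),
        PlantedVariant("CCDC185", 9, "missense_variant"),
        PlantedVariant("MTUS2", 8, "missense_variant"),
    ]
    multis = {
        "ZMIZ1": ([5, 5, 5, 4, 4, 4, 4], "frameshift_variant"),
        "LRFN3": ([5, 5, 5, 5, 5, 5], "frameshift_variant"),
        "OR1L6": ([4, 4, 4, 4], "missense_variant"),
        "RYR3": ([5, 5, 4], "frameshift_variant"),
        "PWWP2B": ([4, 4, 4], "stop_gained"),
        "ZNF92": ([6, 6], "missense_variant"),
        "CYP4F12": ([4, 4, 4], "missense_variant"),
        "NUTM2D": ([5, 5], "missense_variant"),
    }
    planted = list(singles)
    for gene, (counts, term) in multis.items():
        planted.extend(PlantedVariant(gene, c, term) for c in counts)
    return CohortSpec(
        planted=tuple(planted),
        n_null_variants=n_null_variants,
        missing_rate=missing_rate,
        seed=seed,
    )


@dataclass
class SimulatedCohort:
    """A simulated cohort plus its ground-truth manifest."""

    spec: CohortSpec
    genotypes: GenotypeTable
    phenotypes: PhenotypeMap
    truth: pd.DataFrame  # one row per planted variant

    def write_vcf(self, path: str | Path) -> None:
        write_vcf(self.genotypes, path)

    def write_phenotypes(self, path: str | Path) -> None:
        codes = {CONTROL: "1", CASE: "2"}
        with open(path, "w") as fh:
            for sample in self.genotypes.samples:
                fh.write(f"{sample}\t{codes[self.phenotypes.assignments[sample]]}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_regions(self, path: str | Path) -> None:
        """Gene-region TSV covering every planted gene."""
        regions = (
            self.truth.groupby("gene")
            .agg(chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"))
            .reset_index()
        )
        regions = regions.sort_values("start")[["gene", "chrom", "start", "end"]]
        regions.to_csv(path, sep="\t", index=False)


def write_vcf(gt: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable as a minimal plain-text VCF 4.2 file."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in gt.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        order = sorted(range(gt.n_variants), key=lambda j: (gt.variants[j].chrom, gt.variants[j].pos))
        for j in order:
            v = gt.variants[j]
            vid = v.id if not v.id.startswith(f"{v.ref} > ") else "."
            calls = "\t".join(gt_strings[int(x)] for x in gt.calls[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw a cohort according to ``spec`` (deterministic given the seed).

    Null variants: per-sample dosages Binomial(2, f) with f uniform in
    ``maf_range``, identically in cases and controls.  Planted
    variants: exactly ``c_a`` alternate alleles among case chromosomes
    (heterozygotes first), zero among controls.  Missingness is applied
    afterwards and, unless ``protect_planted`` is off, never erases a
    planted carrier call.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"CASE{i + 1:02d}" for i in range(spec.n_cases)] + [
        f"CTRL{i + 1:02d}" for i in range(spec.n_controls)
    ]
    assignments = {
        s: CASE if s.startswith("CASE") else CONTROL for s in samples
    }
    n_samples = len(samples)

    variants: list[VariantSite] = []
    columns: list[np.ndarray] = []
    protected: list[np.ndarray] = []
    truth_rows: list[dict] = []

    # Planted variants: one 10 kb locus per gene, loci spaced 100 kb apart.
    genes = list(dict.fromkeys(p.gene for p in spec.planted))
    gene_base = {g: 1_000_000 + i * 100_000 for i, g in enumerate(genes)}
    gene_offset = {g: 0 for g in genes}
    for k, p in enumerate(spec.planted):
        pos = gene_base[p.gene] + 1_000 * gene_offset[p.gene]
        gene_offset[p.gene] += 1
        col = np.zeros(n_samples, dtype=np.int8)
        n_hom = max(0, p.c_a - spec.n_cases)
        n_het = p.c_a - 2 * n_hom
        carriers = rng.choice(spec.n_cases, size=n_hom + n_het, replace=False)
        col[carriers[:n_hom]] = 2
        col[carriers[n_hom:]] = 1
        site = VariantSite(spec.chrom, pos, "A", "T", f"rsP{k + 1:04d}")
        variants.append(site)
        columns.append(col)
        protected.append(col > 0)
        truth_rows.append(
            {
                "variant_id": site.id,
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "gene": p.gene,
                "c_a": p.c_a,
                "term": p.term,
            }
        )

    # Null variants: same allele frequency in both groups.
    null_base = 10_000_000
    mafs = rng.uniform(*spec.maf_range, size=spec.n_null_variants)
    null_calls = rng.binomial(2, mafs[None, :], size=(n_samples, spec.n_null_variants))
    for j in range(spec.n_null_variants):
        site = VariantSite(
            spec.chrom, null_base + 500 * j, "G", "C", f"rsN{j + 1:05d}"
        )
        variants.append(site)
        columns.append(null_calls[:, j].astype(np.int8))
        protected.append(np.zeros(n_samples, dtype=bool))

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((n_samples, 0), dtype=np.int8)
    )
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        if spec.protect_planted and protected:
            mask &= ~np.stack(protected, axis=1)
        calls = np.where(mask, np.int8(MISSING), calls)

    truth = pd.DataFrame(
        truth_rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene", "c_a", "term"],
    )
    return SimulatedCohort(
        spec=spec,
        genotypes=GenotypeTable(variants, samples, calls),
        phenotypes=PhenotypeMap(assignments),
        truth=truth,
    )


def simulate_annotations(
    cohort: SimulatedCohort,
    n_decoy_genes: int = 40,
    coding_fraction: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """VEP-style annotation table for every variant in the cohort.

    Planted variants receive their specified gene and consequence term;
    null variants receive decoy genes and mostly noncoding terms
    (``coding_fraction`` of them become missense).
    """
    if seed is None:
        seed = cohort.spec.seed + 1
    rng = np.random.default_rng(seed)
    by_id = dict(zip(cohort.truth["variant_id"], cohort.truth.to_dict("records")))
    rows = []
    for v in cohort.genotypes.variants:
        planted = by_id.get(v.id)
        if planted is not None:
            gene, term = planted["gene"], planted["term"]
        else:
            gene = f"DECOY{rng.integers(1, n_decoy_genes + 1):03d}"
            term = (
                "missense_variant"
                if rng.random() < coding_fraction
                else "intron_variant"
            )
        rows.append(
            {
                "Uploaded_variation": v.id,
                "Location": f"{v.chrom}:{v.pos}",
                "SYMBOL": gene,
                "Consequence": term,
            }
        )
    return pd.DataFrame(rows)


def write_vep_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"Uploaded_variation": "#Uploaded_variation"})
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScoreDist:
    """Truncated-normal integer score distribution on [lo, hi]."""

    mean: float
    sd: float
    lo: int = 0
    hi: int = 1000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        return np.clip(np.rint(x), self.lo, self.hi).astype(int)


@dataclass(frozen=True)
class GraphSpec:
    n_nodes: int = 120
    background_edge_prob: float = 0.04
    background_score_dist: ScoreDist = ScoreDist(400, 120, 150, 1000)
    module_nodes: tuple[str, ...] = ()
    module_score_dist: ScoreDist = ScoreDist(950, 25, 800, 1000)
    module_edge_prob: float = 0.9
    seed: int = 0


def simulate_ppi(spec: GraphSpec) -> tuple[nx.Graph, dict]:
    """STRING-like graph: low-score background plus a high-score module.

    Background edges are sampled over all node pairs (including pairs
    touching module nodes) with low scores; module-internal pairs then
    receive high-confidence edges at ``module_edge_prob``, overriding
    any background edge.  The default score design is bimodal (modes
    near 400 and 950), so the score histogram shows an interior minimum
    between them.  Returns the graph and a truth manifest.
    """
    rng = np.random.default_rng(spec.seed)
    background = [f"BG{i + 1:04d}" for i in range(spec.n_nodes)]
    nodes = background + [m for m in spec.module_nodes if m not in background]
    g = nx.Graph()
    g.add_nodes_from(nodes)

    pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    picks = rng.random(len(pairs)) < spec.background_edge_prob
    scores = spec.background_score_dist.sample(rng, len(pairs))
    for (u, v), take, s in zip(pairs, picks, scores):
        if take:
            g.add_edge(u, v, combined_score=int(s))

    module = list(spec.module_nodes)
    mod_pairs = [(u, v) for i, u in enumerate(module) for v in module[i + 1 :]]
    mod_picks = rng.random(len(mod_pairs)) < spec.module_edge_prob
    mod_scores = spec.module_score_dist.sample(rng, len(mod_pairs))
    for (u, v), take, s in zip(mod_pairs, mod_picks, mod_scores):
        if take:
            g.add_edge(u, v, combined_score=int(s))

    truth = {
        "module_nodes": tuple(module),
        "module_edges": sum(1 for u, v in mod_pairs if g.has_edge(u, v)),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    return g, truth
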