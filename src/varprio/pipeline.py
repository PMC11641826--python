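"""End-to-end orchestration: panel scan, case-exclusive list, co-occurrence,
genes of interest, and PPI subnetwork, with table-shaped TSV outputs.

Stages are pure functions of (inputs, config, seed): re-running the
pipeline on the same inputs reproduces every output byte for byte.
Timings go to the log, never into output files.

Outputs written to the configured directory:

========================  =====================================================
``panel_scan.tsv``        candidate-panel variants under ``panel_alpha``
``case_exclusive.tsv``    all significant case-exclusive (variant, gene) rows
``listing.tsv``           one row per variant under ``listing_alpha``
``gene_aggregates.tsv``   per-gene co-occurrence aggregates
``multi_variant_genes.tsv``  aggregates passing the co-occurrence filter
``goi.txt``               genes of interest, one symbol per line
``subnetwork_edges.tsv``  induced subnetwork edge list
``subnetwork_nodes.tsv``  node attributes (route, component)
``components.tsv``        connected components, largest first
``score_histogram.tsv``   raw + normalized score distributions
``manifest.json``         config, seed, per-stage row counts
========================  =====================================================
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .association import AssociationResult, QCParams, qc_filter, run_association
from .case_exclusive import (
    CaseExclusiveVariant,
    case_exclusive_variants,
    prioritize,
    top_per_variant,
)
from .cohort_io import (
    CohortError,
    GenotypeTable,
    PhenotypeMap,
    read_gene_regions,
    read_phenotypes,
    read_vcf,
)
from .consequence import ConsequenceAnnotation, most_severe, read_vep_table
from .cooccurrence import aggregate_by_gene, genes_of_interest, multi_variant_genes
from .ppi import (
    extract_subnetwork,
    filter_edges,
    normalize_scores,
    read_string_links,
    score_distribution,
)

__all__ = [
    "ConfigError",
    "DataError",
    "StageError",
    "PipelineConfig",
    "run_panel_scan",
    "run_full",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 4)."""


@dataclass
class PipelineConfig:
    vcf: str
    phenotypes: str
    vep_table: str
    gene_regions: str
    string_links: str | None = None
    outdir: str = "varprio_out"
    qc: QCParams = field(default_factory=QCParams)
    flank: int = 5000
    panel_alpha: float = 0.01
    exclusive_alpha: float = 0.05
    listing_alpha: float = 0.005
    min_variants: int = 2
    min_allele_sum: int = 10
    norm_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("panel_alpha", "exclusive_alpha", "listing_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.norm_threshold <= 1.0:
            raise ConfigError(
                f"norm_threshold must be in (0, 1], got {self.norm_threshold}"
            )
        if self.min_variants < 1 or self.min_allele_sum < 0:
            raise ConfigError("invalid co-occurrence thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        qc = QCParams(**raw.pop("qc", {}))
        try:
            return cls(qc=qc, **raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def check_inputs(self, require_network: bool = True) -> None:
        paths = {
            "vcf": self.vcf,
            "phenotypes": self.phenotypes,
            "vep_table": self.vep_table,
            "gene_regions": self.gene_regions,
        }
        if require_network:
            if self.string_links is None:
                raise ConfigError("network stage enabled but string_links unset")
            paths["string_links"] = self.string_links
        for name, p in paths.items():
            if not Path(p).exists():
                raise DataError(f"{name} file not found: {p}")


def _sig(x: float | None, digits: int = 4) -> str:
    """Format at ``digits`` significant figures; None/nan render as NA."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{digits}g}"


def _annotations_by_id(
    annotations: Sequence[ConsequenceAnnotation],
) -> dict[str, list[ConsequenceAnnotation]]:
    by_id: dict[str, list[ConsequenceAnnotation]] = {}
    for ann in annotations:
        by_id.setdefault(ann.variant_id, []).append(ann)
    return by_id


def association_table(
    results: Sequence[AssociationResult],
    annotations: Sequence[ConsequenceAnnotation] = (),
    adjust: str = "bh",
) -> pd.DataFrame:
    """Table-2-style frame: chrom id pos gene F_A F_U consequence chi2 p p_adj OR."""
    by_id = _annotations_by_id(annotations)
    rows = []
    for r in results:
        anns = by_id.get(r.variant.id, [])
        gene = anns[0].gene if anns else "-"
        consequence = ",".join(sorted({t for a in anns for t in a.terms})) or "-"
        p_adj = r.p_adj_bonferroni if adjust == "bonferroni" else r.p_adj_bh
        rows.append(
            {
                "chrom": r.variant.chrom,
                "id": r.variant.id,
                "pos": r.variant.pos,
                "gene": gene,
                "F_A": _sig(r.f_a),
                "F_U": _sig(r.f_u),
                "consequence": consequence,
                "chi2": _sig(r.chi2),
                "p": _sig(r.p),
                "p_adj": _sig(p_adj),
                "OR": _sig(r.odds_ratio),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "id", "pos", "gene", "F_A", "F_U",
            "consequence", "chi2", "p", "p_adj", "OR",
        ],
    )


def case_exclusive_table(rows: Sequence[CaseExclusiveVariant]) -> pd.DataFrame:
    """Table-3-style frame: chrom id pos gene C_A consequence chi2 p."""
    return pd.DataFrame(
        [
            {
                "chrom": v.variant.chrom,
                "id": v.variant.id,
                "pos": v.variant.pos,
                "gene": v.gene,
                "C_A": v.c_a,
                "consequence": v.most_severe_term,
                "chi2": _sig(v.chi2),
                "p": _sig(v.p),
            }
            for v in rows
        ],
        columns=["chrom", "id", "pos", "gene", "C_A", "consequence", "chi2", "p"],
    )


def run_panel_scan(
    gt: GenotypeTable,
    ph: PhenotypeMap,
    regions,
    annotations: Sequence[ConsequenceAnnotation] = (),
    qc: QCParams = QCParams(),
    flank: int = 5000,
    panel_alpha: float = 0.01,
) -> pd.DataFrame:
    """Candidate-gene panel scan: +-flank loci, QC, association, p < alpha.

    Output rows are ordered by (p, position) and carry consequence
    labels plus BH-adjusted p-values.
    """
    from .cohort_io import extract_gene_loci

    panel = extract_gene_loci(gt, regions, flank=flank)
    results = run_association(panel, ph, qc)
    hits = [r for r in results if not math.isnan(r.p) and r.p < panel_alpha]
    hits.sort(key=lambda r: (r.p, r.variant.pos))
    return association_table(hits, annotations)


def run_full(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage and write TSV outputs plus a run manifest."""
    t0 = time.perf_counter()
    config.check_inputs(require_network=config.string_links is not None)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    frames: dict[str, pd.DataFrame] = {}

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                out = fn()
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - start)
            return out

        return wrap

    # -- load ---------------------------------------------------------------
    def load():
        try:
            gt = read_vcf(config.vcf)
            ph = read_phenotypes(config.phenotypes)
            regions = read_gene_regions(config.gene_regions)
            annotations = read_vep_table(config.vep_table)
        except (CohortError, ValueError) as exc:
            raise DataError(str(exc)) from exc
        return gt, ph, regions, annotations

    gt, ph, regions, annotations = stage("load")(load)
    by_id = _annotations_by_id(annotations)

    # -- panel scan ---------------------------------------------------------
    panel = stage("panel_scan")(
        lambda: run_panel_scan(
            gt, ph, regions, annotations, config.qc, config.flank, config.panel_alpha
        )
    )
    frames["panel_scan"] = panel
    counts["panel_scan"] = len(panel)

    # -- genome-wide association + case-exclusive filter --------------------
    def exclusive():
        gt_qc, _ = qc_filter(gt, ph, config.qc)
        results = run_association(gt_qc, ph, config.qc, apply_qc=False)
        calls = case_exclusive_variants(gt_qc, ph)
        return prioritize(calls, by_id, results, alpha=config.exclusive_alpha)

    prioritized = stage("case_exclusive")(exclusive)
    frames["case_exclusive"] = case_exclusive_table(prioritized)
    counts["case_exclusive"] = len(prioritized)

    listing = [
        v for v in top_per_variant(prioritized) if v.p < config.listing_alpha
    ]
    frames["listing"] = case_exclusive_table(listing)
    counts["listing"] = len(listing)

    # -- co-occurrence ------------------------------------------------------
    def cooccur():
        aggregates = aggregate_by_gene(prioritized)
        multi = multi_variant_genes(
            aggregates, config.min_variants, config.min_allele_sum
        )
        return aggregates, multi

    aggregates, multi = stage("cooccurrence")(cooccur)

    def agg_frame(aggs):
        return pd.DataFrame(
            [
                {
                    "gene": g.gene,
                    "n_variants": g.n_variants,
                    "allele_counts": ",".join(map(str, g.allele_counts)),
                    "allele_sum": g.allele_sum,
                    "consequences": ",".join(g.terms),
                }
                for g in aggs
            ],
            columns=["gene", "n_variants", "allele_counts", "allele_sum", "consequences"],
        )

    frames["gene_aggregates"] = agg_frame(aggregates)
    frames["multi_variant_genes"] = agg_frame(multi)
    counts["multi_variant_genes"] = len(multi)

    # -- genes of interest --------------------------------------------------
    def goi_stage():
        single = [v.gene for v in listing if v.gene != "-"]
        return genes_of_interest(dict.fromkeys(single), multi)

    goi = stage("genes_of_interest")(goi_stage)
    counts["goi"] = len(goi.union)
    frames["goi"] = pd.DataFrame({"gene": list(goi.union)})

    # -- PPI subnetwork -----------------------------------------------------
    if config.string_links is not None:
        def network():
            g = read_string_links(config.string_links)
            normalize_scores(g)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                raw_edges, raw_pct, _ = score_distribution(g, use_norm=False)
                norm_edges, norm_pct, _ = score_distribution(g, use_norm=True)
            hist = pd.DataFrame(
                {
                    "raw_bin_low": raw_edges[:-1],
                    "raw_percent": [f"{x:.6g}" for x in raw_pct],
                    "norm_bin_low": [f"{x:.6g}" for x in norm_edges[:-1]],
                    "norm_percent": [f"{x:.6g}" for x in norm_pct],
                }
            )
            filtered = filter_edges(g, config.norm_threshold, use_norm=True)
            sub = extract_subnetwork(filtered, goi.union)
            return g, hist, sub

        _, hist, sub = stage("network")(network)
        frames["score_histogram"] = hist

        edge_rows = [
            {
                "protein1": min(u, v),
                "protein2": max(u, v),
                "combined_score": d["combined_score"],
                "norm_score": f"{d['norm_score']:.6g}",
            }
            for u, v, d in sub.graph.edges(data=True)
        ]
        frames["subnetwork_edges"] = (
            pd.DataFrame(
                edge_rows,
                columns=["protein1", "protein2", "combined_score", "norm_score"],
            )
            .sort_values(["protein1", "protein2"])
            .reset_index(drop=True)
        )

        comps = sub.components
        comp_of = {n: i + 1 for i, c in enumerate(comps) for n in c}
        single_set = set(goi.single_variant_genes)
        multi_set = set(goi.multi_variant_genes)
        seed_plus = set()
        for s in goi.union:
            if s in sub.graph:
                seed_plus.add(s)
                seed_plus.update(sub.graph.neighbors(s))

        def route(n: str) -> str:
            if n in single_set:
                return "single-variant"
            if n in multi_set:
                return "multi-variant"
            if n in seed_plus:
                return "neighbor"
            return "expanded"

        frames["subnetwork_nodes"] = pd.DataFrame(
            [
                {"node": n, "route": route(n), "component": comp_of.get(n, 0)}
                for n in sorted(sub.selected_nodes)
            ],
            columns=["node", "route", "component"],
        )
        frames["components"] = pd.DataFrame(
            [
                {
                    "component": i + 1,
                    "size": len(c),
                    "nodes": ",".join(sorted(c)),
                }
                for i, c in enumerate(comps)
            ],
            columns=["component", "size", "nodes"],
        )
        counts["subnetwork_nodes"] = len(sub.selected_nodes)
        counts["subnetwork_edges"] = sub.graph.number_of_edges()
        counts["components"] = len(comps)

    # -- write --------------------------------------------------------------
    for name, frame in frames.items():
        suffix = ".txt" if name == "goi" else ".tsv"
        if name == "goi":
            (outdir / "goi.txt").write_text(
                "".join(f"{g}\n" for g in frame["gene"])
            )
        else:
            frame.to_csv(outdir / f"{name}{suffix}", sep="\t", index=False)

    manifest = {
        "package": "varprio",
        "version": __version__,
        "seed": config.seed,
        # outdir is omitted: the manifest lives inside it, and recording it
        # would make otherwise identical runs differ
        "config": {
            k: (asdict(v) if isinstance(v, QCParams) else v)
            for k, v in asdict(config).items()
            if k != "outdir"
        },
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return frames
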