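"""STRING-style PPI network: ingestion, normalization, subnetwork extraction.

Edges carry an integer ``combined_score`` confidence in [0, 1000].
Filtering on the absolute score can delete every interaction of a gene
whose best partner scores below the cutoff, so scores are first
normalized per gene: with ``M(x)`` the maximum combined_score over
edges incident to ``x``, edge ``(u, v)`` receives

    norm_score = s(u, v) / min(M(u), M(v)),

i.e. the larger of the two per-endpoint normalizations.  Every gene's
strongest interaction then has norm_score = 1 and survives any
threshold <= 1, which is the point of the normalization.  (The
alternative convention — duplicating each edge with both per-endpoint
normalizations — is not used here.)

Subnetwork extraction around a seed-gene list applies the expansion
rule once: S1 = seeds plus all their neighbors; S2 = S1 plus any node
with at least two neighbors inside S1; the result is the subgraph
induced by S2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Subnetwork",
    "read_string_links",
    "write_string_links",
    "normalize_scores",
    "score_distribution",
    "filter_edges",
    "extract_subnetwork",
    "connected_components",
]

logger = logging.getLogger(__name__)

MAX_SCORE = 1000


def read_string_links(path: str | Path) -> nx.Graph:
    """Read a STRING protein-links file into an undirected graph.

    Expects whitespace-delimited ``protein1 protein2 combined_score``
    with a header line.  Self-loops are dropped; duplicate unordered
    pairs are merged keeping the maximum score.
    """
    g = nx.Graph()
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'protein1 protein2 combined_score'"
                )
            u, v, raw = fields
            try:
                score = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer combined_score {raw!r}"
                ) from None
            if not 0 <= score <= MAX_SCORE:
                raise ValueError(
                    f"{path}:{lineno}: combined_score {score} outside [0, {MAX_SCORE}]"
                )
            if u == v:
                continue  # self-loop
            if g.has_edge(u, v):
                g[u][v]["combined_score"] = max(g[u][v]["combined_score"], score)
            else:
                g.add_edge(u, v, combined_score=score)
    return g


def write_string_links(g: nx.Graph, path: str | Path) -> None:
    """Write a graph back to STRING protein-links format (sorted, stable)."""
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, data in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in g.edges(data=True))
        ):
            fh.write(f"{u} {v} {data['combined_score']}\n")


def normalize_scores(g: nx.Graph) -> nx.Graph:
    """Attach ``norm_score = s / min(M(u), M(v))`` to every edge (in place).

    ``M(x)`` is the maximum combined_score among edges incident to
    ``x``; after normalization every non-isolated node has at least one
    edge with norm_score exactly 1.  Isolated nodes are untouched.
    """
    node_max = {
        n: max((d["combined_score"] for _, _, d in g.edges(n, data=True)), default=0)
        for n in g.nodes
    }
    for u, v, data in g.edges(data=True):
        m = min(node_max[u], node_max[v])
        data["norm_score"] = data["combined_score"] / m if m > 0 else 1.0
    return g


def score_distribution(
    g: nx.Graph,
    bin_width: float | None = None,
    use_norm: bool = False,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Histogram of edge scores as percent of total, plus its interior minimum.

    Returns ``(bin_edges, percent, minimum)`` where ``minimum`` is the
    midpoint of the lowest interior bin — the score after which the
    percentage of interactions starts increasing again, the natural
    confidence threshold.  When the histogram has no genuine interior
    minimum (flat or monotone), ``minimum`` is ``None`` and a warning is
    issued; the conventional fallbacks are then 800 on the raw scale
    and 0.8 on the normalized scale.

    Default bin width: 25 score units raw, 0.025 normalized.
    """
    attr = "norm_score" if use_norm else "combined_score"
    scores = np.array([d[attr] for _, _, d in g.edges(data=True)], dtype=float)
    if scores.size == 0:
        raise ValueError("graph has no edges")
    if bin_width is None:
        bin_width = 0.025 if use_norm else 25.0
    hi = 1.0 if use_norm else float(MAX_SCORE)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if len(edges) - 1 < 3:
        raise ValueError("fewer than 3 bins; decrease bin_width")
    counts, edges = np.histogram(scores, bins=edges)
    percent = 100.0 * counts / counts.sum()

    minimum: float | None = None
    occupied = np.nonzero(counts)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    if hi - lo >= 2:
        # argmin over the interior of the occupied support; empty bins
        # outside the support are not candidate minima
        interior = percent[lo + 1 : hi]
        k = lo + 1 + int(np.argmin(interior))
        # genuine minimum: strictly larger mass somewhere on both sides
        if percent[lo : k + 1].max() > percent[k] and percent[k : hi + 1].max() > percent[k]:
            minimum = float((edges[k] + edges[k + 1]) / 2)
    if minimum is None:
        warnings.warn(
            "no interior minimum in score distribution; "
            "fall back to 800 (raw) / 0.8 (normalized)",
            stacklevel=2,
        )
    return edges, percent, minimum


def filter_edges(g: nx.Graph, threshold: float, use_norm: bool = False) -> nx.Graph:
    """Keep edges scoring >= threshold; drop nodes left without edges.

    Raw thresholds are on the 0-1000 combined_score scale, normalized
    thresholds on (0, 1].  Monotone: a higher threshold yields a subset
    of the edges kept at a lower one.
    """
    hi = 1.0 if use_norm else MAX_SCORE
    if not 0 <= threshold <= hi:
        raise ValueError(f"threshold {threshold} outside [0, {hi}]")
    attr = "norm_score" if use_norm else "combined_score"
    out = nx.Graph()
    for u, v, data in g.edges(data=True):
        if data[attr] >= threshold:
            out.add_edge(u, v, **data)
    return out


@dataclass
class Subnetwork:
    """Seed-expanded subgraph with components ordered largest-first."""

    selected_nodes: set[str]
    graph: nx.Graph
    seeds: tuple[str, ...] = ()

    @property
    def components(self) -> list[set[str]]:
        return connected_components(self.graph, ensure_nodes=self.selected_nodes)


def extract_subnetwork(g: nx.Graph, seeds: Iterable[str]) -> Subnetwork:
    """Seeds + neighbors, then one round of two-neighbor expansion.

    S1 = (seeds present in g) and all their neighbors; S2 adds every
    node with >= 2 neighbors inside S1 ("within a distance of one" of
    the selected set).  The expansion is applied exactly once.  The
    result is the subgraph of g induced by S2.
    """
    seeds = tuple(seeds)
    present = [s for s in seeds if s in g]
    if not present:
        warnings.warn("no seed gene present in the graph", stacklevel=2)
        return Subnetwork(set(), nx.Graph(), seeds)
    s1: set[str] = set(present)
    for s in present:
        s1.update(g.neighbors(s))
    s2 = set(s1)
    for node in g.nodes:
        if node in s1:
            continue
        if sum(1 for nb in g.neighbors(node) if nb in s1) >= 2:
            s2.add(node)
    return Subnetwork(s2, g.subgraph(s2).copy(), seeds)


def connected_components(
    g: nx.Graph, ensure_nodes: Iterable[str] = ()
) -> list[set[str]]:
    """Components sorted by size descending, ties by smallest node label.

    ``ensure_nodes`` adds isolated nodes that carry no edges (a seed
    with no surviving interaction is its own singleton component).
    """
    h = g.copy()
    h.add_nodes_from(ensure_nodes)
    comps = [set(c) for c in nx.connected_components(h)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps
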