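"""Scored protein-protein interaction network: reading, filtering, mapping.

The network is held as an undirected simple :class:`networkx.Graph` whose
nodes are opaque, case-sensitive gene symbols and whose edges carry a
``score`` attribute on the 0-1 confidence scale.  High-confidence filtering
keeps edges with score >= the cutoff (inclusive; 0.9 by default, so boundary
scores are retained).  Input tables using the STRING 0-999 integer dialect
are detected (any score above 1) and divided by 1000 before comparison.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .degs import IntegratedDEGSet

logger = logging.getLogger(__name__)

DEFAULT_SCORE_CUTOFF = 0.9


def read_interactions(path: str | Path, score_cutoff: float = DEFAULT_SCORE_CUTOFF) -> nx.Graph:
    """Read a 3-column (geneA, geneB, score) table into a filtered graph.

    Duplicate pairs collapse to their maximum score; self-loops are dropped
    with a logged count; a malformed line raises with its line number.
    """
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, score_text = fields
            try:
                score = float(score_text)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {score_text!r}"
                ) from exc
            raw.append((a, b, score))

    # STRING integer dialect: combined scores printed on a 0-999 scale
    if raw and max(score for _, _, score in raw) > 1.0:
        raw = [(a, b, score / 1000.0) for a, b, score in raw]

    net = nx.Graph()
    n_self = 0
    for a, b, score in raw:
        if a == b:
            n_self += 1
            continue
        if score < score_cutoff:
            continue
        if net.has_edge(a, b):
            net[a][b]["score"] = max(net[a][b]["score"], score)
        else:
            net.add_edge(a, b, score=score)
    if n_self:
        logger.info("%s: dropped %d self-loops", path, n_self)
    if net.number_of_edges() == 0:
        logger.warning("%s: no edges at score cutoff %g", path, score_cutoff)
    return net


def induced_subgraph(net: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph materialized in sorted node order.

    networkx subgraph views may iterate the selector set, whose order
    depends on the per-process hash salt; building in sorted order keeps
    exported files byte-identical across runs.
    """
    keep = sorted(set(nodes) & set(net.nodes))
    keep_set = set(keep)
    sub = nx.Graph()
    for u in keep:
        sub.add_node(u, **net.nodes[u])
    for u in keep:
        for v in sorted(net[u]):
            if v in keep_set and u < v:
                sub.add_edge(u, v, **net[u][v])
    return sub


def map_degs(net: nx.Graph, degs: "IntegratedDEGSet") -> nx.Graph:
    """Induced subgraph on the integrated DEGs present in the network.

    Node attributes record each gene's dysregulation direction and the
    disease context of the DEG set.
    """
    keep = degs.genes() & set(net.nodes)
    if not keep:
        logger.info("no %s DEGs present in the network", degs.context)
    sub = induced_subgraph(net, keep)
    for gene in sub.nodes:
        sub.nodes[gene]["direction"] = degs.members[gene]
        sub.nodes[gene]["context"] = degs.context
    return sub


def maximal_connected_component(net: nx.Graph) -> nx.Graph:
    """Largest connected component; ties go to the one holding the
    lexicographically smallest node id."""
    if net.number_of_nodes() == 0:
        return net.copy()
    components = list(nx.connected_components(net))
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    best = min(tied, key=min)
    return induced_subgraph(net, best)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Simple interaction format: one 'geneA pp geneB' line per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_sif(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            a, _, b = fields
            net.add_edge(a, b)
    return net


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_edge_table(net: nx.Graph, path: str | Path) -> None:
    """3-column edge TSV (geneA, geneB, score), the read_interactions format."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            score = net[a][b].get("score", 1.0)
            fh.write(f"{a}\t{b}\t{score:g}\n")
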