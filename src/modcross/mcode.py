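"""MCODE-style dense-complex detection.

Vertex weighting uses the core-clustering coefficient: for each vertex the
highest k-core of its closed neighborhood is found, and the weight is that
core's k multiplied by the core's edge density.  Complex prediction then
seeds from the highest-weight unvisited vertex and grows breadth-first,
admitting neighbors whose weight exceeds ``(1 - node_score_cutoff)`` times
the seed weight; each vertex can join at most one complex.  Post-processing
optionally trims loosely attached members (haircut: iterated removal of
members with fewer than two in-complex neighbors, i.e. the complex 2-core)
and optionally adds dense neighborhoods (fluff).  Complexes without a
non-empty ``k_core_min``-core are discarded.

Tie-breaking is fixed (lexicographic gene id) so results do not depend on
input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class MCODEParams:
    """Published defaults of the complex-prediction algorithm."""

    node_score_cutoff: float = 0.2
    k_core_min: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must be in [0,1)")
        if self.k_core_min < 2:
            raise ValueError("k_core_min must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")


@dataclass
class GeneModule:
    """A detected complex with its disease context."""

    module_id: tuple[str, int]  # (context, ordinal)
    context: str
    members: frozenset[str]
    seed_gene: str
    score: float  # complex density x size

    def __len__(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def highest_k_core(net: nx.Graph) -> tuple[nx.Graph, int]:
    """The non-empty k-core with maximal k, and that k (0 for edgeless)."""
    if net.number_of_edges() == 0:
        return net.copy(), 0
    core_numbers = nx.core_number(net)
    k = max(core_numbers.values())
    nodes = [v for v, c in core_numbers.items() if c >= k]
    return net.subgraph(nodes).copy(), k


def vertex_weight(net: nx.Graph, v: str) -> float:
    """Core-clustering coefficient weight: k x density of the highest k-core
    of the closed neighborhood of ``v``."""
    if v not in net:
        raise KeyError(f"vertex {v!r} not in network")
    closed = set(net[v]) | {v}
    if len(closed) == 1:
        return 0.0
    sub = net.subgraph(closed)
    core, k = highest_k_core(sub)
    return k * _density(core)


def vertex_weights(net: nx.Graph) -> dict[str, float]:
    return {v: vertex_weight(net, v) for v in net.nodes}


def _haircut(sub: nx.Graph) -> set[str]:
    """Iteratively strip members with < 2 in-complex neighbors (the 2-core)."""
    return set(nx.k_core(sub, 2).nodes)


def _fluff(net: nx.Graph, members: set[str], density_cutoff: float) -> set[str]:
    """Add outside neighbors whose closed neighborhood is dense enough."""
    added = set()
    for m in sorted(members):
        for nbr in net[m]:
            if nbr in members or nbr in added:
                continue
            closed = set(net[nbr]) | {nbr}
            if _density(net.subgraph(closed)) > density_cutoff:
                added.add(nbr)
    return members | added


def mcode_complexes(
    net: nx.Graph,
    params: MCODEParams | None = None,
    context: str = "unknown",
) -> list[GeneModule]:
    """Predict complexes, largest score first.

    Seeds are taken in decreasing weight order (lexicographic id on ties);
    every vertex reached during growth is marked visited, whether or not its
    complex survives post-processing, so complexes never overlap.
    """
    params = params or MCODEParams()
    weights = vertex_weights(net)
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []

    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for nbr in sorted(net[u]):
                    if nbr in members or nbr in visited:
                        continue
                    if weights[nbr] > threshold:
                        members.add(nbr)
                        nxt.append(nbr)
            frontier = nxt
            depth += 1
        visited |= members
        raw.append((seed, members))

    modules: list[GeneModule] = []
    for seed, members in raw:
        if params.haircut:
            members = _haircut(net.subgraph(members))
        if params.fluff:
            members = _fluff(net, set(members), params.fluff_density_cutoff)
        if not members:
            continue
        sub = net.subgraph(members)
        if nx.k_core(sub, params.k_core_min).number_of_nodes() == 0:
            continue
        modules.append(
            GeneModule(
                module_id=(context, 0),
                context=context,
                members=frozenset(members),
                seed_gene=seed,
                score=_density(sub) * sub.number_of_nodes(),
            )
        )

    modules.sort(key=lambda m: (-m.score, min(m.members)))
    return [
        GeneModule(
            module_id=(m.context, i + 1),
            context=m.context,
            members=m.members,
            seed_gene=m.seed_gene,
            score=m.score,
        )
        for i, m in enumerate(modules)
    ]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_modules(path, modules: list[GeneModule]) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tcontext\tseed\tscore\tmembers\n")
        for m in modules:
            fh.write(
                f"{m.module_id[0]}:{m.module_id[1]}\t{m.context}\t{m.seed_gene}\t"
                f"{m.score:.6g}\t{','.join(sorted(m.members))}\n"
            )


def write_module_sifs(net: nx.Graph, modules: list[GeneModule], outdir) -> None:
    """One SIF per module: the module's induced subgraph in ``net``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in modules:
        sub = net.subgraph(m.members)
        path = outdir / f"module_{m.module_id[0]}_{m.module_id[1]}.sif"
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
                fh.write(f"{a}\tpp\t{b}\n")


def read_modules(path) -> list[GeneModule]:
    modules = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            mid, context, seed, score, members = line.rstrip("\n").split("\t")
            ctx, ordinal = mid.rsplit(":", 1)
            modules.append(
                GeneModule(
                    module_id=(ctx, int(ordinal)),
                    context=context,
                    members=frozenset(members.split(",")),
                    seed_gene=seed,
                    score=float(score),
                )
            )
    return modules
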