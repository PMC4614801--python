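"""Module-pair crosstalk significance by degree-preserving permutation.

For an inflammation module A and a cancer module B, crosstalk is the set of
network edges with one endpoint in A\\B and the other in B\\A; edges touching
genes shared by both modules are reported separately as common elements, not
as crosstalk.  The observed count is compared against the same count on an
ensemble of randomized networks in which every node keeps its exact degree
(double edge swaps; proposals creating self-loops or parallel edges are
rejected).  The empirical p-value is

    p = (1/N) * sum_i S_i,   S_i = 1 if the i-th random network has strictly
                             more inter-module edges than observed, else 0,

and a pair is significant at p < alpha (0.05 by default).  A conservative
variant (#(null >= observed) + 1) / (N + 1) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .mcode import GeneModule

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 1000
DEFAULT_SWAPS_PER_EDGE = 10
DEFAULT_ALPHA = 0.05


@dataclass
class CrosstalkResult:
    """Permutation-test verdict for one inflammation x cancer module pair."""

    pair: tuple[tuple[str, int], tuple[str, int]]
    observed_inter_edges: int
    null_counts: np.ndarray
    p_value: float
    shared_genes: frozenset[str]
    shared_edges: frozenset[tuple[str, str]]
    significant: bool

    def recount_p(self) -> float:
        """Recompute p from the stored null counts (exact integer arithmetic)."""
        s = sum(1 for c in self.null_counts if c > self.observed_inter_edges)
        return s / len(self.null_counts)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def inter_module_edges(
    net: nx.Graph, a: GeneModule, b: GeneModule
) -> tuple[int, list[tuple[str, str]]]:
    """Edges between exclusive members of the two modules.

    Edges with an endpoint in the member intersection are excluded here;
    :func:`shared_elements` reports them.
    """
    only_a = a.members - b.members
    only_b = b.members - a.members
    edges = []
    small, other = (only_a, only_b) if len(only_a) <= len(only_b) else (only_b, only_a)
    for u in small:
        if u not in net:
            continue
        for v in net[u]:
            if v in other:
                edges.append((u, v) if small is only_a else (v, u))
    edges.sort()
    return len(edges), edges


def shared_elements(
    a: GeneModule, b: GeneModule, net: nx.Graph
) -> tuple[set[str], set[tuple[str, str]]]:
    """Common genes (member intersection) and the network edges inside it."""
    common = set(a.members & b.members)
    edges: set[tuple[str, str]] = set()
    for u in common:
        if u not in net:
            continue
        for v in net[u]:
            if v in common:
                edges.add(tuple(sorted((u, v))))
    return common, edges


# ---------------------------------------------------------------------------
# degree-preserving randomization
# ---------------------------------------------------------------------------

def randomize_network(
    net: nx.Graph,
    rng_seed: int,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> nx.Graph:
    """Rewire by double edge swaps, preserving every node's degree exactly.

    Performs ``swaps_per_edge * |E|`` successful swaps (uniform edge-pair
    proposals with random orientation); proposals that would create a
    self-loop or parallel edge are rejected and retried.  If the proposal
    budget is exhausted first — as on rigid graphs like a triangle, whose
    degree sequence admits a single simple graph — the current (still
    degree-identical) network is returned with a log message.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    m = net.number_of_edges()
    if m < 2:
        logger.info("fewer than 2 edges; returning the network unchanged")
        return net.copy()
    rng = np.random.default_rng(rng_seed)
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    eset = {(min(u, v), max(u, v)) for u, v in edges}

    target = swaps_per_edge * m
    max_attempts = 200 * target
    swaps = attempts = 0
    batch = 4096
    while swaps < target and attempts < max_attempts:
        idx = rng.integers(0, m, size=(batch, 2))
        flips = rng.integers(0, 2, size=batch)
        for (i, j), flip in zip(idx, flips):
            attempts += 1
            if swaps >= target or attempts > max_attempts:
                break
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if flip:
                x, y = y, x
            # propose u-x and v-y
            if u == x or v == y:
                continue
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in eset or e2 in eset:
                continue
            eset.discard((min(u, v), max(u, v)))
            eset.discard((min(edges[j][0], edges[j][1]), max(edges[j][0], edges[j][1])))
            eset.add(e1)
            eset.add(e2)
            edges[i] = (u, x)
            edges[j] = (v, y)
            swaps += 1
    if swaps < target:
        logger.info(
            "edge-swap budget exhausted after %d attempts (%d/%d swaps done)",
            attempts, swaps, target,
        )
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[u], nodes[v]) for u, v in edges)
    return out


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------

def _membership_arrays(
    nodes: list[str],
    inflammation_modules: list[GeneModule],
    cancer_modules: list[GeneModule],
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    index = {v: i for i, v in enumerate(nodes)}
    im = np.full(len(nodes), -1, dtype=np.int64)
    cm = np.full(len(nodes), -1, dtype=np.int64)
    for k, mod in enumerate(inflammation_modules):
        for g in mod.members:
            if g in index:
                im[index[g]] = k
    for k, mod in enumerate(cancer_modules):
        for g in mod.members:
            if g in index:
                cm[index[g]] = k
    return index, im, cm


def _pair_count_matrix(
    eu: np.ndarray, ev: np.ndarray,
    im: np.ndarray, cm: np.ndarray,
    n_inflammation: int, n_cancer: int,
) -> np.ndarray:
    """Inter-edge counts for every (inflammation, cancer) module pair.

    An edge (u, v) counts for pair (A, B) when u is an exclusive member of A
    (in A, not in B) and v an exclusive member of B, in either orientation.
    """
    counts = np.zeros((n_inflammation, n_cancer), dtype=np.int64)
    for a, b in ((eu, ev), (ev, eu)):
        ia = im[a]
        cb = cm[b]
        mask = (ia >= 0) & (cb >= 0)
        # exclusivity: u must not belong to the cancer module of the pair,
        # v must not belong to the inflammation module of the pair
        mask &= cm[a] != cb
        mask &= im[b] != ia
        np.add.at(counts, (ia[mask], cb[mask]), 1)
    return counts


def _edge_index_arrays(net: nx.Graph, index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    if net.number_of_edges() == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    eu, ev = zip(*((index[u], index[v]) for u, v in net.edges))
    return np.asarray(eu, dtype=np.int64), np.asarray(ev, dtype=np.int64)


def crosstalk_test(
    net: nx.Graph,
    inflammation_modules: list[GeneModule],
    cancer_modules: list[GeneModule],
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    alpha: float = DEFAULT_ALPHA,
    conservative: bool = False,
) -> list[CrosstalkResult]:
    """Test every inflammation x cancer pair against one randomized ensemble.

    All pairs share the same ``n_random`` degree-preserving randomizations of
    the full network, mirroring a single global set of random networks.
    """
    if not inflammation_modules or not cancer_modules:
        logger.info("no modules on one side; crosstalk test skipped")
        return []
    nodes = list(net.nodes)
    index, im, cm = _membership_arrays(nodes, inflammation_modules, cancer_modules)
    n_i, n_c = len(inflammation_modules), len(cancer_modules)

    eu, ev = _edge_index_arrays(net, index)
    observed = _pair_count_matrix(eu, ev, im, cm, n_i, n_c)

    seeds = np.random.SeedSequence(rng_seed).generate_state(n_random) % (2**31)
    null = np.zeros((n_random, n_i, n_c), dtype=np.int64)
    for r in range(n_random):
        rand_net = randomize_network(net, int(seeds[r]), swaps_per_edge)
        ru, rv = _edge_index_arrays(rand_net, index)
        null[r] = _pair_count_matrix(ru, rv, im, cm, n_i, n_c)

    results = []
    for i, mod_a in enumerate(inflammation_modules):
        for j, mod_b in enumerate(cancer_modules):
            obs = int(observed[i, j])
            counts = null[:, i, j]
            if conservative:
                p = (int((counts >= obs).sum()) + 1) / (n_random + 1)
            else:
                p = int((counts > obs).sum()) / n_random
            genes, edges = shared_elements(mod_a, mod_b, net)
            results.append(
                CrosstalkResult(
                    pair=(mod_a.module_id, mod_b.module_id),
                    observed_inter_edges=obs,
                    null_counts=counts.copy(),
                    p_value=p,
                    shared_genes=frozenset(genes),
                    shared_edges=frozenset(edges),
                    significant=p < alpha,
                )
            )
    return results


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_crosstalk_table(path, results: list[CrosstalkResult]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "inflammation_module\tcancer_module\tobserved\tnull_mean\tp\t"
            "significant\tn_shared_genes\tn_shared_edges\n"
        )
        for r in results:
            fh.write(
                f"{r.pair[0][0]}:{r.pair[0][1]}\t{r.pair[1][0]}:{r.pair[1][1]}\t"
                f"{r.observed_inter_edges}\t{float(np.mean(r.null_counts)):.4g}\t"
                f"{r.p_value:.6g}\t{int(r.significant)}\t"
                f"{len(r.shared_genes)}\t{len(r.shared_edges)}\n"
            )


def significant_pair_graph(
    net: nx.Graph,
    results: list[CrosstalkResult],
    inflammation_modules: list[GeneModule],
    cancer_modules: list[GeneModule],
) -> nx.Graph:
    """Merged subnetwork of significant pairs with edge classes
    {intra, crosstalk, common}."""
    by_id = {m.module_id: m for m in inflammation_modules + cancer_modules}
    out = nx.Graph()
    for r in results:
        if not r.significant:
            continue
        a, b = by_id[r.pair[0]], by_id[r.pair[1]]
        members = a.members | b.members
        for u in sorted(members):
            if u not in net:
                continue
            out.add_node(u)
            for v in sorted(net[u]):
                if v not in members or out.has_edge(u, v):
                    continue
                common = u in r.shared_genes or v in r.shared_genes
                in_a = u in a.members and v in a.members
                in_b = u in b.members and v in b.members
                if common:
                    cls = "common"
                elif in_a or in_b:
                    cls = "intra"
                else:
                    cls = "crosstalk"
                out.add_edge(u, v, edge_class=cls, score=net[u][v].get("score", 1.0))
    return out
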