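"""Synthetic study generator with planted, enumerable ground truth.

Emulates the three data layers of a two-disease module-crosstalk study:

* an interactome: a preferential-attachment background (right-skewed degree
  distribution, so degree-preserving nulls are non-trivial) over which dense
  disease modules are overlaid by *adding* edges — planted internal density
  is therefore a lower bound — plus planted inter-module edge excess for
  chosen module pairs;
* multi-dataset expression: per disease context several independent
  datasets in which the planted DEGs are shifted by a configured effect
  size, with directions consistent across the context's datasets and all
  other genes drawn from one Gaussian null;
* a regulator->target map with planted dual-module pivots among uniform
  decoy regulators.

Every planted claim is recorded in :class:`PlantedTruth` and can be checked
by direct enumeration on the emitted files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .degs import DOWN, UP, ExpressionDataset
from .regulators import MIRNA, TF, RegulatorTargetMap

INFLAMMATION = "inflammation"
CANCER = "cancer"
CONTEXTS = (INFLAMMATION, CANCER)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModuleSpec:
    size: int
    internal_density: float
    context: str


@dataclass(frozen=True)
class PlantedCrosstalkSpec:
    """Planted inter-edge count between two modules (list indices).

    ``extra_inter_edges`` is the exact total number of edges joining
    non-shared members of the pair after planting; background edges already
    crossing the pair count toward it.
    """

    module_i: int
    module_j: int
    extra_inter_edges: int


@dataclass(frozen=True)
class PlantedPivotSpec:
    regulator_id: str
    module_i: int
    module_j: int
    targets_per_module: int
    regulator_type: str = TF


@dataclass
class SyntheticConfig:
    rng_seed: int = 0
    n_genes: int = 1000
    background_attachment: int = 2
    planted_modules: list[PlantedModuleSpec] = field(default_factory=list)
    planted_crosstalk: list[PlantedCrosstalkSpec] = field(default_factory=list)
    n_datasets_per_context: int = 3
    samples_per_group: int = 10
    deg_effect_size: float = 5.0
    noise_sd: float = 1.0
    background_deg_fraction: float = 0.3
    n_regulators: int = 30
    targets_per_decoy: int = 20
    planted_pivots: list[PlantedPivotSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.background_attachment <= 0:
            raise ValueError("background_attachment must be positive")
        if self.n_datasets_per_context <= 0:
            raise ValueError("n_datasets_per_context must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.background_deg_fraction <= 1.0:
            raise ValueError("background_deg_fraction must be in [0,1]")
        if self.n_regulators < 0 or self.targets_per_decoy <= 0:
            raise ValueError("regulator counts must be positive")
        for spec in self.planted_modules:
            if spec.context not in CONTEXTS:
                raise ValueError(f"unknown context {spec.context!r}")
            if not 0.0 < spec.internal_density <= 1.0:
                raise ValueError("internal_density must be in (0,1]")
            if spec.size < 2:
                raise ValueError(
                    f"planted module of size {spec.size}: density is undefined "
                    "below 2 genes"
                )
        if sum(s.size for s in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        n_mod = len(self.planted_modules)
        for ct in self.planted_crosstalk:
            if not (0 <= ct.module_i < n_mod and 0 <= ct.module_j < n_mod):
                raise ValueError("crosstalk spec references a missing module")
            if ct.module_i == ct.module_j:
                raise ValueError("crosstalk requires two distinct modules")
            if ct.extra_inter_edges <= 0:
                raise ValueError("extra_inter_edges must be positive")
        for pv in self.planted_pivots:
            for idx in (pv.module_i, pv.module_j):
                if not 0 <= idx < n_mod:
                    raise ValueError("pivot spec references a missing module")
                if pv.targets_per_module > self.planted_modules[idx].size:
                    raise ValueError(
                        f"pivot {pv.regulator_id}: targets_per_module "
                        f"{pv.targets_per_module} exceeds module size "
                        f"{self.planted_modules[idx].size}"
                    )
            if pv.targets_per_module <= 0:
                raise ValueError("targets_per_module must be positive")
            if pv.regulator_type not in (TF, MIRNA):
                raise ValueError(f"unknown regulator type {pv.regulator_type!r}")


@dataclass
class PlantedTruth:
    """Enumerable ground truth for a generated study."""

    module_members: list[frozenset[str]]  # by planted-module index
    module_contexts: list[str]
    module_memberships: dict[str, int]  # gene -> planted module index
    inter_edge_counts: dict[tuple[int, int], int]  # crosstalk pair -> total
    true_deg_sets: dict[str, dict[str, str]]  # context -> gene -> up|down
    true_pivots: set[tuple[str, tuple[int, int]]]

    def modules_of(self, context: str) -> list[int]:
        return [i for i, c in enumerate(self.module_contexts) if c == context]


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def default_config(rng_seed: int = 0) -> SyntheticConfig:
    """The standard synthetic study: 5 modules per context (sizes 8-12,
    density 0.9), two crosstalk pairs with 12 planted inter-edges, one
    planted pivot TF and one pivot miRNA."""
    sizes = [8, 10, 12, 9, 11]
    modules = [PlantedModuleSpec(s, 0.9, INFLAMMATION) for s in sizes]
    modules += [PlantedModuleSpec(s, 0.9, CANCER) for s in sizes]
    return SyntheticConfig(
        rng_seed=rng_seed,
        planted_modules=modules,
        planted_crosstalk=[
            PlantedCrosstalkSpec(0, 5, 12),
            PlantedCrosstalkSpec(1, 6, 12),
        ],
        planted_pivots=[
            PlantedPivotSpec("TF_PIVOT_1", 0, 5, 4, TF),
            PlantedPivotSpec("MIR_PIVOT_1", 1, 6, 4, MIRNA),
        ],
    )


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def _plant_module(
    net: nx.Graph, members: list[str], density: float, rng: np.random.Generator
) -> None:
    """Add edges until the members form a connected subgraph of at least the
    requested internal density (edges are never removed)."""
    size = len(members)
    required = math.ceil(density * size * (size - 1) / 2)
    if required > size * (size - 1) / 2:  # density > 1 is rejected upstream
        raise ValueError("requested density infeasible for module size")
    # random spanning tree guarantees connectivity
    perm = [members[i] for i in rng.permutation(size)]
    for i in range(1, size):
        net.add_edge(perm[i], perm[int(rng.integers(0, i))], score=1.0)
    internal = [
        (members[i], members[j])
        for i in range(size)
        for j in range(i + 1, size)
        if not net.has_edge(members[i], members[j])
    ]
    present = size * (size - 1) // 2 - len(internal)
    deficit = required - present
    if deficit > 0:
        picks = rng.choice(len(internal), size=deficit, replace=False)
        for idx in picks:
            u, v = internal[idx]
            net.add_edge(u, v, score=1.0)


def _plant_crosstalk(
    net: nx.Graph,
    spec: PlantedCrosstalkSpec,
    members_i: frozenset[str],
    members_j: frozenset[str],
    rng: np.random.Generator,
) -> int:
    only_i = sorted(members_i - members_j)
    only_j = sorted(members_j - members_i)
    existing = sum(1 for u in only_i for v in net[u] if v in members_j and v not in members_i)
    if existing > spec.extra_inter_edges:
        raise ValueError(
            f"background already has {existing} inter-edges between modules "
            f"{spec.module_i} and {spec.module_j}; cannot plant exactly "
            f"{spec.extra_inter_edges} without removing edges"
        )
    free = [
        (u, v) for u in only_i for v in only_j if not net.has_edge(u, v)
    ]
    deficit = spec.extra_inter_edges - existing
    if deficit > len(free):
        raise ValueError("not enough non-adjacent cross pairs to plant crosstalk")
    for idx in rng.choice(len(free), size=deficit, replace=False):
        u, v = free[idx]
        net.add_edge(u, v, score=1.0)
    return spec.extra_inter_edges


def generate_interactome(config: SyntheticConfig) -> tuple[nx.Graph, PlantedTruth]:
    config.validate()
    ss = np.random.SeedSequence([0, config.rng_seed])
    rng = np.random.default_rng(ss)
    genes = gene_ids(config.n_genes)

    nx_seed = int(rng.integers(0, 2**31))
    net = nx.barabasi_albert_graph(
        config.n_genes, config.background_attachment, seed=nx_seed
    )
    net = nx.relabel_nodes(net, dict(enumerate(genes)))
    nx.set_edge_attributes(net, 1.0, "score")

    total_planted = sum(s.size for s in config.planted_modules)
    chosen = rng.choice(config.n_genes, size=total_planted, replace=False)
    module_members: list[frozenset[str]] = []
    offset = 0
    for spec in config.planted_modules:
        members = [genes[i] for i in chosen[offset:offset + spec.size]]
        offset += spec.size
        _plant_module(net, members, spec.internal_density, rng)
        module_members.append(frozenset(members))

    inter_counts: dict[tuple[int, int], int] = {}
    for ct in config.planted_crosstalk:
        inter_counts[(ct.module_i, ct.module_j)] = _plant_crosstalk(
            net, ct, module_members[ct.module_i], module_members[ct.module_j], rng
        )

    memberships = {
        g: idx for idx, members in enumerate(module_members) for g in members
    }

    # planted DEGs: module members of the context plus a uniform slice of the
    # remaining genes, with one consistent direction per gene per context
    true_degs: dict[str, dict[str, str]] = {}
    module_gene_pool = set(memberships)
    background_pool = sorted(set(genes) - module_gene_pool)
    for context in CONTEXTS:
        degs: dict[str, str] = {}
        for idx, members in enumerate(module_members):
            if config.planted_modules[idx].context != context:
                continue
            for g in sorted(members):
                degs[g] = UP if rng.random() < 0.5 else DOWN
        n_background = int(round(config.background_deg_fraction * len(background_pool)))
        if n_background:
            picks = rng.choice(len(background_pool), size=n_background, replace=False)
            for i in picks:
                degs[background_pool[i]] = UP if rng.random() < 0.5 else DOWN
        true_degs[context] = degs

    truth = PlantedTruth(
        module_members=module_members,
        module_contexts=[s.context for s in config.planted_modules],
        module_memberships=memberships,
        inter_edge_counts=inter_counts,
        true_deg_sets=true_degs,
        true_pivots={
            (pv.regulator_id, (pv.module_i, pv.module_j))
            for pv in config.planted_pivots
        },
    )
    return net, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig, truth: PlantedTruth
) -> list[ExpressionDataset]:
    """Per context, ``n_datasets_per_context`` independent datasets with the
    planted DEGs shifted by ``deg_effect_size * noise_sd`` consistently."""
    config.validate()
    if config.samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2 (variance undefined)")
    rng = np.random.default_rng(np.random.SeedSequence([1, config.rng_seed]))
    genes = gene_ids(config.n_genes)
    spg = config.samples_per_group
    shift = config.deg_effect_size * config.noise_sd

    datasets = []
    for context in CONTEXTS:
        degs = truth.true_deg_sets.get(context, {})
        offsets = np.zeros(len(genes))
        for i, g in enumerate(genes):
            if g in degs:
                offsets[i] = shift if degs[g] == UP else -shift
        for k in range(config.n_datasets_per_context):
            dataset_id = f"{context}_ds{k + 1}"
            values = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * spg))
            values[:, :spg] += offsets[:, None]  # first block = disease
            samples = [f"{dataset_id}_s{j + 1}" for j in range(2 * spg)]
            labels = {
                s: ("disease" if j < spg else "normal")
                for j, s in enumerate(samples)
            }
            datasets.append(
                ExpressionDataset(
                    dataset_id=dataset_id,
                    genes=list(genes),
                    samples=samples,
                    values=values,
                    group_labels=labels,
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# regulators
# ---------------------------------------------------------------------------

def generate_regulator_map(
    config: SyntheticConfig, truth: PlantedTruth
) -> RegulatorTargetMap:
    """Planted pivots target both of their modules; decoys draw targets
    uniformly from the whole gene universe."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([2, config.rng_seed]))
    genes = gene_ids(config.n_genes)
    rmap = RegulatorTargetMap()

    for pv in config.planted_pivots:
        targets: set[str] = set()
        for idx in (pv.module_i, pv.module_j):
            members = sorted(truth.module_members[idx])
            picks = rng.choice(len(members), size=pv.targets_per_module, replace=False)
            targets |= {members[i] for i in picks}
        # pad with uniform off-module targets up to the decoy target count
        pad = max(0, config.targets_per_decoy - len(targets))
        pool = sorted(set(genes) - targets)
        if pad:
            picks = rng.choice(len(pool), size=pad, replace=False)
            targets |= {pool[i] for i in picks}
        rmap.add(pv.regulator_id, pv.regulator_type, targets, source="planted")

    for d in range(config.n_regulators):
        rtype = TF if d % 2 == 0 else MIRNA
        name = f"{'TF' if rtype == TF else 'MIR'}_DECOY_{d + 1:03d}"
        picks = rng.choice(config.n_genes, size=config.targets_per_decoy, replace=False)
        rmap.add(name, rtype, {genes[i] for i in picks}, source="decoy")
    return rmap


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_regulator_table(rmap: RegulatorTargetMap, path: str | Path) -> None:
    """Generator dialect: regulator TAB type TAB target."""
    with open(path, "w") as fh:
        for reg in sorted(rmap.entries):
            rtype, targets = rmap.entries[reg]
            for t in sorted(targets):
                fh.write(f"{reg}\t{rtype}\t{t}\n")


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "module_members": [sorted(m) for m in truth.module_members],
        "module_contexts": truth.module_contexts,
        "inter_edge_counts": [
            {"module_i": i, "module_j": j, "inter_edges": n}
            for (i, j), n in sorted(truth.inter_edge_counts.items())
        ],
        "true_deg_sets": {
            ctx: dict(sorted(degs.items())) for ctx, degs in truth.true_deg_sets.items()
        },
        "true_pivots": [
            {"regulator": r, "module_i": p[0], "module_j": p[1]}
            for r, p in sorted(truth.true_pivots)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> PlantedTruth:
    with open(path) as fh:
        payload = json.load(fh)
    members = [frozenset(m) for m in payload["module_members"]]
    memberships = {g: i for i, ms in enumerate(members) for g in ms}
    return PlantedTruth(
        module_members=members,
        module_contexts=list(payload["module_contexts"]),
        module_memberships=memberships,
        inter_edge_counts={
            (e["module_i"], e["module_j"]): e["inter_edges"]
            for e in payload["inter_edge_counts"]
        },
        true_deg_sets={
            ctx: dict(d) for ctx, d in payload["true_deg_sets"].items()
        },
        true_pivots={
            (e["regulator"], (e["module_i"], e["module_j"]))
            for e in payload["true_pivots"]
        },
    )
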