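import networkx as nx
import numpy as np
import pytest

from modcross import ExpressionDataset
from modcross import synthetic as syn
from modcross.mcode import GeneModule


def relabeled(graph: nx.Graph, prefix: str = "n") -> nx.Graph:
    return nx.relabel_nodes(graph, {v: f"{prefix}{v}" for v in graph.nodes})


@pytest.fixture
def k4() -> nx.Graph:
    return relabeled(nx.complete_graph(4))


@pytest.fixture
def p3() -> nx.Graph:
    return nx.relabel_nodes(nx.path_graph(3), {0: "a", 1: "b", 2: "c"})


@pytest.fixture
def two_group_dataset() -> ExpressionDataset:
    """(4,5,6) disease vs (1,2,3) normal for one gene, plus a flat gene."""
    return ExpressionDataset(
        dataset_id="toy",
        genes=["g1", "g2"],
        samples=[f"s{i}" for i in range(6)],
        values=np.array([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0],
                         [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]),
        group_labels={f"s{i}": ("disease" if i < 3 else "normal") for i in range(6)},
    )


@pytest.fixture(scope="session")
def default_study():
    """One generated default synthetic study shared across read-only tests."""
    config = syn.default_config(rng_seed=11)
    net, truth = syn.generate_interactome(config)
    return config, net, truth


def truth_modules(truth: syn.PlantedTruth) -> list[GeneModule]:
    """Wrap planted-truth member sets as GeneModule objects."""
    return [
        GeneModule(
            module_id=(truth.module_contexts[i], i + 1),
            context=truth.module_contexts[i],
            members=truth.module_members[i],
            seed_gene=min(truth.module_members[i]),
            score=0.0,
        )
        for i in range(len(truth.module_members))
    ]
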