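"""Shared fixtures: published contingency tables, random-model generators,
and the (session-scoped, seeded) simulation harnesses reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from skinbn import bayes_net, potency, synthetic_data, workflow
from skinbn.bayes_net import CPT, NetworkModel, NetworkStructure, Node
from skinbn.data_model import PotencyClass

# ---------------------------------------------------------------------------
# published contingency tables (predicted rows x reference columns, order
# NS / weak / moderate / strong-extreme)
# ---------------------------------------------------------------------------

TRAIN_4CLASS = np.array(
    [
        [55, 12, 7, 1],
        [7, 20, 8, 6],
        [4, 2, 14, 6],
        [3, 5, 18, 51],
    ]
)
TEST_4CLASS = np.array(
    [
        [20, 1, 2, 0],
        [6, 7, 6, 1],
        [0, 2, 5, 3],
        [2, 7, 7, 9],
    ]
)

#: Empirical training-set class priors (NS, weak, moderate, strong/extreme).
TRAINING_PRIORS = np.array([69.0, 39.0, 47.0, 64.0]) / 219.0


def pairs_from_matrix(matrix) -> tuple[list[PotencyClass], list[PotencyClass]]:
    """Expand a predicted x reference count matrix into the pair multiset."""
    preds, refs = [], []
    for i in range(4):
        for j in range(4):
            preds.extend([PotencyClass(i)] * int(matrix[i, j]))
            refs.extend([PotencyClass(j)] * int(matrix[i, j]))
    return preds, refs


# ---------------------------------------------------------------------------
# random small networks (for inference-oracle and serialization tests)
# ---------------------------------------------------------------------------


def random_model(rng: np.random.Generator, max_extra_nodes: int = 4) -> NetworkModel:
    """A random small DAG model with a 4-state target and random CPTs."""
    n_extra = int(rng.integers(1, max_extra_nodes + 1))
    nodes = [Node("target", 4, "target")]
    for i in range(n_extra):
        kind = "latent" if rng.uniform() < 0.3 else "input"
        nodes.append(Node(f"n{i}", int(rng.integers(2, 4)), kind))
    order = rng.permutation(len(nodes))
    arcs = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if rng.uniform() < 0.5:
                arcs.append((nodes[order[a]].name, nodes[order[b]].name))
    structure = NetworkStructure(nodes=tuple(nodes), arcs=tuple(arcs))
    cards = structure.cards()
    cpts = {}
    for node in structure.node_names:
        parents = structure.parents(node)
        shape = tuple(cards[p] for p in parents) + (cards[node],)
        rows = int(np.prod(shape[:-1])) if len(shape) > 1 else 1
        table = rng.dirichlet(np.ones(shape[-1]), size=rows).reshape(shape)
        cpts[node] = CPT(node, parents, table)
    return NetworkModel(structure=structure, cpts=cpts)


def random_evidence(rng: np.random.Generator, model: NetworkModel) -> dict[str, int]:
    cards = model.structure.cards()
    evidence = {}
    for node in model.structure.nodes:
        if node.kind == "input" and rng.uniform() < 0.6:
            evidence[node.name] = int(rng.integers(0, cards[node.name]))
    return evidence


# ---------------------------------------------------------------------------
# known latent model for the parameter-recovery harness
# ---------------------------------------------------------------------------


def recovery_truth() -> NetworkModel:
    """Known 4-node model: target -> observed X1, target -> latent L -> X2."""
    nodes = (
        Node("target", 4, "target"),
        Node("x1", 3, "input"),
        Node("latent", 3, "latent"),
        Node("x2", 3, "input"),
    )
    arcs = (("target", "x1"), ("target", "latent"), ("latent", "x2"))
    structure = NetworkStructure(nodes=nodes, arcs=arcs)
    prior = np.array([0.35, 0.18, 0.22, 0.25])
    x1_given_t = np.array(
        [
            [0.75, 0.15, 0.10],
            [0.20, 0.65, 0.15],
            [0.15, 0.25, 0.60],
            [0.05, 0.20, 0.75],
        ]
    )
    l_given_t = np.array(
        [
            [0.80, 0.15, 0.05],
            [0.30, 0.55, 0.15],
            [0.15, 0.55, 0.30],
            [0.05, 0.20, 0.75],
        ]
    )
    x2_given_l = np.array(
        [
            [0.70, 0.20, 0.10],
            [0.15, 0.70, 0.15],
            [0.10, 0.20, 0.70],
        ]
    )
    cpts = {
        "target": CPT("target", (), prior),
        "x1": CPT("x1", ("target",), x1_given_t),
        "latent": CPT("latent", ("target",), l_given_t),
        "x2": CPT("x2", ("latent",), x2_given_l),
    }
    return NetworkModel(structure=structure, cpts=cpts, class_priors=prior)


def ancestral_sample(
    model: NetworkModel, n: int, rng: np.random.Generator
) -> list[dict[str, int]]:
    """Sample full joint assignments, then hide the latent nodes."""
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(model.structure.node_names)
    graph.add_edges_from(model.structure.arcs)
    topo = list(nx.topological_sort(graph))
    kinds = model.structure.kinds()
    records = []
    for _ in range(n):
        assignment: dict[str, int] = {}
        for node in topo:
            cpt = model.cpts[node]
            idx = tuple(assignment[p] for p in cpt.parent_order)
            probs = cpt.table[idx]
            assignment[node] = int(rng.choice(len(probs), p=probs))
        records.append(
            {k: v for k, v in assignment.items() if kinds[k] != "latent"}
        )
    return records


# ---------------------------------------------------------------------------
# session-scoped simulation harnesses (expensive; computed once)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def end_to_end():
    """Default-generator pipeline: 500 train / 200 test, fixed seeds."""
    train = synthetic_data.generate_substances(
        synthetic_data.GeneratorConfig(n=500, seed=11)
    )
    test = synthetic_data.generate_substances(
        synthetic_data.GeneratorConfig(n=200, seed=12)
    )
    model = workflow.train_model(train, seed=0, max_iter=80, tol=1e-4)
    profiles = [workflow.predict_profile(model, rec) for rec in test]
    references = [rec.reference_class() for rec in test]
    predictions = [potency.predicted_class(p) for p in profiles]
    accuracy = float(np.mean([p == r for p, r in zip(predictions, references)]))
    return {
        "model": model,
        "test": test,
        "profiles": profiles,
        "predictions": predictions,
        "references": references,
        "accuracy": accuracy,
    }


@pytest.fixture(scope="session")
def null_signal():
    """Same pipeline on class-independent inputs (balanced classes)."""
    marginal = np.full(4, 0.25)
    train = synthetic_data.generate_substances(
        synthetic_data.GeneratorConfig(
            n=500, seed=21, effect_size=0.0, class_marginal=marginal
        )
    )
    test = synthetic_data.generate_substances(
        synthetic_data.GeneratorConfig(
            n=200, seed=22, effect_size=0.0, class_marginal=marginal
        )
    )
    model = workflow.train_model(train, seed=0, max_iter=60, tol=1e-4)
    correct = sum(
        potency.predicted_class(workflow.predict_profile(model, rec))
        == rec.reference_class()
        for rec in test
    )
    return {"accuracy": correct / len(test), "n_test": len(test)}


@pytest.fixture(scope="session")
def recovery():
    """EM refit of data sampled from the known 4-node latent model."""
    truth = recovery_truth()
    rng = np.random.default_rng(42)
    records = ancestral_sample(truth, 2000, rng)
    fitted = bayes_net.fit_em(
        truth.structure, records, max_iter=300, tol=1e-8, seed=3, pseudocount=1.0
    )
    return {"truth": truth, "fitted": fitted, "n": len(records)}
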