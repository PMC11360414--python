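"""Structure validation, exact inference vs. brute force, EM behavior,
serialization round-trips."""

import numpy as np
import pytest

from skinbn.bayes_net import (
    CPT,
    ModelFormatError,
    NetworkModel,
    NetworkStructure,
    Node,
    StructureError,
    build_structure,
    default_config,
    enumerate_joint,
    fit_em,
    infer_profile,
    model_from_yaml,
    model_to_yaml,
)
from skinbn.data_model import ValidationError

from conftest import random_evidence, random_model


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------


def test_default_structure_counts():
    structure = build_structure(default_config())
    kinds = [n.kind for n in structure.nodes]
    assert len(structure.nodes) == 18
    assert kinds.count("input") == 13
    assert kinds.count("latent") == 4
    assert kinds.count("target") == 1
    target = next(n for n in structure.nodes if n.kind == "target")
    assert target.cardinality == 4
    # every input reaches the target through the arcs
    import networkx as nx

    graph = nx.DiGraph(list(structure.arcs))
    for node in structure.nodes:
        if node.kind == "input":
            assert nx.has_path(graph, node.name, structure.target_name)


def test_cycle_rejected():
    config = {
        "nodes": [
            {"name": "t", "kind": "target", "cardinality": 4},
            {"name": "a", "kind": "input", "cardinality": 2},
            {"name": "b", "kind": "input", "cardinality": 2},
        ],
        "arcs": [["a", "b"], ["b", "a"], ["a", "t"]],
    }
    with pytest.raises(StructureError, match="cycle"):
        build_structure(config)


def test_structure_errors():
    with pytest.raises(StructureError, match="unknown node"):
        NetworkStructure(
            nodes=(Node("t", 4, "target"),), arcs=(("t", "ghost"),)
        )
    with pytest.raises(StructureError, match="target"):
        NetworkStructure(nodes=(Node("a", 2, "input"),), arcs=())
    with pytest.raises(StructureError, match="cardinality 4"):
        NetworkStructure(nodes=(Node("t", 3, "target"),), arcs=())


def test_zero_latent_two_input_structure_is_valid():
    config = {
        "nodes": [
            {"name": "t", "kind": "target", "cardinality": 4},
            {"name": "a", "kind": "input", "cardinality": 2},
            {"name": "b", "kind": "input", "cardinality": 3},
        ],
        "arcs": [["t", "a"], ["t", "b"]],
    }
    structure = build_structure(config)
    assert structure.parents("a") == ("t",)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _two_node_model() -> NetworkModel:
    """Binary question embedded in the 4-state target: prior (.5,.5,0,0),
    child X with P(x=1|t0)=0.2, P(x=1|t1)=0.9."""
    structure = NetworkStructure(
        nodes=(Node("target", 4, "target"), Node("x", 2, "input")),
        arcs=(("target", "x"),),
    )
    cpts = {
        "target": CPT("target", (), np.array([0.5, 0.5, 0.0, 0.0])),
        "x": CPT(
            "x",
            ("target",),
            np.array([[0.8, 0.2], [0.1, 0.9], [0.5, 0.5], [0.5, 0.5]]),
        ),
    }
    return NetworkModel(structure=structure, cpts=cpts)


def test_hand_computed_posterior():
    model = _two_node_model()
    profile = infer_profile(model, {"x": 1})
    assert profile.p_weak == pytest.approx(0.8182, abs=5e-5)  # 0.9/1.1
    assert profile.p_ns == pytest.approx(1 - 0.9 / 1.1, abs=5e-5)
    oracle = enumerate_joint(model, {"x": 1})
    assert oracle[1] == pytest.approx(0.9 / 1.1, abs=1e-12)


def test_empty_evidence_returns_marginal():
    model = _two_node_model()
    profile = infer_profile(model, {})
    assert profile.as_array() == pytest.approx([0.5, 0.5, 0.0, 0.0], abs=1e-12)


def test_inference_matches_enumeration_on_random_models():
    """Variable elimination == full-joint enumeration, 120 random models."""
    rng = np.random.default_rng(2718)
    worst = 0.0
    for _ in range(120):
        model = random_model(rng)
        evidence = random_evidence(rng, model)
        try:
            ve = infer_profile(model, evidence).as_array()
            brute = enumerate_joint(model, evidence)
        except ValidationError:
            continue  # zero-probability evidence draw
        worst = max(worst, float(np.max(np.abs(ve - brute))))
    assert worst < 1e-9


def test_evidence_validation():
    model = _two_node_model()
    with pytest.raises(ValidationError, match="outside cardinality"):
        infer_profile(model, {"x": 5})
    with pytest.raises(ValidationError, match="target"):
        infer_profile(model, {"target": 1})
    with pytest.raises(ValidationError, match="unknown"):
        infer_profile(model, {"ghost": 0})
    latent_model = random_model(np.random.default_rng(1))
    for node in latent_model.structure.nodes:
        if node.kind == "latent":
            with pytest.raises(ValidationError, match="latent"):
                infer_profile(latent_model, {node.name: 0})
            break


def test_enumeration_refuses_large_state_space():
    model = _two_node_model()
    with pytest.raises(ValidationError, match="state space"):
        enumerate_joint(model, {}, max_states=3)


def test_marginalizing_a_leaf_equals_absent_evidence():
    """Posterior with a leaf input unobserved == posterior of the model
    with that leaf removed (missing-data contract)."""
    rng = np.random.default_rng(515)
    checked = 0
    while checked < 20:
        model = random_model(rng)
        structure = model.structure
        children = {p for p, _ in structure.arcs}
        leaves = [
            n.name
            for n in structure.nodes
            if n.kind == "input" and n.name not in children
        ]
        if not leaves:
            continue
        leaf = leaves[0]
        reduced = NetworkModel(
            structure=NetworkStructure(
                nodes=tuple(n for n in structure.nodes if n.name != leaf),
                arcs=tuple(a for a in structure.arcs if leaf not in a),
            ),
            cpts={k: v for k, v in model.cpts.items() if k != leaf},
        )
        evidence = {
            k: v for k, v in random_evidence(rng, model).items() if k != leaf
        }
        full = infer_profile(model, evidence).as_array()
        marginalized = infer_profile(reduced, evidence).as_array()
        assert full == pytest.approx(marginalized, abs=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _observed_chain():
    structure = NetworkStructure(
        nodes=(Node("target", 4, "target"), Node("x", 3, "input")),
        arcs=(("target", "x"),),
    )
    rng = np.random.default_rng(77)
    records = []
    for _ in range(120):
        t = int(rng.integers(0, 4))
        x = int(rng.integers(0, 3)) if t < 2 else int(rng.integers(1, 3))
        records.append({"target": t, "x": x})
    return structure, records


def test_fully_observed_em_equals_counting():
    """Without latent nodes or gaps, EM reduces to smoothed frequencies."""
    structure, records = _observed_chain()
    model = fit_em(structure, records, max_iter=10, seed=4, pseudocount=1.0)
    t_counts = np.bincount([r["target"] for r in records], minlength=4)
    expected_prior = (t_counts + 1) / (t_counts.sum() + 4)
    assert model.cpts["target"].table == pytest.approx(expected_prior, abs=1e-12)
    joint = np.zeros((4, 3))
    for rec in records:
        joint[rec["target"], rec["x"]] += 1
    expected = (joint + 1) / (joint + 1).sum(axis=1, keepdims=True)
    assert model.cpts["x"].table == pytest.approx(expected, abs=1e-12)
    # empirical (unsmoothed) class priors feed the Bayes factors
    assert model.class_priors == pytest.approx(t_counts / t_counts.sum())


def test_em_is_seed_reproducible():
    structure, records = _observed_chain()
    a = fit_em(structure, records, max_iter=15, seed=9)
    b = fit_em(structure, records, max_iter=15, seed=9)
    assert a.equals(b)  # bit-identical CPTs, priors and metadata


def test_em_ve_fallback_matches_enumeration():
    """E-step via per-family variable elimination == enumeration E-step."""
    truth_records = [
        {"target": t % 4, "x1": (t + 1) % 3, "x2": t % 3} for t in range(40)
    ]
    structure = NetworkStructure(
        nodes=(
            Node("target", 4, "target"),
            Node("x1", 3, "input"),
            Node("latent", 2, "latent"),
            Node("x2", 3, "input"),
        ),
        arcs=(("target", "x1"), ("target", "latent"), ("latent", "x2")),
    )
    by_enum = fit_em(structure, truth_records, max_iter=20, seed=6)
    by_ve = fit_em(structure, truth_records, max_iter=20, seed=6, enumeration_cap=1)
    for node in structure.node_names:  # same statistics up to float noise
        assert by_ve.cpts[node].table == pytest.approx(
            by_enum.cpts[node].table, abs=1e-12
        )
    assert by_ve.training_meta.final_log_likelihood == pytest.approx(
        by_enum.training_meta.final_log_likelihood, abs=1e-9
    )


def test_em_single_class_training():
    structure, _ = _observed_chain()
    records = [{"target": 2, "x": i % 3} for i in range(30)]
    model = fit_em(structure, records, max_iter=5, seed=1)
    # priors degenerate at the one observed class, up to smoothing
    assert np.argmax(model.class_priors) == 2
    assert model.class_priors[2] == pytest.approx((30 + 1) / 34)


def test_em_input_validation():
    structure, records = _observed_chain()
    with pytest.raises(ValidationError):
        fit_em(structure, [])
    with pytest.raises(ValidationError, match="target"):
        fit_em(structure, [{"x": 1}])


def test_parameter_recovery_with_latent_node(recovery):
    """Refit of data from a known latent model recovers the identifiable
    parameters (observed-parent CPTs and the latent-marginalized
    predictive P(x2|target)) within 0.05."""
    truth, fitted = recovery["truth"], recovery["fitted"]
    assert np.max(np.abs(
        fitted.cpts["target"].table - truth.cpts["target"].table
    )) < 0.05
    assert np.max(np.abs(
        fitted.cpts["x1"].table - truth.cpts["x1"].table
    )) < 0.05
    implied_true = truth.cpts["latent"].table @ truth.cpts["x2"].table
    implied_fit = fitted.cpts["latent"].table @ fitted.cpts["x2"].table
    assert np.max(np.abs(implied_fit - implied_true)) < 0.05


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_model_round_trip_is_lossless():
    rng = np.random.default_rng(33)
    model = random_model(rng)
    text = model_to_yaml(model)
    assert model_from_yaml(text).equals(model)


def test_untrained_default_skeleton_round_trips():
    structure = build_structure(default_config())
    cards = structure.cards()
    cpts = {}
    for node in structure.node_names:
        parents = structure.parents(node)
        shape = tuple(cards[p] for p in parents) + (cards[node],)
        cpts[node] = CPT(node, parents, np.full(shape, 1.0 / shape[-1]))
    skeleton = NetworkModel(structure=structure, cpts=cpts)
    assert model_from_yaml(model_to_yaml(skeleton)).equals(skeleton)


def test_tampered_cpt_rejected():
    model = _two_node_model()
    text = model_to_yaml(model)
    bad = text.replace("- 0.8", "- 0.7", 1)
    with pytest.raises(ModelFormatError, match="sum to 1"):
        model_from_yaml(bad)


def test_schema_version_mismatch_rejected():
    model = _two_node_model()
    text = model_to_yaml(model).replace(
        "skinbn_model_version: 1", "skinbn_model_version: 99"
    )
    with pytest.raises(ModelFormatError, match="version"):
        model_from_yaml(text)
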