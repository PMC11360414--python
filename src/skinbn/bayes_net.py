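"""Discrete Bayesian network: structure, EM fitting, exact inference.

The network predicts the 4-class LLNA potency of a substance from
categorical evidence.  Its structure is supplied, not learned: observed
input nodes (discretized assay values, categorical calls) feed a small set
of latent summary nodes -- bioavailability, metabolism, cysteine reactivity
and the U-SENS axis -- which, together with the inputs wired directly,
parent the 4-state target node.

Parameters are learned by Expectation-Maximization, which handles both the
never-observed latent nodes and missing/inconclusive inputs: the E-step
computes exact expected family counts per record (by enumerating the few
unobserved variables, or by variable elimination when that space is large),
the M-step re-estimates every conditional probability table with additive
pseudocount smoothing.  The smoothed (Dirichlet-penalized) log-likelihood
objective is checked to be non-decreasing at every iteration, and fitting
is bit-reproducible from the seed.

Inference is exact (variable elimination); ``enumerate_joint`` provides an
independent brute-force oracle over the full joint for small models.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import yaml

from ._factors import Factor, variable_elimination
from .data_model import ValidationError
from .discretization import DiscretizationSpec
from .potency import ProbabilityProfile

__all__ = [
    "Node",
    "NetworkStructure",
    "CPT",
    "TrainingMeta",
    "NetworkModel",
    "StructureError",
    "ModelFormatError",
    "build_structure",
    "default_config",
    "fit_em",
    "infer_profile",
    "enumerate_joint",
    "save_model",
    "load_model",
    "model_to_yaml",
    "model_from_yaml",
]

MODEL_SCHEMA_VERSION = 1

NODE_KINDS = ("input", "latent", "target")


class StructureError(ValidationError):
    """Invalid network structure (cycle, bad target, unknown node...)."""


class ModelFormatError(ValidationError):
    """Model document cannot be parsed or fails validation."""


@dataclass(frozen=True)
class Node:
    name: str
    cardinality: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise StructureError(f"{self.name}: unknown node kind {self.kind!r}")
        if self.cardinality < 1:
            raise StructureError(f"{self.name}: cardinality must be >= 1")


@dataclass(frozen=True)
class NetworkStructure:
    """Validated DAG over input, latent and target nodes."""

    nodes: tuple[Node, ...]
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "arcs", tuple((str(p), str(c)) for p, c in self.arcs)
        )
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise StructureError("duplicate node names")
        known = set(names)
        for parent, child in self.arcs:
            if parent not in known or child not in known:
                raise StructureError(f"arc ({parent} -> {child}) references unknown node")
        targets = [n for n in self.nodes if n.kind == "target"]
        if len(targets) != 1:
            raise StructureError(f"exactly one target node required, found {len(targets)}")
        if targets[0].cardinality != 4:
            raise StructureError("target node must have cardinality 4 (potency classes)")
        graph = nx.DiGraph()
        graph.add_nodes_from(names)
        graph.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(graph):
            raise StructureError("network graph contains a cycle")

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def target_name(self) -> str:
        return next(n.name for n in self.nodes if n.kind == "target")

    def cards(self) -> dict[str, int]:
        return {n.name: n.cardinality for n in self.nodes}

    def kinds(self) -> dict[str, str]:
        return {n.name: n.kind for n in self.nodes}

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of ``name`` in arc-declaration order (the CPT axis order)."""
        return tuple(p for p, c in self.arcs if c == name)


@dataclass
class CPT:
    """P(node | parents) as a dense table, axes ``parent_order + (node,)``."""

    node: str
    parent_order: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parent_order = tuple(self.parent_order)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != len(self.parent_order) + 1:
            raise ModelFormatError(
                f"{self.node}: CPT has {self.table.ndim} axes, "
                f"expected {len(self.parent_order) + 1}"
            )
        if np.any(self.table < 0):
            raise ModelFormatError(f"{self.node}: negative probability in CPT")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, rtol=0, atol=1e-9):
            raise ModelFormatError(
                f"{self.node}: conditional distributions must sum to 1 "
                f"(max deviation {np.abs(sums - 1).max():.3g})"
            )


@dataclass
class TrainingMeta:
    n_records: int
    em_iterations: int
    final_log_likelihood: float
    seed: int


@dataclass
class NetworkModel:
    """A (possibly fitted) network: structure, CPTs, preprocessing, priors."""

    structure: NetworkStructure
    cpts: dict[str, CPT]
    discretization: dict[str, DiscretizationSpec] = field(default_factory=dict)
    encodings: dict[str, tuple[str, ...]] = field(default_factory=dict)
    class_priors: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    training_meta: Optional[TrainingMeta] = None

    def __post_init__(self) -> None:
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if self.class_priors.shape != (4,):
            raise ModelFormatError("class_priors must have four entries")
        if abs(self.class_priors.sum() - 1.0) > 1e-9:
            raise ModelFormatError("class_priors must sum to 1 within 1e-9")
        self.encodings = {k: tuple(v) for k, v in self.encodings.items()}
        cards = self.structure.cards()
        for node in self.structure.nodes:
            cpt = self.cpts.get(node.name)
            if cpt is None:
                raise ModelFormatError(f"missing CPT for node {node.name!r}")
            expected_parents = self.structure.parents(node.name)
            if cpt.parent_order != expected_parents:
                raise ModelFormatError(
                    f"{node.name}: CPT parent order {cpt.parent_order} does not "
                    f"match structure {expected_parents}"
                )
            expected_shape = tuple(cards[p] for p in expected_parents) + (
                node.cardinality,
            )
            if cpt.table.shape != expected_shape:
                raise ModelFormatError(
                    f"{node.name}: CPT shape {cpt.table.shape} != {expected_shape}"
                )

    def equals(self, other: "NetworkModel") -> bool:
        """Bit-exact equality of structure, tables, specs, priors, metadata."""
        if self.structure != other.structure:
            return False
        for name in self.structure.node_names:
            a, b = self.cpts[name], other.cpts[name]
            if a.parent_order != b.parent_order or not np.array_equal(a.table, b.table):
                return False
        return (
            self.discretization == other.discretization
            and self.encodings == other.encodings
            and np.array_equal(self.class_priors, other.class_priors)
            and self.training_meta == other.training_meta
        )


# ---------------------------------------------------------------------------
# structure configuration
# ---------------------------------------------------------------------------

#: Shipped default structure: 13 inputs, 4 latent summaries, 1 target.
#: Physico-chemical inputs feed the bioavailability latent, TIMES-SS feeds
#: metabolism, DPRA-cysteine and the KeratinoSens readouts feed cysteine
#: reactivity, the U-SENS readouts feed the U-SENS latent; the four latents
#: plus the ToxTree domain and DPRA-lysine parent the target.  Any aspect
#: (roster, arcs, cardinalities, category levels) is overridable via a user
#: config of the same shape.
DEFAULT_NETWORK_CONFIG: dict = {
    "schema_version": 1,
    "nodes": [
        {"name": "llna_potency", "kind": "target", "cardinality": 4},
        {"name": "bioavailability", "kind": "latent", "cardinality": 3},
        {"name": "metabolism", "kind": "latent", "cardinality": 3},
        {"name": "cysteine", "kind": "latent", "cardinality": 3},
        {"name": "usens", "kind": "latent", "cardinality": 3},
        {"name": "mw", "kind": "input", "quantitative": True},
        {"name": "clogp", "kind": "input", "quantitative": True},
        {"name": "volatility", "kind": "input", "levels": ["low", "medium", "high"]},
        {"name": "times_ss_call", "kind": "input", "levels": ["negative", "positive"]},
        {
            "name": "toxtree_domain",
            "kind": "input",
            "levels": ["no_alert", "michael_acceptor", "sn_reactive"],
        },
        {"name": "dpra_cys_depletion", "kind": "input", "quantitative": True},
        {"name": "dpra_lys_depletion", "kind": "input", "quantitative": True},
        {"name": "ks_ec15", "kind": "input", "quantitative": True},
        {"name": "ks_ic50", "kind": "input", "quantitative": True},
        {"name": "ks_imax", "kind": "input", "quantitative": True},
        {"name": "usens_ec150", "kind": "input", "quantitative": True},
        {"name": "usens_cv70", "kind": "input", "quantitative": True},
        {"name": "usens_call", "kind": "input", "levels": ["negative", "positive"]},
    ],
    "arcs": [
        ["mw", "bioavailability"],
        ["clogp", "bioavailability"],
        ["volatility", "bioavailability"],
        ["times_ss_call", "metabolism"],
        ["dpra_cys_depletion", "cysteine"],
        ["ks_ec15", "cysteine"],
        ["ks_ic50", "cysteine"],
        ["ks_imax", "cysteine"],
        ["usens_ec150", "usens"],
        ["usens_cv70", "usens"],
        ["usens_call", "usens"],
        ["bioavailability", "llna_potency"],
        ["metabolism", "llna_potency"],
        ["cysteine", "llna_potency"],
        ["usens", "llna_potency"],
        ["toxtree_domain", "llna_potency"],
        ["dpra_lys_depletion", "llna_potency"],
    ],
}

DEFAULT_QUANTITATIVE_CARDINALITY = 3


def default_config() -> dict:
    """A deep copy of the shipped network configuration."""
    return copy.deepcopy(DEFAULT_NETWORK_CONFIG)


def build_structure(
    config: Mapping, quantitative_cards: Optional[Mapping[str, int]] = None
) -> NetworkStructure:
    """Build and validate a :class:`NetworkStructure` from a config mapping.

    Node entries carry ``name``, ``kind`` and one of: explicit
    ``cardinality``, categorical ``levels`` (cardinality = number of
    levels), or ``quantitative: true`` (cardinality resolved from
    ``quantitative_cards``, the fitted discretization, defaulting to 3).
    """
    if "nodes" not in config or "arcs" not in config:
        raise StructureError("network config needs 'nodes' and 'arcs' entries")
    quantitative_cards = dict(quantitative_cards or {})
    nodes = []
    for entry in config["nodes"]:
        name = entry["name"]
        kind = entry.get("kind", "input")
        if "cardinality" in entry:
            card = int(entry["cardinality"])
        elif "levels" in entry:
            card = len(entry["levels"])
        elif entry.get("quantitative"):
            card = int(quantitative_cards.get(name, DEFAULT_QUANTITATIVE_CARDINALITY))
        else:
            raise StructureError(
                f"{name}: need 'cardinality', 'levels' or 'quantitative: true'"
            )
        nodes.append(Node(name=name, cardinality=card, kind=kind))
    arcs = tuple((str(p), str(c)) for p, c in config["arcs"])
    return NetworkStructure(nodes=tuple(nodes), arcs=arcs)


def config_encodings(config: Mapping) -> dict[str, tuple[str, ...]]:
    """Category-label orderings for the categorical inputs of a config."""
    return {
        entry["name"]: tuple(entry["levels"])
        for entry in config["nodes"]
        if "levels" in entry
    }


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _check_evidence(
    structure: NetworkStructure,
    evidence: Mapping[str, int],
    allow_target: bool,
) -> dict[str, int]:
    cards = structure.cards()
    kinds = structure.kinds()
    clean: dict[str, int] = {}
    for name, value in evidence.items():
        if value is None:
            continue
        if name not in cards:
            raise ValidationError(f"evidence on unknown node {name!r}")
        if kinds[name] == "latent":
            raise ValidationError(f"evidence on latent node {name!r} is not allowed")
        if kinds[name] == "target" and not allow_target:
            raise ValidationError(f"evidence on target node {name!r} is not allowed")
        value = int(value)
        if not 0 <= value < cards[name]:
            raise ValidationError(
                f"evidence {name}={value} outside cardinality {cards[name]}"
            )
        clean[name] = value
    return clean


def _cpt_factors(structure: NetworkStructure, cpts: Mapping[str, CPT]) -> list[Factor]:
    factors = []
    for node in structure.node_names:
        cpt = cpts[node]
        factors.append(Factor(cpt.parent_order + (node,), cpt.table))
    return factors


def _enumeration_estep(node_names, parent_map, cards, tables, obs, unobs):
    """Exact per-record posterior sufficient statistics by enumeration.

    Returns ``(log_likelihood, {node: weighted family count table})`` for
    one record; ``unobs`` are the latent/missing variables enumerated.
    """
    sizes = [cards[v] for v in unobs]
    if sizes:
        grids = np.indices(sizes).reshape(len(sizes), -1)
        assign = {v: grids[i] for i, v in enumerate(unobs)}
        n_comp = grids.shape[1]
    else:
        assign = {}
        n_comp = 1
    logp = np.zeros(n_comp)
    fam_idx: dict[str, tuple] = {}
    for node in node_names:
        fam = parent_map[node] + (node,)
        idx = tuple(assign[v] if v in assign else obs[v] for v in fam)
        fam_idx[node] = idx
        with np.errstate(divide="ignore"):
            logp = logp + np.log(tables[node][idx])
    peak = logp.max()
    if not np.isfinite(peak):
        raise ValidationError("record has zero likelihood under the model")
    weights = np.exp(logp - peak)
    z = weights.sum()
    log_like = float(peak + np.log(z))
    weights /= z

    counts: dict[str, np.ndarray] = {}
    for node in node_names:
        fam = parent_map[node] + (node,)
        dims = tuple(cards[v] for v in fam)
        idx = fam_idx[node]
        if all(np.isscalar(i) for i in idx):
            table = np.zeros(dims)
            table[idx] = 1.0
        else:
            flat = np.ravel_multi_index(idx, dims, mode="raise")
            flat = np.broadcast_to(flat, (n_comp,)) if np.isscalar(flat) else flat
            table = np.bincount(
                flat, weights=weights, minlength=int(np.prod(dims))
            ).reshape(dims)
        counts[node] = table
    return log_like, counts


def _ve_estep(structure, cpts, cards, obs):
    """E-step statistics via variable elimination (large unobserved spaces)."""
    factors = _cpt_factors(structure, cpts)
    _, z = variable_elimination(factors, (), obs, cards)
    if z <= 0:
        raise ValidationError("record has zero likelihood under the model")
    log_like = float(np.log(z))
    counts: dict[str, np.ndarray] = {}
    for node in structure.node_names:
        fam = structure.parents(node) + (node,)
        dims = tuple(cards[v] for v in fam)
        unobs_fam = tuple(v for v in fam if v not in obs)
        table = np.zeros(dims)
        index = tuple(obs[v] if v in obs else slice(None) for v in fam)
        if unobs_fam:
            joint, z_fam = variable_elimination(factors, unobs_fam, obs, cards)
            table[index] = joint / z_fam
        else:
            table[index] = 1.0
        counts[node] = table
    return log_like, counts


def fit_em(
    structure: NetworkStructure,
    records: Sequence[Mapping[str, Optional[int]]],
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    pseudocount: float = 1.0,
    enumeration_cap: int = 200_000,
) -> NetworkModel:
    """Fit all CPTs by EM over latent nodes and missing inputs.

    ``records`` map observed node names to category indices (``None`` or an
    absent key = missing).  The target must be observed in every record.
    CPTs are initialized from per-row uniform Dirichlet draws seeded by
    ``seed``; iteration stops when the (Dirichlet-penalized) log-likelihood
    objective improves by less than ``tol`` or after ``max_iter``
    iterations.  That objective is asserted non-decreasing every iteration;
    the raw observed-data log-likelihood is reported in the training
    metadata.
    """
    if len(records) == 0:
        raise ValidationError("cannot fit a model on zero records")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    cards = structure.cards()
    target = structure.target_name
    node_names = structure.node_names
    parent_map = {n: structure.parents(n) for n in node_names}

    prepared: dict[tuple, list] = {}
    target_counts = np.zeros(4)
    for rec in records:
        obs = _check_evidence(structure, rec, allow_target=True)
        if target not in obs:
            raise ValidationError("every training record must observe the target")
        target_counts[obs[target]] += 1
        key = tuple(sorted(obs.items()))
        if key in prepared:
            prepared[key][1] += 1
        else:
            prepared[key] = [obs, 1]
    unique_records = list(prepared.values())

    rng = np.random.default_rng(seed)
    tables: dict[str, np.ndarray] = {}
    for node in node_names:
        shape = tuple(cards[p] for p in parent_map[node]) + (cards[node],)
        rows = int(np.prod(shape[:-1], dtype=np.int64)) if len(shape) > 1 else 1
        tables[node] = rng.dirichlet(np.ones(shape[-1]), size=rows).reshape(shape)

    # With pseudocount smoothing the M-step maximizes a Dirichlet-penalized
    # expected complete log-likelihood, so the guaranteed-monotone objective
    # is ll + pseudocount * sum(log CPT entries); the raw observed-data
    # log-likelihood can dip by tiny amounts and is reported, not asserted.
    def penalty() -> float:
        return pseudocount * float(
            sum(np.log(tables[node]).sum() for node in node_names)
        )

    prev_obj = -np.inf
    ll = -np.inf
    iterations = 0
    for _ in range(max_iter):
        counts = {
            node: np.zeros(tables[node].shape) for node in node_names
        }
        ll = 0.0
        for obs, mult in unique_records:
            unobs = [v for v in node_names if v not in obs]
            space = int(np.prod([cards[v] for v in unobs], dtype=np.int64))
            if space <= enumeration_cap:
                rec_ll, rec_counts = _enumeration_estep(
                    node_names, parent_map, cards, tables, obs, unobs
                )
            else:
                interim = {
                    n: CPT(n, parent_map[n], tables[n]) for n in node_names
                }
                rec_ll, rec_counts = _ve_estep(structure, interim, cards, obs)
            ll += mult * rec_ll
            for node, table in rec_counts.items():
                counts[node] += mult * table
        iterations += 1
        objective = ll + penalty()
        if objective < prev_obj - 1e-7 * (1.0 + abs(objective)):
            raise RuntimeError(
                f"EM penalized objective decreased: {prev_obj} -> {objective}"
            )
        converged = np.isfinite(prev_obj) and (objective - prev_obj) < tol
        prev_obj = objective
        # M-step (also after the final E-step: parameters match the counts)
        for node in node_names:
            smoothed = counts[node] + pseudocount
            tables[node] = smoothed / smoothed.sum(axis=-1, keepdims=True)
        if converged:
            break

    if np.all(target_counts > 0):
        priors = target_counts / target_counts.sum()
    else:  # smoothing keeps priors strictly positive for the GBF
        priors = (target_counts + pseudocount) / (
            target_counts.sum() + 4 * pseudocount
        )

    cpts = {n: CPT(n, parent_map[n], tables[n]) for n in node_names}
    meta = TrainingMeta(
        n_records=len(records),
        em_iterations=iterations,
        final_log_likelihood=float(ll),
        seed=seed,
    )
    return NetworkModel(
        structure=structure,
        cpts=cpts,
        class_priors=priors,
        training_meta=meta,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer_profile(
    model: NetworkModel, evidence: Mapping[str, Optional[int]]
) -> ProbabilityProfile:
    """Exact posterior over the four target states given partial evidence.

    Missing/unobserved input nodes are simply absent from ``evidence``; with
    no evidence at all this returns the model's marginal over the target.
    """
    obs = _check_evidence(model.structure, evidence, allow_target=False)
    cards = model.structure.cards()
    factors = _cpt_factors(model.structure, model.cpts)
    table, z = variable_elimination(
        factors, (model.structure.target_name,), obs, cards
    )
    if z <= 0:
        raise ValidationError("evidence has zero probability under the model")
    return ProbabilityProfile.from_array(table / z)


def enumerate_joint(
    model: NetworkModel,
    evidence: Mapping[str, Optional[int]],
    max_states: int = 10_000_000,
) -> np.ndarray:
    """Brute-force oracle: sum the full joint over all completions.

    Refuses when the unobserved state space exceeds ``max_states``.
    Returns the normalized distribution over target states.
    """
    obs = _check_evidence(model.structure, evidence, allow_target=False)
    cards = model.structure.cards()
    node_names = model.structure.node_names
    target = model.structure.target_name
    unobs = [v for v in node_names if v not in obs]
    space = int(np.prod([cards[v] for v in unobs], dtype=np.int64))
    if space > max_states:
        raise ValidationError(
            f"enumeration state space {space} exceeds limit {max_states}"
        )
    sizes = [cards[v] for v in unobs]
    grids = np.indices(sizes).reshape(len(sizes), -1)
    assign = {v: grids[i] for i, v in enumerate(unobs)}
    prob = np.ones(grids.shape[1] if sizes else 1)
    for node in node_names:
        fam = model.structure.parents(node) + (node,)
        idx = tuple(assign[v] if v in assign else obs[v] for v in fam)
        prob = prob * model.cpts[node].table[idx]
    target_states = assign[target]
    dist = np.bincount(target_states, weights=prob, minlength=4)
    total = dist.sum()
    if total <= 0:
        raise ValidationError("evidence has zero probability under the model")
    return dist / total


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_yaml(model: NetworkModel) -> str:
    """Serialize a model to versioned YAML (floats at full precision)."""
    doc = {
        "skinbn_model_version": MODEL_SCHEMA_VERSION,
        "structure": {
            "nodes": [
                {"name": n.name, "cardinality": n.cardinality, "kind": n.kind}
                for n in model.structure.nodes
            ],
            "arcs": [[p, c] for p, c in model.structure.arcs],
        },
        "cpts": {
            name: {
                "parent_order": list(cpt.parent_order),
                "table": cpt.table.tolist(),
            }
            for name, cpt in model.cpts.items()
        },
        "discretization": {
            name: list(spec.thresholds)
            for name, spec in model.discretization.items()
        },
        "encodings": {name: list(levels) for name, levels in model.encodings.items()},
        "class_priors": model.class_priors.tolist(),
        "training_meta": (
            None
            if model.training_meta is None
            else {
                "n_records": model.training_meta.n_records,
                "em_iterations": model.training_meta.em_iterations,
                "final_log_likelihood": model.training_meta.final_log_likelihood,
                "seed": model.training_meta.seed,
            }
        ),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> NetworkModel:
    """Parse and validate a model document produced by :func:`model_to_yaml`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelFormatError(f"cannot parse model document: {exc}") from None
    if not isinstance(doc, dict):
        raise ModelFormatError("model document is not a mapping")
    version = doc.get("skinbn_model_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        structure = NetworkStructure(
            nodes=tuple(
                Node(e["name"], int(e["cardinality"]), e["kind"])
                for e in doc["structure"]["nodes"]
            ),
            arcs=tuple((p, c) for p, c in doc["structure"]["arcs"]),
        )
        cpts = {
            name: CPT(name, tuple(e["parent_order"]), np.array(e["table"], dtype=float))
            for name, e in doc["cpts"].items()
        }
        discretization = {
            name: DiscretizationSpec(name, tuple(ts))
            for name, ts in (doc.get("discretization") or {}).items()
        }
        encodings = {
            name: tuple(levels)
            for name, levels in (doc.get("encodings") or {}).items()
        }
        meta_doc = doc.get("training_meta")
        meta = (
            None
            if meta_doc is None
            else TrainingMeta(
                n_records=int(meta_doc["n_records"]),
                em_iterations=int(meta_doc["em_iterations"]),
                final_log_likelihood=float(meta_doc["final_log_likelihood"]),
                seed=int(meta_doc["seed"]),
            )
        )
        return NetworkModel(
            structure=structure,
            cpts=cpts,
            discretization=discretization,
            encodings=encodings,
            class_priors=np.array(doc["class_priors"], dtype=float),
            training_meta=meta,
        )
    except ModelFormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"invalid model document: {exc}") from None


def save_model(model: NetworkModel, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(model_to_yaml(model))


def load_model(path) -> NetworkModel:
    with open(path, "r", encoding="utf-8") as handle:
        return model_from_yaml(handle.read())
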