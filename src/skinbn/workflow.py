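"""End-to-end glue: substances in, fitted model / prediction table out.

Training: fit the MDL discretization of every quantitative input against
the LLNA reference classes, resolve the network structure's cardinalities,
encode the records (missing/inconclusive -> absent evidence) and run EM.
Prediction: encode a record with the model's stored discretization and
category encodings, run exact inference, and derive predicted class, PoD,
and weight-of-evidence confidence.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import bayes_net, discretization, potency
from .bayes_net import NetworkModel
from .data_model import (
    CATEGORICAL_FIELDS,
    PoDWeights,
    QUANTITATIVE_FIELDS,
    SubstanceRecord,
    ValidationError,
)

__all__ = ["train_model", "encode_record", "predict_profile", "predict_table"]

#: Prediction CSV column order.
PREDICTION_COLUMNS = (
    "substance_id",
    "p_ns",
    "p_weak",
    "p_moderate",
    "p_strong",
    "predicted_class",
    "class_pod_lower_bound",
    "pod_bn",
    "max_w",
    "confidence",
    "no_evidence",
)


def _input_nodes(structure) -> tuple[str, ...]:
    return tuple(n.name for n in structure.nodes if n.kind == "input")


def train_model(
    records: Sequence[SubstanceRecord],
    config: Optional[Mapping] = None,
    *,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    pseudocount: float = 1.0,
    max_bins: int = 3,
    enumeration_cap: int = 200_000,
) -> NetworkModel:
    """Discretize, encode and EM-fit a network on referenced records."""
    if len(records) == 0:
        raise ValidationError("no training records")
    config = config if config is not None else bayes_net.default_config()
    labels = [rec.reference_class() for rec in records]
    encodings = bayes_net.config_encodings(config)

    config_fields = {entry["name"] for entry in config["nodes"]}
    quantitative = [
        entry["name"]
        for entry in config["nodes"]
        if entry.get("quantitative") and entry.get("kind", "input") == "input"
    ]
    specs: dict[str, discretization.DiscretizationSpec] = {}
    cards: dict[str, int] = {}
    for name in quantitative:
        if name not in QUANTITATIVE_FIELDS:
            raise ValidationError(f"config marks unknown field {name!r} quantitative")
        observed = [
            (getattr(rec.inputs, name), lab)
            for rec, lab in zip(records, labels)
            if getattr(rec.inputs, name) is not None
        ]
        if len(observed) >= 2:
            values, obs_labels = zip(*observed)
            spec = discretization.mdl_discretize(
                values, [int(l) for l in obs_labels], max_bins=max_bins,
                variable_name=name,
            )
        else:
            spec = discretization.DiscretizationSpec(name)
        specs[name] = spec
        cards[name] = spec.n_categories

    structure = bayes_net.build_structure(config, quantitative_cards=cards)
    target = structure.target_name
    input_nodes = set(_input_nodes(structure))
    unknown_inputs = input_nodes - config_fields
    if unknown_inputs:
        raise ValidationError(f"inputs without config entries: {sorted(unknown_inputs)}")

    encoded = []
    for rec, label in zip(records, labels):
        evidence = encode_record(rec, specs, encodings, input_nodes)
        evidence[target] = int(label)
        encoded.append(evidence)

    model = bayes_net.fit_em(
        structure,
        encoded,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        pseudocount=pseudocount,
        enumeration_cap=enumeration_cap,
    )
    model.discretization = specs
    model.encodings = {k: tuple(v) for k, v in encodings.items()}
    return model


def encode_record(
    record: SubstanceRecord,
    specs: Mapping[str, discretization.DiscretizationSpec],
    encodings: Mapping[str, Sequence[str]],
    input_nodes: set[str],
) -> dict[str, int]:
    """Map a record's inputs to category indices; missing fields are absent."""
    evidence: dict[str, int] = {}
    for name in input_nodes:
        value = getattr(record.inputs, name, None)
        if value is None:
            continue
        if name in specs:
            code = discretization.apply_thresholds(value, specs[name])
        elif name in encodings:
            levels = list(encodings[name])
            if value not in levels:
                raise ValidationError(
                    f"{record.substance_id}: {name}={value!r} not one of {levels}"
                )
            code = levels.index(value)
        else:
            raise ValidationError(f"no encoding known for input node {name!r}")
        if code is not None:
            evidence[name] = int(code)
    return evidence


def predict_profile(
    model: NetworkModel, record: SubstanceRecord
) -> potency.ProbabilityProfile:
    """Posterior potency profile of one substance under the fitted model."""
    input_nodes = set(_input_nodes(model.structure))
    evidence = encode_record(record, model.discretization, model.encodings, input_nodes)
    return bayes_net.infer_profile(model, evidence)


def _prediction_row(
    substance_id: str,
    profile: potency.ProbabilityProfile,
    priors,
    weights: PoDWeights,
    no_evidence: bool,
) -> dict:
    cls = potency.predicted_class(profile)
    conf = potency.confidence(profile, priors)
    return {
        "substance_id": substance_id,
        "p_ns": profile.p_ns,
        "p_weak": profile.p_weak,
        "p_moderate": profile.p_moderate,
        "p_strong": profile.p_strong,
        "predicted_class": cls.label,
        "class_pod_lower_bound": potency.class_pod_lower_bound(cls, weights),
        "pod_bn": potency.pod_bn(profile, weights),
        "max_w": conf.max_w,
        "confidence": conf.level,
        "no_evidence": no_evidence,
    }


def predict_table(
    model: NetworkModel,
    records: Sequence[SubstanceRecord],
    weights: PoDWeights = PoDWeights(),
) -> pd.DataFrame:
    """One prediction row per record (profile, class, PoD, confidence).

    Records with no usable evidence get the model's target marginal and are
    flagged via the ``no_evidence`` column.
    """
    input_nodes = set(_input_nodes(model.structure))
    rows = []
    for rec in records:
        evidence = encode_record(rec, model.discretization, model.encodings, input_nodes)
        profile = bayes_net.infer_profile(model, evidence)
        rows.append(
            _prediction_row(
                rec.substance_id,
                profile,
                model.class_priors,
                weights,
                no_evidence=len(evidence) == 0,
            )
        )
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def profiles_to_table(
    frame: pd.DataFrame,
    priors,
    weights: PoDWeights = PoDWeights(),
) -> pd.DataFrame:
    """Derive class/PoD/confidence directly from given probability profiles.

    ``frame`` needs columns substance_id, p_ns, p_weak, p_moderate,
    p_strong; inference is bypassed entirely.
    """
    needed = {"substance_id", "p_ns", "p_weak", "p_moderate", "p_strong"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValidationError(f"profile table lacks columns: {sorted(missing)}")
    rows = []
    for row in frame.itertuples(index=False):
        profile = potency.ProbabilityProfile(
            float(row.p_ns), float(row.p_weak), float(row.p_moderate), float(row.p_strong)
        )
        rows.append(
            _prediction_row(str(row.substance_id), profile, priors, weights, False)
        )
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
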