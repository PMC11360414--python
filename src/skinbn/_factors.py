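"""Minimal discrete-factor algebra and variable elimination.

Internal support for exact inference on small categorical networks: factors
are dense numpy tables with named axes; elimination order is chosen greedily
by the size of the factor each elimination would create.  Tables here are
small (a handful of 2-4-state variables per factor), so dense products are
the right tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class Factor:
    variables: tuple[str, ...]
    table: np.ndarray  # one axis per variable, in ``variables`` order

    def __post_init__(self) -> None:
        assert self.table.ndim == len(self.variables)


def reduce_evidence(factor: Factor, evidence: Mapping[str, int]) -> Factor:
    """Fix observed variables to their values, dropping those axes."""
    keep: list[str] = []
    index: list[object] = []
    for var in factor.variables:
        if var in evidence:
            index.append(int(evidence[var]))
        else:
            index.append(slice(None))
            keep.append(var)
    return Factor(tuple(keep), factor.table[tuple(index)])


def product(factors: Sequence[Factor]) -> Factor:
    """Pointwise product of factors over the union of their variables."""
    out_vars: list[str] = []
    for f in factors:
        for v in f.variables:
            if v not in out_vars:
                out_vars.append(v)
    out = np.ones((1,) * len(out_vars)) if out_vars else np.ones(())
    for f in factors:
        axes = [out_vars.index(v) for v in f.variables]
        order = np.argsort(axes)
        table = np.transpose(f.table, order) if len(order) > 1 else f.table
        shape = [1] * len(out_vars)
        for ax, dim in zip(sorted(axes), table.shape):
            shape[ax] = dim
        out = out * table.reshape(shape)
    return Factor(tuple(out_vars), out)


def marginalize(factor: Factor, var: str) -> Factor:
    axis = factor.variables.index(var)
    new_vars = factor.variables[:axis] + factor.variables[axis + 1 :]
    return Factor(new_vars, factor.table.sum(axis=axis))


def variable_elimination(
    factors: Iterable[Factor],
    query: Sequence[str],
    evidence: Mapping[str, int],
    cards: Mapping[str, int],
) -> tuple[np.ndarray, float]:
    """Unnormalized joint over ``query`` given ``evidence``.

    Returns ``(table, z)``: ``table`` has one axis per query variable in the
    requested order and sums to ``z``, the probability of the evidence.
    """
    work = [reduce_evidence(f, evidence) for f in factors]
    query = tuple(query)
    involved = {v for f in work for v in f.variables}
    to_eliminate = set(involved) - set(query)

    while to_eliminate:
        # greedy: eliminate the variable creating the smallest intermediate
        best_var, best_size = None, None
        for var in to_eliminate:
            scope: set[str] = set()
            for f in work:
                if var in f.variables:
                    scope.update(f.variables)
            size = int(np.prod([cards[v] for v in scope]))
            if best_size is None or size < best_size or (
                size == best_size and var < best_var
            ):
                best_var, best_size = var, size
        related = [f for f in work if best_var in f.variables]
        work = [f for f in work if best_var not in f.variables]
        work.append(marginalize(product(related), best_var))
        to_eliminate.discard(best_var)

    joint = product(work)
    # expand to the full query scope (query vars absent from every factor
    # would only occur for degenerate empty-model queries)
    missing = [v for v in query if v not in joint.variables]
    if missing:
        table = joint.table
        for v in missing:
            table = np.multiply.outer(table, np.ones(cards[v]))
        joint = Factor(joint.variables + tuple(missing), table)
    order = [joint.variables.index(v) for v in query]
    table = np.transpose(joint.table, order) if len(order) > 1 else joint.table
    if not query:
        table = np.asarray(joint.table)
    z = float(table.sum())
    return table, z
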