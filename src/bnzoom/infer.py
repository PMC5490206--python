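"""Exact inference on discrete Bayesian networks by variable elimination.

Queries return exact posteriors P(target | evidence); the elimination order is
chosen greedily to minimize the size of each intermediate factor. The
networks used here (14 nodes, up to 19 categories) are far below the scale
where approximate inference would be needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import BayesianNetwork
from .schema import BCSR, SchemaError


class ZeroEvidenceError(ValueError):
    """The conditioning event has probability zero under the network."""


@dataclass(frozen=True)
class Factor:
    """Nonnegative table over a tuple of variables (one axis each)."""

    variables: tuple[str, ...]
    values: np.ndarray

    def reduce(self, evidence_codes: Mapping[str, int]) -> "Factor":
        """Instantiate any of this factor's variables present in evidence."""
        keep_vars = []
        index: list = []
        for i, v in enumerate(self.variables):
            if v in evidence_codes:
                index.append(evidence_codes[v])
            else:
                index.append(slice(None))
                keep_vars.append(v)
        return Factor(tuple(keep_vars), self.values[tuple(index)])


def _product(factors: Sequence[Factor]) -> Factor:
    all_vars: list[str] = []
    for f in factors:
        for v in f.variables:
            if v not in all_vars:
                all_vars.append(v)
    out = None
    for f in factors:
        # broadcast to the union axis order
        shape = [1] * len(all_vars)
        perm = [f.variables.index(v) for v in all_vars if v in f.variables]
        arr = np.transpose(f.values, perm) if f.variables else f.values
        j = 0
        for i, v in enumerate(all_vars):
            if v in f.variables:
                shape[i] = arr.shape[j]
                j += 1
        arr = arr.reshape(shape)
        out = arr if out is None else out * arr
    return Factor(tuple(all_vars), out if out is not None else np.array(1.0))


def _sum_out(factor: Factor, variable: str) -> Factor:
    axis = factor.variables.index(variable)
    return Factor(
        tuple(v for v in factor.variables if v != variable),
        factor.values.sum(axis=axis),
    )


def _cpt_factor(bn: BayesianNetwork, node: str) -> Factor:
    cpt = bn.cpts[node]
    shape = cpt.parent_shape + (len(cpt.categories),)
    return Factor(cpt.parents + (node,), cpt.table.reshape(shape))


def _evidence_codes(bn: BayesianNetwork, evidence: Mapping[str, str]) -> dict[str, int]:
    codes = {}
    for name, cat in evidence.items():
        if name not in bn.schema:
            raise SchemaError(f"evidence variable {name!r} not in network")
        codes[name] = bn.schema[name].index(cat)
    return codes


def query(
    bn: BayesianNetwork, target: str, evidence: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Exact posterior P(target | evidence) as a category -> probability map."""
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} appears in the evidence")
    if target not in bn.schema or target not in bn.dag.nodes:
        raise SchemaError(f"no node named {target!r}")
    codes = _evidence_codes(bn, evidence)

    factors = [_cpt_factor(bn, node).reduce(codes) for node in bn.dag.nodes]
    factors = [f for f in factors if f.variables or float(np.asarray(f.values)) != 1.0]
    to_eliminate = [
        v for v in bn.dag.nodes if v != target and v not in evidence
    ]
    # greedy order: eliminate the variable whose combined factor is smallest
    while to_eliminate:
        best_var, best_cost = None, None
        for v in to_eliminate:
            involved = [f for f in factors if v in f.variables]
            vars_union = {u for f in involved for u in f.variables}
            cost = 1
            for u in vars_union:
                cost *= bn.schema[u].n_categories
            if best_cost is None or cost < best_cost or (
                cost == best_cost and v < best_var
            ):
                best_var, best_cost = v, cost
        involved = [f for f in factors if best_var in f.variables]
        rest = [f for f in factors if best_var not in f.variables]
        if involved:
            rest.append(_sum_out(_product(involved), best_var))
        factors = rest
        to_eliminate.remove(best_var)

    result = _product(factors)
    values = np.asarray(result.values, dtype=float)
    if result.variables != (target,):
        # scalar factors multiplied in; ensure only the target axis remains
        values = values.reshape(bn.schema[target].n_categories)
    total = values.sum()
    if total <= 0.0:
        raise ZeroEvidenceError(f"evidence {evidence!r} has probability zero")
    probs = values / total
    return {
        cat: float(p) for cat, p in zip(bn.schema[target].categories, probs)
    }


def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """P(V = assignment) for a full assignment (product of CPT entries)."""
    return bn.joint_probability(assignment)


def predict_treatment(
    bn: BayesianNetwork,
    record: Mapping[str, str],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Most probable treatment given a record's non-treatment variables.

    ``exclude`` removes variables from the evidence (e.g. willingness W,
    which is nearly deterministic given the treatment and leaks the label).
    Ties go to BCSR, the guideline-recommended majority treatment.
    """
    t_name = bn.schema.treatment.name
    evidence = {
        k: v
        for k, v in record.items()
        if k != t_name and k not in exclude and k in bn.dag.nodes
    }
    missing = [
        v for v in bn.dag.nodes if v != t_name and v not in exclude and v not in evidence
    ]
    if missing:
        raise ValueError(f"record missing variables {missing}")
    posterior = query(bn, t_name, evidence)
    best = max(posterior.items(), key=lambda kv: kv[1])
    others = [p for c, p in posterior.items() if c != best[0]]
    if others and abs(best[1] - max(others)) < 1e-12:
        return BCSR
    return best[0]
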