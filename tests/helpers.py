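"""Shared test utilities: tiny schemas, random networks, brute-force oracles.

The brute-force functions enumerate the full joint of a network directly
from the factorization; they are deliberately independent of the package's
variable-elimination engine and hill-climbing search.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from bnzoom.cohort import CohortTable
from bnzoom.network import CPT, DAG, BayesianNetwork
from bnzoom.schema import Variable, VariableSchema


def make_schema(spec: dict[str, tuple[str, ...]], treatment: str = "T") -> VariableSchema:
    """Schema from {name: categories}; ``treatment`` gets the treatment role."""
    return VariableSchema(
        tuple(
            Variable(
                name,
                "treatment" if name == treatment else "clinical",
                cats,
            )
            for name, cats in spec.items()
        )
    )


def make_cohort(schema: VariableSchema, rows: list[dict]) -> CohortTable:
    return CohortTable(schema, pd.DataFrame(rows))


def make_bn(schema: VariableSchema, arcs, tables: dict[str, np.ndarray]) -> BayesianNetwork:
    """Network from explicit CPT arrays (rows over sorted-parent configs)."""
    dag = DAG(schema.names, tuple(arcs))
    cpts = {}
    for node in schema.names:
        parents = tuple(sorted(dag.parents(node)))
        cpts[node] = CPT(
            node,
            parents,
            schema[node].categories,
            tuple(schema[p].categories for p in parents),
            np.asarray(tables[node], dtype=float),
        )
    return BayesianNetwork(schema, dag, cpts)


def random_network(rng: np.random.Generator, max_nodes: int = 6, max_card: int = 4,
                   treatment_last: bool = True) -> BayesianNetwork:
    """Random DAG (edges only forward in a random order) with random CPTs."""
    n_nodes = int(rng.integers(2, max_nodes + 1))
    names = [f"V{i}" for i in range(n_nodes)]
    if treatment_last:
        names[-1] = "T"
    spec = {}
    for name in names:
        if name == "T":
            spec[name] = ("BCS", "BCSR")
        else:
            k = int(rng.integers(2, max_card + 1))
            spec[name] = tuple(f"c{j}" for j in range(k))
    schema = make_schema(spec, treatment="T" if treatment_last else names[0])
    arcs = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.4
    ]
    tables = {}
    dag = DAG(schema.names, tuple(arcs))
    for node in names:
        parents = tuple(sorted(dag.parents(node)))
        k = schema[node].n_categories
        q = int(np.prod([schema[p].n_categories for p in parents])) if parents else 1
        t = rng.random((q, k)) + 0.05
        tables[node] = t / t.sum(axis=1, keepdims=True)
    return make_bn(schema, arcs, tables)


def brute_force_query(bn: BayesianNetwork, target: str, evidence: dict) -> dict:
    """P(target | evidence) by summing the full joint, category by category."""
    free = [n for n in bn.dag.nodes if n != target and n not in evidence]
    cats = bn.schema[target].categories
    totals = np.zeros(len(cats))
    for ti, tc in enumerate(cats):
        for combo in itertools.product(
            *[bn.schema[f].categories for f in free]
        ):
            a = dict(evidence)
            a[target] = tc
            a.update(dict(zip(free, combo)))
            totals[ti] += bn.joint_probability(a)
    if totals.sum() == 0:
        raise ValueError("zero-probability evidence")
    totals = totals / totals.sum()
    return dict(zip(cats, totals))


def all_dags_3(names: tuple[str, str, str]):
    """All 25 DAGs on three labelled nodes."""
    a, b, c = names
    pairs = [(a, b), (a, c), (b, c)]
    dags = []
    for states in itertools.product((0, 1, 2), repeat=3):
        arcs = []
        for (x, y), s in zip(pairs, states):
            if s == 1:
                arcs.append((x, y))
            elif s == 2:
                arcs.append((y, x))
        try:
            dags.append(DAG((a, b, c), tuple(arcs)))
        except ValueError:
            continue
    assert len(dags) == 25
    return dags
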