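"""Discrete Bayesian network containers: DAG, CPTs, and the joint model.

The joint distribution factorizes as P(V) = prod_v p(v | pa(v)): one
conditional probability table (CPT) per node given its DAG parents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .schema import SchemaError, VariableSchema


class CyclicGraphError(ValueError):
    """The proposed arc set contains a directed cycle."""


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        seen = set()
        for parent, child in self.arcs:
            if parent == child:
                raise ValueError(f"self-loop on {parent!r}")
            if parent not in node_set or child not in node_set:
                raise ValueError(f"arc ({parent!r}, {child!r}) uses unknown node")
            if (parent, child) in seen:
                raise ValueError(f"duplicate arc ({parent!r}, {child!r})")
            seen.add((parent, child))
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CyclicGraphError("arc set contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.arcs if c == node)

    def topological_order(self) -> list[str]:
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset((p, c)) for p, c in self.arcs}

    def with_arcs(self, arcs: Iterable[tuple[str, str]]) -> "DAG":
        return DAG(self.nodes, tuple(arcs))

    def to_json(self) -> dict:
        return {"nodes": list(self.nodes), "arcs": [list(a) for a in self.arcs]}

    @classmethod
    def from_json(cls, obj: dict) -> "DAG":
        return cls(tuple(obj["nodes"]), tuple((p, c) for p, c in obj["arcs"]))


def would_be_acyclic(
    nodes: Iterable[str], arcs: set[tuple[str, str]]
) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(arcs)
    return nx.is_directed_acyclic_graph(g)


@dataclass(frozen=True)
class CPT:
    """Conditional distribution of ``child`` given its ordered ``parents``.

    ``table`` has shape (prod of parent cardinalities, n child categories);
    rows are indexed by the C-order ravel of parent category indices, so row
    0 is the first category of every parent. With no parents the table is a
    single row: the marginal of the child.
    """

    child: str
    parents: tuple[str, ...]
    categories: tuple[str, ...]
    parent_categories: tuple[tuple[str, ...], ...]
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(len(c) for c in self.parent_categories)
        n_rows = int(np.prod(shape)) if shape else 1
        table = np.asarray(self.table, dtype=float)
        if table.shape != (n_rows, len(self.categories)):
            raise ValueError(
                f"CPT for {self.child!r}: table shape {table.shape} does not "
                f"match ({n_rows}, {len(self.categories)})"
            )
        if (table < -1e-12).any():
            raise ValueError(f"CPT for {self.child!r} has negative entries")
        sums = table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.child!r} do not sum to 1")
        object.__setattr__(self, "table", table)

    @property
    def parent_shape(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.parent_categories)

    def row_index(self, parent_codes: Mapping[str, int]) -> int:
        if not self.parents:
            return 0
        idx = tuple(parent_codes[p] for p in self.parents)
        return int(np.ravel_multi_index(idx, self.parent_shape))

    def prob(self, child_code: int, parent_codes: Mapping[str, int]) -> float:
        return float(self.table[self.row_index(parent_codes), child_code])


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one CPT per node, over the variables of ``schema``."""

    schema: VariableSchema
    dag: DAG
    cpts: Mapping[str, CPT]

    def __post_init__(self) -> None:
        if set(self.dag.nodes) != set(self.cpts):
            raise ValueError("CPTs must cover exactly the DAG nodes")
        for node in self.dag.nodes:
            if node not in self.schema:
                raise SchemaError(f"DAG node {node!r} missing from schema")
            cpt = self.cpts[node]
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.dag.parents(node))):
                raise ValueError(
                    f"CPT parents of {node!r} differ from DAG parents"
                )
            if cpt.categories != self.schema[node].categories:
                raise ValueError(f"CPT categories of {node!r} differ from schema")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """P(V = assignment) as the product of matching CPT entries."""
        missing = [n for n in self.dag.nodes if n not in assignment]
        if missing:
            raise ValueError(f"assignment incomplete, missing {missing}")
        codes = {
            name: self.schema[name].index(assignment[name])
            for name in self.dag.nodes
        }
        p = 1.0
        for node in self.dag.nodes:
            p *= self.cpts[node].prob(codes[node], codes)
        return p

    def to_json(self) -> dict:
        return {
            "schema": self.schema.to_json(),
            "dag": self.dag.to_json(),
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "table": cpt.table.tolist(),
                }
                for node, cpt in self.cpts.items()
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BayesianNetwork":
        schema = VariableSchema.from_json(obj["schema"])
        dag = DAG.from_json(obj["dag"])
        cpts = {}
        for node, spec in obj["cpts"].items():
            parents = tuple(spec["parents"])
            cpts[node] = CPT(
                child=node,
                parents=parents,
                categories=schema[node].categories,
                parent_categories=tuple(schema[p].categories for p in parents),
                table=np.asarray(spec["table"], dtype=float),
            )
        return cls(schema, dag, cpts)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, ensure_ascii=False)

    @classmethod
    def load(cls, path) -> "BayesianNetwork":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def load_detroit_dag() -> DAG:
    """The physician-validated 23-arc Detroit DAG shipped with the package."""
    with resources.files("bnzoom.data").joinpath("detroit_dag.json").open(
        encoding="utf-8"
    ) as fh:
        return DAG.from_json(json.load(fh))
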