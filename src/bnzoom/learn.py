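"""Score-based structure learning and CPT estimation.

Hill climbing over DAGs with a decomposable score (BIC by default, BDeu as an
alternative), starting from the empty graph and greedily applying the single
best arc addition, deletion or reversal until no move improves the score.
Model averaging runs the search on nonparametric bootstrap resamples, keeps
arcs whose undirected support reaches a strength threshold, and orients them
by majority direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.special import gammaln

from .cohort import CohortTable
from .network import CPT, DAG, BayesianNetwork, would_be_acyclic
from .schema import VariableSchema

_EPS = 1e-9


@dataclass(frozen=True)
class _Coded:
    """Integer-coded cohort plus schema cardinalities, for fast counting."""

    names: tuple[str, ...]
    cards: tuple[int, ...]
    codes: np.ndarray  # (n, p) int64

    @classmethod
    def from_table(cls, table: CohortTable) -> "_Coded":
        return cls(
            names=table.schema.names,
            cards=tuple(v.n_categories for v in table.schema),
            codes=table.codes(),
        )

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def col(self, name: str) -> int:
        return self.names.index(name)


def _family_counts(
    data: _Coded, child: str, parents: tuple[str, ...]
) -> np.ndarray:
    """Count matrix (n_parent_configs, child_cardinality)."""
    ci = data.col(child)
    r = data.cards[ci]
    if not parents:
        counts = np.bincount(data.codes[:, ci], minlength=r)
        return counts.reshape(1, r).astype(float)
    p_cols = [data.col(p) for p in parents]
    p_cards = [data.cards[c] for c in p_cols]
    q = int(np.prod(p_cards))
    flat = np.zeros(data.codes.shape[0], dtype=np.int64)
    for c, card in zip(p_cols, p_cards):
        flat = flat * card + data.codes[:, c]
    flat = flat * r + data.codes[:, ci]
    return np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)


def _family_loglik(counts: np.ndarray) -> float:
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log(counts) - np.log(row_tot))
    return float(np.nansum(np.where(counts > 0, ll, 0.0)))


def _bic_family(data: _Coded, child: str, parents: tuple[str, ...]) -> float:
    counts = _family_counts(data, child, parents)
    r = counts.shape[1]
    q = counts.shape[0]
    penalty = 0.5 * math.log(data.n) * (r - 1) * q
    return _family_loglik(counts) - penalty


def _bdeu_family(
    data: _Coded, child: str, parents: tuple[str, ...], ess: float = 1.0
) -> float:
    counts = _family_counts(data, child, parents)
    q, r = counts.shape
    a_jk = ess / (q * r)
    a_j = ess / q
    row_tot = counts.sum(axis=1)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + row_tot))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )
    return score


_SCORES: Mapping[str, Callable[[_Coded, str, tuple[str, ...]], float]] = {
    "bic": _bic_family,
    "bdeu": _bdeu_family,
}


def bic_score(dag: DAG, table: CohortTable) -> float:
    """BIC of ``dag``: sum over families of max log-likelihood minus
    (ln n / 2) per free parameter; natural log, decomposable per family."""
    data = _Coded.from_table(table)
    for node in dag.nodes:
        if node not in table.schema:
            raise ValueError(f"DAG node {node!r} absent from cohort")
    return sum(_bic_family(data, v, tuple(sorted(dag.parents(v)))) for v in dag.nodes)


class _HillClimber:
    """Greedy DAG search with memoized family scores."""

    def __init__(self, data: _Coded, score: str, max_iter: int):
        if score not in _SCORES:
            raise ValueError(f"unknown score {score!r}")
        self.data = data
        self.score_fn = _SCORES[score]
        self.max_iter = max_iter
        self.cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents: frozenset[str]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self.cache:
            val = self.score_fn(self.data, child, key[1])
            if not math.isfinite(val):
                raise ValueError(f"non-finite score for family of {child!r}")
            self.cache[key] = val
        return self.cache[key]

    def run(self) -> DAG:
        nodes = self.data.names
        parents: dict[str, set[str]] = {v: set() for v in nodes}
        arcs: set[tuple[str, str]] = set()
        for _ in range(self.max_iter):
            move = self._best_move(nodes, parents, arcs)
            if move is None:
                break
            kind, p, c = move
            if kind == "add":
                arcs.add((p, c))
                parents[c].add(p)
            elif kind == "delete":
                arcs.discard((p, c))
                parents[c].discard(p)
            else:  # reverse p->c into c->p
                arcs.discard((p, c))
                parents[c].discard(p)
                arcs.add((c, p))
                parents[p].add(c)
        ordered = tuple(sorted(arcs))
        return DAG(nodes, ordered)

    def _best_move(self, nodes, parents, arcs):
        best = None
        best_delta = _EPS
        # additions, in lexicographic (parent, child) order
        for p in nodes:
            for c in nodes:
                if p == c or (p, c) in arcs or (c, p) in arcs:
                    continue
                if not would_be_acyclic(nodes, arcs | {(p, c)}):
                    continue
                old = self.family(c, frozenset(parents[c]))
                new = self.family(c, frozenset(parents[c] | {p}))
                if new - old > best_delta:
                    best_delta = new - old
                    best = ("add", p, c)
        # deletions
        for p, c in sorted(arcs):
            old = self.family(c, frozenset(parents[c]))
            new = self.family(c, frozenset(parents[c] - {p}))
            if new - old > best_delta:
                best_delta = new - old
                best = ("delete", p, c)
        # reversals
        for p, c in sorted(arcs):
            if not would_be_acyclic(nodes, (arcs - {(p, c)}) | {(c, p)}):
                continue
            delta = (
                self.family(c, frozenset(parents[c] - {p}))
                - self.family(c, frozenset(parents[c]))
                + self.family(p, frozenset(parents[p] | {c}))
                - self.family(p, frozenset(parents[p]))
            )
            if delta > best_delta:
                best_delta = delta
                best = ("reverse", p, c)
        return best


def hill_climb(
    table: CohortTable,
    score: str = "bic",
    max_iter: int = 200,
    seed: int | None = None,
) -> DAG:
    """Greedy ascent from the empty graph; deterministic given the data.

    ``seed`` is accepted for interface symmetry; the search itself is
    deterministic (ties broken lexicographically by move type, parent, child).
    """
    if table.n == 0:
        raise ValueError("cannot learn structure from an empty cohort")
    return _HillClimber(_Coded.from_table(table), score, max_iter).run()


@dataclass(frozen=True)
class ArcStrengthTable:
    """Bootstrap support per undirected pair, with majority direction.

    ``entries`` maps a lexicographically sorted pair (x, y) to
    ``(strength, direction_prob)``: the fraction of replicates containing an
    arc between x and y in either direction, and — among those — the fraction
    oriented x -> y.
    """

    nodes: tuple[str, ...]
    replicates: int
    entries: Mapping[tuple[str, str], tuple[float, float]]

    def strength(self, x: str, y: str) -> float:
        return self.entries.get(tuple(sorted((x, y))), (0.0, 0.0))[0]


def bootstrap_arc_strength(
    table: CohortTable,
    replicates: int = 1000,
    seed: int = 0,
    score: str = "bic",
    max_iter: int = 200,
) -> ArcStrengthTable:
    """Arc strengths from hill climbs on bootstrap resamples of the cohort."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    data = _Coded.from_table(table)
    rng = np.random.default_rng(seed)
    pair_count: dict[tuple[str, str], int] = {}
    dir_count: dict[tuple[str, str], int] = {}
    for _ in range(replicates):
        idx = rng.integers(0, data.n, size=data.n)
        boot = _Coded(data.names, data.cards, data.codes[idx])
        dag = _HillClimber(boot, score, max_iter).run()
        for p, c in dag.arcs:
            key = tuple(sorted((p, c)))
            pair_count[key] = pair_count.get(key, 0) + 1
            if (p, c) == key:
                dir_count[key] = dir_count.get(key, 0) + 1
    entries = {
        key: (cnt / replicates, dir_count.get(key, 0) / cnt)
        for key, cnt in pair_count.items()
    }
    return ArcStrengthTable(data.names, replicates, entries)


def average_network(strengths: ArcStrengthTable, threshold: float = 0.25) -> DAG:
    """Arcs with strength >= threshold, majority-oriented; cycles repaired by
    dropping the weakest retained arc until the graph is acyclic."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    kept: list[tuple[float, tuple[str, str]]] = []
    for (x, y), (strength, dir_prob) in sorted(strengths.entries.items()):
        if strength >= threshold:
            arc = (x, y) if dir_prob >= 0.5 else (y, x)
            kept.append((strength, arc))
    arcs = {arc for _, arc in kept}
    while not would_be_acyclic(strengths.nodes, arcs):
        weakest = min(
            (s, arc) for s, arc in kept if arc in arcs
        )
        arcs.discard(weakest[1])
    return DAG(strengths.nodes, tuple(sorted(arcs)))


def fit_cpts(
    dag: DAG, table: CohortTable, pseudo_count: float = 1.0
) -> BayesianNetwork:
    """Estimate one CPT per node: (count + pseudo) / (row total + pseudo * k).

    With ``pseudo_count`` 0 this is maximum likelihood; unseen parent
    configurations then get a uniform row so the CPT stays a distribution.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be nonnegative")
    schema = table.schema.subset(list(dag.nodes))
    data = _Coded.from_table(CohortTable(schema, table.records[list(schema.names)]))
    cpts = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.parents(node)))
        counts = _family_counts(data, node, parents)
        k = counts.shape[1]
        smoothed = counts + pseudo_count
        row_tot = smoothed.sum(axis=1, keepdims=True)
        probs = np.where(
            row_tot > 0, smoothed / np.where(row_tot == 0, 1.0, row_tot), 1.0 / k
        )
        empty = counts.sum(axis=1) == 0
        if pseudo_count == 0 and empty.any():
            probs[empty] = 1.0 / k
        cpts[node] = CPT(
            child=node,
            parents=parents,
            categories=schema[node].categories,
            parent_categories=tuple(schema[p].categories for p in parents),
            table=probs,
        )
    return BayesianNetwork(schema, DAG(dag.nodes, tuple(sorted(dag.arcs))), cpts)
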