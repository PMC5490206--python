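"""Synthetic SEER-like cohorts: reference network, sampling, planted effects.

The reference network reproduces the published Detroit conditions: the
physician-validated 23-arc DAG, single-variable marginals matching the
registry contingency table within 0.02, and an overall BCS rate near 0.21.
Where the registry table pins down a conditional (any variable tabulated
against treatment), the CPT kernel uses those real likelihood ratios; for
parent-child pairs the table says nothing about, a fixed seeded log-linear
association of moderate strength (log odds perturbations with s.d. 0.5,
comparable to the ~2-fold odds ratios typical of registry covariates) makes
every arc statistically detectable at cohort scale. Marginals are then
calibrated by iterative proportional adjustment of CPT columns, which
preserves the log-linear interactions while pinning the margins.

``plant_divergence`` creates ground truth for heuristic validation: it
rescales the CPT of a chosen variable so the conditional probability of one
category differs between treatments by at least a requested delta, with a
compensating rescale on the other treatment side to keep marginals near
their calibrated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .infer import query
from .network import CPT, DAG, BayesianNetwork, load_detroit_dag, would_be_acyclic
from .schema import BCS, VariableSchema, detroit_schema, load_table1
from .zoomin import Condition

_KERNEL_SEED = 170628  # fixed: the reference network is a deterministic object
_KERNEL_SD = 0.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to draw one synthetic cohort."""

    network: BayesianNetwork
    n: int
    seed: int
    planted: tuple = field(default_factory=tuple)
    # each planted entry: (Condition, stage_set, target treatment, delta)


def _table1_margins(schema: VariableSchema) -> dict[str, np.ndarray]:
    raw = load_table1()
    n = raw["n"]
    margins = {}
    for v in raw["variables"]:
        name = v["name"]
        if name == schema.treatment.name:
            margins[name] = np.array(
                [raw["all_patients"]["BCS"] / n, raw["all_patients"]["BCSR"] / n]
            )
        else:
            margins[name] = np.array(
                [(c["BCS"] + c["BCSR"]) / n for c in v["categories"]]
            )
    return margins


def _treatment_likelihood_ratios(schema: VariableSchema) -> dict[str, np.ndarray]:
    """P(category | T=t) / P(category), from the registry table, per variable."""
    raw = load_table1()
    n_bcs = raw["all_patients"]["BCS"]
    n_bcsr = raw["all_patients"]["BCSR"]
    n = raw["n"]
    ratios = {}
    for v in raw["variables"]:
        if v["name"] == schema.treatment.name:
            continue
        out = np.zeros((len(v["categories"]), 2))
        for i, c in enumerate(v["categories"]):
            marginal = (c["BCS"] + c["BCSR"]) / n
            # small floor keeps zero cells (e.g. 0 BCS patients) finite
            out[i, 0] = max(c["BCS"] / n_bcs, 1e-4) / marginal
            out[i, 1] = max(c["BCSR"] / n_bcsr, 1e-4) / marginal
        ratios[v["name"]] = out
    return ratios


def _exact_marginals(bn: BayesianNetwork) -> dict[str, np.ndarray]:
    out = {}
    for node in bn.dag.nodes:
        dist = query(bn, node, {})
        out[node] = np.array([dist[c] for c in bn.schema[node].categories])
    return out


def _build_initial_cpts(
    schema: VariableSchema, dag: DAG, margins, t_ratios, rng
) -> dict[str, CPT]:
    t_name = schema.treatment.name
    cpts = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.parents(node)))
        k = schema[node].n_categories
        p_cards = [schema[p].n_categories for p in parents]
        n_rows = int(np.prod(p_cards)) if parents else 1
        table = np.tile(margins[node], (n_rows, 1))
        grid = np.unravel_index(np.arange(n_rows), tuple(p_cards)) if parents else ()
        for ax, parent in enumerate(parents):
            if node == t_name:
                # P(t|p=j)/P(t) equals P(p=j|t)/P(p=j) (Bayes), which the
                # registry table provides directly
                kernel = t_ratios[parent]  # (parent categories, 2)
            elif parent == t_name:
                kernel = t_ratios[node].T  # (2, child categories)
            else:
                kernel = np.exp(
                    rng.normal(0.0, _KERNEL_SD, size=(p_cards[ax], k))
                )
            # multiply each row by the kernel slice for its parent category
            table = table * kernel[grid[ax], :]
            table = table / table.sum(axis=1, keepdims=True)
        cpts[node] = CPT(
            child=node,
            parents=parents,
            categories=schema[node].categories,
            parent_categories=tuple(schema[p].categories for p in parents),
            table=table,
        )
    return cpts


def _calibrate(
    schema: VariableSchema,
    dag: DAG,
    cpts: dict[str, CPT],
    margins,
    tol: float = 0.02,
    max_sweeps: int = 60,
) -> dict[str, CPT]:
    """Iterative proportional adjustment of CPT columns toward target margins."""
    order = dag.topological_order()
    for _ in range(max_sweeps):
        bn = BayesianNetwork(schema, dag, cpts)
        current = _exact_marginals(bn)
        worst = max(
            float(np.max(np.abs(current[v] - margins[v]))) for v in dag.nodes
        )
        if worst < tol:
            break
        new = dict(cpts)
        for node in order:
            ratio = margins[node] / np.clip(current[node], 1e-9, None)
            table = cpts[node].table * np.clip(ratio, 0.2, 5.0)
            table = table / table.sum(axis=1, keepdims=True)
            new[node] = CPT(
                child=node,
                parents=cpts[node].parents,
                categories=cpts[node].categories,
                parent_categories=cpts[node].parent_categories,
                table=table,
            )
        cpts = new
    return cpts


@lru_cache(maxsize=1)
def detroit_reference_network() -> BayesianNetwork:
    """Fully specified 14-variable network with the published parent sets."""
    schema = detroit_schema()
    dag = load_detroit_dag()
    margins = _table1_margins(schema)
    t_ratios = _treatment_likelihood_ratios(schema)
    rng = np.random.default_rng(_KERNEL_SEED)
    cpts = _build_initial_cpts(schema, dag, margins, t_ratios, rng)
    cpts = _calibrate(schema, dag, cpts, margins)
    return BayesianNetwork(schema, dag, cpts)


def treatment_null_network(bn: BayesianNetwork | None = None) -> BayesianNetwork:
    """A copy of ``bn`` (default: the reference network) with the treatment
    made independent of every other variable.

    The treatment node's CPT rows are replaced by its marginal, and the CPTs
    of its children are averaged over the treatment axis (weighted by that
    marginal), so the joint factorizes with T independent. This is the null
    background for planted-divergence validation: any treatment divergence
    found afterwards is attributable to the plant alone.
    """
    if bn is None:
        bn = detroit_reference_network()
    schema = bn.schema
    t_name = schema.treatment.name
    marginal = np.array(
        [query(bn, t_name, {})[c] for c in schema.treatment.categories]
    )
    cpts = dict(bn.cpts)
    t_cpt = cpts[t_name]
    cpts[t_name] = CPT(
        t_name, t_cpt.parents, t_cpt.categories, t_cpt.parent_categories,
        np.tile(marginal, (t_cpt.table.shape[0], 1)),
    )
    for node in bn.dag.nodes:
        cpt = cpts[node]
        if node == t_name or t_name not in cpt.parents:
            continue
        shape = cpt.parent_shape + (len(cpt.categories),)
        arr = cpt.table.reshape(shape)
        t_axis = cpt.parents.index(t_name)
        w = marginal.reshape(
            [-1 if i == t_axis else 1 for i in range(len(shape))]
        )
        averaged = (arr * w).sum(axis=t_axis, keepdims=True)
        arr = np.broadcast_to(averaged, shape).copy()
        table = arr.reshape(cpt.table.shape)
        table = table / table.sum(axis=1, keepdims=True)
        cpts[node] = CPT(
            node, cpt.parents, cpt.categories, cpt.parent_categories, table
        )
    return BayesianNetwork(schema, bn.dag, cpts)


def sample_records(bn: BayesianNetwork, n: int, seed: int) -> CohortTable:
    """Ancestral sampling: each node drawn from its CPT given sampled parents."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            shape = cpt.parent_shape
            flat = np.zeros(n, dtype=np.int64)
            for p, card in zip(cpt.parents, shape):
                flat = flat * card + codes[p]
            rows = cpt.table[flat]
        else:
            rows = np.tile(cpt.table[0], (n, 1))
        u = rng.random(n)
        cum = np.cumsum(rows, axis=1)
        codes[node] = (u[:, None] > cum).sum(axis=1).clip(0, rows.shape[1] - 1)
    data = {
        node: pd.Categorical.from_codes(
            codes[node], categories=list(bn.schema[node].categories)
        ).astype(str)
        for node in bn.schema.names
        if node in codes
    }
    schema = bn.schema.subset([v for v in bn.schema.names if v in codes])
    return CohortTable(schema, pd.DataFrame(data))


def sample_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a cohort, applying any planted divergences to the network first."""
    bn = config.network
    for cond, stage_set, target, delta in config.planted:
        bn = plant_divergence(bn, cond, stage_set, target, delta)
    return sample_records(bn, config.n, config.seed)


def plant_divergence(
    network: BayesianNetwork,
    cond: Condition,
    stage_set: Sequence[str | None],
    target: str,
    delta: float,
    stage_variable: str = "S",
    max_rounds: int = 80,
) -> BayesianNetwork:
    """Return a network where P(cond | S=s, T=target) - P(cond | S=s, T=other)
    is at least ``delta - 0.02`` in every stage of ``stage_set``.

    The CPT of ``cond.variable`` is rescaled multiplicatively: mass moves
    toward the category on treatment-target rows and away from it on the
    other rows, with renormalization spreading the change proportionally
    over the remaining categories. If the treatment is not yet a parent of
    the variable, the arc T -> variable is added (the CPT is tiled along the
    new axis); planting on the stage or treatment variable is an error.
    """
    schema = network.schema
    t_name = schema.treatment.name
    if cond.variable in (t_name, stage_variable):
        raise ValueError(f"cannot plant a divergence on {cond.variable!r}")
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    if delta == 0.0:
        return network
    other = [c for c in schema.treatment.categories if c != target][0]
    cat_idx = schema[cond.variable].index(cond.category)
    target_idx = schema.treatment.index(target)

    dag = network.dag
    cpts = dict(network.cpts)
    v = cond.variable
    if t_name not in dag.parents(v):
        new_arcs = set(dag.arcs) | {(t_name, v)}
        if not would_be_acyclic(dag.nodes, new_arcs):
            raise ValueError(
                f"cannot plant on {v!r}: adding the treatment as a parent "
                "would create a cycle"
            )
        dag = DAG(dag.nodes, tuple(sorted(new_arcs)))
        old = cpts[v]
        parents = tuple(sorted(old.parents + (t_name,)))
        p_cats = tuple(schema[p].categories for p in parents)
        shape = old.parent_shape + (len(old.categories),)
        # tile the old table along the new treatment axis, preserving order
        old_arr = old.table.reshape(shape) if old.parents else old.table[0]
        n_rows = int(np.prod([len(c) for c in p_cats]))
        table = np.zeros((n_rows, len(old.categories)))
        grid = np.unravel_index(
            np.arange(n_rows), tuple(len(c) for c in p_cats)
        )
        for r in range(n_rows):
            if old.parents:
                idx = tuple(grid[parents.index(p)][r] for p in old.parents)
                table[r] = old_arr[idx]
            else:
                table[r] = old_arr
        cpts[v] = CPT(v, parents, old.categories, p_cats, table)

    def achieved(bn: BayesianNetwork) -> float:
        diffs = []
        for stage in stage_set:
            ev_t = {t_name: target}
            ev_o = {t_name: other}
            if stage is not None:
                ev_t[stage_variable] = stage
                ev_o[stage_variable] = stage
            p_t = query(bn, v, ev_t)[cond.category]
            p_o = query(bn, v, ev_o)[cond.category]
            diffs.append(p_t - p_o)
        return min(diffs)

    cpt = cpts[v]
    t_axis = cpt.parents.index(t_name)
    n_rows = cpt.table.shape[0]
    grid = np.unravel_index(np.arange(n_rows), cpt.parent_shape)
    on_target = grid[t_axis] == target_idx
    factor = 1.12
    bn = BayesianNetwork(schema, dag, cpts)
    for _ in range(max_rounds):
        if achieved(bn) >= delta - 0.02:
            return bn
        table = cpts[v].table.copy()
        up = table[on_target, cat_idx] * factor
        table[on_target, cat_idx] = np.minimum(up, 0.995)
        table[~on_target, cat_idx] = table[~on_target, cat_idx] / factor
        table = table / table.sum(axis=1, keepdims=True)
        cpts = dict(cpts)
        cpts[v] = CPT(
            v, cpt.parents, cpt.categories, cpt.parent_categories, table
        )
        bn = BayesianNetwork(schema, dag, cpts)
    raise ValueError(
        f"could not reach divergence {delta} on {cond} within {max_rounds} rounds"
    )


def marginal_report(table: CohortTable, network: BayesianNetwork) -> pd.DataFrame:
    """Empirical minus exact marginal per category, with binomial SEs."""
    if set(table.schema.names) != set(network.schema.names):
        raise ValueError("cohort schema does not match network schema")
    exact = _exact_marginals(network)
    rows = []
    n = table.n
    for var in network.dag.nodes:
        counts = table.records[var].value_counts()
        for i, cat in enumerate(network.schema[var].categories):
            p = exact[var][i]
            emp = counts.get(cat, 0) / n if n else 0.0
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "empirical": emp,
                    "exact": p,
                    "deviation": emp - p,
                    "se": float(np.sqrt(p * (1 - p) / n)) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
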