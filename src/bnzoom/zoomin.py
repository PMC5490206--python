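"""The zoom-in heuristic: iterative subgroup characterization on a network.

The heuristic grows an ordered conditioning set v* of (variable, category)
pairs whose conditional probability, given stage and the conditions selected
so far, is higher under the target treatment than under the alternative by
more than a tolerance (default 0.04). The first iteration scans clinical
variables only (they should be the leading determinants of treatment); later
iterations scan clinical and non-clinical variables alike. With several
stages under study, a category qualifies only if its signed difference
exceeds the tolerance in every stage, and candidates are ranked by their
minimum difference across stages.

The difference is signed toward the target treatment, not absolute: a
category much more probable under the *other* treatment characterizes the
complementary group and is never selected for the target's profile.

Inference is abstracted behind a small backend protocol so that a fitted
network and a table of published conditional probabilities are
interchangeable; the latter backs the worked-example reproductions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Protocol, Sequence

from .infer import query
from .network import BayesianNetwork
from .schema import BCS, BCSR, VariableSchema, detroit_schema

DEFAULT_TOLERANCE = 0.04


@dataclass(frozen=True, order=True)
class Condition:
    """One (variable, category) membership condition."""

    variable: str
    category: str


class InferenceBackend(Protocol):
    """Minimal conditional-query surface the heuristic needs."""

    schema: VariableSchema

    def conditional(
        self, variable: str, evidence: Mapping[str, str]
    ) -> dict[str, float] | None:
        """P(variable | evidence), or None when the backend cannot answer."""


class NetworkBackend:
    """Exact-query backend over a fitted :class:`BayesianNetwork`."""

    def __init__(self, bn: BayesianNetwork):
        self.bn = bn
        self.schema = bn.schema

    def conditional(self, variable, evidence):
        return query(self.bn, variable, evidence)


class TableBackend:
    """Backend answering only from a fixed set of conditional tables.

    Each block provides P(variable | evidence, T=t) for both treatments.
    Queries outside the stored blocks return None, so the heuristic simply
    skips variables the tables do not cover — which is exactly how a
    published subset of a model's query results behaves.
    """

    def __init__(self, blocks: Sequence[dict], schema: VariableSchema):
        self.schema = schema
        self._index: dict[tuple[str, frozenset], dict[str, float]] = {}
        for block in blocks:
            base = frozenset(block["evidence"].items())
            for t_cat, probs in block["probs"].items():
                key = (block["variable"], base | {(schema.treatment.name, t_cat)})
                self._index[key] = dict(probs)

    @classmethod
    def load_detroit(cls) -> "TableBackend":
        with resources.files("bnzoom.data").joinpath(
            "printed_conditionals_detroit.json"
        ).open(encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(raw["blocks"], detroit_schema())

    def conditional(self, variable, evidence):
        return self._index.get((variable, frozenset(evidence.items())))


def _as_backend(model) -> InferenceBackend:
    if isinstance(model, BayesianNetwork):
        return NetworkBackend(model)
    return model


def _other_treatment(schema: VariableSchema, target: str) -> str:
    cats = schema.treatment.categories
    if target not in cats:
        raise ValueError(f"unknown treatment {target!r}")
    others = [c for c in cats if c != target]
    return others[0]


def _evidence(
    schema: VariableSchema,
    stage: str | None,
    treatment: str,
    conditions: Sequence[Condition],
    stage_variable: str,
) -> dict[str, str]:
    ev = {}
    if stage is not None:
        ev[stage_variable] = stage
    ev[schema.treatment.name] = treatment
    for cond in conditions:
        ev[cond.variable] = cond.category
    return ev


def signed_difference(
    model,
    cond: Condition,
    stage: str | None,
    target: str,
    conditions: Sequence[Condition] = (),
    stage_variable: str = "S",
) -> float | None:
    """P(cond | stage, T=target, v*) - P(cond | stage, T=other, v*).

    Positive values favor the target treatment. Returns None when the
    backend cannot answer the query.
    """
    backend = _as_backend(model)
    schema = backend.schema
    if any(c.variable == cond.variable for c in conditions):
        raise ValueError(f"{cond.variable!r} is already conditioned")
    other = _other_treatment(schema, target)
    p_t = backend.conditional(
        cond.variable, _evidence(schema, stage, target, conditions, stage_variable)
    )
    p_o = backend.conditional(
        cond.variable, _evidence(schema, stage, other, conditions, stage_variable)
    )
    if p_t is None or p_o is None:
        return None
    return p_t.get(cond.category, 0.0) - p_o.get(cond.category, 0.0)


@dataclass(frozen=True)
class Candidate:
    """One examined (variable, category) with its per-stage differences."""

    condition: Condition
    differences: tuple[tuple[str | None, float], ...]  # (stage, signed diff)
    min_difference: float
    qualifies: bool


@dataclass(frozen=True)
class Iteration:
    index: int
    scanned: tuple[str, ...]
    candidates: tuple[Candidate, ...]
    selection: Condition | None


@dataclass(frozen=True)
class ZoomInTrace:
    """Full record of a heuristic run: selections and per-iteration scans."""

    stage_set: tuple[str | None, ...]
    target: str
    other: str
    tolerance: float
    selected: tuple[Condition, ...]
    iterations: tuple[Iteration, ...]
    terminated: str  # "no-candidates" | "exhausted"
    stage_variable: str = "S"

    def to_json(self) -> dict:
        return {
            "stage_set": list(self.stage_set),
            "target": self.target,
            "other": self.other,
            "tolerance": self.tolerance,
            "stage_variable": self.stage_variable,
            "selected": [
                {"variable": c.variable, "category": c.category}
                for c in self.selected
            ],
            "terminated": self.terminated,
            "iterations": [
                {
                    "index": it.index,
                    "scanned": list(it.scanned),
                    "selection": (
                        {"variable": it.selection.variable,
                         "category": it.selection.category}
                        if it.selection else None
                    ),
                    "candidates": [
                        {
                            "variable": c.condition.variable,
                            "category": c.condition.category,
                            "differences": [
                                {"stage": s, "difference": d}
                                for s, d in c.differences
                            ],
                            "min_difference": c.min_difference,
                            "qualifies": c.qualifies,
                        }
                        for c in it.candidates
                    ],
                }
                for it in self.iterations
            ],
        }


def _scan(
    backend: InferenceBackend,
    scan_vars: Sequence[str],
    stage_set: Sequence[str | None],
    target: str,
    conditions: Sequence[Condition],
    tolerance: float,
    stage_variable: str,
) -> list[Candidate]:
    candidates = []
    for var in sorted(scan_vars):
        for cat in backend.schema[var].categories:
            cond = Condition(var, cat)
            diffs = []
            available = True
            for stage in stage_set:
                d = signed_difference(
                    backend, cond, stage, target, conditions, stage_variable
                )
                if d is None:
                    available = False
                    break
                diffs.append((stage, d))
            if not available:
                break  # backend cannot answer for this variable at all
            min_diff = min(d for _, d in diffs)
            candidates.append(
                Candidate(cond, tuple(diffs), min_diff, min_diff > tolerance)
            )
    return candidates


def find_candidates(
    model,
    scan_vars: Sequence[str],
    stage_set: Sequence[str | None],
    target: str,
    conditions: Sequence[Condition] = (),
    tolerance: float = DEFAULT_TOLERANCE,
    stage_variable: str = "S",
) -> list[tuple[Condition, float]]:
    """Qualifying (condition, min-over-stages difference) pairs."""
    backend = _as_backend(model)
    cands = _scan(
        backend, scan_vars, stage_set, target, conditions, tolerance, stage_variable
    )
    return [(c.condition, c.min_difference) for c in cands if c.qualifies]


def _scannable(
    schema: VariableSchema,
    conditions: Sequence[Condition],
    stage_variable: str,
    clinical_only: bool,
) -> list[str]:
    used = {c.variable for c in conditions}
    pool = schema.clinical if clinical_only else schema.clinical + schema.non_clinical
    return [
        v for v in pool
        if v != stage_variable and v != schema.treatment.name and v not in used
    ]


def _run(
    backend: InferenceBackend,
    stage_set: Sequence[str | None],
    target: str,
    tolerance: float,
    initial: Sequence[Condition],
    start_index: int,
    stage_variable: str,
) -> tuple[list[Condition], list[Iteration], str]:
    selected = list(initial)
    iterations: list[Iteration] = []
    index = start_index
    terminated = "no-candidates"
    while True:
        clinical_only = index == 1
        scan_vars = _scannable(backend.schema, selected, stage_variable, clinical_only)
        if not scan_vars:
            terminated = "exhausted"
            break
        candidates = _scan(
            backend, scan_vars, stage_set, target, selected, tolerance, stage_variable
        )
        qualifying = [c for c in candidates if c.qualifies]
        if not qualifying:
            iterations.append(Iteration(index, tuple(scan_vars), tuple(candidates), None))
            terminated = "no-candidates"
            break
        best = min(
            qualifying,
            key=lambda c: (-c.min_difference, c.condition.variable, c.condition.category),
        )
        iterations.append(
            Iteration(index, tuple(scan_vars), tuple(candidates), best.condition)
        )
        selected.append(best.condition)
        index += 1
    return selected, iterations, terminated


def zoomin_run(
    model,
    stage_set: Sequence[str | None],
    target: str,
    tolerance: float = DEFAULT_TOLERANCE,
    stage_variable: str = "S",
) -> ZoomInTrace:
    """Run the full heuristic and return its trace.

    ``stage_set`` lists the stage categories conditioned on in every query; a
    single ``None`` entry means no stage conditioning (used after refitting a
    network within one stage).
    """
    if not stage_set:
        raise ValueError("stage_set must be nonempty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    backend = _as_backend(model)
    other = _other_treatment(backend.schema, target)
    selected, iterations, terminated = _run(
        backend, tuple(stage_set), target, tolerance, (), 1, stage_variable
    )
    return ZoomInTrace(
        tuple(stage_set), target, other, tolerance,
        tuple(selected), tuple(iterations), terminated, stage_variable,
    )


def zoomin_branch(
    model,
    base: ZoomInTrace,
    branch: Condition,
    at_depth: int,
    tolerance: float | None = None,
) -> ZoomInTrace:
    """Replace the selections after ``at_depth`` with ``branch`` and resume.

    Branching probes a manually chosen, non-maximal category — e.g. a
    subgroup receiving an unexpected treatment — and re-runs the remaining
    iterations from that conditioning set.
    """
    if not 0 <= at_depth <= len(base.selected):
        raise ValueError("at_depth outside the base trace")
    kept = base.selected[:at_depth]
    if any(c.variable == branch.variable for c in kept):
        raise ValueError(
            f"{branch.variable!r} already conditioned at or before depth {at_depth}"
        )
    backend = _as_backend(model)
    tol = base.tolerance if tolerance is None else tolerance
    initial = list(kept) + [branch]
    selected, iterations, terminated = _run(
        backend, base.stage_set, base.target, tol, initial,
        at_depth + 2, base.stage_variable,
    )
    return ZoomInTrace(
        base.stage_set, base.target, base.other, tol,
        tuple(selected), tuple(iterations), terminated, base.stage_variable,
    )


def stage_controlled_run(
    table,
    stage: str,
    target: str,
    learn_config: Mapping | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    stage_variable: str = "S",
) -> ZoomInTrace:
    """Refit the network within one stage and run the heuristic there.

    The cohort is filtered to ``stage`` (dropping the now-constant stage
    variable), the structure is relearned (or a fixed DAG restricted to the
    remaining variables is used) and CPTs refitted, and the heuristic runs
    with stage conditioning removed from the queries.
    """
    from .cohort import filter_by_stage
    from .learn import average_network, bootstrap_arc_strength, fit_cpts, hill_climb

    cfg = dict(learn_config or {})
    sub = filter_by_stage(table, {stage}, stage_variable, drop_constant=True)
    fixed = cfg.get("dag")
    if fixed is not None:
        keep = [n for n in fixed.nodes if n in sub.schema]
        arcs = [(p, c) for p, c in fixed.arcs if p in keep and c in keep]
        dag = fixed.__class__(tuple(keep), tuple(arcs))
    else:
        replicates = int(cfg.get("replicates", 0))
        score = cfg.get("score", "bic")
        max_iter = int(cfg.get("max_iter", 200))
        seed = int(cfg.get("seed", 0))
        if replicates > 0:
            strengths = bootstrap_arc_strength(
                sub, replicates=replicates, seed=seed, score=score, max_iter=max_iter
            )
            dag = average_network(strengths, float(cfg.get("threshold", 0.25)))
        else:
            dag = hill_climb(sub, score=score, max_iter=max_iter, seed=seed)
    bn = fit_cpts(dag, sub, pseudo_count=float(cfg.get("pseudo_count", 1.0)))
    return zoomin_run(
        bn, (None,), target, tolerance=tolerance, stage_variable=stage_variable
    )


__all__ = [
    "BCS",
    "BCSR",
    "Candidate",
    "Condition",
    "DEFAULT_TOLERANCE",
    "InferenceBackend",
    "Iteration",
    "NetworkBackend",
    "TableBackend",
    "ZoomInTrace",
    "find_candidates",
    "signed_difference",
    "stage_controlled_run",
    "zoomin_branch",
    "zoomin_run",
]
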