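"""End-to-end orchestration: load/simulate -> learn -> fit -> zoom-in -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import __version__
from .cohort import CohortTable, load_cohort, split_train_test
from .evaluation import compare_models, fit_logistic_baseline
from .learn import average_network, bootstrap_arc_strength, fit_cpts, hill_climb
from .network import DAG
from .schema import BCSR, VariableSchema, detroit_schema
from .zoomin import zoomin_run


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a full regional analysis."""

    cohort_path: str | None = None
    region: str = "unnamed"
    train_fraction: float = 0.7
    seed: int = 0
    # structure learning
    fixed_dag: DAG | None = None
    replicates: int = 0
    threshold: float = 0.25
    score: str = "bic"
    max_iter: int = 200
    pseudo_count: float = 1.0
    # heuristic runs: list of (stage_set tuple, target treatment)
    heuristic_runs: tuple = ((("0",), "BCS"), (("I", "IIA", "IIB"), "BCSR"))
    tolerance: float = 0.04
    stage_variable: str = "S"
    # evaluation
    positive: str = BCSR
    exclude: tuple = ()

    def to_json(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items()
            if k not in ("fixed_dag", "heuristic_runs")
        }
        d["fixed_dag"] = self.fixed_dag.to_json() if self.fixed_dag else None
        d["heuristic_runs"] = [
            {"stage_set": list(s), "target": t} for s, t in self.heuristic_runs
        ]
        return d


def run_full(
    config: RunConfig,
    table: CohortTable | None = None,
    schema: VariableSchema | None = None,
) -> dict:
    """Execute split -> learn/fix -> fit -> heuristic runs -> evaluation.

    ``table`` may be passed directly (e.g. a simulated cohort); otherwise the
    cohort CSV named in the config is loaded against ``schema`` (Detroit
    schema by default). Returns a JSON-serializable report embedding the
    config, learned DAG, traces, and metrics.
    """
    if table is None:
        if config.cohort_path is None:
            raise ValueError("load stage failed: no cohort path or table given")
        try:
            table = load_cohort(config.cohort_path, schema or detroit_schema())
        except FileNotFoundError as exc:
            raise RuntimeError(f"load stage failed: {exc}") from exc

    train, test = split_train_test(table, config.train_fraction, config.seed)

    if config.fixed_dag is not None:
        dag = config.fixed_dag
    elif config.replicates > 0:
        strengths = bootstrap_arc_strength(
            train, replicates=config.replicates, seed=config.seed,
            score=config.score, max_iter=config.max_iter,
        )
        dag = average_network(strengths, config.threshold)
    else:
        dag = hill_climb(
            train, score=config.score, max_iter=config.max_iter, seed=config.seed
        )

    bn = fit_cpts(dag, train, pseudo_count=config.pseudo_count)

    traces = []
    for stage_set, target in config.heuristic_runs:
        trace = zoomin_run(
            bn, tuple(stage_set), target,
            tolerance=config.tolerance, stage_variable=config.stage_variable,
        )
        traces.append(trace.to_json())

    lr = fit_logistic_baseline(train, exclude=config.exclude)
    comparison = compare_models(
        bn, lr, test, positive=config.positive, exclude=config.exclude
    )

    return {
        "version": __version__,
        "region": config.region,
        "config": config.to_json(),
        "n_train": train.n,
        "n_test": test.n,
        "dag": dag.to_json(),
        "traces": traces,
        "evaluation": {
            name: {
                "metrics": res["metrics"].to_json(),
                "confusion": {
                    "tp": res["confusion"].tp, "fp": res["confusion"].fp,
                    "tn": res["confusion"].tn, "fn": res["confusion"].fn,
                    "positive": res["confusion"].positive_label,
                },
            }
            for name, res in comparison.items()
        },
    }
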