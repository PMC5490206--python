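"""Cohort tables: I/O, treatment contingency tabulation, stage filtering, splits.

A :class:`CohortTable` is a patient-level table of categorical records
validated against a :class:`~bnzoom.schema.VariableSchema`. Internally it is a
pandas DataFrame with one column per schema variable, in schema order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import BCS, BCSR, SchemaError, VariableSchema

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed registry tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CohortTable:
    """Patient-level categorical records conforming to a schema."""

    schema: VariableSchema
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [n for n in self.schema.names if n not in df.columns]
        if missing:
            raise SchemaError(f"records missing schema columns: {missing}")
        df = df[list(self.schema.names)].reset_index(drop=True)
        for var in self.schema:
            col = df[var.name]
            bad = ~col.isin(var.categories)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"row {row}: value {col.iloc[row]!r} is not a category of "
                    f"variable {var.name!r}"
                )
        object.__setattr__(self, "records", df)

    @property
    def n(self) -> int:
        return len(self.records)

    def codes(self) -> np.ndarray:
        """Integer-coded records, shape (n, n_variables), schema category order."""
        cols = []
        for var in self.schema:
            cat = pd.Categorical(
                self.records[var.name], categories=list(var.categories)
            )
            cols.append(cat.codes.astype(np.int64))
        if not cols:
            return np.empty((0, 0), dtype=np.int64)
        return np.column_stack(cols)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.schema, self.records.loc[mask])


@dataclass(frozen=True)
class TreatmentContingency:
    """Per-(variable, category) counts and row percentages by treatment.

    ``rows`` has columns: variable, category, count_BCS, pct_BCS, count_BCSR,
    pct_BCSR, total. The first row is the "All Patients" summary.
    """

    rows: pd.DataFrame

    def row(self, variable: str, category: str) -> pd.Series:
        sel = self.rows[
            (self.rows["variable"] == variable) & (self.rows["category"] == category)
        ]
        if sel.empty:
            raise KeyError((variable, category))
        return sel.iloc[0]


def _pct_rows(var: str, cat: str, n_bcs: int, n_bcsr: int) -> dict:
    total = n_bcs + n_bcsr
    return {
        "variable": var,
        "category": cat,
        "count_BCS": n_bcs,
        "pct_BCS": round_half_away(100.0 * n_bcs / total) if total else 0.0,
        "count_BCSR": n_bcsr,
        "pct_BCSR": round_half_away(100.0 * n_bcsr / total) if total else 0.0,
        "total": total,
    }


def tabulate_by_treatment(table: CohortTable) -> TreatmentContingency:
    """Registry-style contingency: counts and row percentages by treatment."""
    if table.n == 0:
        raise ValueError("cannot tabulate an empty cohort")
    t_name = table.schema.treatment.name
    t_col = table.records[t_name]
    rows = [_pct_rows("All", "All Patients", int((t_col == BCS).sum()),
                      int((t_col == BCSR).sum()))]
    for var in table.schema:
        if var.name == t_name:
            continue
        for cat in var.categories:
            in_cat = table.records[var.name] == cat
            rows.append(
                _pct_rows(
                    var.name, cat,
                    int((in_cat & (t_col == BCS)).sum()),
                    int((in_cat & (t_col == BCSR)).sum()),
                )
            )
    return TreatmentContingency(pd.DataFrame(rows))


def contingency_from_counts(raw: dict) -> TreatmentContingency:
    """Rebuild a contingency from packaged count data, recomputing percentages.

    ``raw`` follows the packaged Table-1 JSON layout; stored (printed)
    percentages are ignored and recomputed from the counts, so callers can
    check the transcription against the printed values.
    """
    rows = [
        _pct_rows("All", "All Patients", raw["all_patients"]["BCS"],
                  raw["all_patients"]["BCSR"])
    ]
    for v in raw["variables"]:
        if all("BCS" in c for c in v["categories"]):
            for c in v["categories"]:
                rows.append(_pct_rows(v["name"], c["label"], c["BCS"], c["BCSR"]))
    return TreatmentContingency(pd.DataFrame(rows))


def load_cohort(path, schema: VariableSchema) -> CohortTable:
    """Read a cohort CSV (UTF-8, one patient per row) against ``schema``.

    Columns beyond the schema are ignored with a warning; a missing schema
    column or an out-of-vocabulary cell raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    extra = [c for c in df.columns if c not in schema.names]
    if extra:
        logger.warning("ignoring extra columns: %s", extra)
    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing schema columns: {missing}")
    return CohortTable(schema, df[list(schema.names)])


def write_cohort(table: CohortTable, path) -> None:
    table.records.to_csv(path, index=False)


def filter_by_stage(
    table: CohortTable,
    stages: set[str] | list[str],
    stage_variable: str = "S",
    drop_constant: bool = False,
) -> CohortTable:
    """Restrict the cohort to records whose stage is in ``stages``.

    With ``drop_constant``, variables left with a single observed category
    (always the stage variable itself when one stage is kept) are removed
    from the returned schema — used when refitting a network within a stage.
    """
    var = table.schema[stage_variable]
    stages = set(stages)
    bad = stages - set(var.categories)
    if bad:
        raise SchemaError(f"unknown stage categories: {sorted(bad)}")
    mask = table.records[stage_variable].isin(stages).to_numpy()
    if not mask.any():
        raise ValueError(f"no patients in stages {sorted(stages)}")
    sub = table.records.loc[mask]
    schema = table.schema
    if drop_constant:
        keep = [n for n in schema.names if sub[n].nunique() > 1]
        schema = schema.subset(keep)
        sub = sub[keep]
    return CohortTable(schema, sub)


def split_train_test(
    table: CohortTable, train_fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Simple-random disjoint partition; train size = floor(fraction * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n
    n_train = math.floor(train_fraction * n)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return (
        CohortTable(table.schema, table.records.iloc[train_idx]),
        CohortTable(table.schema, table.records.iloc[test_idx]),
    )
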