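"""Variable schemas for categorical cancer-registry cohorts.

A cohort is described by an ordered set of categorical variables, each with a
fixed category vocabulary and a role: ``clinical`` (tumor and patient biology:
age, histology, grade, primary site, stage, invasiveness, behavior, tumor
size), ``non-clinical`` (registry context: race/ethnicity, marital status,
insurance, willingness to receive radiotherapy, year of diagnosis) or
``treatment`` (the binary outcome, breast-conservation surgery without
radiotherapy, BCS, vs with radiotherapy, BCSR).

``Unknown``/``Undetermined`` are ordinary category levels, never missing
values: registries tabulate them and the subgroup heuristic can select them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

ROLE_CLINICAL = "clinical"
ROLE_NONCLINICAL = "non-clinical"
ROLE_TREATMENT = "treatment"
_ROLES = (ROLE_CLINICAL, ROLE_NONCLINICAL, ROLE_TREATMENT)

BCS = "BCS"
BCSR = "BCSR"
TREATMENTS = (BCS, BCSR)


class SchemaError(ValueError):
    """A table or record does not conform to the variable schema."""


@dataclass(frozen=True)
class Variable:
    """One categorical variable: name, role, ordered category vocabulary."""

    name: str
    role: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if len(self.categories) < 2:
            raise SchemaError(f"variable {self.name!r} needs >=2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"duplicate categories in {self.name!r}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise SchemaError(
                f"{category!r} is not a category of variable {self.name!r}"
            ) from None


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of :class:`Variable` with exactly one treatment."""

    variables: tuple[Variable, ...]
    _by_name: Mapping[str, Variable] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        treatments = [v for v in self.variables if v.role == ROLE_TREATMENT]
        if len(treatments) != 1:
            raise SchemaError("schema must contain exactly one treatment variable")
        object.__setattr__(self, "_by_name", {v.name: v for v in self.variables})

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Variable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"no variable named {name!r} in schema") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def treatment(self) -> Variable:
        return next(v for v in self.variables if v.role == ROLE_TREATMENT)

    @property
    def clinical(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == ROLE_CLINICAL)

    @property
    def non_clinical(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == ROLE_NONCLINICAL)

    def validate_assignment(self, assignment: Mapping[str, str]) -> None:
        """Raise :class:`SchemaError` unless every variable gets a valid category."""
        for var in self.variables:
            if var.name not in assignment:
                raise SchemaError(f"assignment missing variable {var.name!r}")
            var.index(assignment[var.name])

    def subset(self, names: list[str] | tuple[str, ...]) -> "VariableSchema":
        """Schema restricted to ``names`` (order preserved from this schema)."""
        keep = set(names)
        return VariableSchema(
            tuple(v for v in self.variables if v.name in keep)
        )

    def to_json(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "role": v.role, "categories": list(v.categories)}
                for v in self.variables
            ]
        }

    @classmethod
    def from_json(cls, obj: dict) -> "VariableSchema":
        return cls(
            tuple(
                Variable(d["name"], d["role"], tuple(d["categories"]))
                for d in obj["variables"]
            )
        )


def _load_data(name: str) -> dict:
    with resources.files("bnzoom.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def load_table1() -> dict:
    """Packaged Detroit treatment contingency (counts and printed percentages)."""
    return _load_data("table1_detroit.json")


def detroit_schema() -> VariableSchema:
    """The 14-variable Detroit SEER schema, with Table-1 category vocabularies."""
    raw = load_table1()
    variables = []
    for v in raw["variables"]:
        cats = tuple(c["label"] for c in v["categories"])
        variables.append(Variable(v["name"], v["role"], cats))
    return VariableSchema(tuple(variables))
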