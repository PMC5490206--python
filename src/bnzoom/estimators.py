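"""Scikit-learn style estimators for treatment prediction.

Two classifiers share the sklearn fit/predict contract so they can be
compared head-to-head and dropped into sklearn model selection:

* :class:`BNTreatmentClassifier` — learns (or accepts) a Bayesian-network
  structure over all variables, fits CPTs, and predicts the treatment as the
  argmax of the exact posterior given a record's other variables.
* :class:`LogisticTreatmentBaseline` — unpenalized binary logistic regression
  on indicator-coded categories, the field's traditional baseline.

Both accept ``X`` as a pandas DataFrame of categorical columns and ``y`` as
treatment labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .cohort import CohortTable
from .infer import predict_treatment, query
from .learn import average_network, bootstrap_arc_strength, fit_cpts, hill_climb
from .schema import (
    BCS,
    BCSR,
    ROLE_CLINICAL,
    ROLE_TREATMENT,
    Variable,
    VariableSchema,
)


def _infer_schema(X: pd.DataFrame, y: pd.Series, treatment_name: str) -> VariableSchema:
    variables = []
    for col in X.columns:
        cats = tuple(sorted(pd.unique(X[col].astype(str))))
        variables.append(Variable(str(col), ROLE_CLINICAL, cats))
    t_cats = tuple(sorted(pd.unique(pd.Series(y).astype(str))))
    variables.append(Variable(treatment_name, ROLE_TREATMENT, t_cats))
    return VariableSchema(tuple(variables))


class BNTreatmentClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian-network classifier for treatment receipt.

    Parameters
    ----------
    structure : "learn" or "fixed"
        Learn the DAG by BIC hill climbing (optionally bootstrap-averaged)
        or use the DAG supplied in ``dag`` (e.g. a physician-validated one).
    dag : DAG, optional
        Required when ``structure="fixed"``.
    replicates : int
        Number of bootstrap replicates for model averaging; 0 means a single
        hill climb on the training data.
    threshold : float
        Minimum bootstrap arc strength retained by model averaging.
    score : "bic" or "bdeu"
        Structure-learning score.
    pseudo_count : float
        Laplace smoothing added to every CPT cell; keeps sparse strata
        (single-patient categories) from producing zero conditioning rows.
    exclude : tuple of str
        Variables withheld from the prediction evidence (they still
        participate in the joint model).
    schema : VariableSchema, optional
        Category vocabularies; inferred from the training data when omitted.
    """

    def __init__(
        self,
        structure: str = "learn",
        dag=None,
        replicates: int = 0,
        threshold: float = 0.25,
        score: str = "bic",
        max_iter: int = 200,
        pseudo_count: float = 1.0,
        exclude: tuple = (),
        schema=None,
        treatment_name: str = "T",
        random_state: int = 0,
    ):
        self.structure = structure
        self.dag = dag
        self.replicates = replicates
        self.threshold = threshold
        self.score = score
        self.max_iter = max_iter
        self.pseudo_count = pseudo_count
        self.exclude = exclude
        self.schema = schema
        self.treatment_name = treatment_name
        self.random_state = random_state

    def _table(self, X: pd.DataFrame, y) -> CohortTable:
        schema = self.schema
        t_name = schema.treatment.name if schema is not None else self.treatment_name
        df = X.copy()
        df[t_name] = np.asarray(y)
        if schema is None:
            schema = _infer_schema(X, df[t_name], t_name)
        return CohortTable(schema, df)

    def fit(self, X: pd.DataFrame, y):
        table = self._table(X, y)
        self.schema_ = table.schema
        if self.structure == "fixed":
            if self.dag is None:
                raise ValueError("structure='fixed' requires a dag")
            dag = self.dag
        elif self.structure == "learn":
            if self.replicates > 0:
                strengths = bootstrap_arc_strength(
                    table,
                    replicates=self.replicates,
                    seed=self.random_state,
                    score=self.score,
                    max_iter=self.max_iter,
                )
                dag = average_network(strengths, self.threshold)
                self.arc_strengths_ = strengths
            else:
                dag = hill_climb(
                    table, score=self.score, max_iter=self.max_iter,
                    seed=self.random_state,
                )
        else:
            raise ValueError(f"unknown structure {self.structure!r}")
        self.dag_ = dag
        self.network_ = fit_cpts(dag, table, pseudo_count=self.pseudo_count)
        self.classes_ = np.asarray(sorted(self.schema_.treatment.categories))
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "network_")
        t_name = self.schema_.treatment.name
        out = np.zeros((len(X), len(self.classes_)))
        exclude = set(self.exclude)
        for i, (_, row) in enumerate(X.iterrows()):
            evidence = {
                k: str(v)
                for k, v in row.items()
                if k in self.schema_ and k != t_name and k not in exclude
            }
            posterior = query(self.network_, t_name, evidence)
            out[i] = [posterior.get(c, 0.0) for c in self.classes_]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "network_")
        t_name = self.schema_.treatment.name
        preds = []
        for _, row in X.iterrows():
            record = {
                k: str(v) for k, v in row.items()
                if k in self.schema_ and k != t_name
            }
            preds.append(
                predict_treatment(self.network_, record, exclude=set(self.exclude))
            )
        return np.asarray(preds)


class LogisticTreatmentBaseline(ClassifierMixin, BaseEstimator):
    """Unpenalized logistic regression on indicator-coded categories.

    Every covariate enters as dummies against a reference level (the first
    category alphabetically unless ``reference_levels`` names one). Aliased
    (linearly dependent) columns are dropped with a warning; perfect
    separation or non-convergence is recorded in ``fit_warnings_``. The
    positive class is BCSR and classification uses a 0.5 threshold.
    """

    def __init__(
        self,
        reference_levels: dict | None = None,
        exclude: tuple = (),
        positive: str = BCSR,
        max_iter: int = 2000,
    ):
        self.reference_levels = reference_levels
        self.exclude = exclude
        self.positive = positive
        self.max_iter = max_iter

    def _design(self, X: pd.DataFrame, fit: bool) -> pd.DataFrame:
        X = X[[c for c in X.columns if c not in set(self.exclude)]]
        dummies = []
        for col in X.columns:
            series = X[col].astype(str)
            if fit:
                levels = sorted(series.unique())
                ref = (self.reference_levels or {}).get(col, levels[0])
                if ref in levels:
                    levels = [ref] + [l for l in levels if l != ref]
                self._levels_[col] = levels
            levels = self._levels_[col]
            for level in levels[1:]:
                dummies.append(
                    (series == level).astype(float).rename(f"{col}={level}")
                )
        if not dummies:
            return pd.DataFrame(index=X.index)
        return pd.concat(dummies, axis=1)

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y).astype(str)).reset_index(drop=True)
        self.classes_ = np.asarray(sorted(y.unique()))
        self.fit_warnings_: list[str] = []
        self._levels_: dict[str, list[str]] = {}
        design = self._design(X, fit=True).reset_index(drop=True)
        y01 = (y == self.positive).astype(int).to_numpy()

        # drop aliased columns (rank-deficient design)
        if design.shape[1] > 1:
            mat = np.column_stack([np.ones(len(design)), design.to_numpy()])
            _, r = np.linalg.qr(mat)
            keep = np.abs(np.diag(r)) > 1e-8
            dropped = [c for c, k in zip(design.columns, keep[1:]) if not k]
            if dropped:
                warnings.warn(f"dropping aliased columns: {dropped}")
                self.fit_warnings_.append(f"aliased columns dropped: {dropped}")
                design = design[[c for c, k in zip(design.columns, keep[1:]) if k]]
        self._columns_ = list(design.columns)

        if design.shape[1] == 0:
            # intercept-only model: the base rate
            self.intercept_only_ = True
            rate = float(y01.mean())
            rate = min(max(rate, 1e-12), 1 - 1e-12)
            self.intercept_ = float(np.log(rate / (1 - rate)))
            self.coefficients_ = pd.Series(dtype=float)
            return self
        self.intercept_only_ = False
        model = LogisticRegression(
            penalty=None, solver="lbfgs", max_iter=self.max_iter
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(design.to_numpy(), y01)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                self.fit_warnings_.append(
                    "did not converge (possible perfect separation)"
                )
        self._model_ = model
        self.intercept_ = float(model.intercept_[0])
        self.coefficients_ = pd.Series(model.coef_[0], index=self._columns_)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coefficients_")
        if self.intercept_only_:
            p = 1.0 / (1.0 + np.exp(-self.intercept_))
            pos = np.full(len(X), p)
        else:
            design = self._design(X, fit=False)[self._columns_]
            pos = self._model_.predict_proba(design.to_numpy())[:, 1]
        out = np.zeros((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            out[:, j] = pos if c == self.positive else 1.0 - pos
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coefficients_")
        pos_idx = list(self.classes_).index(self.positive)
        pos = self.predict_proba(X)[:, pos_idx]
        negative = [c for c in self.classes_ if c != self.positive][0]
        return np.where(pos >= 0.5, self.positive, negative)


__all__ = ["BNTreatmentClassifier", "LogisticTreatmentBaseline", "BCS", "BCSR"]
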