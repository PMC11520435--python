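"""Covariate schema and reference-coded design-matrix construction.

A :class:`CovariateSchema` lists the categorical variables (labels, marginal
proportions, reference category) and the continuous variables (bounds,
distribution tag) of a child-level table.  :func:`encode_design` turns such a
table into an outcome vector plus a design matrix with an intercept first,
continuous columns passed through unscaled, and one dummy per non-reference
category labeled ``"Variable:Category"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gibbs import EncodedDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoricalSpec:
    """One categorical variable: labels with marginal proportions; the
    reference category (first label by default) gets no dummy column."""

    name: str
    labels: tuple[str, ...]
    proportions: tuple[float, ...]
    reference: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.proportions):
            raise ValueError(f"{self.name}: need one proportion per label")
        if len(self.labels) < 2:
            raise ValueError(f"{self.name}: need at least two categories")
        if any(p < 0 for p in self.proportions):
            raise ValueError(f"{self.name}: proportions must be nonnegative")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: proportions must sum to 1")
        ref = self.reference if self.reference is not None else self.labels[0]
        if ref not in self.labels:
            raise ValueError(f"{self.name}: reference '{ref}' not among labels")
        object.__setattr__(self, "reference", ref)


@dataclass(frozen=True)
class ContinuousSpec:
    """One continuous variable with its support and sampling distribution."""

    name: str
    low: float
    high: float
    distribution: str = "discrete_uniform"  # or "uniform"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: bounds must be ordered low < high")
        if self.distribution not in ("discrete_uniform", "uniform"):
            raise ValueError(f"{self.name}: unknown distribution tag '{self.distribution}'")


@dataclass(frozen=True)
class CovariateSchema:
    """Full covariate schema driving both encoding and synthetic generation."""

    categorical_specs: tuple[CategoricalSpec, ...]
    continuous_specs: tuple[ContinuousSpec, ...]

    @property
    def variable_names(self) -> list[str]:
        return [c.name for c in self.continuous_specs] + [c.name for c in self.categorical_specs]

    def design_labels(self) -> list[str]:
        """Design-column labels: intercept, continuous, then dummies."""
        labels = ["Intercept"]
        labels += [c.name for c in self.continuous_specs]
        for cat in self.categorical_specs:
            labels += [f"{cat.name}:{lab}" for lab in cat.labels if lab != cat.reference]
        return labels

    @property
    def n_design_columns(self) -> int:
        return len(self.design_labels())


def encode_design(table, schema: CovariateSchema, outcome_column: str = "bmi") -> EncodedDataset:
    """Encode a child-level table into an :class:`EncodedDataset`.

    Rows with missing values in the outcome or any schema variable are
    dropped (complete-case) with a logged count.  An unknown category raises
    an error naming the row and variable.
    """
    import pandas as pd

    missing_cols = [v for v in schema.variable_names + [outcome_column] if v not in table.columns]
    if missing_cols:
        raise ValueError(f"table is missing required columns: {missing_cols}")

    used = table[[outcome_column] + schema.variable_names]
    complete = used.dropna()
    dropped = len(used) - len(complete)
    if dropped:
        logger.info("dropped %d rows with missing values (complete-case)", dropped)

    n = len(complete)
    for cat in schema.categorical_specs:
        col = complete[cat.name]
        bad = ~col.isin(cat.labels)
        if bad.any():
            row = complete.index[bad][0]
            raise ValueError(
                f"unknown category {col.loc[row]!r} for variable '{cat.name}' at row {row}"
            )

    columns = [np.ones(n)]
    labels = ["Intercept"]
    for cont in schema.continuous_specs:
        columns.append(complete[cont.name].to_numpy(dtype=float))
        labels.append(cont.name)
    empty: list[str] = []
    for cat in schema.categorical_specs:
        col = complete[cat.name]
        for lab in cat.labels:
            if lab == cat.reference:
                continue
            dummy = (col == lab).to_numpy(dtype=float)
            if dummy.any():
                columns.append(dummy)
                labels.append(f"{cat.name}:{lab}")
            else:
                # a category absent from the data would add an all-zero
                # column and break the full-rank contract
                empty.append(f"{cat.name}:{lab}")
    if empty:
        logger.info("dropped %d empty dummy columns: %s", len(empty), empty)

    design = np.column_stack(columns)
    return EncodedDataset(
        outcome=complete[outcome_column].to_numpy(dtype=float),
        design=design,
        column_labels=labels,
    )
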