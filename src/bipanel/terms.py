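"""Fixed-effect terms and design-matrix construction for the expenditure model.

A model term is a (covariate, time_transform) pair.  A transform of ``"none"``
denotes the covariate's main effect; any other transform denotes the
interaction of the covariate indicator with that function of time (months
since the product's first expenditure record, starting at 1).  The pseudo
covariate ``"time"`` is the linear time main effect itself and takes no
transform.  At most one time transform per covariate is permitted in a spec.

Categorical covariates are dummy-coded against a fixed reference level, the
lexicographically smallest level of the registry.  The level registry is built
once from the full covariate table and then frozen, so that design columns are
identical across refits on subsets of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelTerm",
    "ModelSpec",
    "build_levels",
    "design_matrix",
    "time_basis",
    "TIME_TRANSFORMS",
    "BINARY_COVARIATES",
    "CATEGORICAL_COVARIATES",
]

BINARY_COVARIATES = ("orphan", "ce", "fic")
CATEGORICAL_COVARIATES = ("tumor_site", "molecule_type")
SPECIAL_COVARIATES = ("intercept", "time")
ALL_COVARIATES = SPECIAL_COVARIATES + BINARY_COVARIATES + CATEGORICAL_COVARIATES

#: time transforms offered as interaction bases: t, t^2 ... t^6 and sqrt(t)
TIME_TRANSFORMS = ("t", "t2", "t3", "t4", "t5", "t6", "sqrt")

_TRANSFORM_LABEL = {
    "t": "t",
    "t2": "t^2",
    "t3": "t^3",
    "t4": "t^4",
    "t5": "t^5",
    "t6": "t^6",
    "sqrt": "sqrt(t)",
}


def time_basis(transform: str, t: np.ndarray) -> np.ndarray:
    """Evaluate a time transform on a vector of month indices (t >= 1)."""
    t = np.asarray(t, dtype=float)
    if transform == "sqrt":
        return np.sqrt(t)
    if transform in ("t", "t1"):
        return t
    if transform in ("t2", "t3", "t4", "t5", "t6"):
        return t ** int(transform[1])
    raise ValueError(f"unknown time transform {transform!r}")


@dataclass(frozen=True)
class ModelTerm:
    """One fixed-effect term: a covariate and an optional time transform."""

    covariate: str
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.covariate not in ALL_COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.covariate in SPECIAL_COVARIATES:
            if self.transform != "none":
                raise ValueError(
                    f"{self.covariate!r} takes no time transform "
                    "(use covariate='time' for the linear time effect)"
                )
        elif self.transform != "none" and self.transform not in TIME_TRANSFORMS:
            raise ValueError(f"unknown time transform {self.transform!r}")

    @property
    def label(self) -> str:
        if self.covariate == "intercept":
            return "intercept"
        if self.transform == "none":
            return self.covariate
        return f"{_TRANSFORM_LABEL[self.transform]}:{self.covariate}"

    def to_dict(self) -> dict:
        return {"covariate": self.covariate, "transform": self.transform}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelTerm":
        return cls(d["covariate"], d.get("transform", "none"))


def build_levels(profiles: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """Freeze the categorical level registry from a full covariate table.

    Reference level of each categorical covariate is the lexicographically
    smallest level.
    """
    levels: dict[str, tuple[str, ...]] = {}
    for cov in CATEGORICAL_COVARIATES:
        if cov in profiles.columns:
            levels[cov] = tuple(sorted(profiles[cov].astype(str).unique()))
    return levels


@dataclass(frozen=True)
class ModelSpec:
    """Declarative fixed-effects structure.

    The random structure (per-product intercept + time slope) and the AR(1)
    within-product residual correlation are fixed by design and are not part
    of the spec.
    """

    terms: tuple[ModelTerm, ...]
    levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "levels", dict(self.levels))
        if not terms or terms[0] != ModelTerm("intercept"):
            raise ValueError("spec must start with the intercept term")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in spec")
        seen: dict[str, str] = {}
        for tm in terms:
            if tm.transform != "none":
                if tm.covariate in seen:
                    raise ValueError(
                        f"covariate {tm.covariate!r} has two time transforms "
                        f"({seen[tm.covariate]!r} and {tm.transform!r})"
                    )
                seen[tm.covariate] = tm.transform

    @classmethod
    def intercept_only(cls, levels: Mapping[str, tuple[str, ...]] | None = None) -> "ModelSpec":
        return cls((ModelTerm("intercept"),), levels or {})

    def with_term(self, term: ModelTerm) -> "ModelSpec":
        return ModelSpec(self.terms + (term,), self.levels)

    def has_term(self, term: ModelTerm) -> bool:
        return term in self.terms

    def time_transform_of(self, covariate: str) -> str | None:
        for tm in self.terms:
            if tm.covariate == covariate and tm.transform != "none":
                return tm.transform
        return None

    def term_columns(self, term: ModelTerm) -> list[str]:
        """Design column names generated by one term."""
        cov = term.covariate
        if cov in CATEGORICAL_COVARIATES:
            if cov not in self.levels:
                raise ValueError(f"no level registry for {cov!r}")
            ref, *rest = self.levels[cov]
            if term.transform == "none":
                return [f"{cov}[{lv}]" for lv in rest]
            return [f"{_TRANSFORM_LABEL[term.transform]}:{cov}[{lv}]" for lv in rest]
        return [term.label]

    def column_names(self) -> list[str]:
        cols: list[str] = []
        for tm in self.terms:
            cols.extend(self.term_columns(tm))
        return cols

    def to_dict(self) -> dict:
        return {
            "terms": [tm.to_dict() for tm in self.terms],
            "levels": {k: list(v) for k, v in self.levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            tuple(ModelTerm.from_dict(t) for t in d["terms"]),
            {k: tuple(v) for k, v in d.get("levels", {}).items()},
        )


def _check_levels(values: pd.Series, cov: str, known: Sequence[str]) -> None:
    unseen = set(values.astype(str).unique()) - set(known)
    if unseen:
        warnings.warn(
            f"unseen level(s) {sorted(unseen)} of {cov!r} mapped to the "
            f"reference level {known[0]!r}",
            stacklevel=3,
        )


def design_matrix(
    cov_frame: pd.DataFrame, t: Iterable[int], spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects design matrix.

    Parameters
    ----------
    cov_frame : DataFrame
        One row per observation, carrying the product covariate columns
        (orphan/ce/fic as 0/1 or bool, tumor_site/molecule_type as strings).
    t : array-like of int
        Month index (>= 1) per observation, row-aligned with ``cov_frame``.
    spec : ModelSpec
        Fixed-effects structure with a frozen level registry.

    Returns
    -------
    (X, column_names)
        Column order is deterministic: terms in spec order, categorical
        levels in registry (sorted) order with the first level as reference.
    """
    t = np.asarray(list(t) if not isinstance(t, np.ndarray) else t, dtype=float)
    n = len(t)
    if len(cov_frame) != n:
        raise ValueError("cov_frame and t must be row-aligned")
    if n and t.min() < 1:
        raise ValueError("month index must be >= 1")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.terms:
        cov = term.covariate
        if cov == "intercept":
            cols.append(np.ones(n))
            names.append("intercept")
            continue
        if cov == "time":
            cols.append(t.copy())
            names.append("time")
            continue
        if cov in BINARY_COVARIATES:
            v = cov_frame[cov].to_numpy().astype(float)
            if term.transform == "none":
                cols.append(v)
            else:
                cols.append(v * time_basis(term.transform, t))
            names.append(term.label)
            continue
        # categorical
        lvls = spec.levels.get(cov)
        if not lvls:
            raise ValueError(f"no level registry for {cov!r}")
        vals = cov_frame[cov].astype(str)
        if n:
            _check_levels(vals, cov, lvls)
        base = np.ones(n) if term.transform == "none" else time_basis(term.transform, t)
        for lv in lvls[1:]:
            cols.append((vals == lv).to_numpy().astype(float) * base)
        names.extend(spec.term_columns(term))

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names
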