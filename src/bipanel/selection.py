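"""Forward stepwise construction of the fixed-effects structure.

Starting from an intercept-only model, each step fits the current structure
plus every admissible candidate term and ranks candidates by AIC.  The
best-AIC candidate is accepted only if its AIC strictly improves on the
current model AND its Wald p-value is below the entry threshold (0.10); if
the p-gate fails, the next-best AIC candidate is considered, and so on.
Selection stops when no candidate qualifies.

Candidates per covariate are its main effect and its interaction with each
of sqrt(t) and t, t^2, ..., t^6; at most one time interaction per covariate
is ever allowed, and main effects of accepted interactions are NOT forced
into the model.  The linear time main effect is an ordinary candidate.  The
random-effects and AR(1) correlation structure are held fixed throughout.

A likelihood-ratio p-gate is available as a switch (``use_lr=True``); the
default gate is the Wald test (joint chi-square for multi-level terms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .model import BudgetImpactLMM, EstimationError, LMMResults
from .panel import PanelDataset
from .terms import (
    BINARY_COVARIATES,
    CATEGORICAL_COVARIATES,
    TIME_TRANSFORMS,
    ModelSpec,
    ModelTerm,
    build_levels,
)

__all__ = ["candidate_terms", "forward_select", "SelectionTrace", "SelectionStep"]

log = logging.getLogger(__name__)

#: entry threshold of the p-gate
P_ENTER = 0.10
#: AIC ties closer than this are broken by candidate enumeration order
AIC_TIE = 1e-6


def candidate_terms(
    covariates: list[str], current: ModelSpec
) -> list[ModelTerm]:
    """Admissible candidate terms given the current structure.

    For each product covariate: its main effect plus one interaction per
    time transform, excluding terms already present and excluding every
    further time interaction for a covariate that already has one.  The
    linear time main effect is offered as well.
    """
    cands: list[ModelTerm] = []
    tm_time = ModelTerm("time")
    if not current.has_term(tm_time):
        cands.append(tm_time)
    for cov in covariates:
        if cov not in BINARY_COVARIATES + CATEGORICAL_COVARIATES:
            raise ValueError(f"unknown product covariate {cov!r}")
        main = ModelTerm(cov)
        if not current.has_term(main):
            cands.append(main)
        if current.time_transform_of(cov) is None:
            for tf in TIME_TRANSFORMS:
                cands.append(ModelTerm(cov, tf))
    return cands


@dataclass
class SelectionStep:
    """One step of the forward search."""

    aic_before: float
    candidates: pd.DataFrame  # term, aic, p, converged
    chosen: ModelTerm | None
    aic_after: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s_idx, step in enumerate(self.steps):
            for _, row in step.candidates.iterrows():
                rows.append(
                    {
                        "step": s_idx + 1,
                        "candidate": row["term"].label,
                        "aic": row["aic"],
                        "p": row["p"],
                        "accepted": step.chosen is not None
                        and row["term"] == step.chosen,
                    }
                )
        return pd.DataFrame(rows, columns=["step", "candidate", "aic", "p", "accepted"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = []
        for s_idx, step in enumerate(self.steps):
            chosen = step.chosen.label if step.chosen else "<stop>"
            lines.append(
                f"step {s_idx + 1}: AIC {step.aic_before:.2f} -> "
                f"{step.aic_after:.2f}, chose {chosen} "
                f"({len(step.candidates)} candidates)"
            )
        return "\n".join(lines)


def _lr_p(res1: LMMResults, res0: LMMResults, df: int) -> float:
    lr = max(2.0 * (res1.llf - res0.llf), 0.0)
    return float(stats.chi2.sf(lr, df=max(df, 1)))


def forward_select(
    training_dataset: PanelDataset,
    covariates: list[str] | None = None,
    levels: dict | None = None,
    p_enter: float = P_ENTER,
    use_lr: bool = False,
    max_steps: int = 50,
) -> tuple[ModelSpec, SelectionTrace]:
    """Forward stepwise AIC selection on a training panel.

    ``levels`` fixes the categorical level registry (pass the registry built
    from the full covariate file so design columns stay comparable across
    cohort subsets); by default it is built from the training profiles.
    Candidate fits that fail to converge are skipped with a warning.
    """
    if covariates is None:
        covariates = [
            c
            for c in BINARY_COVARIATES + CATEGORICAL_COVARIATES
            if c in training_dataset.profiles.columns
        ]
    if levels is None:
        levels = build_levels(training_dataset.profiles)

    spec = ModelSpec.intercept_only(levels)
    current = BudgetImpactLMM(training_dataset, spec).fit()
    trace = SelectionTrace()

    for _ in range(max_steps):
        cands = candidate_terms(covariates, spec)
        rows = []
        fits: dict[int, LMMResults] = {}
        for j, term in enumerate(cands):
            try:
                res = BudgetImpactLMM(training_dataset, spec.with_term(term)).fit()
            except EstimationError as exc:
                log.warning("candidate %s failed: %s", term.label, exc)
                rows.append({"term": term, "aic": float("inf"), "p": float("nan"),
                             "converged": False})
                continue
            if not res.converged:
                log.warning("candidate %s did not converge; skipped", term.label)
                rows.append({"term": term, "aic": res.aic, "p": float("nan"),
                             "converged": False})
                continue
            if use_lr:
                df = len(res.column_names) - len(current.column_names)
                p = _lr_p(res, current, df)
            else:
                p = res.wald_p(term)
            rows.append({"term": term, "aic": res.aic, "p": p, "converged": True})
            fits[j] = res
        cand_df = pd.DataFrame(rows, columns=["term", "aic", "p", "converged"])

        # rank by AIC (ties within AIC_TIE broken by enumeration order),
        # accept the first that strictly improves AIC and passes the p-gate
        order = sorted(
            fits.keys(), key=lambda j: (round(cand_df.at[j, "aic"] / AIC_TIE), j)
        )
        chosen = None
        chosen_res = None
        for j in order:
            if cand_df.at[j, "aic"] < current.aic and cand_df.at[j, "p"] < p_enter:
                chosen = cands[j]
                chosen_res = fits[j]
                break
        trace.steps.append(
            SelectionStep(
                aic_before=current.aic,
                candidates=cand_df,
                chosen=chosen,
                aic_after=chosen_res.aic if chosen_res else current.aic,
            )
        )
        if chosen is None:
            break
        spec = spec.with_term(chosen)
        current = chosen_res
    return spec, trace
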