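"""Rolling-forecasting-origin cross-validation with continuous retraining.

For each validation product *k* the passage of time is simulated: in the
cycle with ``t_data`` months of *k*'s own records available (t_data = 0, 1,
..., t_max - 1, bounded by *k*'s record count), the calendar split
``t_split`` = first record month of *k* + t_data, and the training set holds

* every training-pool product's records with calendar month strictly before
  ``t_split`` (each product already trimmed to its first t_max months), plus
* the first ``t_data`` records of *k* itself.

The model (fixed fixed-effects structure, selected once on the initial
training cohort) is refit on every cycle's training set, and months
``t_pred`` in [t_data + 1, t_max] of *k* are predicted, exponentiated to
euros and capped: floor at a fixed minimum (default 5000 EUR) and ceiling at
a multiple (default 2x) of the maximum monthly expenditure in the total
dataset.  Observed expenditure is never capped.  A full-history product
yields t_max (t_max + 1) / 2 cells (1035 at t_max = 45).

For robustness the whole procedure can be run at two horizons (t_max = 45
and 42, each with its own structure selection) and the euro-scale capped
predictions averaged per (product, t_data, t_pred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import BudgetImpactLMM, EstimationError
from .panel import PanelDataset, month, split_cohort, trim_to_tmax
from .selection import forward_select
from .terms import ModelSpec, build_levels

__all__ = [
    "RunConfig",
    "ValidationCell",
    "RollingResult",
    "compute_max_cap",
    "cap_prediction",
    "rolling_validate",
    "dual_tmax_run",
    "apply_cap_regime",
]

log = logging.getLogger(__name__)

CELL_COLUMNS = [
    "product_id",
    "t_data",
    "t_pred",
    "raw_pred_eur",
    "pred_eur",
    "observed_eur",
    "capped",
    "t_max_run",
    "min_cap_eur",
    "max_cap_eur",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one validation run."""

    split_month: pd.Period
    spec: ModelSpec | None = None  # selected on the initial training set
    t_max: int = 45
    min_cap_eur: float = 5000.0
    max_cap_factor: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "split_month", month(self.split_month))
        if self.t_max < 2:
            raise ValueError("t_max must be >= 2")
        if self.min_cap_eur <= 0 or self.max_cap_factor <= 0:
            raise ValueError("caps must be positive")


@dataclass(frozen=True)
class ValidationCell:
    """One (product, t_data, t_pred) prediction."""

    product_id: str
    t_data: int
    t_pred: int
    raw_pred_eur: float
    pred_eur: float
    observed_eur: float | None
    capped: str  # none | min | max
    t_max_run: object  # 45 | 42 | "merged"


def compute_max_cap(dataset: PanelDataset, factor: float) -> float:
    """Ceiling: factor x the maximum monthly BI in the total dataset."""
    if dataset.records.empty:
        raise ValueError("empty dataset")
    return float(factor) * float(dataset.records["bi_eur"].max())


def cap_prediction(
    raw_eur: float, min_cap: float, max_cap: float
) -> tuple[float, str]:
    """Clamp a euro-scale prediction to [min_cap, max_cap] with a flag."""
    if not min_cap < max_cap:
        raise ValueError("min_cap must be below max_cap")
    if raw_eur < min_cap:
        return min_cap, "min"
    if raw_eur > max_cap:
        return max_cap, "max"
    return raw_eur, "none"


@dataclass
class RollingResult:
    """Cells plus per-cycle bookkeeping of one validation run."""

    cells: pd.DataFrame
    n_cycles: int = 0
    failed_cycles: list[tuple[str, int]] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def rolling_validate(
    dataset: PanelDataset,
    split_month,
    config: RunConfig,
    collect_audit: bool = True,
) -> RollingResult:
    """Run the rolling-origin validation at one horizon.

    ``config.spec`` must carry the fixed fixed-effects structure (with the
    level registry frozen from the full covariate file).  Cycles whose refit
    fails are logged, counted and excluded from the cells; if more than 5%
    of cycles fail a run-level warning is logged.
    """
    if config.spec is None:
        raise ValueError("config.spec is required (select it on the training set)")
    t_max = config.t_max
    data = trim_to_tmax(dataset, t_max)
    split = split_cohort(data, split_month)
    max_cap = compute_max_cap(data, config.max_cap_factor)
    min_cap = config.min_cap_eur

    rec = data.records
    prof = data.profiles.set_index("product_id", drop=False)
    train_rec = rec[rec["product_id"].isin(split.training_products)]
    first = prof["first_record_month"]

    rows: list[tuple] = []
    failed: list[tuple[str, int]] = []
    audit: list[dict] = []
    n_cycles = 0

    for k in split.validation_products:
        k_rec = rec[rec["product_id"] == k].sort_values("month_index")
        m_k = len(k_rec)
        observed = dict(zip(k_rec["month_index"], k_rec["bi_eur"]))
        profile_k = prof.loc[k]
        for t_data in range(0, min(t_max - 1, m_k) + 1):
            n_cycles += 1
            t_split = first[k] + t_data
            pool = train_rec[train_rec["calendar_month"] < t_split]
            k_part = k_rec[k_rec["month_index"] <= t_data]
            cycle_rec = pd.concat([pool, k_part], ignore_index=True)
            try:
                if cycle_rec.empty:
                    raise EstimationError("empty training set")
                model = BudgetImpactLMM.from_frames(
                    cycle_rec, data.profiles, config.spec
                )
                res = model.fit()
            except EstimationError as exc:
                log.warning("cycle (%s, t_data=%d) failed: %s", k, t_data, exc)
                failed.append((k, t_data))
                continue
            if collect_audit:
                audit.append(
                    {
                        "product_id": k,
                        "t_data": t_data,
                        "t_split": t_split,
                        "training_months": dict(
                            cycle_rec.groupby("product_id")["month_index"].max()
                        ),
                    }
                )
            t_pred = np.arange(t_data + 1, t_max + 1)
            log_pred = res.predict_log_bi(
                profile_k, t_pred, product_id=k if t_data > 0 else None, t_max=t_max
            )
            raw = np.exp(log_pred)
            for tp, rw in zip(t_pred, raw):
                pred, flag = cap_prediction(float(rw), min_cap, max_cap)
                rows.append(
                    (
                        k,
                        t_data,
                        int(tp),
                        float(rw),
                        pred,
                        observed.get(int(tp), np.nan),
                        flag,
                        t_max,
                        min_cap,
                        max_cap,
                    )
                )

    if n_cycles and len(failed) > 0.05 * n_cycles:
        log.warning(
            "%d of %d rolling cycles failed to refit", len(failed), n_cycles
        )
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return RollingResult(cells, n_cycles=n_cycles, failed_cycles=failed, audit=audit)


def _merge_runs(runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Average euro-scale (capped) predictions per (product, t_data, t_pred)."""
    allcells = pd.concat(runs, ignore_index=True)
    grp = allcells.groupby(["product_id", "t_data", "t_pred"], as_index=False)
    merged = grp.agg(
        raw_pred_eur=("raw_pred_eur", "mean"),
        pred_eur=("pred_eur", "mean"),
        observed_eur=("observed_eur", "first"),
        capped=("capped", lambda s: s.iloc[0] if s.nunique() == 1 else "mixed"),
        min_cap_eur=("min_cap_eur", "mean"),
        max_cap_eur=("max_cap_eur", "mean"),
    )
    merged["t_max_run"] = "merged"
    return merged[CELL_COLUMNS]


def dual_tmax_run(
    dataset: PanelDataset,
    split_month,
    base_config: RunConfig,
    t_maxes: tuple[int, ...] = (45, 42),
    reselect: bool = True,
    collect_audit: bool = False,
) -> tuple[RollingResult, dict[int, RollingResult]]:
    """Run selection + rolling validation per horizon, then merge.

    Structure selection is redone independently on each horizon's initial
    training cohort unless ``reselect=False`` (then ``base_config.spec`` is
    used for every horizon).  The merged cell for each (product, t_data,
    t_pred) is the mean of the horizons' capped euro predictions where both
    exist, else the single available one.
    """
    levels = build_levels(dataset.profiles)
    per_run: dict[int, RollingResult] = {}
    for tm in t_maxes:
        data_tm = trim_to_tmax(dataset, tm)
        split = split_cohort(data_tm, split_month)
        cfg = replace(base_config, t_max=tm)
        if reselect or cfg.spec is None:
            training = data_tm.subset(split.training_products)
            spec, _ = forward_select(training, levels=levels)
            cfg = replace(cfg, spec=spec)
        per_run[tm] = rolling_validate(
            dataset, split_month, cfg, collect_audit=collect_audit
        )
    merged = _merge_runs([r.cells for r in per_run.values()])
    out = RollingResult(
        merged,
        n_cycles=sum(r.n_cycles for r in per_run.values()),
        failed_cycles=[f for r in per_run.values() for f in r.failed_cycles],
    )
    return out, per_run


def apply_cap_regime(cells: pd.DataFrame, regime: str) -> pd.DataFrame:
    """Re-derive capped predictions from the stored raw predictions.

    ``regime`` is one of ``base`` (both caps), ``min-only``, ``max-only``,
    ``none``.  Observed values are never touched.
    """
    if regime not in {"base", "min-only", "max-only", "none"}:
        raise ValueError(f"unknown cap regime {regime!r}")
    out = cells.copy()
    raw = out["raw_pred_eur"].to_numpy(dtype=float)
    lo = out["min_cap_eur"].to_numpy(dtype=float)
    hi = out["max_cap_eur"].to_numpy(dtype=float)
    pred = raw.copy()
    flag = np.full(len(out), "none", dtype=object)
    if regime in ("base", "min-only"):
        m = raw < lo
        pred[m] = lo[m]
        flag[m] = "min"
    if regime in ("base", "max-only"):
        m = raw > hi
        pred[m] = hi[m]
        flag[m] = "max"
    out["pred_eur"] = pred
    out["capped"] = flag
    return out
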