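"""Monthly budget-impact panel: domain types, CSV I/O, cohort split, trimming.

The panel holds one row per product per calendar month with the product's
monthly budget impact (BI, list price x volume) in euros.  Month indexing is
product-relative: a product's first recorded month has ``month_index`` 1 and
indices run consecutively without gaps, so that time transforms such as
sqrt(t) are defined and positive.  Calendar months are whole year-month units
(pandas ``Period[M]``); "one month prior" means the previous calendar month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BIRecord",
    "ProductProfile",
    "PanelDataset",
    "CohortSplit",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel_csv",
    "write_panel_csv",
    "split_cohort",
    "trim_to_tmax",
    "month",
]

RECORD_COLUMNS = ["product_id", "calendar_month", "bi_eur"]
PROFILE_COLUMNS = [
    "product_id",
    "tumor_site",
    "molecule_type",
    "orphan",
    "ce",
    "fic",
    "first_record_month",
]


class PanelFormatError(ValueError):
    """Input file does not have the expected columns/encoding."""


class PanelValidationError(ValueError):
    """Panel content violates a dataset invariant."""


def month(s) -> pd.Period:
    """Parse a year-month ('YYYY-MM') into a monthly Period."""
    if isinstance(s, pd.Period):
        return s.asfreq("M")
    return pd.Period(str(s), freq="M")


@dataclass(frozen=True)
class BIRecord:
    """One product-month observation."""

    product_id: str
    month_index: int  # months since the product's first record; first = 1
    calendar_month: pd.Period
    bi_eur: float  # strictly positive (log transform must exist)


@dataclass(frozen=True)
class ProductProfile:
    """Per-product covariates, fixed at marketing authorization."""

    product_id: str
    tumor_site: str
    molecule_type: str
    orphan: bool
    ce: bool  # conditional approval OR exceptional circumstances (one flag)
    fic: bool  # FDA first-in-class
    first_record_month: pd.Period


@dataclass
class PanelDataset:
    """Validated panel: records plus exactly one profile per recorded product.

    ``records`` columns: product_id, month_index, calendar_month (Period[M]),
    bi_eur.  ``profiles`` columns: product_id, tumor_site, molecule_type,
    orphan, ce, fic, first_record_month (Period[M]).
    """

    records: pd.DataFrame
    profiles: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.profiles = self.profiles.reset_index(drop=True)
        if self.validate:
            self._validate()

    # -- invariants -----------------------------------------------------
    def _validate(self) -> None:
        rec, prof = self.records, self.profiles
        for c in ["product_id", "month_index", "calendar_month", "bi_eur"]:
            if c not in rec.columns:
                raise PanelFormatError(f"records missing column {c!r}")
        for c in PROFILE_COLUMNS:
            if c not in prof.columns:
                raise PanelFormatError(f"profiles missing column {c!r}")
        if prof["product_id"].duplicated().any():
            dupes = prof.loc[prof["product_id"].duplicated(), "product_id"].tolist()
            raise PanelValidationError(f"duplicate profiles for {dupes}")

        bad = rec.loc[rec["bi_eur"] <= 0]
        if len(bad):
            r = bad.iloc[0]
            raise PanelValidationError(
                f"non-positive BI for product {r['product_id']!r} "
                f"in {r['calendar_month']}"
            )

        known = set(prof["product_id"])
        missing = set(rec["product_id"]) - known
        if missing:
            raise PanelValidationError(
                f"products without covariate profile: {sorted(missing)}"
            )

        prof_first = prof.set_index("product_id")["first_record_month"]
        for pid, grp in rec.groupby("product_id", sort=False):
            grp = grp.sort_values("month_index")
            idx = grp["month_index"].to_numpy()
            if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
                raise PanelValidationError(
                    f"product {pid!r}: month_index not consecutive from 1"
                )
            first = grp["calendar_month"].iloc[0]
            offsets = (grp["calendar_month"] - first).apply(lambda d: d.n).to_numpy()
            if not np.array_equal(offsets, idx - 1):
                raise PanelValidationError(
                    f"product {pid!r}: gap in calendar months"
                )
            if first != prof_first[pid]:
                raise PanelValidationError(
                    f"product {pid!r}: first record {first} does not match "
                    f"profile first_record_month {prof_first[pid]}"
                )

    # -- convenience ----------------------------------------------------
    @property
    def product_ids(self) -> list[str]:
        return sorted(self.profiles["product_id"])

    def n_months(self, product_id: str) -> int:
        return int((self.records["product_id"] == product_id).sum())

    def subset(self, product_ids, validate: bool = False) -> "PanelDataset":
        pids = set(product_ids)
        return PanelDataset(
            self.records[self.records["product_id"].isin(pids)],
            self.profiles[self.profiles["product_id"].isin(pids)],
            validate=validate,
        )

    def equals(self, other: "PanelDataset") -> bool:
        a = self.records.sort_values(["product_id", "month_index"]).reset_index(drop=True)
        b = other.records.sort_values(["product_id", "month_index"]).reset_index(drop=True)
        pa = self.profiles.sort_values("product_id").reset_index(drop=True)
        pb = other.profiles.sort_values("product_id").reset_index(drop=True)
        return a.equals(b) and pa.equals(pb)


@dataclass(frozen=True)
class CohortSplit:
    """Partition of products into a training pool and a validation set."""

    training_products: tuple[str, ...]
    validation_products: tuple[str, ...]
    split_month: pd.Period


# -- I/O ---------------------------------------------------------------


def _parse_months(series: pd.Series, colname: str) -> pd.Series:
    try:
        return series.astype(str).apply(lambda s: pd.Period(s, freq="M"))
    except Exception as exc:  # noqa: BLE001
        raise PanelFormatError(f"cannot parse {colname!r} as YYYY-MM: {exc}") from exc


def read_panel_csv(path, covariates_path) -> PanelDataset:
    """Read a panel CSV plus its covariate CSV into a validated dataset.

    ``month_index`` is derived from calendar months (first record per
    product = 1); gaps or non-positive BI raise :class:`PanelValidationError`.
    """
    rec = pd.read_csv(path, dtype={"product_id": str})
    for c in ["product_id", "calendar_month", "bi_eur"]:
        if c not in rec.columns:
            raise PanelFormatError(f"panel file missing column {c!r}")
    prof = pd.read_csv(covariates_path, dtype={"product_id": str})
    for c in PROFILE_COLUMNS:
        if c not in prof.columns:
            raise PanelFormatError(f"covariate file missing column {c!r}")

    rec["calendar_month"] = _parse_months(rec["calendar_month"], "calendar_month")
    rec["bi_eur"] = rec["bi_eur"].astype(float)
    rec = rec.sort_values(["product_id", "calendar_month"]).reset_index(drop=True)
    rec["month_index"] = rec.groupby("product_id").cumcount() + 1
    rec = rec[["product_id", "month_index", "calendar_month", "bi_eur"]]

    prof["first_record_month"] = _parse_months(
        prof["first_record_month"], "first_record_month"
    )
    for c in ["orphan", "ce", "fic"]:
        prof[c] = prof[c].astype(int).astype(bool)
    for c in ["tumor_site", "molecule_type"]:
        prof[c] = prof[c].astype(str)
    prof = prof[PROFILE_COLUMNS].sort_values("product_id").reset_index(drop=True)
    return PanelDataset(rec, prof)


def write_panel_csv(dataset: PanelDataset, path, covariates_path) -> None:
    """Write panel and covariates as UTF-8 CSV; round-trips through read."""
    rec = dataset.records.copy()
    rec["calendar_month"] = rec["calendar_month"].astype(str)
    rec[RECORD_COLUMNS].to_csv(path, index=False)
    prof = dataset.profiles.copy()
    prof["first_record_month"] = prof["first_record_month"].astype(str)
    for c in ["orphan", "ce", "fic"]:
        prof[c] = prof[c].astype(int)
    prof[PROFILE_COLUMNS].to_csv(covariates_path, index=False)


# -- study design ------------------------------------------------------


def split_cohort(dataset: PanelDataset, split_month) -> CohortSplit:
    """Assign whole products to cohorts by first-record date.

    A product whose first record falls on or after ``split_month`` goes to
    the validation set; strictly earlier launches form the training pool.
    """
    sm = month(split_month)
    prof = dataset.profiles
    is_val = prof["first_record_month"] >= sm
    train = tuple(sorted(prof.loc[~is_val, "product_id"]))
    val = tuple(sorted(prof.loc[is_val, "product_id"]))
    if not train:
        warnings.warn("empty training cohort", stacklevel=2)
    if not val:
        warnings.warn("empty validation cohort", stacklevel=2)
    return CohortSplit(train, val, sm)


def trim_to_tmax(dataset: PanelDataset, t_max: int) -> PanelDataset:
    """Keep only each product's first ``t_max`` monthly records (idempotent)."""
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    rec = dataset.records[dataset.records["month_index"] <= t_max]
    return PanelDataset(rec, dataset.profiles, validate=False)
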