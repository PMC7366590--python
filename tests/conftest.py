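"""Shared fixtures: hand-built toy panels and one reduced validation run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bipanel.panel import PanelDataset, month, split_cohort, trim_to_tmax
from bipanel.selection import forward_select
from bipanel.simulate import PAPERLIKE_SPLIT, paperlike_config, simulate_cohort
from bipanel.terms import build_levels
from bipanel.validation import RunConfig, rolling_validate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(products: dict[str, tuple[str, list[float]]],
               profiles: dict[str, dict]) -> PanelDataset:
    """Build a validated panel from {pid: (first_month, [bi...])} plus covariates."""
    rec_rows = []
    prof_rows = []
    for pid, (first, series) in products.items():
        m0 = month(first)
        for i, bi in enumerate(series):
            rec_rows.append((pid, i + 1, m0 + i, float(bi)))
        row = {"product_id": pid, "tumor_site": "breast",
               "molecule_type": "small_molecule", "orphan": False,
               "ce": False, "fic": False, "first_record_month": m0}
        row.update(profiles.get(pid, {}))
        prof_rows.append(row)
    rec = pd.DataFrame(
        rec_rows, columns=["product_id", "month_index", "calendar_month", "bi_eur"]
    )
    return PanelDataset(rec, pd.DataFrame(prof_rows))


@pytest.fixture
def toy_dataset() -> PanelDataset:
    return make_panel(
        {
            "A": ("2010-01", [1000.0, 1100.0, 1210.0, 1331.0]),
            "B": ("2011-06", [50000.0, 52000.0, 49000.0]),
        },
        {
            "A": {"orphan": True, "tumor_site": "lung"},
            "B": {"molecule_type": "mab"},
        },
    )


@pytest.fixture(scope="session")
def reduced_cohort():
    """Reduced study-like cohort: 12 training + 18 validation products."""
    cfg = paperlike_config(seed=11, n_training=12, n_validation=18,
                           months_range=(6, 18))
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def reduced_run(reduced_cohort):
    """Single-horizon (t_max = 15) selection + rolling validation with audit.

    This is the desk-scale stand-in for the study's full validation: same
    procedure, smaller cohort and horizon.
    """
    cfg, ds = reduced_cohort
    t_max = 15
    levels = build_levels(ds.profiles)
    data = trim_to_tmax(ds, t_max)
    split = split_cohort(data, PAPERLIKE_SPLIT)
    training = data.subset(split.training_products)
    spec, trace = forward_select(training, levels=levels)
    run_cfg = RunConfig(split_month=PAPERLIKE_SPLIT, spec=spec, t_max=t_max)
    result = rolling_validate(ds, PAPERLIKE_SPLIT, run_cfg, collect_audit=True)
    return {
        "config": cfg,
        "dataset": ds,
        "t_max": t_max,
        "split": split,
        "spec": spec,
        "trace": trace,
        "run_config": run_cfg,
        "result": result,
    }
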