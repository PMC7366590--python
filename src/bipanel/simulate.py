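"""Synthetic expenditure cohorts with the exact structure the model assumes.

The generative model mirrors the estimator: for product *i* at month *t*
(t = 1..n_i since launch),

    log(BI_it) = x_it' beta + b0_i + b1_i * t + e_it,

with (b0_i, b1_i) bivariate normal with covariance ``re_cov``, and e_it a
stationary AR(1) process with marginal variance ``sigma2`` and lag-one
correlation ``phi`` (innovation variance sigma2 * (1 - phi^2)).  Euro-scale
BI = exp(log BI), which makes monthly expenditure right-skewed by
construction.  Covariates are drawn independently per product from the
configured prevalences.

The original national sales panel behind the study design is proprietary, so
these cohorts stand in for it everywhere: ``paperlike_config`` reproduces the
study's cohort geometry (25 products launched before the May 2012 split, 44
after, up to 45 monthly records each, panel ending September 2017) while the
euro level and variance parameters are free choices documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import PanelDataset, month
from .terms import ModelSpec, ModelTerm, design_matrix

__all__ = ["SimulationConfig", "simulate_cohort", "paperlike_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort.

    ``beta`` is aligned with ``spec.column_names()`` (log-euro scale).
    ``launch_strata`` fixes how many products launch inside each calendar
    window, so cohort splits have deterministic sizes; month counts are drawn
    uniformly from ``months_range`` and censored at ``panel_end`` (products
    launched later have fewer records).
    """

    n_products: int
    spec: ModelSpec
    beta: tuple[float, ...]
    re_cov: tuple[tuple[float, float], tuple[float, float]]
    sigma2: float
    phi: float
    covariate_prevalence: Mapping[str, object]
    launch_strata: tuple[tuple[pd.Period, pd.Period, int], ...]
    months_range: tuple[int, int] = (6, 45)
    panel_end: pd.Period = field(default_factory=lambda: month("2017-09"))
    round_eur: bool = True  # store euros at 2 decimals
    seed: int = 0

    def __post_init__(self) -> None:
        G = np.asarray(self.re_cov, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(G).min() < -1e-12:
            raise ValueError("re_cov must be positive semi-definite")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if len(self.beta) != len(self.spec.column_names()):
            raise ValueError(
                f"beta has {len(self.beta)} entries but spec has "
                f"{len(self.spec.column_names())} columns"
            )
        if sum(c for _, _, c in self.launch_strata) != self.n_products:
            raise ValueError("launch_strata counts must sum to n_products")
        for cov, p in self.covariate_prevalence.items():
            if isinstance(p, Mapping):
                if abs(sum(p.values()) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for {cov!r} must sum to 1")
            elif not 0 <= float(p) <= 1:
                raise ValueError(f"prevalence of {cov!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_products": self.n_products,
            "spec": self.spec.to_dict(),
            "beta": list(self.beta),
            "re_cov": [list(r) for r in self.re_cov],
            "sigma2": self.sigma2,
            "phi": self.phi,
            "covariate_prevalence": {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in self.covariate_prevalence.items()
            },
            "launch_strata": [
                [str(a), str(b), c] for a, b, c in self.launch_strata
            ],
            "months_range": list(self.months_range),
            "panel_end": str(self.panel_end),
            "round_eur": self.round_eur,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(
            n_products=int(d["n_products"]),
            spec=ModelSpec.from_dict(d["spec"]),
            beta=tuple(d["beta"]),
            re_cov=tuple(tuple(r) for r in d["re_cov"]),
            sigma2=float(d["sigma2"]),
            phi=float(d["phi"]),
            covariate_prevalence=d["covariate_prevalence"],
            launch_strata=tuple(
                (month(a), month(b), int(c)) for a, b, c in d["launch_strata"]
            ),
            months_range=tuple(d.get("months_range", (6, 45))),
            panel_end=month(d.get("panel_end", "2017-09")),
            round_eur=bool(d.get("round_eur", True)),
            seed=int(d.get("seed", 0)),
        )


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_products
    prof = pd.DataFrame({"product_id": [f"P{i:03d}" for i in range(1, n + 1)]})
    for cov in ("tumor_site", "molecule_type"):
        probs = cfg.covariate_prevalence[cov]
        lvls = sorted(probs)  # lexicographic, matches the level registry
        p = np.array([probs[l] for l in lvls])
        prof[cov] = rng.choice(lvls, size=n, p=p)
    for cov in ("orphan", "ce", "fic"):
        prof[cov] = rng.random(n) < float(cfg.covariate_prevalence[cov])
    return prof


def _draw_launches(cfg: SimulationConfig, rng: np.random.Generator) -> list[pd.Period]:
    launches: list[pd.Period] = []
    for start, end, count in cfg.launch_strata:
        span = (end - start).n + 1
        offs = rng.integers(0, span, size=count)
        launches.extend(start + int(o) for o in offs)
    return launches


def _ar1(n: int, sigma2: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with marginal variance sigma2, lag-1 correlation phi."""
    if sigma2 == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, np.sqrt(sigma2))
    innov_sd = np.sqrt(sigma2 * (1.0 - phi**2))
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_cohort(config: SimulationConfig) -> PanelDataset:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    prof = _draw_covariates(config, rng)
    launches = _draw_launches(config, rng)
    lo, hi = config.months_range
    draws = rng.integers(lo, hi + 1, size=config.n_products)

    G = np.asarray(config.re_cov, dtype=float)
    L = np.linalg.cholesky(G + 1e-15 * np.eye(2)) if G.any() else np.zeros((2, 2))
    beta = np.asarray(config.beta, dtype=float)

    rows = []
    first_months = []
    for i in range(config.n_products):
        launch = launches[i]
        horizon = (config.panel_end - launch).n + 1
        n_i = int(min(draws[i], max(horizon, 1)))
        t = np.arange(1, n_i + 1)
        X, _ = design_matrix(
            prof.iloc[[i] * n_i].reset_index(drop=True), t, config.spec
        )
        b = L @ rng.standard_normal(2)
        eps = _ar1(n_i, config.sigma2, config.phi, rng)
        log_bi = X @ beta + b[0] + b[1] * t + eps
        bi = np.exp(log_bi)
        if config.round_eur:
            bi = np.round(bi, 2)
        pid = prof.loc[i, "product_id"]
        first_months.append(launch)
        for k in range(n_i):
            rows.append((pid, k + 1, launch + k, bi[k]))

    rec = pd.DataFrame(rows, columns=["product_id", "month_index", "calendar_month", "bi_eur"])
    prof = prof.assign(first_record_month=first_months)
    prof = prof[
        ["product_id", "tumor_site", "molecule_type", "orphan", "ce", "fic", "first_record_month"]
    ]
    return PanelDataset(rec, prof)


#: split month of the study design the default cohort emulates
PAPERLIKE_SPLIT = "2012-05"


def paperlike_config(
    seed: int = 0,
    n_training: int = 25,
    n_validation: int = 44,
    months_range: tuple[int, int] = (6, 45),
) -> SimulationConfig:
    """Default cohort emulating the study's geometry.

    25 products launch in 2005-01..2012-04 (training pool under a 2012-05
    split) and 44 in 2012-05..2016-06 (validation), with up to 45 monthly
    records each, censored at the 2017-09 panel end.  The fixed-effect
    structure is the study's final model: time, time x CE, molecule type,
    and sqrt(t) interactions with orphan status, first-in-class status and
    tumor site.  Effect sizes and variance parameters are package choices
    (see the methods note); euro levels centre near e^10.5 ~ 36 k EUR/month.

    Pass smaller ``n_training``/``n_validation``/``months_range`` for
    reduced cohorts; the launch windows and structure are unchanged.
    """
    prevalence = {
        "tumor_site": {"breast": 0.25, "hematologic": 0.25, "lung": 0.30, "other": 0.20},
        "molecule_type": {"mab": 0.35, "small_molecule": 0.55, "targeted_conjugate": 0.10},
        "orphan": 0.35,
        "ce": 0.20,
        "fic": 0.25,
    }
    levels = {
        "tumor_site": tuple(sorted(prevalence["tumor_site"])),
        "molecule_type": tuple(sorted(prevalence["molecule_type"])),
    }
    spec = ModelSpec(
        (
            ModelTerm("intercept"),
            ModelTerm("time"),
            ModelTerm("ce", "t"),
            ModelTerm("molecule_type"),
            ModelTerm("orphan", "sqrt"),
            ModelTerm("fic", "sqrt"),
            ModelTerm("tumor_site", "sqrt"),
        ),
        levels,
    )
    # aligned with spec.column_names():
    # intercept, time, t:ce, molecule_type[small_molecule],
    # molecule_type[targeted_conjugate], sqrt(t):orphan, sqrt(t):fic,
    # sqrt(t):tumor_site[hematologic], sqrt(t):tumor_site[lung],
    # sqrt(t):tumor_site[other]
    beta = (10.5, 0.05, -0.03, -0.6, 0.4, -0.30, 0.20, 0.25, 0.15, -0.20)
    return SimulationConfig(
        n_products=n_training + n_validation,
        spec=spec,
        beta=beta,
        re_cov=((1.0, 0.0), (0.0, 0.004)),
        sigma2=0.25,
        phi=0.6,
        covariate_prevalence=prevalence,
        launch_strata=(
            (month("2005-01"), month("2012-04"), n_training),
            (month(PAPERLIKE_SPLIT), month("2016-06"), n_validation),
        ),
        months_range=months_range,
        seed=seed,
    )
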