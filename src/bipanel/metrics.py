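"""Symmetric forecast-error metrics, aggregation and summary tests.

The central accuracy measure is the symmetric error ratio

    error = exp(|ln(observed BI / predicted BI)|)  >= 1,

which treats a two-fold over- and a two-fold under-prediction identically
(an error of 2 with observed 10 000 EUR means the prediction was 5 000 or
20 000 EUR).  For comparability with the published forecasting literature a
signed percentage difference (predicted - observed) / observed x 100 and
the fractions of samples within +/-40% and +/-100% are also computed.

Error samples exist only for validation cells with an observed value.  They
can be aggregated three ways: per (t_pred, t_data) cell, per t_data, or not
at all.  Summary tests: one-sample t-test of mean ln(observed/predicted)
against 0, an exact binomial test of the underprediction probability
(underprediction <=> ln ratio > 0; exact ties excluded), and an OLS
regression of the error ratio on t_data over individual samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "error_ratio",
    "pct_difference",
    "error_samples",
    "aggregate",
    "band_fractions",
    "summary_tests",
    "SummaryTests",
    "scenario_caps",
]

log = logging.getLogger(__name__)

DEFAULT_BANDS = (40.0, 100.0)
CAP_REGIMES = ("base", "min-only", "max-only", "none")


def error_ratio(observed_eur, predicted_eur):
    """Symmetric error ratio exp(|ln(observed/predicted)|), always >= 1."""
    obs = np.asarray(observed_eur, dtype=float)
    pred = np.asarray(predicted_eur, dtype=float)
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("observed and predicted BI must be strictly positive")
    # hi/lo ordering makes the symmetry exact in floating point
    out = np.maximum(obs, pred) / np.minimum(obs, pred)
    return float(out) if out.ndim == 0 else out


def pct_difference(predicted_eur, observed_eur):
    """Signed percentage difference (predicted - observed)/observed x 100."""
    obs = np.asarray(observed_eur, dtype=float)
    pred = np.asarray(predicted_eur, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed BI must be strictly positive")
    out = (pred - obs) / obs * 100.0
    return float(out) if out.ndim == 0 else out


def error_samples(cells: pd.DataFrame) -> pd.DataFrame:
    """Derive error samples from validation cells (observed rows only).

    Adds ``ln_ratio`` (signed ln(observed/predicted)), ``error_ratio`` =
    exp(|ln_ratio|) and ``pct_diff``.
    """
    obs = cells.dropna(subset=["observed_eur"]).copy()
    obs = obs[obs["observed_eur"] > 0]
    obs["ln_ratio"] = np.log(obs["observed_eur"] / obs["pred_eur"])
    obs["error_ratio"] = np.exp(obs["ln_ratio"].abs())
    obs["pct_diff"] = pct_difference(obs["pred_eur"], obs["observed_eur"])
    return obs.reset_index(drop=True)


def _summary(group: pd.DataFrame) -> dict:
    e = group["error_ratio"].to_numpy(dtype=float)
    qs = np.percentile(e, [5, 25, 50, 75, 95]) if len(e) else [np.nan] * 5
    return {
        "n": len(e),
        "mean": float(e.mean()) if len(e) else np.nan,
        "sd": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
        "median": float(qs[2]),
        "iqr": float(qs[3] - qs[1]),
        "p5": float(qs[0]),
        "p25": float(qs[1]),
        "p75": float(qs[3]),
        "p95": float(qs[4]),
    }


def aggregate(samples: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Summaries of the error ratio per aggregation mode.

    ``mode``: ``per_tpred_tdata``, ``per_tdata`` or ``none``.  Percentiles
    use linear interpolation between order statistics; the IQR is the single
    width p75 - p25; sd of a singleton group is reported as 0.
    """
    if mode == "per_tpred_tdata":
        keys = ["t_pred", "t_data"]
    elif mode == "per_tdata":
        keys = ["t_data"]
    elif mode == "none":
        keys = []
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if not keys:
        return pd.DataFrame([_summary(samples)])
    rows = []
    for key, grp in samples.groupby(keys):
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(_summary(grp))
        rows.append(row)
    return pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)


def band_fractions(samples: pd.DataFrame, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Fraction of samples with |percentage difference| <= each band."""
    if samples.empty:
        raise ValueError("no error samples")
    pct = samples["pct_diff"].abs().to_numpy(dtype=float)
    rows = [
        {"band_pct": float(b), "n_within": int((pct <= b).sum()),
         "fraction": float((pct <= b).mean())}
        for b in bands
    ]
    return pd.DataFrame(rows)


@dataclass
class SummaryTests:
    n: int
    mean_ln_ratio: float
    t_stat: float
    t_p: float
    t_ci: tuple[float, float]
    prob_underprediction: float
    binom_p: float
    binom_ci: tuple[float, float]
    n_ties_excluded: int
    slope_tdata: float
    slope_se: float
    slope_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "mean_ln_ratio", "t_p", "t_ci_low", "t_ci_high",
                    "prob_underprediction", "binom_p", "binom_ci_low",
                    "binom_ci_high", "slope_tdata", "slope_se", "slope_p", "n",
                ],
                "value": [
                    self.mean_ln_ratio, self.t_p, self.t_ci[0], self.t_ci[1],
                    self.prob_underprediction, self.binom_p, self.binom_ci[0],
                    self.binom_ci[1], self.slope_tdata, self.slope_se,
                    self.slope_p, self.n,
                ],
            }
        )


def summary_tests(samples: pd.DataFrame, slope_on_log: bool = False) -> SummaryTests:
    """Bias and information-content tests on the individual error samples.

    ``slope_on_log`` switches the error-vs-t_data regression response from
    the raw error ratio (default) to its natural log.
    """
    if len(samples) < 2:
        raise ValueError("need at least two error samples")
    ln = samples["ln_ratio"].to_numpy(dtype=float)
    tt = stats.ttest_1samp(ln, 0.0)
    ci = tt.confidence_interval(0.95)

    nonzero = ln[ln != 0.0]
    ties = len(ln) - len(nonzero)
    if ties:
        log.info("%d exact ties excluded from the binomial test", ties)
    n_under = int((nonzero > 0).sum())
    bt = stats.binomtest(n_under, len(nonzero), 0.5)
    bci = bt.proportion_ci(0.95)

    X = sm.add_constant(samples["t_data"].to_numpy(dtype=float))
    resp = samples["error_ratio"].to_numpy(dtype=float)
    if slope_on_log:
        resp = np.log(resp)
    ols = sm.OLS(resp, X).fit()
    return SummaryTests(
        n=len(samples),
        mean_ln_ratio=float(ln.mean()),
        t_stat=float(tt.statistic),
        t_p=float(tt.pvalue),
        t_ci=(float(ci.low), float(ci.high)),
        prob_underprediction=n_under / max(len(nonzero), 1),
        binom_p=float(bt.pvalue),
        binom_ci=(float(bci.low), float(bci.high)),
        n_ties_excluded=ties,
        slope_tdata=float(ols.params[1]),
        slope_se=float(ols.bse[1]),
        slope_p=float(ols.pvalues[1]),
    )


def scenario_caps(
    cells_raw: pd.DataFrame, bands=DEFAULT_BANDS
) -> dict[str, dict]:
    """Recompute headline metrics under the four capping regimes.

    ``cells_raw`` must carry the pre-cap predictions (``raw_pred_eur``) and
    the cap bounds.  For each regime the unaggregated error summary, band
    fractions and the counts of min-/max-adjusted predictions are returned.
    """
    from .validation import apply_cap_regime

    out: dict[str, dict] = {}
    for regime in CAP_REGIMES:
        recapped = apply_cap_regime(cells_raw, regime)
        samples = error_samples(recapped)
        out[regime] = {
            "summary": aggregate(samples, "none"),
            "bands": band_fractions(samples, bands),
            "n_min_adjusted": int((recapped["capped"] == "min").sum()),
            "n_max_adjusted": int((recapped["capped"] == "max").sum()),
        }
    return out
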