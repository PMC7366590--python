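"""Linear mixed model for log monthly expenditure with AR(1) errors.

Model
-----
For product *i* with observations at months t = 1..n_i,

    y_i = X_i beta + Z_i b_i + e_i,        y = log(BI, euros)

with Z_i = [1, t] (random intercept and random time slope per product),
b_i ~ N(0, G) (2x2), and e_i ~ N(0, sigma2 * R_i(phi)) where
R_i(phi)[a, b] = phi^|a-b| is the AR(1) correlation in month index.

Estimation is maximum likelihood: beta is profiled out by GLS given the
variance parameters, which are optimised by quasi-Newton (L-BFGS-B) on
unconstrained transforms (Cholesky of G with log diagonal, log sigma2,
atanh phi).  ML rather than REML because AIC comparison across different
fixed-effects structures during stepwise selection is only valid under ML.
The AIC parameter count is k = p + 5 (fixed coefficients + 3 for G + sigma2
+ phi).

Because every product's months are the consecutive prefix 1..n_i, the
marginal covariance V_i = Z_i G Z_i' + sigma2 R_i depends on n_i only, so
each likelihood evaluation needs one Cholesky per distinct series length.

Predictions are conditional means: population-level x'beta for a product
with no data in the fit, x'beta + b0_i + b1_i t using the product's BLUP
otherwise.  They are marginal over the AR(1) residual (the estimated
residual autocorrelation is not used to forecast future residuals), and
euro-scale predictions are the naive exponential exp(y_hat) without a
smearing correction - a documented downward-bias source.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.linalg import solve_triangular

from .panel import PanelDataset
from .terms import ModelSpec, ModelTerm, design_matrix

__all__ = [
    "LMMParams",
    "BudgetImpactLMM",
    "LMMResults",
    "neg_log_likelihood",
    "ar1_corr",
    "EstimationError",
]

_LOG2PI = np.log(2.0 * np.pi)


class EstimationError(RuntimeError):
    pass


def ar1_corr(phi: float, n: int) -> np.ndarray:
    """AR(1) correlation matrix phi^|a-b| for n consecutive months."""
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class LMMParams:
    """Full parameter set on the natural scale."""

    beta: np.ndarray
    re_cov: np.ndarray  # 2x2 PSD
    sigma2: float
    phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "re_cov", np.asarray(self.re_cov, dtype=float))


def _theta_to_varparams(theta: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Unconstrained 5-vector -> (G, sigma2, phi)."""
    l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    G = L @ L.T
    return G, float(np.exp(theta[3])), float(np.tanh(theta[4]))


class BudgetImpactLMM:
    """Mixed-effects model of log monthly budget impact for a panel.

    Parameters
    ----------
    dataset : PanelDataset
        Panel with records and covariate profiles.  Each product's months
        must be the consecutive prefix 1..n_i.
    spec : ModelSpec
        Fixed-effects structure; the random intercept+slope and AR(1)
        correlation structure are fixed by design.

    All-zero design columns (a categorical level absent from this subset of
    the panel) are dropped from estimation and reported with coefficient 0.
    """

    def __init__(self, dataset: PanelDataset, spec: ModelSpec):
        self.spec = spec
        rec = dataset.records.sort_values(["product_id", "month_index"])
        prof = dataset.profiles.set_index("product_id")
        self.product_ids = sorted(rec["product_id"].unique())
        if len(self.product_ids) < 1:
            raise EstimationError("no observations")

        merged = rec.merge(
            prof.reset_index(), on="product_id", how="left", validate="m:1"
        )
        t = merged["month_index"].to_numpy()
        X_full, self.column_names_full = design_matrix(merged, t, spec)
        y = np.log(merged["bi_eur"].to_numpy(dtype=float))

        keep = ~np.all(X_full == 0.0, axis=0)
        self.kept = np.flatnonzero(keep)
        self.dropped_columns = [
            c for c, k in zip(self.column_names_full, keep) if not k
        ]
        if self.dropped_columns:
            warnings.warn(
                f"design columns with no support dropped: {self.dropped_columns}",
                stacklevel=2,
            )
        self.column_names = [self.column_names_full[j] for j in self.kept]
        X = X_full[:, self.kept]

        # per-product blocks, grouped by series length
        self._pids: list[str] = []
        lengths: list[int] = []
        Xs: dict[str, np.ndarray] = {}
        ys: dict[str, np.ndarray] = {}
        for pid, grp in merged.groupby("product_id", sort=True):
            grp = grp.sort_values("month_index")
            n_i = len(grp)
            mi = grp["month_index"].to_numpy()
            if not np.array_equal(mi, np.arange(1, n_i + 1)):
                raise EstimationError(
                    f"product {pid!r}: months are not the consecutive prefix 1..n"
                )
            pos = grp.index.to_numpy()
            self._pids.append(pid)
            lengths.append(n_i)
            Xs[pid] = X[pos]
            ys[pid] = y[pos]

        self.n_obs = int(sum(lengths))
        self.p = X.shape[1]
        if self.n_obs <= self.p:
            raise EstimationError(
                f"{self.n_obs} observations cannot identify {self.p} coefficients"
            )
        # groups: length -> (pids, Y (n x m), Xg (n x m x p))
        self._groups: dict[int, tuple[list[str], np.ndarray, np.ndarray]] = {}
        for n_i in sorted(set(lengths)):
            pids = [pid for pid, l in zip(self._pids, lengths) if l == n_i]
            Y = np.column_stack([ys[pid] for pid in pids])
            Xg = np.stack([Xs[pid] for pid in pids], axis=1)
            self._groups[n_i] = (pids, Y, Xg)
        self._X, self._y = X, y

    @classmethod
    def from_frames(
        cls, records: pd.DataFrame, profiles: pd.DataFrame, spec: ModelSpec
    ) -> "BudgetImpactLMM":
        return cls(PanelDataset(records, profiles, validate=False), spec)

    # -- likelihood machinery ------------------------------------------

    def _decompose(self, G: np.ndarray, sigma2: float, phi: float) -> dict:
        """Per-length Cholesky factors of V_n = Z G Z' + sigma2 R_n(phi)."""
        out = {}
        for n_i in self._groups:
            t = np.arange(1, n_i + 1, dtype=float)
            Z = np.column_stack([np.ones(n_i), t])
            V = Z @ G @ Z.T + sigma2 * ar1_corr(phi, n_i)
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError as exc:
                pid = self._groups[n_i][0][0]
                raise EstimationError(
                    f"non-positive-definite marginal covariance "
                    f"(first affected product {pid!r})"
                ) from exc
            out[n_i] = (Z, C)
        return out

    def _gls_pieces(self, chol: dict) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Accumulate A = sum X'V^-1 X, b = sum X'V^-1 y, q = sum y'V^-1 y,
        and the total log|V|."""
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        q = 0.0
        logdet = 0.0
        for n_i, (pids, Y, Xg) in self._groups.items():
            _, C = chol[n_i]
            m = Y.shape[1]
            Yt = solve_triangular(C, Y, lower=True)
            Xt = solve_triangular(
                C, Xg.reshape(n_i, m * p), lower=True
            ).reshape(n_i, m, p)
            A += np.einsum("nmp,nmq->pq", Xt, Xt)
            b += np.einsum("nmp,nm->p", Xt, Yt)
            q += float((Yt**2).sum())
            logdet += m * 2.0 * float(np.log(np.diag(C)).sum())
        return A, b, q, logdet

    @staticmethod
    def _solve_beta(A: np.ndarray, b: np.ndarray) -> np.ndarray:
        try:
            c, low = linalg.cho_factor(A)
            return linalg.cho_solve((c, low), b)
        except linalg.LinAlgError:
            return np.linalg.lstsq(A, b, rcond=None)[0]

    def _profiled_nll(self, theta: np.ndarray) -> float:
        G, sigma2, phi = _theta_to_varparams(theta)
        try:
            chol = self._decompose(G, sigma2, phi)
        except EstimationError:
            return 1e12
        A, b, q, logdet = self._gls_pieces(chol)
        beta = self._solve_beta(A, b)
        rss = q - float(b @ beta)
        return 0.5 * (self.n_obs * _LOG2PI + logdet + rss)

    def loglike(self, params: LMMParams) -> float:
        """Exact log-likelihood at a full parameter set."""
        chol = self._decompose(params.re_cov, params.sigma2, params.phi)
        A, b, q, logdet = self._gls_pieces(chol)
        beta = params.beta
        if beta.shape[0] == len(self.column_names_full):
            beta = beta[self.kept]
        rss = q - 2.0 * float(b @ beta) + float(beta @ A @ beta)
        return -0.5 * (self.n_obs * _LOG2PI + logdet + rss)

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        method: str = "ML",
        maxiter: int = 500,
        tol: float = 1e-8,
        start: np.ndarray | None = None,
    ) -> "LMMResults":
        """Maximum-likelihood fit; deterministic (fixed starting values).

        Returns an :class:`LMMResults`; on optimizer failure the best-found
        parameters are returned with ``converged=False``, never silently.
        """
        if method != "ML":
            raise ValueError("only ML estimation is supported")
        # fixed starting values: OLS residual variance, G = 0.1 I, phi = 0
        beta_ols, *_ = np.linalg.lstsq(self._X, self._y, rcond=None)
        resid = self._y - self._X @ beta_ols
        dof = max(self.n_obs - self.p, 1)
        s2_ols = max(float(resid @ resid) / dof, 1e-8)
        if start is None:
            start = np.array(
                [0.5 * np.log(0.1), 0.0, 0.5 * np.log(0.1), np.log(s2_ols), 0.0]
            )
        bounds = [(-10, 10), (-50, 50), (-10, 10), (-30, 30), (-7, 7)]
        opt = optimize.minimize(
            self._profiled_nll,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "maxfun": 20 * maxiter},
        )
        G, sigma2, phi = _theta_to_varparams(opt.x)
        chol = self._decompose(G, sigma2, phi)
        A, b, q, logdet = self._gls_pieces(chol)
        beta = self._solve_beta(A, b)
        rss = q - float(b @ beta)
        llf = -0.5 * (self.n_obs * _LOG2PI + logdet + rss)
        try:
            cov_beta = linalg.inv(A)
        except linalg.LinAlgError:
            cov_beta = np.linalg.pinv(A)

        # BLUPs: b_i = G Z_i' V_i^-1 (y_i - X_i beta)
        blups: dict[str, tuple[float, float]] = {}
        for n_i, (pids, Y, Xg) in self._groups.items():
            Z, C = chol[n_i]
            R = Y - np.einsum("nmp,p->nm", Xg, beta)
            u = solve_triangular(C, R, lower=True)
            v = solve_triangular(C.T, u, lower=False)  # V^-1 r
            B = G @ (Z.T @ v)  # 2 x m
            for j, pid in enumerate(pids):
                blups[pid] = (float(B[0, j]), float(B[1, j]))

        n_params = self.p + 5
        return LMMResults(
            model=self,
            spec=self.spec,
            column_names=list(self.column_names),
            column_names_full=list(self.column_names_full),
            dropped_columns=list(self.dropped_columns),
            beta=beta,
            bse=np.sqrt(np.diag(cov_beta)),
            cov_beta=cov_beta,
            re_cov=G,
            sigma2=sigma2,
            phi=phi,
            llf=llf,
            n_obs=self.n_obs,
            n_params=n_params,
            blups=pd.DataFrame.from_dict(
                blups, orient="index", columns=["b0", "b1"]
            ).sort_index(),
            converged=bool(opt.success),
            optimizer_message=str(opt.message),
            n_iter=int(opt.nit),
        )


@dataclass
class LMMResults:
    """Fitted model: estimates, uncertainties, BLUPs, diagnostics."""

    spec: ModelSpec
    column_names: list[str]
    column_names_full: list[str]
    dropped_columns: list[str]
    beta: np.ndarray
    bse: np.ndarray
    cov_beta: np.ndarray
    re_cov: np.ndarray
    sigma2: float
    phi: float
    llf: float
    n_obs: int
    n_params: int
    blups: pd.DataFrame
    converged: bool
    optimizer_message: str = ""
    n_iter: int = 0
    model: BudgetImpactLMM | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        """AIC = 2 k - 2 loglik, k = p + 5 (beta, G, sigma2, phi)."""
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.column_names, name="coef")

    def _term_indices(self, term: ModelTerm) -> list[int]:
        cols = self.spec.term_columns(term)
        return [self.column_names.index(c) for c in cols if c in self.column_names]

    def wald_p(self, term: ModelTerm) -> float:
        """Two-sided Wald p-value for a term; joint chi-square if the term
        spans several design columns (multi-level categorical)."""
        if term not in self.spec.terms:
            raise ValueError(f"term {term.label!r} not in the fitted spec")
        idx = self._term_indices(term)
        if not idx:
            return float("nan")
        if len(idx) == 1:
            j = idx[0]
            if self.bse[j] == 0:
                return 1.0 if self.beta[j] == 0 else 0.0
            z = self.beta[j] / self.bse[j]
            return float(2.0 * stats.norm.sf(abs(z)))
        bj = self.beta[idx]
        Cj = self.cov_beta[np.ix_(idx, idx)]
        try:
            w = float(bj @ np.linalg.solve(Cj, bj))
        except np.linalg.LinAlgError:
            w = float(bj @ np.linalg.pinv(Cj) @ bj)
        return float(stats.chi2.sf(w, df=len(idx)))

    def predict_log_bi(
        self,
        profile: pd.Series | pd.DataFrame,
        t_values,
        product_id: str | None = None,
        t_max: int | None = None,
    ) -> np.ndarray:
        """Predicted log BI for a product profile over month indices.

        If ``product_id`` has a BLUP in this fit (its history participated in
        estimation), the conditional mean x'beta + b0 + b1 t is returned;
        otherwise the population-level x'beta.
        """
        t = np.asarray(list(t_values), dtype=float)
        if t.size and (t.min() < 1 or (t_max is not None and t.max() > t_max)):
            hi = t_max if t_max is not None else "inf"
            raise ValueError(f"prediction months must lie in [1, {hi}]")
        if isinstance(profile, pd.Series):
            frame = profile.to_frame().T
        else:
            frame = profile
        frame = pd.concat([frame] * len(t), ignore_index=True) if len(frame) == 1 else frame
        X_full, _ = design_matrix(frame, t, self.spec)
        kept = [self.column_names_full.index(c) for c in self.column_names]
        pred = X_full[:, kept] @ self.beta
        if product_id is not None and product_id in self.blups.index:
            b0, b1 = self.blups.loc[product_id]
            pred = pred + b0 + b1 * t
        return pred

    def summary(self) -> str:
        lines = [
            "Budget-impact mixed model (ML), log(BI) response",
            f"  n_obs = {self.n_obs}, products = {len(self.blups)}, "
            f"k = {self.n_params}",
            f"  logLik = {self.llf:.4f}, AIC = {self.aic:.4f}, "
            f"converged = {self.converged}",
            "",
            f"{'term':<32}{'coef':>12}{'se':>12}{'z':>9}{'p':>10}",
        ]
        for j, name in enumerate(self.column_names):
            se = self.bse[j]
            z = self.beta[j] / se if se > 0 else np.nan
            pz = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(
                f"{name:<32}{self.beta[j]:>12.4f}{se:>12.4f}{z:>9.2f}{pz:>10.4f}"
            )
        for name in self.dropped_columns:
            lines.append(f"{name:<32}{'dropped (no support)':>22}")
        g = self.re_cov
        lines += [
            "",
            f"Random effects: var(b0) = {g[0, 0]:.4f}, var(b1) = {g[1, 1]:.4g}, "
            f"cov = {g[0, 1]:.4g}",
            f"Residual: sigma2 = {self.sigma2:.4f}, AR(1) phi = {self.phi:.4f}",
        ]
        return "\n".join(lines)

    # -- serialization --------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "spec": self.spec.to_dict(),
            "column_names": self.column_names,
            "column_names_full": self.column_names_full,
            "dropped_columns": self.dropped_columns,
            "beta": self.beta.tolist(),
            "bse": self.bse.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "re_cov": self.re_cov.tolist(),
            "sigma2": self.sigma2,
            "phi": self.phi,
            "llf": self.llf,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "blups": {pid: list(map(float, row)) for pid, row in self.blups.iterrows()},
            "converged": self.converged,
            "optimizer_message": self.optimizer_message,
            "n_iter": self.n_iter,
        }
        s = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "LMMResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            spec=ModelSpec.from_dict(doc["spec"]),
            column_names=doc["column_names"],
            column_names_full=doc["column_names_full"],
            dropped_columns=doc["dropped_columns"],
            beta=np.asarray(doc["beta"]),
            bse=np.asarray(doc["bse"]),
            cov_beta=np.asarray(doc["cov_beta"]),
            re_cov=np.asarray(doc["re_cov"]),
            sigma2=doc["sigma2"],
            phi=doc["phi"],
            llf=doc["llf"],
            n_obs=doc["n_obs"],
            n_params=doc["n_params"],
            blups=pd.DataFrame.from_dict(
                doc["blups"], orient="index", columns=["b0", "b1"]
            ).sort_index(),
            converged=doc["converged"],
            optimizer_message=doc.get("optimizer_message", ""),
            n_iter=doc.get("n_iter", 0),
        )


def neg_log_likelihood(
    dataset: PanelDataset, spec: ModelSpec, params: LMMParams
) -> float:
    """Negative log-likelihood of the mixed model at a full parameter set."""
    return -BudgetImpactLMM(dataset, spec).loglike(params)
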