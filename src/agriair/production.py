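"""County-year agricultural TFP from production functions.

Four estimators of total factor productivity from aggregate output value
and four primary inputs (cropland, labor, fertilizer, machinery):

``tlcpf``
    Translog conventional production function (baseline).
``tlcpf-crs``
    Translog with constant returns to scale imposed as linear
    homogeneity restrictions on first- and second-order coefficients.
``cdcpf``
    Cobb–Douglas conventional production function.
``cdsfa-crs``
    Cobb–Douglas stochastic frontier (normal/half-normal composed error)
    with CRS imposed by estimating in per-cropland form.

TFP is the residual-based index: output over the predicted frontier
output at the observed inputs (intercept excluded), normalized to a unit
sample geometric mean.  For the frontier model the index is the
Jondrow-type technical efficiency.  Labor productivity (output per
worker) is provided as the partial-productivity companion measure.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "INPUTS",
    "ESTIMATORS",
    "ProductionModel",
    "ProductionResults",
    "fit_cobb_douglas",
    "fit_translog",
    "fit_sfa_cd",
    "tfp_index",
    "labor_productivity",
]

logger = logging.getLogger(__name__)

INPUTS = ("cropland", "labor", "fertilizer", "machinery")
ESTIMATORS = ("tlcpf", "tlcpf-crs", "cdcpf", "cdsfa-crs")


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message names the columns."""


def _check_rank(X: np.ndarray, names: list[str], tol: float = 1e-10) -> None:
    _, rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(rmat))
    scale = diag.max() if diag.size else 0.0
    bad = [names[i] for i in np.where(diag <= tol * max(scale, 1.0))[0]]
    if bad:
        raise RankDeficientError(f"collinear design columns: {bad}")


def _restricted_ls(X: np.ndarray, y: np.ndarray, R: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least squares subject to R b = q (closed form)."""
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    XtX_inv_Rt = np.linalg.solve(XtX, R.T)
    correction = XtX_inv_Rt @ np.linalg.solve(R @ XtX_inv_Rt, R @ b - q)
    return b - correction


def _translog_columns(logs: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(logs))], ["const"]
    for j in INPUTS:
        cols.append(logs[j].to_numpy())
        names.append(f"ln_{j}")
    for j in INPUTS:
        cols.append(0.5 * logs[j].to_numpy() ** 2)
        names.append(f"half_sq_{j}")
    for j, k in itertools.combinations(INPUTS, 2):
        cols.append(logs[j].to_numpy() * logs[k].to_numpy())
        names.append(f"cross_{j}_{k}")
    return np.column_stack(cols), names


def _halfnormal_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    k = X.shape[1]
    b = params[:k]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sigma_v = np.exp(0.5 * params[k])
        sigma_u = np.exp(0.5 * params[k + 1])
        sigma2 = sigma_v**2 + sigma_u**2
        sigma = np.sqrt(sigma2)
        lam = sigma_u / sigma_v
        eps = y - X @ b
        ll = (
            np.log(2.0)
            - np.log(sigma)
            + stats.norm.logpdf(eps / sigma)
            + stats.norm.logcdf(-eps * lam / sigma)
        )
        total = float(ll.sum())
    return total if np.isfinite(total) else -1e12


@dataclasses.dataclass
class ProductionResults:
    """Fitted production function and the implied TFP series.

    Attributes
    ----------
    estimator : str
        One of ``tlcpf``, ``tlcpf-crs``, ``cdcpf``, ``cdsfa-crs``.
    params : pandas.Series
        Coefficients (frontier coefficients for the SFA).
    sigma_v, sigma_u : float or None
        Frontier variance components (SFA only).
    fitted : pandas.Series
        Fitted log output on the estimation rows.
    model : ProductionModel
    """

    estimator: str
    params: pd.Series
    fitted: pd.Series
    model: "ProductionModel"
    sigma_v: float | None = None
    sigma_u: float | None = None
    loglik: float | None = None
    efficiency: pd.Series | None = None

    @property
    def rss(self) -> float:
        resid = self.model.log_output - self.fitted
        return float((resid**2).sum())

    def tfp(self) -> pd.Series:
        """TFP index normalized to a unit sample geometric mean.

        Residual-based for the conventional estimators (output over the
        slope-only frontier prediction); Jondrow-type technical
        efficiency for the stochastic frontier.
        """
        if self.efficiency is not None:
            log_tfp = np.log(self.efficiency)
        else:
            slope_pred = self.fitted - self.params["const"]
            log_tfp = self.model.log_output - slope_pred
        log_tfp = log_tfp - log_tfp.mean()
        return np.exp(log_tfp).rename("tfp")

    def returns_to_scale(self) -> float:
        """Sum of output elasticities evaluated at the sample mean of logs."""
        logs = self.model.logs
        rts = 0.0
        for j in INPUTS:
            rts += self.params.get(f"ln_{j}", 0.0)
            if f"half_sq_{j}" in self.params:
                rts += self.params[f"half_sq_{j}"] * logs[j].mean()
            for k in INPUTS:
                if j == k:
                    continue
                name = f"cross_{min(j,k,key=INPUTS.index)}_{max(j,k,key=INPUTS.index)}"
                if name in self.params:
                    rts += 0.5 * self.params[name] * logs[k].mean()
        return float(rts)

    def summary(self) -> str:
        lines = [
            f"Production function fit: {self.estimator}",
            f"  observations: {len(self.fitted)}",
            f"  residual sum of squares: {self.rss:.6g}",
        ]
        if self.sigma_u is not None:
            lines.append(f"  sigma_v={self.sigma_v:.4f}  sigma_u={self.sigma_u:.4f}")
        if self.loglik is not None:
            lines.append(f"  log-likelihood: {self.loglik:.4f}")
        lines.append("  coefficients:")
        for name, value in self.params.items():
            lines.append(f"    {name:<28s} {value: .6f}")
        return "\n".join(lines)


class ProductionModel:
    """Production-function model for county-year records.

    Parameters
    ----------
    records : DataFrame
        Columns ``output`` (deflated value) and the four inputs
        ``cropland``, ``labor``, ``fertilizer``, ``machinery``.  Rows
        with nonpositive output or inputs are excluded with a log entry.
    """

    def __init__(self, records: pd.DataFrame):
        needed = ["output", *INPUTS]
        missing = [c for c in needed if c not in records.columns]
        if missing:
            raise KeyError(f"records missing columns: {missing}")
        positive = (records[needed] > 0).all(axis=1) & records[needed].notna().all(axis=1)
        n_bad = int((~positive).sum())
        if n_bad:
            logger.warning("excluding %d rows with nonpositive/missing output or inputs", n_bad)
        self.records = records.loc[positive].copy()
        if len(self.records) < 2 * (len(INPUTS) + 1):
            raise ValueError("too few valid records to estimate a production function")
        self.log_output = np.log(self.records["output"]).rename("log_output")
        self.logs = np.log(self.records[list(INPUTS)])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **rename) -> "ProductionModel":
        """Build from a dataframe with nonstandard column names."""
        return cls(df.rename(columns={v: k for k, v in rename.items()}))

    # -- estimators -----------------------------------------------------

    def fit(self, estimator: str = "tlcpf", **kwargs) -> ProductionResults:
        if estimator == "cdcpf":
            return self.fit_cobb_douglas(crs=False)
        if estimator == "cdcpf-crs":
            return self.fit_cobb_douglas(crs=True)
        if estimator == "tlcpf":
            return self.fit_translog(crs=False)
        if estimator == "tlcpf-crs":
            return self.fit_translog(crs=True)
        if estimator == "cdsfa-crs":
            return self.fit_sfa_cd(crs=True, **kwargs)
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")

    def fit_cobb_douglas(self, crs: bool = False) -> ProductionResults:
        """Least squares of log output on log inputs; optional CRS.

        CRS restricts the input elasticities to sum to one via restricted
        least squares.
        """
        names = ["const"] + [f"ln_{j}" for j in INPUTS]
        X = np.column_stack([np.ones(len(self.logs))] + [self.logs[j] for j in INPUTS])
        _check_rank(X, names)
        y = self.log_output.to_numpy()
        if crs:
            R = np.zeros((1, X.shape[1]))
            R[0, 1:] = 1.0
            b = _restricted_ls(X, y, R, np.array([1.0]))
        else:
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
        params = pd.Series(b, index=names)
        fitted = pd.Series(X @ b, index=self.log_output.index)
        tag = "cdcpf-crs" if crs else "cdcpf"
        return ProductionResults(tag, params, fitted, self)

    def fit_translog(self, crs: bool = False) -> ProductionResults:
        """Full second-order translog; optional CRS homogeneity restrictions.

        With the half-square convention (columns ``0.5·ln x_j²``), linear
        homogeneity is Σ_j β_j = 1 and, for each j, β_jj + Σ_{k≠j} β_jk = 0.
        """
        X, names = _translog_columns(self.logs)
        _check_rank(X, names)
        cond = np.linalg.cond(X)
        if cond > 1e10:
            logger.warning("translog design near-singular (condition number %.3g)", cond)
        y = self.log_output.to_numpy()
        if crs:
            p = len(names)
            rows = []
            r1 = np.zeros(p)
            for j in INPUTS:
                r1[names.index(f"ln_{j}")] = 1.0
            rows.append(r1)
            for j in INPUTS:
                r = np.zeros(p)
                r[names.index(f"half_sq_{j}")] = 1.0
                for k in INPUTS:
                    if k == j:
                        continue
                    a, bname = sorted((j, k), key=INPUTS.index)
                    r[names.index(f"cross_{a}_{bname}")] = 1.0
                rows.append(r)
            R = np.vstack(rows)
            q = np.concatenate([[1.0], np.zeros(len(INPUTS))])
            b = _restricted_ls(X, y, R, q)
        else:
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
        params = pd.Series(b, index=names)
        fitted = pd.Series(X @ b, index=self.log_output.index)
        tag = "tlcpf-crs" if crs else "tlcpf"
        return ProductionResults(tag, params, fitted, self)

    def fit_sfa_cd(
        self,
        crs: bool = True,
        n_restarts: int = 4,
        seed: int = 0,
        sigma_u_floor: float = 1e-4,
    ) -> ProductionResults:
        """Cobb–Douglas stochastic frontier by maximum likelihood.

        Composed error ε = v − u with v ~ N(0, σ_v²) and u half-normal
        with scale σ_u.  CRS is imposed by estimating in per-cropland
        form (output and non-land inputs divided by cropland).  The
        likelihood is maximized over log-variances from an OLS start
        plus seeded perturbations; a boundary solution σ_u → 0 is
        reported as the least-squares limit.
        """
        if crs:
            y = (self.log_output - self.logs["cropland"]).to_numpy()
            reg_inputs = [j for j in INPUTS if j != "cropland"]
            Xcols = [self.logs[j] - self.logs["cropland"] for j in reg_inputs]
            names = ["const"] + [f"ln_{j}_per_cropland" for j in reg_inputs]
        else:
            y = self.log_output.to_numpy()
            reg_inputs = list(INPUTS)
            Xcols = [self.logs[j] for j in reg_inputs]
            names = ["const"] + [f"ln_{j}" for j in reg_inputs]
        X = np.column_stack([np.ones(len(y))] + [np.asarray(c) for c in Xcols])
        _check_rank(X, names)

        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ b_ols
        s2 = float(resid.var())
        rng = np.random.default_rng(seed)
        starts = [np.concatenate([b_ols, [np.log(0.8 * s2), np.log(0.4 * s2)]])]
        for _ in range(n_restarts):
            jitter = rng.normal(scale=0.3, size=len(b_ols) + 2)
            starts.append(starts[0] + jitter)

        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda p: -_halfnormal_loglik(p, X, y),
                x0,
                method="L-BFGS-B",
            )
            if best is None or (res.success and res.fun < best.fun):
                if best is None or res.fun < best.fun:
                    best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("stochastic frontier likelihood failed to converge")

        k = X.shape[1]
        b = best.x[:k]
        sigma_v = float(np.exp(0.5 * best.x[k]))
        sigma_u = float(np.exp(0.5 * best.x[k + 1]))
        loglik = -float(best.fun)

        if sigma_u < sigma_u_floor * np.sqrt(s2 + 1e-300):
            # boundary: frontier collapses to OLS with a one-sided part of 0
            logger.info("sigma_u at boundary; reporting the least-squares limit")
            b = b_ols
            sigma_u = 0.0
            sigma_v = float(np.sqrt(s2))
            eff = np.ones(len(y))
        else:
            sigma2 = sigma_v**2 + sigma_u**2
            eps = y - X @ b
            mu_star = -eps * sigma_u**2 / sigma2
            s_star = sigma_u * sigma_v / np.sqrt(sigma2)
            z = mu_star / s_star
            cond_mean_u = mu_star + s_star * np.exp(
                stats.norm.logpdf(z) - stats.norm.logcdf(z)
            )
            eff = np.exp(-cond_mean_u)

        params = pd.Series(b, index=names)
        fitted = pd.Series(X @ b, index=self.log_output.index)
        if crs:
            # back to total-output scale for fitted log output
            fitted = fitted + self.logs["cropland"]
        return ProductionResults(
            "cdsfa-crs" if crs else "cdsfa",
            params,
            fitted,
            self,
            sigma_v=sigma_v,
            sigma_u=sigma_u,
            loglik=loglik,
            efficiency=pd.Series(np.clip(eff, None, 1.0), index=self.log_output.index),
        )


# -- module-level operation wrappers ------------------------------------


def fit_cobb_douglas(records: pd.DataFrame, crs: bool = False) -> ProductionResults:
    return ProductionModel(records).fit_cobb_douglas(crs=crs)


def fit_translog(records: pd.DataFrame, crs: bool = False) -> ProductionResults:
    return ProductionModel(records).fit_translog(crs=crs)


def fit_sfa_cd(records: pd.DataFrame, crs: bool = True, **kw) -> ProductionResults:
    return ProductionModel(records).fit_sfa_cd(crs=crs, **kw)


def tfp_index(fit: ProductionResults, records: pd.DataFrame | None = None) -> pd.Series:
    """County-year TFP series from a fitted production function.

    Output over the slope-only frontier prediction, normalized so the
    sample geometric mean is 1; see :meth:`ProductionResults.tfp`.
    """
    return fit.tfp()


def labor_productivity(records: pd.DataFrame) -> pd.Series:
    """Output value per agricultural worker; zero labor flagged missing."""
    labor = records["labor"].astype(float)
    out = records["output"].astype(float) / labor.where(labor > 0)
    n_bad = int((~(labor > 0)).sum())
    if n_bad:
        logger.warning("labor productivity undefined for %d rows with zero labor", n_bad)
    return out.rename("labor_productivity")
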