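"""Two-way fixed-effects panel IV with wind-direction instruments.

Fits the log-linear outcome model

    log(TFP_it) = β_O3·Ozone_it + β_PM·PM2.5_it + X_it'γ + α_i + λ_t + u_it

by OLS, two-stage least squares, or LIML, with the pollution variables
jointly instrumented by group-specific wind-direction bin-day counts
(spatial-group indicator × days per 90° wind quadrant, the quadrant
[270°, 360°) serving as reference).  County and year fixed effects are
absorbed by alternating demeaning; standard errors are cluster-robust
(county clusters by default); instrument strength is diagnosed with the
cluster-robust Kleibergen–Paap rank Wald F and the Cragg–Donald F.

The public surface is the statsmodels-style pair
:class:`PanelIVModel` → :class:`PanelIVResults`.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .weather import WIND_BIN_COLUMNS, temperature_bin_labels, CONTINUOUS_CONTROLS

__all__ = [
    "PanelIVModel",
    "PanelIVResults",
    "within_transform",
    "build_instruments",
    "cluster_vcov",
    "kp_f",
    "cragg_donald_f",
    "fit_ols",
    "fit_2sls",
    "fit_liml",
    "default_control_columns",
]

logger = logging.getLogger(__name__)

#: Temperature bin dropped as the reference category (bins sum to the
#: days in the year, so one must be omitted once fixed effects absorb
#: constants).
REFERENCE_TEMP_BIN = "tbin_15_20"


# ---------------------------------------------------------------------
# building blocks


def within_transform(
    X: np.ndarray,
    factors: list[np.ndarray],
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Demean columns of ``X`` by each factor in turn until converged.

    Alternating projections for two-way (or n-way) fixed effects; for a
    balanced panel a single sweep of county-then-year demeaning already
    converges.  Unbalanced panels iterate until every group mean is
    below ``tol`` in absolute value.

    Parameters
    ----------
    X : ndarray, shape (N, k) or (N,)
    factors : list of integer-coded arrays of shape (N,)
    """
    X = np.array(X, dtype=float, copy=True)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    codes = [np.asarray(pd.factorize(f)[0]) for f in factors]
    counts = [np.bincount(c).astype(float) for c in codes]
    for sweep in range(max_sweeps):
        max_mean = 0.0
        for c, n in zip(codes, counts):
            for j in range(X.shape[1]):
                sums = np.bincount(c, weights=X[:, j])
                means = sums / n
                X[:, j] -= means[c]
                max_mean = max(max_mean, float(np.abs(means).max(initial=0.0)))
        if max_mean < tol:
            break
    else:
        raise RuntimeError(f"within transform did not converge in {max_sweeps} sweeps")
    return X[:, 0] if squeeze else X


def drop_singletons(panel: pd.DataFrame, fe_cols: tuple[str, str]) -> pd.DataFrame:
    """Iteratively drop observations that are singletons in any absorbed level."""
    out = panel
    while True:
        keep = np.ones(len(out), bool)
        for col in fe_cols:
            counts = out[col].map(out[col].value_counts())
            keep &= counts.to_numpy() >= 2
        if keep.all():
            return out
        logger.info("dropping %d singleton observations", int((~keep).sum()))
        out = out.loc[keep]


def build_instruments(
    panel: pd.DataFrame,
    group_col: str = "group",
    wind_cols: tuple[str, ...] = WIND_BIN_COLUMNS[:3],
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Instrument matrix: spatial-group indicators × wind-bin day counts.

    One column per (group g, quadrant a ∈ {0, 1, 2}) — the quadrant
    [270°, 360°) is the reference and supplies no column — in
    deterministic group-major order.  Collinear columns are dropped by a
    sequential QR test at ``tol`` (relative residual norm), logged.
    """
    groups = np.sort(panel[group_col].unique())
    cols, names = [], []
    for g in groups:
        indicator = (panel[group_col] == g).to_numpy(float)
        for a, wc in enumerate(wind_cols):
            cols.append(indicator * panel[wc].to_numpy(float))
            names.append(f"z_g{g}_bin{a}")
    Z = np.column_stack(cols)
    keep, dropped = _sequential_qr_keep(Z, tol)
    if dropped:
        logger.info("dropped %d collinear instrument columns: %s",
                    len(dropped), [names[i] for i in dropped][:10])
    if not keep:
        raise ValueError("all instrument columns collinear; no identification")
    return pd.DataFrame(Z[:, keep], columns=[names[i] for i in keep], index=panel.index)


def _sequential_qr_keep(Z: np.ndarray, tol: float) -> tuple[list[int], list[int]]:
    """Greedy rank-revealing pass in the given column order."""
    N = Z.shape[0]
    Q = np.empty((N, 0))
    keep, dropped = [], []
    for j in range(Z.shape[1]):
        col = Z[:, j]
        norm0 = np.linalg.norm(col)
        if norm0 <= tol:
            dropped.append(j)
            continue
        r = col - Q @ (Q.T @ col)
        r = r - Q @ (Q.T @ r)  # reorthogonalize
        norm_r = np.linalg.norm(r)
        if norm_r <= tol * norm0:
            dropped.append(j)
        else:
            keep.append(j)
            Q = np.column_stack([Q, r / norm_r])
    return keep, dropped


def cluster_vcov(
    design: np.ndarray,
    resid: np.ndarray,
    clusters: np.ndarray,
    bread: np.ndarray | None = None,
    k_params: int | None = None,
) -> np.ndarray:
    """Cluster-robust sandwich covariance.

    V = B (Σ_c s_c s_c') B' with s_c the within-cluster sum of scores
    ``design_i · resid_i`` and B the bread (``(design'design)^(-1)`` by
    default), scaled by the small-sample factor G/(G−1)·(N−1)/(N−k).

    With every observation its own cluster this reduces to the
    HC1-style heteroskedasticity-robust estimator.
    """
    design = np.asarray(design, float)
    resid = np.asarray(resid, float)
    codes, uniques = pd.factorize(clusters)
    G = len(uniques)
    if G < 2:
        raise ValueError("need at least 2 clusters for cluster-robust inference")
    N, k = design.shape
    if k_params is None:
        k_params = k
    scores = design * resid[:, None]
    cluster_sums = np.zeros((G, k))
    np.add.at(cluster_sums, codes, scores)
    meat = cluster_sums.T @ cluster_sums
    if bread is None:
        bread = np.linalg.pinv(design.T @ design)
    factor = (G / (G - 1.0)) * ((N - 1.0) / (N - k_params))
    return factor * (bread @ meat @ bread)


def _project(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Projection of the columns of X onto the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, X, rcond=None)
    return Z @ coef


def kp_f(
    endog: np.ndarray,
    instruments: np.ndarray,
    clusters: np.ndarray,
    k_absorbed: int = 0,
) -> float:
    """Cluster-robust Kleibergen–Paap rank Wald F statistic.

    Tests that the first-stage coefficient matrix Π (endogenous on
    excluded instruments, exogenous regressors already partialled out)
    has full column rank, using the robust variance of the orthonormal-
    coordinates estimate; the rank statistic is divided by the number of
    instruments, as econometrics software reports it.

    Parameters
    ----------
    endog : ndarray (N, m)
        Endogenous regressors, within-transformed and with included
        exogenous regressors partialled out.
    instruments : ndarray (N, L)
        Excluded instruments, transformed/partialled the same way.
    clusters : array (N,)
    k_absorbed : int
        Parameters absorbed/partialled before this call, for the
        small-sample degrees-of-freedom factor.
    """
    X = np.atleast_2d(np.asarray(endog, float))
    if X.shape[0] == 1 and X.size > 1:
        X = X.T
    Z = np.asarray(instruments, float)
    N, m = X.shape
    L = Z.shape[1]
    if L < m:
        raise ValueError("under-identified: fewer instruments than endogenous")

    g = linalg.cholesky(Z.T @ Z / N, lower=False)
    f = linalg.cholesky(X.T @ X / N, lower=False)
    Z_o = linalg.solve_triangular(g, Z.T, lower=False, trans="T").T / 1.0
    X_o = linalg.solve_triangular(f, X.T, lower=False, trans="T").T
    theta = Z_o.T @ X_o / N
    pi_o, *_ = np.linalg.lstsq(Z_o, X_o, rcond=None)
    eps = X_o - Z_o @ pi_o

    # robust variance of vec(sqrt(N)·theta) from cluster-summed scores
    codes, uniques = pd.factorize(clusters)
    G = len(uniques)
    scores = (eps[:, :, None] * Z_o[:, None, :]).reshape(N, m * L)  # vec(z eps')
    cluster_sums = np.zeros((G, m * L))
    np.add.at(cluster_sums, codes, scores)
    k_fs = L + k_absorbed
    factor = (G / (G - 1.0)) * ((N - 1.0) / max(N - k_fs, 1.0))
    V = factor * (cluster_sums.T @ cluster_sums) / N

    U, s, Vh = np.linalg.svd(theta)
    r = m - 1
    U2 = U[:, r:]  # L × (L-r)
    V2 = Vh.T[:, r:]  # m × 1
    lam = U2.T @ theta @ V2  # (L-r) × 1
    # scores flat index j·L + l matches column-major vec of the L×m score
    # matrix z_i ε_i', so vec(U2' θ V2) = (V2' ⊗ U2') vec(θ)
    T = np.kron(V2.T, U2.T)
    Vlam = T @ V @ T.T
    rk = float((N * lam.T @ np.linalg.solve(Vlam, lam))[0, 0])
    return rk / L


def cragg_donald_f(
    endog: np.ndarray,
    instruments: np.ndarray,
    k_other: int = 0,
) -> float:
    """Cragg–Donald minimum-eigenvalue first-stage F statistic."""
    X = np.atleast_2d(np.asarray(endog, float))
    if X.shape[0] == 1 and X.size > 1:
        X = X.T
    Z = np.asarray(instruments, float)
    N, m = X.shape
    L = Z.shape[1]
    Xhat = _project(Z, X)
    E = X - Xhat
    dof = max(N - L - k_other, 1)
    sigma = E.T @ E / dof
    sigma_inv_half = np.linalg.inv(linalg.cholesky(sigma, lower=True))
    M = sigma_inv_half @ (Xhat.T @ Xhat) @ sigma_inv_half.T
    return float(np.linalg.eigvalsh(M).min() / L)


# ---------------------------------------------------------------------
# model / results


class PanelIVModel:
    """Fixed-effects panel model with wind-direction instruments.

    Parameters
    ----------
    panel : DataFrame
        County-year rows; must contain the outcome, endogenous and
        control columns, the fixed-effect identifiers, the cluster id,
        the spatial group label and the wind-bin day counts.
    outcome : str
        Log outcome column (log TFP or log labor productivity).
    endog : sequence of str
        Jointly instrumented pollution regressors.
    controls : sequence of str
        Exogenous weather controls (treated as their own instruments).
    fe : (str, str)
        County and year identifier columns, absorbed as fixed effects.
    cluster : str
        Cluster identifier for robust inference.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        outcome: str,
        endog: list[str],
        controls: list[str],
        fe: tuple[str, str] = ("county", "year"),
        cluster: str = "county",
        group_col: str = "group",
        wind_cols: tuple[str, ...] = WIND_BIN_COLUMNS[:3],
        instruments: pd.DataFrame | None = None,
    ):
        self.outcome = outcome
        self.endog_names = list(endog)
        self.control_names = list(controls)
        self.fe = fe
        self.cluster = cluster
        self.group_col = group_col
        self.wind_cols = wind_cols

        est_cols = [outcome, *endog, *controls]
        dup = panel.duplicated(subset=list(fe))
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (county, year) rows")
        complete = panel[est_cols].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("listwise deletion removed %d rows with missing values", n_dropped)
        data = panel.loc[complete]
        data = drop_singletons(data, fe)
        self.data = data.reset_index(drop=True)
        self._external_instruments = (
            instruments.loc[data.index].reset_index(drop=True)
            if instruments is not None
            else None
        )

        n_counties = self.data[fe[0]].nunique()
        n_years = self.data[fe[1]].nunique()
        #: parameters absorbed by the two-way fixed effects (plus grand mean)
        self.k_absorbed = (n_counties - 1) + (n_years - 1) + 1

    @classmethod
    def from_panel(
        cls,
        panel: pd.DataFrame,
        outcome: str = "log_tfp",
        ozone: str = "annual",
        cluster: str = "county",
        **kwargs,
    ) -> "PanelIVModel":
        """Build the standard specification from the panel CSV dialect.

        ``ozone`` selects the exposure metric: ``annual`` (annual mean
        MDA8), ``seasonal`` (winter and nonwinter means as two
        regressors), or ``aot40``/``sum06``/``w126``.
        """
        if ozone == "annual":
            ozone_cols = ["ozone_annual"]
        elif ozone == "seasonal":
            ozone_cols = ["ozone_winter", "ozone_nonwinter"]
        elif ozone in ("aot40", "sum06", "w126"):
            ozone_cols = [ozone]
        else:
            raise ValueError(f"unknown ozone metric {ozone!r}")
        endog = ozone_cols + ["pm25"]
        controls = default_control_columns(panel)
        return cls(panel, outcome, endog, controls, cluster=cluster, **kwargs)

    # -- estimation -----------------------------------------------------

    def _matrices(self):
        d = self.data
        y = d[self.outcome].to_numpy(float)
        Xe = d[self.endog_names].to_numpy(float)
        C = d[self.control_names].to_numpy(float) if self.control_names else np.empty((len(d), 0))
        if self._external_instruments is not None:
            Z = self._external_instruments.to_numpy(float)
            z_names = list(self._external_instruments.columns)
        else:
            zdf = build_instruments(d, self.group_col, self.wind_cols)
            Z = zdf.to_numpy(float)
            z_names = list(zdf.columns)
        factors = [d[self.fe[0]].to_numpy(), d[self.fe[1]].to_numpy()]
        stacked = np.column_stack([y[:, None], Xe, C, Z])
        tilde = within_transform(stacked, factors)
        m, kc = Xe.shape[1], C.shape[1]
        y_t = tilde[:, 0]
        Xe_t = tilde[:, 1 : 1 + m]
        C_t = tilde[:, 1 + m : 1 + m + kc]
        Z_t = tilde[:, 1 + m + kc :]
        clusters = d[self.cluster].to_numpy()
        return y_t, Xe_t, C_t, Z_t, z_names, clusters

    def fit(self, method: str = "2sls") -> "PanelIVResults":
        """Fit by ``"ols"``, ``"2sls"`` or ``"liml"``."""
        method = method.lower()
        if method not in ("ols", "2sls", "liml"):
            raise ValueError(f"unknown method {method!r}")
        y, Xe, C, Z, z_names, clusters = self._matrices()
        N = len(y)
        m = Xe.shape[1]
        X = np.column_stack([Xe, C])
        names = self.endog_names + self.control_names
        k = X.shape[1]
        k_total = k + self.k_absorbed

        # equilibrate columns so quadratic weather terms do not wreck the
        # conditioning of the normal equations
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        Xs = X / scale

        kappa = None
        if method == "ols":
            keep, dropped = _sequential_qr_keep(Xs, 1e-10)
            if dropped:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design; collinear columns: {[names[i] for i in dropped]}"
                )
            A = Xs.T @ Xs
            bs = np.linalg.solve(A, Xs.T @ y)
            u = y - Xs @ bs
            design = Xs
            bread = np.linalg.pinv(A)
        else:
            Zfull = np.column_stack([Z, C])
            if Z.shape[1] < m:
                raise ValueError(
                    f"under-identified: {Z.shape[1]} instruments for {m} endogenous"
                )
            if method == "2sls":
                kappa = 1.0
            else:
                kappa = self._liml_kappa(y, Xe, C, Z)
            PXs = _project(Zfull, Xs)
            # kappa-class: X'(I − κ M)X b = X'(I − κ M)y
            Xk = (1 - kappa) * Xs + kappa * PXs
            A = Xk.T @ Xs
            bs = np.linalg.solve(A, Xk.T @ y)
            u = y - Xs @ bs
            design = Xk
            bread = np.linalg.pinv(A)
        b = bs / scale
        vcov_s = cluster_vcov(design, u, clusters, bread=bread, k_params=k_total)
        vcov = vcov_s / np.outer(scale, scale)

        # first-stage diagnostics (IV methods only)
        kp = cd = None
        first_stage = None
        if method != "ols":
            MC = lambda A: A - _project(C, A) if C.shape[1] else A
            Xe_p = MC(Xe)
            Z_p = MC(Z)
            kp = kp_f(Xe_p, Z_p, clusters, k_absorbed=self.k_absorbed + C.shape[1])
            cd = cragg_donald_f(Xe_p, Z_p, k_other=self.k_absorbed + C.shape[1])
            pi, *_ = np.linalg.lstsq(Z_p, Xe_p, rcond=None)
            first_stage = pd.DataFrame(pi, index=z_names, columns=self.endog_names)

        G = pd.unique(clusters).shape[0]
        return PanelIVResults(
            model=self,
            method=method,
            params=pd.Series(b, index=names),
            cov=pd.DataFrame(vcov, index=names, columns=names),
            resid=pd.Series(u),
            nobs=N,
            n_clusters=G,
            n_instruments=Z.shape[1] if method != "ols" else 0,
            kappa=kappa,
            kp_f=kp,
            cragg_donald=cd,
            first_stage=first_stage,
            df_resid=N - k_total,
        )

    @staticmethod
    def _liml_kappa(y, Xe, C, Z):
        MC = lambda A: A - _project(C, A) if C.shape[1] else A
        W = MC(np.column_stack([y[:, None], Xe]))
        Zp = MC(Z)
        MW = W - _project(Zp, W)
        WW = W.T @ W
        WMW = MW.T @ MW
        # smallest generalized eigenvalue of WW v = κ WMW v
        vals = linalg.eigvals(WW, WMW)
        vals = np.real(vals[np.isfinite(vals)])
        kappa = float(vals.min())
        return max(kappa, 1.0)


@dataclasses.dataclass
class PanelIVResults:
    """Estimates, cluster-robust uncertainty and first-stage diagnostics."""

    model: PanelIVModel
    method: str
    params: pd.Series
    cov: pd.DataFrame
    resid: pd.Series
    nobs: int
    n_clusters: int
    n_instruments: int
    df_resid: int
    kappa: float | None = None
    kp_f: float | None = None
    cragg_donald: float | None = None
    first_stage: pd.DataFrame | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        df = max(self.n_clusters - 1, 1)
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        df = max(self.n_clusters - 1, 1)
        q = stats.t.ppf(1 - alpha / 2, df)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def semi_elasticities(self) -> pd.Series:
        """Coefficients × 100: percent change in the outcome per unit
        regressor, the first-order reading of the log-linear model."""
        return (self.params * 100.0).rename("percent_per_unit")

    def summary(self, top: int | None = 8) -> str:
        ci = self.conf_int()
        lines = [
            f"Panel {self.method.upper()} — outcome {self.model.outcome!r}",
            f"  N = {self.nobs}, clusters = {self.n_clusters}, "
            f"absorbed FE params = {self.model.k_absorbed}",
        ]
        if self.method != "ols":
            lines.append(
                f"  instruments = {self.n_instruments}, "
                f"KP F = {self.kp_f:.4f}, Cragg–Donald F = {self.cragg_donald:.4f}"
            )
            if self.kappa is not None:
                lines.append(f"  kappa = {self.kappa:.6f}")
        lines.append(f"  {'':24s} {'coef':>10s} {'se':>10s} {'t':>8s} {'[0.025':>10s} {'0.975]':>10s}")
        show = self.params.index if top is None else self.params.index[:top]
        for name in show:
            lines.append(
                f"  {name:<24s} {self.params[name]:>10.4f} {self.bse[name]:>10.4f} "
                f"{self.tvalues[name]:>8.2f} {ci.loc[name,'lower']:>10.4f} {ci.loc[name,'upper']:>10.4f}"
            )
        if top is not None and len(self.params) > top:
            lines.append(f"  ... ({len(self.params) - top} more controls)")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# convenience wrappers matching the operation surface


def default_control_columns(panel: pd.DataFrame) -> list[str]:
    """The standard exogenous control set present in a panel frame:
    temperature-bin day counts (minus the reference bin) plus linear and
    quadratic continuous weather terms."""
    tbins = [c for c in temperature_bin_labels() if c in panel.columns and c != REFERENCE_TEMP_BIN]
    cont = [c for c in CONTINUOUS_CONTROLS if c in panel.columns]
    cont_sq = [f"{c}_sq" for c in cont if f"{c}_sq" in panel.columns]
    return tbins + cont + cont_sq


def fit_ols(panel: pd.DataFrame, **spec) -> PanelIVResults:
    return PanelIVModel.from_panel(panel, **spec).fit("ols")


def fit_2sls(panel: pd.DataFrame, **spec) -> PanelIVResults:
    return PanelIVModel.from_panel(panel, **spec).fit("2sls")


def fit_liml(panel: pd.DataFrame, **spec) -> PanelIVResults:
    return PanelIVModel.from_panel(panel, **spec).fit("liml")
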