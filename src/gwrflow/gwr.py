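"""Global OLS and geographically weighted regression (GWR).

The GWR model lets every regression coefficient vary over space:

    y_i = beta_0(u_i, v_i) + sum_k beta_k(u_i, v_i) x_ik + eps_i

and is estimated at each site i by weighted least squares,

    beta_hat(u_i, v_i) = (X' W_i X)^-1 X' W_i y,

where W_i is a diagonal kernel-weight matrix built from distances to site i.
The default kernel is adaptive bisquare: the bandwidth is a nearest-neighbour
count (50 by default), the kernel radius at each site is the distance to the
bandwidth-th nearest neighbour (the site itself counts), and weights decay
monotonically to zero at that radius. Bandwidth selection minimises the
corrected AIC computed from the GWR hat matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: two-sided standard-normal critical values for the 90/95/99% classes
SIGNIFICANCE_THRESHOLDS = {90: 1.6448536269514722, 95: 1.959963984540054, 99: 2.5758293035489004}


@dataclass(frozen=True)
class KernelSpec:
    """Spatial kernel for the local regressions.

    kind: 'adaptive' (bandwidth = nearest-neighbour count, site inclusive)
    or 'fixed' (bandwidth = distance in metres).
    weight_function: 'bisquare' (default) or 'uniform'.
    """

    kind: str = "adaptive"
    bandwidth: float = 50
    weight_function: str = "bisquare"

    def __post_init__(self) -> None:
        if self.kind not in ("adaptive", "fixed"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.weight_function not in ("bisquare", "uniform"):
            raise ValueError(f"unknown weight function {self.weight_function!r}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kind == "adaptive" and int(self.bandwidth) != self.bandwidth:
            raise ValueError("adaptive bandwidth is a neighbour count (integer)")


@dataclass
class GlobalFit:
    """Ordinary least squares fit of the global (spatially constant) model."""

    coefficients: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    r_squared: float
    sigma2: float
    aicc: float
    nobs: int
    fitted: np.ndarray
    residuals: np.ndarray


@dataclass
class GWRSummary:
    """Table-2-style summary: per-coefficient min/max/mean/range plus local-R2 spread."""

    coefficients: pd.DataFrame  # index: coefficient name; columns: min, max, mean, range
    local_r2_min: float
    local_r2_mean: float
    local_r2_max: float
    bandwidth: float
    n_regressions: int


@dataclass
class GWRResults:
    """Local fits: one weighted regression per retained neighbourhood.

    ``local`` is indexed by neighbourhood id with one column block per
    coefficient (``beta_*``, ``se_*``, ``t_*``, ``sig_*``) plus ``local_r2``,
    ``fitted``, ``residual`` and ``leverage`` (the hat-matrix diagonal).
    """

    local: pd.DataFrame
    response: str
    covariates: tuple[str, ...]
    spec: KernelSpec
    tr_S: float
    sigma2: float
    aicc: float
    nobs: int
    coefficient_names: tuple[str, ...] = field(default_factory=tuple)

    def coefficient(self, name: str) -> pd.Series:
        return self.local[f"beta_{name}"]

    def t_value(self, name: str) -> pd.Series:
        return self.local[f"t_{name}"]

    def significance(self, name: str) -> pd.Series:
        return self.local[f"sig_{name}"]


def classify_significance(t: float, reference: str = "normal", dof: float | None = None) -> int:
    """Two-sided significance class of a local t statistic: 0, 90, 95 or 99.

    The default reference distribution is the standard normal; ``reference='t'``
    uses a Student t with ``dof`` effective degrees of freedom instead.
    A non-finite statistic yields class 0 with a warning.
    """
    if not np.isfinite(t):
        warnings.warn("non-finite t statistic classified as not significant", stacklevel=2)
        return 0
    if reference == "normal":
        cuts = SIGNIFICANCE_THRESHOLDS
    elif reference == "t":
        if dof is None or dof <= 0:
            raise ValueError("reference='t' needs positive effective dof")
        from scipy.stats import t as t_dist

        cuts = {lvl: t_dist.ppf(1 - (1 - lvl / 100) / 2, dof) for lvl in (90, 95, 99)}
    else:
        raise ValueError(f"unknown reference distribution {reference!r}")
    a = abs(t)
    if a >= cuts[99]:
        return 99
    if a >= cuts[95]:
        return 95
    if a >= cuts[90]:
        return 90
    return 0


def _design(table: pd.DataFrame, response: str, covariates: Sequence[str]):
    missing = [c for c in [response, *covariates] if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    X = table.loc[:, list(covariates)].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in design or response")
    Xd = np.column_stack([np.ones(len(X)), X])
    return Xd, y


def _rank_check(Xd: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # pivoted QR: columns with tiny R diagonal are the dependent ones
        from scipy.linalg import qr

        _, _, piv = qr(Xd, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])  # trailing pivots are the dependent columns
        all_names = ["intercept", *names]
        offending = [all_names[j] for j in bad]
        raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")


def fit_global_ols(table: pd.DataFrame, response: str, covariates: Sequence[str]) -> GlobalFit:
    """Fit the global model ``y = beta_0 + sum_k beta_k x_k + eps`` by OLS."""
    covariates = list(covariates)
    Xd, y = _design(table, response, covariates)
    n, p = Xd.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations for {p - 1} covariates, got {n}")
    _rank_check(Xd, covariates)
    model = sm.OLS(y, Xd).fit()
    names = ["intercept", *covariates]
    if y.var() == 0.0:
        r2 = 0.0  # degenerate response: define R^2 = 0
    else:
        r2 = float(model.rsquared)
    sigma2 = float(model.ssr / (n - p))
    sigma_hat = np.sqrt(model.ssr / n)
    aicc = _aicc_from(n, sigma_hat, float(p))
    if y.var() == 0.0 or model.ssr == 0.0:
        tvals = np.zeros_like(model.params)  # no residual variance: inference degenerate
    else:
        tvals = model.tvalues
    return GlobalFit(
        coefficients=pd.Series(model.params, index=names),
        std_errors=pd.Series(model.bse, index=names),
        t_values=pd.Series(tvals, index=names),
        r_squared=r2,
        sigma2=sigma2,
        aicc=aicc,
        nobs=n,
        fitted=np.asarray(model.fittedvalues),
        residuals=np.asarray(model.resid),
    )


def kernel_weights(site: int, coords: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel weight of every observation for the local regression at ``site``.

    Adaptive kernels set the radius to the distance of the bandwidth-th
    nearest neighbour (the site itself counts as its own first neighbour);
    fixed kernels use the bandwidth as the radius directly. Bisquare:
    ``w = (1 - (d/r)^2)^2`` for ``d < r``, else 0; uniform: 1 for ``d <= r``.
    """
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords - coords[site]) ** 2).sum(axis=1))
    if spec.kind == "adaptive":
        k = int(spec.bandwidth)
        if k > len(coords):
            raise ValueError(f"adaptive bandwidth {k} exceeds the {len(coords)} available sites")
        r = np.partition(d, k - 1)[k - 1]
        if r == 0.0:
            raise ValueError(
                "kernel radius is zero (duplicate coordinates within the bandwidth); "
                "jitter the coordinates or enlarge the bandwidth"
            )
    else:
        r = float(spec.bandwidth)
    if spec.weight_function == "bisquare":
        w = np.where(d < r, (1.0 - (d / r) ** 2) ** 2, 0.0)
    else:
        w = (d <= r).astype(float)
    return w


def _aicc_from(n: int, sigma_hat: float, tr_S: float) -> float:
    if sigma_hat <= 0:
        sigma_hat = np.finfo(float).tiny
    return float(2 * n * np.log(sigma_hat) + n * np.log(2 * np.pi) + n * (n + tr_S) / (n - 2 - tr_S))


def fit_gwr(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    spec: KernelSpec = KernelSpec(),
    coord_columns: tuple[str, str] = ("u", "v"),
    id_column: str = "id",
    significance_reference: str = "normal",
) -> GWRResults:
    """Fit one kernel-weighted regression per neighbourhood.

    Local standard errors use the sandwich (X'WX)^-1 X'W^2X (X'WX)^-1 scaled
    by the global residual variance RSS/(n - tr S); the local R^2 is the
    kernel-weighted coefficient of determination. A locally constant
    covariate (zero weighted variance inside a kernel) is flagged
    unestimable at that site (NaN) and the run continues.
    """
    covariates = list(covariates)
    Xd, y = _design(table, response, covariates)
    n, p = Xd.shape
    _rank_check(Xd, covariates)
    coords = table.loc[:, list(coord_columns)].to_numpy(dtype=float)
    if spec.kind == "adaptive" and spec.bandwidth < p + 1:
        raise ValueError(f"adaptive bandwidth must be at least k + 2 = {p + 1}")

    names = ["intercept", *covariates]
    betas = np.full((n, p), np.nan)
    var_unscaled = np.full((n, p), np.nan)
    leverage = np.empty(n)
    fitted = np.empty(n)
    local_r2 = np.empty(n)

    for i in range(n):
        w = kernel_weights(i, coords, spec)
        active = w > 0
        Xi, yi, wi = Xd, y, w
        keep = np.ones(p, dtype=bool)
        # columns (beyond the intercept) with no weighted variance are unestimable here
        for j in range(1, p):
            xj = Xd[active, j]
            if np.ptp(xj) == 0.0:
                keep[j] = False
        if not keep.all():
            dropped = [names[j] for j in range(p) if not keep[j]]
            logger.warning("site %d: locally constant covariate(s) %s flagged unestimable", i, dropped)
        Xk = Xi[:, keep]
        XtW = Xk.T * wi
        A = XtW @ Xk
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            logger.warning("site %d: singular local design, all coefficients unestimable", i)
            leverage[i] = 0.0
            fitted[i] = np.nan
            local_r2[i] = np.nan
            continue
        C = Ainv @ XtW  # beta = C y; rows of C give sampling weights
        b = C @ yi
        betas[i, keep] = b
        var_unscaled[i, keep] = np.sum(C**2, axis=1)
        leverage[i] = float(Xk[i] @ C[:, i])
        fitted[i] = float(Xk[i] @ b)
        resid_local = yi - Xk @ b
        ybar_w = np.average(yi, weights=wi)
        tss = float(np.sum(wi * (yi - ybar_w) ** 2))
        rss = float(np.sum(wi * resid_local**2))
        local_r2[i] = 0.0 if tss == 0.0 else float(np.clip(1.0 - rss / tss, 0.0, 1.0))

    residuals = y - fitted
    tr_S = float(np.nansum(leverage))
    rss_total = float(np.nansum(residuals**2))
    dof_eff = n - tr_S
    sigma2 = rss_total / dof_eff if dof_eff > 0 else np.nan
    sigma_hat = np.sqrt(rss_total / n)
    aicc = _aicc_from(n, sigma_hat, tr_S) if tr_S < n - 2 else np.inf

    se = np.sqrt(sigma2 * var_unscaled)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = betas / se
    dof = dof_eff if significance_reference == "t" else None

    data: dict[str, object] = {}
    for j, name in enumerate(names):
        data[f"beta_{name}"] = betas[:, j]
        data[f"se_{name}"] = se[:, j]
        data[f"t_{name}"] = tvals[:, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data[f"sig_{name}"] = [
                classify_significance(t, reference=significance_reference, dof=dof)
                for t in tvals[:, j]
            ]
    data["local_r2"] = local_r2
    data["fitted"] = fitted
    data["residual"] = residuals
    data["leverage"] = leverage
    ids = table[id_column] if id_column in table.columns else pd.RangeIndex(n)
    local = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    return GWRResults(
        local=local,
        response=response,
        covariates=tuple(covariates),
        spec=spec,
        tr_S=tr_S,
        sigma2=float(sigma2),
        aicc=aicc,
        nobs=n,
        coefficient_names=tuple(names),
    )


def select_bandwidth_aicc(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    candidates: Sequence[float],
    kind: str = "adaptive",
    weight_function: str = "bisquare",
    **fit_kwargs,
) -> float:
    """Pick the candidate bandwidth minimising the GWR AICc.

    Candidates whose hat-matrix trace reaches n - 2 (AICc undefined) are
    skipped with a warning; ties break toward the larger (smoother) bandwidth.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate bandwidth list is empty")
    best_bw, best_aicc = None, np.inf
    for bw in sorted(candidates):
        res = fit_gwr(table, response, covariates, KernelSpec(kind, bw, weight_function), **fit_kwargs)
        if not np.isfinite(res.aicc):
            warnings.warn(f"bandwidth {bw}: tr S >= n - 2, AICc undefined; candidate skipped", stacklevel=2)
            continue
        if res.aicc <= best_aicc:  # <= so ties go to the larger bandwidth
            best_bw, best_aicc = bw, res.aicc
    if best_bw is None:
        raise ValueError("no candidate bandwidth yielded a defined AICc")
    return best_bw


def summarize_gwr(results: GWRResults) -> GWRSummary:
    """Per-coefficient min/max/mean/range and the local-R2 spread."""
    if results.local.empty:
        raise ValueError("no local fits to summarize")
    rows = {}
    for name in results.coefficient_names:
        vals = results.local[f"beta_{name}"]
        if vals.isna().all():
            rows[name] = {"min": np.nan, "max": np.nan, "mean": np.nan, "range": np.nan}
            continue
        lo, hi = float(vals.min()), float(vals.max())
        rows[name] = {"min": lo, "max": hi, "mean": float(vals.mean()), "range": hi - lo}
    coef = pd.DataFrame.from_dict(rows, orient="index")[["min", "max", "mean", "range"]]
    r2 = results.local["local_r2"]
    return GWRSummary(
        coefficients=coef,
        local_r2_min=float(r2.min()),
        local_r2_mean=float(r2.mean()),
        local_r2_max=float(r2.max()),
        bandwidth=results.spec.bandwidth,
        n_regressions=len(results.local),
    )


def correlation_diagnostics(
    table: pd.DataFrame, columns: Sequence[str], threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Global Pearson correlations with advisory multicollinearity flags.

    Pairs with |r| above ``threshold`` are flagged (logged) as moderate
    multicollinearity; zero-variance columns yield NaN entries.
    """
    cols = list(columns)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlation diagnostics")
    sub = table.loc[:, cols].astype(float)
    corr = sub.corr()  # pandas leaves NaN for zero-variance columns
    flagged = []
    for a_idx in range(len(cols)):
        for b_idx in range(a_idx + 1, len(cols)):
            r = corr.iloc[a_idx, b_idx]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((cols[a_idx], cols[b_idx], float(r)))
    for a, b, r in flagged:
        logger.info("moderate multicollinearity: %s ~ %s (r = %.3f)", a, b, r)
    return corr, flagged
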