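"""Monthly partitioning of net stem CO2 flux into respiration, photosynthesis, transport.

The procedure, per tree and calendar month:

1. Fit respiration -dFCO2 = R0 exp(b temp) by nonlinear least squares on the
   low-sap-flow subset of dark-chamber data, where the transport term vanishes.
2. Predict R' over the full record from xylem temperature.
3. Transport residual T = dFCO2 + R' (dark flux is -R' + T); negative values
   are kept -- they are physically meaningful (downward gradient episodes).
4. Photosynthesis P = tFCO2 - dFCO2 on daytime rows (the transparent/dark
   chamber difference; the dark chamber suppresses light, everything else is
   assumed equal).
5. Fit the light response P' = Pmax f PPFD / (f PPFD + Pmax) (rectangular
   hyperbola; Pmax is the saturation point, f the quantum yield) and the
   transport model T' = e J (zero-intercept regression, closed form).

All fits report standard errors from the covariance RSE^2 (J^T J)^-1, t = est/SE
against H0: theta = 0, and 95 % confidence intervals on n - p degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (AlignmentError, InsufficientDataError, MonthMissingError,
                     SingularDesignError)

DAYTIME_PPFD = 10.0


@dataclass(frozen=True)
class ParamFit:
    """One fitted model: estimates with covariance-derived inference."""

    model: str                       # respiration | photosynthesis | transport
    names: tuple[str, ...]
    estimates: tuple[float, ...]
    se: tuple[float, ...]
    t: tuple[float, ...]
    p: tuple[float, ...]
    ci_lo: tuple[float, ...]
    ci_hi: tuple[float, ...]
    n: int
    rse: float
    dof: int
    converged: bool = True
    cov: tuple[tuple[float, ...], ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.estimates[self.names.index(name)]

    def se_of(self, name: str) -> float:
        return self.se[self.names.index(name)]

    def ci_of(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return self.ci_lo[i], self.ci_hi[i]


def parameter_inference(estimates: np.ndarray, cov: np.ndarray, n: int,
                        model: str, names: tuple[str, ...], rse: float,
                        converged: bool = True) -> ParamFit:
    """t statistics, two-sided p values and 95 % CIs from a fit covariance."""
    dof = n - len(estimates)
    if dof <= 0:
        raise InsufficientDataError(f"{model}: n={n} leaves no residual degrees of freedom")
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, estimates / se, np.inf * np.sign(estimates))
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    tcrit = stats.t.ppf(0.975, dof)
    return ParamFit(
        model=model, names=tuple(names),
        estimates=tuple(float(v) for v in estimates),
        se=tuple(float(v) for v in se),
        t=tuple(float(v) for v in tstat),
        p=tuple(float(v) for v in pval),
        ci_lo=tuple(float(v - tcrit * s) for v, s in zip(estimates, se)),
        ci_hi=tuple(float(v + tcrit * s) for v, s in zip(estimates, se)),
        n=int(n), rse=float(rse), dof=int(dof), converged=converged,
        cov=tuple(tuple(float(v) for v in row) for row in np.atleast_2d(cov)),
    )


def nls_fit(
    model,
    xdata: np.ndarray,
    ydata: np.ndarray,
    p0: np.ndarray,
    bounds: tuple = (-np.inf, np.inf),
    max_nfev: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Nonlinear least squares with covariance RSE^2 (J^T J)^-1.

    Trust-region reflective minimisation (reduces to Levenberg-Marquardt steps
    in the interior) at tight tolerances so zero-residual problems are solved
    to machine precision.  Returns (estimates, covariance, rse, converged);
    a singular Jacobian at the solution raises :class:`SingularDesignError`,
    hitting the evaluation cap returns ``converged=False``.
    """
    ydata = np.asarray(ydata, dtype=float)
    p0 = np.asarray(p0, dtype=float)

    def residuals(theta):
        return model(xdata, *theta) - ydata

    sol = optimize.least_squares(
        residuals, p0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev)
    converged = sol.status > 0
    jac = sol.jac
    n, p = len(ydata), len(p0)
    if n <= p:
        raise InsufficientDataError(f"nls_fit: n={n} <= p={p}")
    jtj = jac.T @ jac
    if np.linalg.cond(jtj) > 1e12:
        raise SingularDesignError("singular Jacobian: parameters not identifiable")
    rse = float(np.sqrt(2.0 * sol.cost / (n - p)))
    cov = rse ** 2 * np.linalg.inv(jtj)
    return sol.x, cov, rse, converged


# --------------------------------------------------------------------------
# model functions


def respiration_model(temp, r0, b):
    return r0 * np.exp(b * np.asarray(temp, dtype=float))


def light_response_model(ppfd, pmax, f):
    ppfd = np.asarray(ppfd, dtype=float)
    return pmax * f * ppfd / (f * ppfd + pmax)


# --------------------------------------------------------------------------
# fits


def fit_respiration(subset: pd.DataFrame, month: int | None = None,
                    min_n: int = 30) -> ParamFit:
    """Fit the exponential temperature response of dark-chamber respiration.

    ``subset`` must be the low-sap-flow aligned rows (dark-chamber flux in
    ``dfco2``); the response fitted is y = -dFCO2.  Initial values come from a
    log-linear regression ln(y) ~ temp over the rows with y > 0; if none exist,
    a Q10~2 fallback (b0 = 0.07) anchors R0 at the median response.
    """
    rows = subset if month is None else subset.loc[subset.index.month == month]
    y = -rows["dfco2"].to_numpy(dtype=float)
    temp = rows["temp"].to_numpy(dtype=float)
    n = len(y)
    if n < min_n:
        raise InsufficientDataError(
            f"respiration fit month={month}: n={n} < min_n={min_n}")
    if np.ptp(temp) == 0:
        raise SingularDesignError(
            "respiration fit: constant temperature, R0 and b are not separable")

    positive = y > 0
    n_nonpos = int((~positive).sum())
    if positive.sum() >= 3:
        slope, intercept = np.polyfit(temp[positive], np.log(y[positive]), 1)
        p0 = np.array([np.exp(intercept), max(slope, 1e-4)])
    else:
        b0 = 0.07
        p0 = np.array([np.median(y) / np.exp(b0 * temp.mean()), b0])
    if n_nonpos:
        warnings.warn(f"respiration fit: {n_nonpos} nonpositive rows excluded "
                      "from the log-linear initialisation", stacklevel=2)

    est, cov, rse, conv = nls_fit(
        respiration_model, temp, y, p0,
        bounds=(np.array([1e-12, 1e-12]), np.array([np.inf, np.inf])))
    return parameter_inference(est, cov, n, "respiration", ("r0", "b"), rse, conv)


def predict_respiration(params: ParamFit, temp: pd.Series) -> pd.Series:
    """R' = R0 exp(b temp) over an arbitrary temperature series."""
    out = pd.Series(respiration_model(temp.to_numpy(dtype=float),
                                      params["r0"], params["b"]),
                    index=temp.index, name="r_prime")
    return out


def compute_transport(dfco2: pd.Series, r_prime: pd.Series) -> pd.Series:
    """Transport residual T = dFCO2 + R' (dark flux is -R' + T).

    Negative values are retained: they indicate sap arriving depleted in CO2
    relative to the chamber section (common in morning hours).
    """
    if not dfco2.index.equals(r_prime.index):
        raise AlignmentError("dark flux and predicted respiration are misaligned")
    t = dfco2 + r_prime
    t.name = "t_resid"
    return t


def compute_photosynthesis(tfco2: pd.Series, dfco2: pd.Series,
                           day_mask: pd.Series) -> pd.Series:
    """Chamber-difference photosynthesis P = tFCO2 - dFCO2 on daytime rows.

    Night rows are NaN (excluded from light-response fitting).  Negative
    daytime values are retained; their count is a useful diagnostic of noise
    and chamber mismatch late in the season.
    """
    if not tfco2.index.equals(dfco2.index):
        raise AlignmentError("chamber series are misaligned")
    day = day_mask.reindex(tfco2.index, fill_value=False).to_numpy(dtype=bool)
    if not day.any():
        raise InsufficientDataError("no daytime rows: cannot compute photosynthesis")
    p = (tfco2 - dfco2).where(day)
    p.name = "p_meas"
    return p


def fit_photosynthesis(p: pd.Series, ppfd: pd.Series, month: int | None = None,
                       min_n: int = 30) -> ParamFit:
    """Fit the rectangular-hyperbola light response to chamber-difference P.

    Uses daytime rows (PPFD > 0, P defined).  Initialisation: Pmax0 = 95th
    percentile of P (floored at a small positive value), f0 = slope of an
    origin-constrained OLS over the lowest PPFD quartile.  Non-convergence is
    flagged on the returned fit, not raised.
    """
    if month is not None:
        sel = p.index.month == month
        p, ppfd = p.loc[sel], ppfd.loc[sel]
    ok = p.notna() & (ppfd > 0)
    y = p.loc[ok].to_numpy(dtype=float)
    x = ppfd.loc[ok].to_numpy(dtype=float)
    n = len(y)
    if n < min_n:
        raise InsufficientDataError(f"light-response fit month={month}: n={n} < {min_n}")

    pmax0 = max(float(np.percentile(y, 95)), 1e-3)
    low = x <= np.percentile(x, 25)
    sxx = float(np.sum(x[low] ** 2))
    f0 = float(np.sum(x[low] * y[low]) / sxx) if sxx > 0 else 1e-3
    f0 = min(max(f0, 1e-5), 0.5)

    est, cov, rse, conv = nls_fit(
        light_response_model, x, y, np.array([pmax0, f0]),
        bounds=(np.array([1e-9, 1e-9]), np.array([np.inf, np.inf])))
    return parameter_inference(est, cov, n, "photosynthesis", ("pmax", "f"),
                               rse, conv)


def fit_transport(t: pd.Series, j: pd.Series, month: int | None = None,
                  min_n: int = 30, resp_fit: ParamFit | None = None,
                  temp: pd.Series | None = None) -> ParamFit:
    """Zero-intercept regression of the transport residual on sap flux density.

    Closed form: e = sum(T J) / sum(J^2); the residual-variance term of the
    standard error is RSE / sqrt(sum J^2) with RSE^2 = sum(T - e J)^2 / (n - 1).
    The sign of e is unconstrained.

    Because T is a *derived* response (T = dFCO2 + R' with R' predicted from a
    fitted respiration model), the respiration-parameter error is shared across
    all rows and is not captured by the residual variance.  When ``resp_fit``
    and the matching ``temp`` series are supplied, the delta-method propagation
    g Cov(R0, b) g^T with g = sum_i J_i * dR'/d(R0, b)(temp_i) / sum J^2 is
    added to Var(e); without them the plain closed form is returned.
    """
    if month is not None:
        sel = t.index.month == month
        t, j = t.loc[sel], j.loc[sel]
        if temp is not None:
            temp = temp.loc[temp.index.month == month]
    ok = t.notna() & j.notna()
    y = t.loc[ok].to_numpy(dtype=float)
    x = j.loc[ok].to_numpy(dtype=float)
    n = len(y)
    if n < min_n:
        raise InsufficientDataError(f"transport fit month={month}: n={n} < {min_n}")
    sxx = float(np.sum(x ** 2))
    if sxx == 0:
        raise SingularDesignError("transport fit: all sap-flux values are zero")
    e = float(np.sum(x * y) / sxx)
    resid = y - e * x
    rse = float(np.sqrt(np.sum(resid ** 2) / (n - 1)))
    var_e = rse ** 2 / sxx
    if resp_fit is not None and temp is not None:
        tv = temp.loc[ok.index[ok]].to_numpy(dtype=float)
        r0, b = resp_fit["r0"], resp_fit["b"]
        grad = np.array([
            float(np.sum(x * np.exp(b * tv))) / sxx,
            float(np.sum(x * r0 * tv * np.exp(b * tv))) / sxx,
        ])
        var_e += float(grad @ np.asarray(resp_fit.cov) @ grad)
    cov = np.array([[var_e]])
    return parameter_inference(np.array([e]), cov, n, "transport", ("e",), rse)


# --------------------------------------------------------------------------
# per-month orchestration


@dataclass(frozen=True)
class MonthlyParameterSet:
    """Fitted respiration/light/transport parameters for one tree's season."""

    tree: str
    respiration: dict[int, ParamFit]
    photosynthesis: dict[int, ParamFit]
    transport: dict[int, ParamFit]

    def months(self) -> list[int]:
        return sorted(self.respiration)

    def fit_for(self, model: str, month: int) -> ParamFit:
        table = getattr(self, model)
        if month not in table:
            raise MonthMissingError(f"no {model} parameters for month {month}")
        return table[month]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (tree, month, model, parameter, estimate, se, t, p, ci, n, rse)."""
        rows = []
        for model in ("respiration", "photosynthesis", "transport"):
            for month, fit in sorted(getattr(self, model).items()):
                for i, name in enumerate(fit.names):
                    rows.append({
                        "tree": self.tree, "month": month, "model": model,
                        "parameter": name, "estimate": fit.estimates[i],
                        "se": fit.se[i], "t": fit.t[i], "p": fit.p[i],
                        "ci_lo": fit.ci_lo[i], "ci_hi": fit.ci_hi[i],
                        "n": fit.n, "rse": fit.rse, "converged": fit.converged,
                    })
        return pd.DataFrame(rows)


def fit_season(
    table: pd.DataFrame,
    low_flow: pd.DataFrame,
    tree: str = "A",
    min_n: int = 30,
    ppfd_day_threshold: float = DAYTIME_PPFD,
) -> MonthlyParameterSet:
    """Run the monthly partitioning fits over a whole season.

    ``table`` is the full aligned table, ``low_flow`` its low-sap-flow subset
    (respiration conditioning).  Returns per-month parameter fits for all three
    models.
    """
    months = sorted(set(table.index.month))
    resp: dict[int, ParamFit] = {}
    photo: dict[int, ParamFit] = {}
    trans: dict[int, ParamFit] = {}
    day_mask = table["ppfd"] > ppfd_day_threshold

    for month in months:
        resp[month] = fit_respiration(low_flow, month=month, min_n=min_n)

    r_prime = predict_with_monthly(resp, table["temp"])
    t_resid = compute_transport(table["dfco2"], r_prime)
    p_meas = compute_photosynthesis(table["tfco2"], table["dfco2"], day_mask)

    for month in months:
        photo[month] = fit_photosynthesis(p_meas, table["ppfd"], month=month,
                                          min_n=min_n)
        trans[month] = fit_transport(t_resid, table["sapflux"], month=month,
                                     min_n=min_n, resp_fit=resp[month],
                                     temp=table["temp"])
    return MonthlyParameterSet(tree=tree, respiration=resp,
                               photosynthesis=photo, transport=trans)


def predict_with_monthly(fits: dict[int, ParamFit], temp: pd.Series) -> pd.Series:
    """R' from month-specific parameters over a temperature series."""
    months = temp.index.month
    out = np.empty(len(temp))
    for month in sorted(set(months)):
        if month not in fits:
            raise MonthMissingError(f"no respiration parameters for month {month}")
        sel = months == month
        fit = fits[month]
        out[sel] = respiration_model(temp.to_numpy(dtype=float)[sel],
                                     fit["r0"], fit["b"])
    return pd.Series(out, index=temp.index, name="r_prime")


def partition_series(
    table: pd.DataFrame,
    params: MonthlyParameterSet,
    ppfd_day_threshold: float = DAYTIME_PPFD,
) -> pd.DataFrame:
    """Per-timestamp component series R', T, P plus the model predictions P', T'.

    By construction -R' + P + T = tFCO2 exactly on every row where P is defined
    (P = tFCO2 - dFCO2 and T = dFCO2 + R' telescope).  ``p_all`` extends the
    chamber difference over night rows (pure noise around zero there) so that
    monthly-mean budgets close exactly; ``p_meas`` is the daytime-only series
    used for fitting.
    """
    months = table.index.month
    r_prime = predict_with_monthly(params.respiration, table["temp"])
    t_resid = compute_transport(table["dfco2"], r_prime)
    day_mask = table["ppfd"] > ppfd_day_threshold
    p_meas = compute_photosynthesis(table["tfco2"], table["dfco2"], day_mask)

    p_model = np.empty(len(table))
    t_model = np.empty(len(table))
    ppfd = table["ppfd"].to_numpy(dtype=float)
    sap = table["sapflux"].to_numpy(dtype=float)
    for month in sorted(set(months)):
        sel = months == month
        pf = params.fit_for("photosynthesis", month)
        tf = params.fit_for("transport", month)
        p_model[sel] = light_response_model(ppfd[sel], pf["pmax"], pf["f"])
        t_model[sel] = tf["e"] * sap[sel]

    out = pd.DataFrame({
        "dfco2": table["dfco2"],
        "tfco2": table["tfco2"],
        "r_prime": r_prime,
        "t_resid": t_resid,
        "p_meas": p_meas,
        "p_all": table["tfco2"] - table["dfco2"],
        "p_model": p_model,
        "t_model": t_model,
        "temp": table["temp"],
        "ppfd": table["ppfd"],
        "sapflux": table["sapflux"],
        "tree": table["tree"],
    }, index=table.index)
    out.index.name = "timestamp"
    return out
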