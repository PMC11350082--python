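"""Validation and reporting: holdout reconstruction, diurnal means, contributions, recovery.

The partitioning is validated the way the field campaign did: split the aligned
table 8:2, fit the monthly parameters on the training part, sum the three
modelled components -R' + P' + T' on the held-out part and regress the measured
transparent-chamber flux on that sum.  Reporting covers hourly diurnal courses
per month and the two normalisations of monthly contribution fractions; against
synthetic truth, a recovery report scores bias, relative error and confidence-
interval coverage of every parameter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError, MonthMissingError
from .partition import MonthlyParameterSet, fit_season, partition_series
from .synthetic import SimTruth

#: maps generator truth fields to (model, parameter) of the fitted set
TRUTH_TO_FIT = {
    "r0": ("respiration", "r0"),
    "b": ("respiration", "b"),
    "pmax": ("photosynthesis", "pmax"),
    "f": ("photosynthesis", "f"),
    "e": ("transport", "e"),
}


def train_test_split(
    table: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    stratify_by_month: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random partition of the aligned table into train/test rows.

    Train size is ceil(ratio * n) (per month when stratified, so every month
    appears in both sets); the split is a true partition and reproducible per
    seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigError(f"split ratio must be in (0, 1), got {ratio}")
    if len(table) < 10:
        raise InsufficientDataError(f"n={len(table)} < 10: refusing to split")
    rng = np.random.default_rng(seed)
    n = len(table)
    train_mask = np.zeros(n, dtype=bool)
    if stratify_by_month:
        months = table.index.month.to_numpy()
        for month in np.unique(months):
            idx = np.flatnonzero(months == month)
            k = int(np.ceil(ratio * len(idx)))
            train_mask[rng.choice(idx, size=k, replace=False)] = True
    else:
        k = int(np.ceil(ratio * n))
        train_mask[rng.choice(n, size=k, replace=False)] = True
    return table.loc[train_mask], table.loc[~train_mask]


def validate_reconstruction(
    test: pd.DataFrame,
    params: MonthlyParameterSet,
    ppfd_day_threshold: float = 10.0,
) -> pd.DataFrame:
    """Regress measured tFCO2 on the summed modelled components on held-out rows.

    Predictions are -R' + P' + T' from parameters fitted on training data only.
    Returns one row per month plus a pooled row with slope, intercept, R^2
    (squared Pearson correlation, floored at 0 with a flag) and RSE.
    """
    comp = partition_series(test, params, ppfd_day_threshold)
    predicted = (-comp["r_prime"] + comp["p_model"] + comp["t_model"]).to_numpy()
    measured = comp["tfco2"].to_numpy(dtype=float)
    months = comp.index.month.to_numpy()

    def regress(sel: np.ndarray, label) -> dict | None:
        x, y = predicted[sel], measured[sel]
        if len(x) < 2:
            warnings.warn(f"validation: month {label} has <2 test rows; skipped",
                          stacklevel=3)
            return None
        if np.ptp(x) == 0:
            slope, intercept, r = np.nan, np.nan, np.nan
        else:
            res = stats.linregress(x, y)
            slope, intercept, r = res.slope, res.intercept, res.rvalue
        resid = y - (slope * x + intercept)
        rsq = r ** 2 if np.isfinite(r) else np.nan
        floored = bool(np.isfinite(rsq) and rsq < 0)
        return {
            "month": label, "slope": slope, "intercept": intercept,
            "r2": max(rsq, 0.0) if np.isfinite(rsq) else np.nan,
            "r2_floored": floored,
            "rse": float(np.sqrt(np.nansum(resid ** 2) / max(len(x) - 2, 1))),
            "n_test": int(len(x)),
        }

    rows = []
    for month in sorted(np.unique(months)):
        row = regress(months == month, int(month))
        if row:
            rows.append(row)
    pooled = regress(np.ones(len(comp), dtype=bool), "pooled")
    if pooled:
        rows.append(pooled)
    return pd.DataFrame(rows)


def diurnal_means(components: pd.DataFrame, columns: tuple[str, ...] = (
        "r_prime", "p_meas", "p_model", "t_resid", "t_model", "tfco2", "dfco2")
        ) -> pd.DataFrame:
    """Hourly means of each component per month (hour-of-day 0-23 x month).

    Empty hour cells are missing values, never zero; ``n`` counts the rows in
    each cell, and cell counts sum to the series length.
    """
    frame = components.copy()
    frame["hour"] = frame.index.hour
    frame["month"] = frame.index.month
    grouped = frame.groupby(["month", "hour"])
    out = grouped[list(columns)].mean()
    out["n"] = grouped.size()
    return out.reset_index()


def monthly_contributions(components: pd.DataFrame,
                          per_row: bool = False) -> pd.DataFrame:
    """Monthly contribution fractions of -R', P, T in both normalisations.

    Ratio form: each component's monthly mean divided by the monthly mean net
    flux, with -R'/FCO2 + P/FCO2 + T/FCO2 = 1 exactly (FCO2 < 0, so the
    respiration ratio exceeds 1 and the others are typically negative).  Share
    form: |R'|, |P|, |T| as percentages of their sum.  Means-of-components is
    the default; ``per_row=True`` averages per-row ratios instead (diagnostic;
    unstable where FCO2 crosses zero).

    P here is the chamber difference extended over night rows so the budget
    closes identically on any input.
    """
    frame = components.copy()
    frame["month"] = frame.index.month
    rows = []
    for month, grp in frame.groupby("month"):
        r = float(grp["r_prime"].mean())
        p = float(grp["p_all"].mean())
        t = float(grp["t_resid"].mean())
        fco2 = float(grp["tfco2"].mean())
        row = {"month": int(month), "mean_r_prime": r, "mean_p": p, "mean_t": t,
               "mean_fco2": fco2}
        if per_row:
            f_rows = grp["tfco2"].to_numpy(dtype=float)
            ok = f_rows != 0
            row["ratio_r"] = float(np.mean(-grp["r_prime"].to_numpy()[ok] / f_rows[ok]))
            row["ratio_p"] = float(np.mean(grp["p_all"].to_numpy()[ok] / f_rows[ok]))
            row["ratio_t"] = float(np.mean(grp["t_resid"].to_numpy()[ok] / f_rows[ok]))
            row["ratio_defined"] = bool(ok.all())
        elif fco2 == 0:
            row.update(ratio_r=np.nan, ratio_p=np.nan, ratio_t=np.nan,
                       ratio_defined=False)
        else:
            row.update(ratio_r=-r / fco2, ratio_p=p / fco2, ratio_t=t / fco2,
                       ratio_defined=True)
        total = abs(r) + abs(p) + abs(t)
        if total == 0:
            row.update(share_r_pct=np.nan, share_p_pct=np.nan, share_t_pct=np.nan)
        else:
            row.update(share_r_pct=100.0 * abs(r) / total,
                       share_p_pct=100.0 * abs(p) / total,
                       share_t_pct=100.0 * abs(t) / total)
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_report(params: MonthlyParameterSet, truth: SimTruth) -> pd.DataFrame:
    """Score fitted parameters against generator truth: bias, relative error, CI hit.

    One row per parameter x month with the estimate, truth, bias
    (estimate - truth), relative error and whether the truth lies inside the
    fitted 95 % confidence interval.
    """
    fit_months = set(params.months())
    truth_months = set(truth.months())
    if not fit_months <= truth_months:
        raise MonthMissingError(
            f"fitted months {sorted(fit_months - truth_months)} missing from truth")
    rows = []
    for month in sorted(fit_months):
        for tname, (model, pname) in TRUTH_TO_FIT.items():
            fit = params.fit_for(model, month)
            est = fit[pname]
            tru = truth.param(tname, month)
            lo, hi = fit.ci_of(pname)
            rows.append({
                "month": month, "parameter": tname, "estimate": est,
                "truth": tru, "bias": est - tru,
                "rel_error": (est - tru) / tru if tru != 0 else np.nan,
                "se": fit.se_of(pname),
                "ci_lo": lo, "ci_hi": hi,
                "in_ci": bool(lo <= tru <= hi),
            })
    return pd.DataFrame(rows)


def coverage_study(
    drivers: pd.DataFrame,
    truth: SimTruth,
    n_seeds: int = 100,
    noise_sd: float = 0.1,
    base_seed: int = 0,
    min_n: int = 30,
    sapflow_threshold: float = 5.0,
    ppfd_day_threshold: float = 10.0,
) -> pd.DataFrame:
    """Replicate the noisy pipeline over many seeds and pool recovery scores.

    For each replicate: regenerate noisy chamber fluxes on the shared drivers,
    rebuild the aligned table, refit all monthly parameters and score them
    against truth.  Returns the concatenated recovery rows with a ``seed``
    column; aggregate coverage is the mean of ``in_ci`` per parameter.
    """
    from .qc import align, select_low_sapflow
    from .synthetic import generate_true_fluxes

    reports = []
    for i in range(n_seeds):
        seed = (base_seed + 1000003 * i) % (2 ** 31 - 1)
        truth_i = truth.replace(noise_sd=noise_sd, rng_seed=seed)
        dark, transparent, _ = generate_true_fluxes(drivers, truth_i)
        table, _ = align(dark, transparent, drivers)
        low, _ = select_low_sapflow(table, threshold=sapflow_threshold)
        fits = fit_season(table, low, min_n=min_n,
                          ppfd_day_threshold=ppfd_day_threshold)
        rep = recovery_report(fits, truth_i)
        rep["seed"] = seed
        reports.append(rep)
    return pd.concat(reports, ignore_index=True)
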