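"""Quality control and table assembly: flag-then-drop data cleaning.

Filters never delete or mutate flux values; each appends a named flag so the
accounting ("removals constituted X % of available data") is auditable and the
result is independent of the order the filters ran in.  Rows carrying any
drop-flag are excluded only when the aligned dark/transparent table is
assembled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError

TECH_FAIL = "TECH_FAIL"
OUTLIER_3SD = "OUTLIER_3SD"
RH_HIGH = "RH_HIGH"
RH_MISSING = "RH_MISSING"

#: Flags that exclude a record at assembly time.
DROP_FLAGS = frozenset({TECH_FAIL, OUTLIER_3SD, RH_HIGH, RH_MISSING, "NOISY_FIT"})


def add_flag(records: pd.DataFrame, mask, flag: str) -> pd.DataFrame:
    """Append ``flag`` to the flag set of every row where ``mask`` is true."""
    records = records.copy()
    mask = np.asarray(mask, dtype=bool)
    current = records["flags"].to_numpy(dtype=object)
    updated = [
        f if (not m or flag in f.split(";")) else (f"{f};{flag}" if f else flag)
        for f, m in zip(current, mask)
    ]
    records["flags"] = updated
    return records


def has_flag(records: pd.DataFrame, flag: str) -> pd.Series:
    return records["flags"].str.split(";").map(lambda fl: flag in fl)


def is_dropped(records: pd.DataFrame, drop_flags=DROP_FLAGS) -> pd.Series:
    """True for rows carrying at least one drop-flag."""
    return records["flags"].str.split(";").map(
        lambda fl: any(f in drop_flags for f in fl if f))


def flag_counts(records: pd.DataFrame) -> dict[str, int]:
    counts: dict[str, int] = {}
    for flags in records["flags"]:
        for f in flags.split(";"):
            if f:
                counts[f] = counts.get(f, 0) + 1
    return counts


def technical_qc(records: pd.DataFrame, limits: dict[str, tuple[float, float]]
                 ) -> pd.DataFrame:
    """Flag records whose instrument diagnostics leave their accepted range.

    ``limits`` maps a column name (e.g. ``flow``, ``pressure``,
    ``closure_rmse_ppm``) to an inclusive (lo, hi) range; columns absent from
    the table are ignored.  Out-of-range records gain ``TECH_FAIL``.
    """
    mask = np.zeros(len(records), dtype=bool)
    for column, (lo, hi) in limits.items():
        if column not in records.columns:
            continue
        values = records[column].to_numpy(dtype=float)
        mask |= (values < lo) | (values > hi) | ~np.isfinite(values)
    return add_flag(records, mask, TECH_FAIL)


def filter_outliers_3sd(
    records: pd.DataFrame,
    sd_mult: float = 3.0,
    group_cols: tuple[str, ...] = ("tree", "chamber"),
    min_group: int = 10,
) -> pd.DataFrame:
    """Flag fluxes more than ``sd_mult`` standard deviations from their group mean.

    Mean and SD are computed in a single pass over each tree x chamber group's
    currently unflagged records (the whole-season dataset, not re-estimated
    after removals).  Groups with fewer than ``min_group`` unflagged records are
    skipped with a warning.
    """
    out = records
    mask = np.zeros(len(records), dtype=bool)
    dropped = is_dropped(records).to_numpy()
    groups = records.groupby(list(group_cols), sort=False).indices
    for key, idx in groups.items():
        idx = np.asarray(idx)
        clean = idx[~dropped[idx]]
        if len(clean) < min_group:
            warnings.warn(f"group {key}: only {len(clean)} unflagged records; "
                          "3-SD filter skipped", stacklevel=2)
            continue
        values = records["fco2"].to_numpy(dtype=float)
        mu = values[clean].mean()
        sd = values[clean].std(ddof=1)
        if sd == 0:
            continue
        mask[idx] = np.abs(values[idx] - mu) > sd_mult * sd
    mask &= ~dropped  # already-dropped rows keep their original flags only
    return add_flag(out, mask, OUTLIER_3SD)


def window_mean_rh(records: pd.DataFrame, drivers: pd.DataFrame,
                   window_s: float = 100.0) -> pd.Series:
    """Mean driver RH over each record's closure window [t, t + window]."""
    rh = drivers["rh"]
    if len(drivers) > 1:
        step = (drivers.index[1] - drivers.index[0]).total_seconds()
    else:
        step = window_s
    if step <= window_s:
        # drivers resolve the window: average all samples inside it
        means = []
        for stamp in records.index:
            sel = rh.loc[stamp: stamp + pd.Timedelta(seconds=window_s)]
            means.append(sel.mean() if len(sel) else np.nan)
        return pd.Series(means, index=records.index)
    # coarser drivers: nearest sample represents the window
    return rh.reindex(records.index, method="nearest",
                      tolerance=pd.Timedelta(seconds=step))


def filter_high_rh(
    records: pd.DataFrame,
    drivers: pd.DataFrame,
    threshold_pct: float = 85.0,
    window_s: float = 100.0,
) -> pd.DataFrame:
    """Flag records measured while relative humidity exceeded the condensation limit.

    Window-mean RH above ``threshold_pct`` gains ``RH_HIGH``; records whose RH
    cannot be resolved gain ``RH_MISSING`` (treated as removed downstream).
    """
    rh = window_mean_rh(records, drivers, window_s)
    missing = rh.isna().to_numpy()
    high = (rh.to_numpy() > threshold_pct) & ~missing
    records = add_flag(records, high, RH_HIGH)
    return add_flag(records, missing, RH_MISSING)


def align(
    dark: pd.DataFrame,
    transparent: pd.DataFrame,
    drivers: pd.DataFrame,
    drop_flags=DROP_FLAGS,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the aligned analysis table, dropping flagged rows.

    Inner join of the two chambers on timestamp (per tree), with drivers
    attached at each closure timestamp; any row whose dark or transparent
    record carries a drop-flag is excluded.  Returns (table, report) where the
    report tallies inputs, flag-based exclusions and output rows.

    Columns: dfco2, tfco2, temp, ppfd, rh, sapflux, month, tree.
    """
    shared = dark.index.intersection(transparent.index)
    if len(shared) == 0:
        raise AlignmentError("dark and transparent chambers share no timestamps")
    d = dark.loc[shared]
    t = transparent.loc[shared]
    keep = ~(is_dropped(d, drop_flags).to_numpy()
             | is_dropped(t, drop_flags).to_numpy())
    table = pd.DataFrame({
        "dfco2": d["fco2"].to_numpy(dtype=float),
        "tfco2": t["fco2"].to_numpy(dtype=float),
        "tree": d["tree"].to_numpy(),
    }, index=shared)
    for col in ("temp", "ppfd", "rh", "sapflux"):
        table[col] = drivers[col].reindex(shared, method="nearest").to_numpy()
    table = table.loc[keep]
    table["month"] = table.index.month
    table.index.name = "timestamp"
    report = {
        "n_dark_in": int(len(dark)),
        "n_transparent_in": int(len(transparent)),
        "n_shared_timestamps": int(len(shared)),
        "n_dropped_flagged": int((~keep).sum()),
        "n_out": int(len(table)),
        "dark_flag_counts": flag_counts(dark),
        "transparent_flag_counts": flag_counts(transparent),
    }
    return table, report


def select_low_sapflow(
    table: pd.DataFrame,
    threshold: float = 5.0,
    mode: str = "fixed",
    fraction: float = 0.05,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Rows with sap flux below the near-zero-flow threshold (respiration subset).

    ``fixed`` uses ``threshold`` directly (default 5 g m^-2 h^-1);
    ``fraction_of_max`` uses ``fraction`` x the seasonal maximum of J, which the
    campaign's threshold corresponded to.  Returns (subset, n retained per
    month); months with no retained rows are warned about by name.
    """
    if mode == "fraction_of_max":
        threshold = fraction * float(table["sapflux"].max())
    subset = table.loc[table["sapflux"] < threshold]
    per_month = {int(m): int(n) for m, n in
                 subset.groupby(subset.index.month).size().items()}
    for month in sorted(set(table.index.month)):
        if per_month.get(int(month), 0) == 0:
            warnings.warn(f"month {int(month)}: no low-sap-flow rows below "
                          f"{threshold:.3g}", stacklevel=2)
    return subset, per_month
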