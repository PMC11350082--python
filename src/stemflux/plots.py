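"""Optional matplotlib views of the standard artifacts.

Figures mirror the tabular outputs: seasonal parameter courses with 95 % CI
bands, diurnal component panels per month, and stacked monthly contribution
shares.  All functions take the corresponding DataFrame and return the Figure.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_PARAM_ORDER = ["r0", "b", "pmax", "f", "e"]
_PARAM_LABEL = {
    "r0": "$R_0$ (umol m$^{-2}$ s$^{-1}$)",
    "b": "$b$ (degC$^{-1}$)",
    "pmax": "$P_{max}$ (umol m$^{-2}$ s$^{-1}$)",
    "f": "$f$ (umol CO$_2$ umol$^{-1}$)",
    "e": "$e$ (per J-unit)",
}


def plot_parameter_courses(params_frame: pd.DataFrame):
    """Seasonal course of each fitted parameter with its 95 % CI band."""
    fig, axes = plt.subplots(1, 5, figsize=(16, 3), constrained_layout=True)
    for ax, name in zip(axes, _PARAM_ORDER):
        sub = params_frame.loc[params_frame["parameter"] == name].sort_values("month")
        ax.fill_between(sub["month"], sub["ci_lo"], sub["ci_hi"], alpha=0.3)
        ax.plot(sub["month"], sub["estimate"], "o-")
        ax.set_xlabel("month")
        ax.set_title(_PARAM_LABEL[name], fontsize=9)
    return fig


def plot_diurnal_panels(diurnal: pd.DataFrame):
    """Hourly mean components per month: -R', P, T and the chamber fluxes."""
    months = sorted(diurnal["month"].unique())
    fig, axes = plt.subplots(1, len(months), figsize=(4 * len(months), 3),
                             sharey=True, constrained_layout=True)
    axes = np.atleast_1d(axes)
    for ax, month in zip(axes, months):
        sub = diurnal.loc[diurnal["month"] == month]
        ax.plot(sub["hour"], -sub["r_prime"], label="$-R'$")
        ax.plot(sub["hour"], sub["p_meas"], label="$P$")
        ax.plot(sub["hour"], sub["t_resid"], label="$T$")
        ax.plot(sub["hour"], sub["tfco2"], "k--", label="tFCO$_2$")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"month {month}")
        ax.set_xlabel("hour")
    axes[0].set_ylabel("flux (umol m$^{-2}$ s$^{-1}$)")
    axes[-1].legend(fontsize=8)
    return fig


def plot_contribution_stacks(contrib: pd.DataFrame):
    """Stacked |R'|, |P|, |T| shares (100 % normalisation) per month."""
    fig, ax = plt.subplots(figsize=(5, 3), constrained_layout=True)
    months = contrib["month"]
    bottom = np.zeros(len(contrib))
    for col, label in [("share_r_pct", "$|R'|$"), ("share_p_pct", "$|P|$"),
                       ("share_t_pct", "$|T|$")]:
        ax.bar(months, contrib[col], bottom=bottom, label=label)
        bottom += contrib[col].to_numpy()
    ax.set_xlabel("month")
    ax.set_ylabel("share of $|R'|+|P|+|T|$ (%)")
    ax.legend(fontsize=8)
    return fig
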