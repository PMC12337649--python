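"""Optional figure panels mirroring the analysis surfaces (matplotlib)."""

from __future__ import annotations

import numpy as np

from .models import DilutionResults, RetentionResults, TidalTrendResults


def plot_dilution(results: DilutionResults, ax=None, nutrient="N"):
    """Concentration vs salinity with the conservative dilution line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = results.classifications.query("nutrient == @nutrient")
    for label, marker in (("above", "^"), ("on", "o"), ("below", "v")):
        part = sub[sub["label"] == label]
        ax.scatter(part["salinity"], part["concentration"], marker=marker,
                   label=label)
    line = results.lines[nutrient]
    s = np.linspace(0, max(line.reference_salinity, sub["salinity"].max()), 50)
    ax.plot(s, line.reference_concentration * s / line.reference_salinity,
            "k--", label="dilution line")
    ax.set_xlabel("bulk salinity")
    ax.set_ylabel(f"{nutrient} (umol/L)")
    ax.legend()
    return ax


def plot_retention(profiles, bulk, results: RetentionResults, nutrient="N", ax=None):
    """Bulk vs bottom-ice IC concentration with the SMA line and 1:k guides."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    joint = profiles.merge(bulk, on=["date", "site"])
    col = "no3no2_umol_l" if nutrient == "N" else "sioh4_umol_l"
    x = joint[f"bottom_ice_ic_{nutrient}"]
    ax.scatter(x, joint[col], s=12)
    res = results.sma[nutrient]
    if res is not None:
        grid = np.linspace(0, x.max(), 20)
        ax.plot(grid, res.slope * grid + res.intercept, "r-",
                label=f"SMA slope {res.slope:.2f}")
    for k in (1, 11):
        ax.plot([0, x.max()], [0, x.max() / k], "k--", lw=0.6, label=f"1:{k}")
    ax.set_xlabel(f"bottom-ice IC-{nutrient} (umol/L)")
    ax.set_ylabel(f"bulk {nutrient} (umol/L)")
    ax.legend()
    return ax


def plot_timeseries(results: TidalTrendResults, axes=None):
    """Currents, chl a, IC-N^B, IC-Si^B and ln(N:Si) panels vs time."""
    import matplotlib.pyplot as plt

    s = results.series
    if axes is None:
        _, axes = plt.subplots(5, 1, sharex=True, figsize=(6, 10))
    t = s["elapsed_days"]
    panels = [
        ("daily_max_current", "max current (m/s)"),
        ("chla_areal_mg_m2", "chl a (mg/m^2)"),
        ("ic_chl_N", "IC-N$^B$ (umol/mg)"),
        ("ic_chl_Si", "IC-Si$^B$ (umol/mg)"),
    ]
    for ax, (col, label) in zip(axes, panels):
        ax.plot(t, s[col], "o-")
        ax.set_ylabel(label)
    axes[4].plot(t, np.log(s["n_si"]), "o-")
    axes[4].set_ylabel("ln(IC N:Si)")
    axes[4].set_xlabel("days since campaign start")
    return axes
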