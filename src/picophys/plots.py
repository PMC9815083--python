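"""Plotting helpers for fit results and ensemble envelopes."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_monod_fit(results, ax=None):
    """Growth points and the three fitted Monod curves on a log-S axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    points = results.model.points
    s = np.array([p.glucose_g_L for p in points])
    mu = np.array([p.mu_gm for p in points])
    sd = np.array([p.mu_sd for p in points])
    ax.errorbar(s, mu, yerr=sd, fmt="o", color="k", capsize=3,
                label="geometric-mean rates")
    grid = np.logspace(np.log10(s.min()) - 0.5, np.log10(s.max()) + 0.5, 200)
    styles = {"mean": "k-", "upper_boundary": "r--", "lower_boundary": "b--"}
    for p in results.params:
        mu_fit = p.mu_max * grid / (p.ks + grid)
        ax.plot(grid, mu_fit, styles[p.variant],
                label=f"{p.variant} (KS={p.ks_ug_L:.0f} ug/L)")
    ax.set_xscale("log")
    ax.set_xlabel("glucose [g/L]")
    ax.set_ylabel("specific growth rate [1/h]")
    ax.legend(fontsize=8)
    return ax


def plot_phenotype_space(envelopes: pd.DataFrame, var: str = "x", ax=None):
    """Quantile envelope band of one state variable over the ensemble."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = envelopes["t_h"]
    ax.fill_between(t, envelopes[f"{var}_min"], envelopes[f"{var}_max"],
                    alpha=0.2, label="min-max")
    ax.fill_between(t, envelopes[f"{var}_q05"], envelopes[f"{var}_q95"],
                    alpha=0.4, label="5-95%")
    ax.plot(t, envelopes[f"{var}_median"], "k-", label="median")
    labels = {"x": "biomass X [g/L]", "s": "substrate S [g/L]",
              "p": "product P [Cmol/L]"}
    ax.set_xlabel("time [h]")
    ax.set_ylabel(labels.get(var, var))
    ax.legend(fontsize=8)
    return ax
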