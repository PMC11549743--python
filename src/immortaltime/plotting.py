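"""Minimal plots for sweep results and survival curves."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_sweep(result: pd.DataFrame, path, true_rr: float | None = None) -> None:
    """Median estimated rate ratio against the swept parameter value.

    One line per estimator (and per prevalence level, for exposure
    sweeps); an optional horizontal reference line marks the true
    effect.
    """
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    group_cols = ["estimator"]
    if "p_exposed" in result.columns:
        group_cols.append("p_exposed")
    xcol = "mean_exposure_time" if "mean_exposure_time" in result.columns else "value"
    for key, grp in result.groupby(group_cols):
        label = key if isinstance(key, str) else "/".join(str(k) for k in key)
        grp = grp.sort_values(xcol)
        ax.plot(grp[xcol], grp["median_rr"], marker="o", ms=3, label=label)
    if true_rr is not None:
        ax.axhline(true_rr, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(result["parameter"].iloc[0] if "parameter" in result.columns else xcol)
    ax.set_ylabel("median estimated rate ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(curves: dict, path) -> None:
    """Overlay Kaplan-Meier step curves, one per labelled cohort."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
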