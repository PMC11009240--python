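"""Minimal diagnostic figures for fitted models and detected onsets."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_ctmi_fit", "plot_hsr_fit", "plot_dls_ramp", "plot_psup_scatter"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_ctmi_fit(results, temperature=None, mu=None, ax=None):
    """Growth rate vs temperature with the fitted CTMI curve overlaid."""
    ax = _ax(ax)
    grid = np.linspace(results.t_min - 2, results.t_max + 2, 400)
    ax.plot(grid, results.predict(grid), label="CTMI fit")
    if temperature is not None:
        ax.plot(temperature, mu, "o", label="observed")
    ax.axvline(results.t_opt, ls=":", lw=0.8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("max specific growth rate (h$^{-1}$)")
    ax.legend()
    return ax


def plot_hsr_fit(results, temperature=None, response=None, ax=None):
    """Heat-shock-response curve with the fitted skew-normal overlaid."""
    ax = _ax(ax)
    lo = results.xi - 4 * results.omega
    hi = results.xi + 4 * results.omega
    grid = np.linspace(lo, hi, 400)
    ax.plot(grid, results.predict(grid), label="skew-normal fit")
    if temperature is not None:
        ax.plot(temperature, response, "o", label="observed")
    ax.axvline(results.t_max_response, ls=":", lw=0.8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("response (fold over mock)")
    ax.legend()
    return ax


def plot_dls_ramp(ramp, result=None, ax=None):
    """Hydrodynamic radius vs temperature with baseline and detected onset."""
    ax = _ax(ax)
    ax.plot(ramp["temperature_c"], ramp["rh_nm"], ".", ms=3)
    if result is not None:
        ax.axhline(result.baseline_rh, ls="--", lw=0.8, label="monomer baseline")
        if result.detected:
            ax.axvline(
                result.t_condense, color="r", ls=":", label="T$_{condense}$"
            )
        ax.legend()
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("R$_h$ (nm)")
    return ax


def plot_psup_scatter(basal, shocked, classes=None, ax=None):
    """Shocked vs basal pSup per protein, optionally colored by class."""
    import pandas as pd

    ax = _ax(ax)
    merged = pd.merge(
        basal[["protein_id", "psup"]],
        shocked[["protein_id", "psup"]],
        on="protein_id",
        suffixes=("_basal", "_shocked"),
    ).dropna()
    if classes is not None:
        merged["cls"] = merged["protein_id"].map(classes)
        for label, sub in merged.groupby("cls"):
            ax.plot(sub["psup_basal"], sub["psup_shocked"], ".", ms=3, label=label)
        ax.legend()
    else:
        ax.plot(merged["psup_basal"], merged["psup_shocked"], ".", ms=3)
    ax.plot([0, 1], [0, 1], "k-", lw=0.6)
    ax.set_xlabel("pSup (basal)")
    ax.set_ylabel("pSup (heat shock)")
    return ax
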