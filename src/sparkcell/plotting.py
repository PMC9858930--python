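"""Quick-look figures for simulation traces (matplotlib)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engine import SimulationTrace

__all__ = ["plot_trace", "plot_currents"]


def plot_trace(trace: SimulationTrace, t_range=None, path=None):
    """Stacked panels: V, bulk/NSR Ca, open-channel counts, spark raster.

    Returns the matplotlib figure; writes ``path`` if given.
    """
    df = trace.df
    if t_range is not None:
        df = df[(df.time_s >= t_range[0]) & (df.time_s <= t_range[1])]
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(9, 8))
    axes[0].plot(df.time_s, df.v, lw=0.7, color="k")
    axes[0].set_ylabel("V (mV)")
    axes[1].plot(df.time_s, df.ca_myo, lw=0.7, color="tab:red")
    axes[1].set_ylabel("[Ca]$_{myo}$ (µM)")
    ax1b = axes[1].twinx()
    ax1b.plot(df.time_s, df.ca_nsr, lw=0.7, color="tab:blue")
    ax1b.set_ylabel("[Ca]$_{nsr}$ (µM)", color="tab:blue")
    axes[2].plot(df.time_s, df.open_ryr, lw=0.5, label="RyR2 open")
    axes[2].plot(df.time_s, df.open_lcc, lw=0.5, label="LCC open")
    axes[2].set_ylabel("open channels")
    axes[2].legend(frameon=False, fontsize=8)
    ev = trace.events
    if t_range is not None and len(ev):
        ev = ev[(ev.start_s >= t_range[0]) & (ev.start_s <= t_range[1])]
    if len(ev):
        axes[3].plot(ev.start_s, ev.cru_id, ",", color="k", alpha=0.5)
    axes[3].set_ylabel("spark raster (CRU)")
    axes[3].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=130)
    return fig


def plot_currents(trace: SimulationTrace, t_range=None, path=None):
    """Membrane currents (I_Na clipped for readability), one panel each."""
    df = trace.df
    if t_range is not None:
        df = df[(df.time_s >= t_range[0]) & (df.time_s <= t_range[1])]
    cols = ["i_na", "i_ca_l", "i_k", "i_k1", "i_ncx", "i_nak"]
    fig, axes = plt.subplots(len(cols), 1, sharex=True, figsize=(9, 9))
    for ax, col in zip(axes, cols):
        y = df[col]
        if col == "i_na":
            y = y.clip(lower=-25)
        ax.plot(df.time_s, y, lw=0.6)
        ax.set_ylabel(col)
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=130)
    return fig
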