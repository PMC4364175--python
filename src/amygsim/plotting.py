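"""Figure-style panels for paradigm runs.

Each function takes the per-trial record table from
:func:`amygsim.paradigms.records_to_frame` and draws one panel of the
standard paradigm read-outs: population activities at US arrival, the
CeLOn/CeLOff competition, normalised plastic-weight evolution, the tonic
ACh trace, and probe bar pairs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_activities", "plot_prediction", "plot_weights",
           "plot_ach", "plot_probes", "plot_paradigm"]


def plot_activities(frame: pd.DataFrame, ax=None):
    ax = ax or plt.gca()
    ax.plot(frame["trial"], frame["U_LA"], "^-", color="tab:blue", label="LA")
    ax.plot(frame["trial"], frame["U_BAf"], "s-", color="tab:cyan", label="BAf")
    ax.plot(frame["trial"], frame["U_BAe"], "s-", color="tab:green", label="BAe")
    ax.set_xlabel("trial")
    ax.set_ylabel("mean rate at US arrival")
    ax.legend(fontsize=8)
    return ax


def plot_prediction(frame: pd.DataFrame, ax=None):
    ax = ax or plt.gca()
    ax.plot(frame["trial"], frame["U_CeLOn"], "o-", color="tab:blue", label="CeLOn")
    ax.plot(frame["trial"], frame["U_CeLOff"], "o-", color="tab:green", label="CeLOff")
    ax.set_xlabel("trial")
    ax.set_ylabel("rate at US arrival")
    ax.legend(fontsize=8)
    return ax


def plot_weights(frame: pd.DataFrame, ax=None):
    ax = ax or plt.gca()
    styles = {"normW_Cortex->LA": ("^-", "tab:blue", "Cortex→LA"),
              "normW_Hippo->BAf": ("s-", "tab:cyan", "Hippo→BAf"),
              "normW_IL->BAe": ("s-", "tab:green", "IL→BAe")}
    for col, (fmt, color, label) in styles.items():
        if col in frame:
            ax.plot(frame["trial"], frame[col], fmt, color=color, label=label)
    ax.set_xlabel("trial")
    ax.set_ylabel("mean weight (normalised)")
    ax.legend(fontsize=8)
    return ax


def plot_ach(frame: pd.DataFrame, ax=None):
    ax = ax or plt.gca()
    ax.plot(frame["trial"], frame["ach_level"], "o-", color="tab:orange",
            label="ACh level")
    ax.plot(frame["trial"], frame["ach_v"], ":", color="tab:gray",
            label="uncertainty trace")
    ax.set_xlabel("trial")
    ax.legend(fontsize=8)
    return ax


def plot_probes(frame: pd.DataFrame, ax=None):
    """Bar pair of the cue-only and context-only probe predictions, with the
    no-stimulus baseline as a horizontal line."""
    ax = ax or plt.gca()
    cs = frame.loc[frame["label"] == "probe_cs", "prediction"]
    ctx = frame.loc[frame["label"] == "probe_ctx", "prediction"]
    base = frame.loc[frame["label"] == "baseline", "prediction"]
    ax.bar(["CS only", "CTX only"],
           [cs.iloc[-1] if len(cs) else float("nan"),
            ctx.iloc[-1] if len(ctx) else float("nan")],
           color=["tab:blue", "tab:green"])
    if len(base):
        ax.axhline(base.iloc[-1], color="k", ls="--", lw=1, label="baseline")
        ax.legend(fontsize=8)
    ax.set_ylabel("CeLOn prediction")
    return ax


def plot_paradigm(frame: pd.DataFrame, path: Optional[str | Path] = None,
                  title: str = ""):
    """Multi-panel summary figure for one paradigm run."""
    has_probes = (frame["label"] == "probe_cs").any()
    n = 5 if has_probes else 4
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2))
    plot_activities(frame, axes[0])
    plot_prediction(frame, axes[1])
    plot_weights(frame, axes[2])
    plot_ach(frame, axes[3])
    if has_probes:
        plot_probes(frame, axes[4])
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
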