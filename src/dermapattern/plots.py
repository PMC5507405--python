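"""Figures for the trajectory analyses: protractor and join-probability plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_CLASS_COLORS = {"condensate": "crimson", "intercondensate": "steelblue"}


def protractor_plot(windows: pd.DataFrame, path=None, window_label: str | None = None):
    """Half-circle plot of per-window Euclidean angles vs Euclidean distances.

    Each defined-angle window is one ray at its angle (0-180 deg) with
    length equal to its Euclidean distance; condensate windows in red,
    intercondensate in blue.
    """
    sub = windows[windows.angle_defined]
    if window_label is not None:
        sub = sub[sub.window_label == window_label]
    fig = plt.figure(figsize=(6, 3.5))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    for cls, color in _CLASS_COLORS.items():
        s = sub[sub.cls == cls]
        ax.plot(
            np.deg2rad(s.euclid_angle), s.euclid_dist, ".", ms=4, alpha=0.6,
            color=color, label=f"{cls} (n={len(s)})",
        )
    ax.set_title("Euclidean angle vs distance" + (f", {window_label}" if window_label else ""))
    ax.legend(loc="lower left", bbox_to_anchor=(0.8, 0.9), fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def join_probability_plot(curve: pd.DataFrame, path=None):
    """Probability of joining the condensate vs initial distance to its centre."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = curve[~curve.low_n]
    ax.plot(ok.bin_center, ok.probability, "o-", color="black")
    low = curve[curve.low_n]
    if len(low):
        ax.plot(low.bin_center, low.probability, "o", mfc="none", color="grey", label="n < 5")
        ax.legend(fontsize=8)
    ax.set_xlabel("initial distance to condensate centre (um)")
    ax.set_ylabel("P(join condensate)")
    ax.set_ylim(-0.02, 1.02)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
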