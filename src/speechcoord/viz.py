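"""Plotting helpers: cross-recurrence plots and diagonal profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .recurrence import CrossRecurrencePlot, DiagonalProfile


def plot_crp(crp: CrossRecurrencePlot, path: str | Path, title: str = "") -> None:
    """Render the plot as an image; recurrent cells dark, origin lower-left."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(crp.matrix, origin="lower", cmap="Blues", interpolation="nearest")
    ax.set_xlabel("partner A time (s)")
    ax.set_ylabel("partner B time (s)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(profile: DiagonalProfile, path: str | Path, title: str = "") -> None:
    """Recurrence rate per lag; the dashed line marks the line of synchrony."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.lags, profile.rates, marker=".", lw=1)
    ax.axvline(0, ls="--", color="grey")
    ax.set_xlabel("lag (s); positive = B follows A")
    ax.set_ylabel("RR")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
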