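"""Minimal figures for study reports: spectra vs. surrogate CI, effect bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_widths_vs_ci", "plot_sd_distance_bars"]


def plot_widths_vs_ci(per_song, ax=None):
    """Per-song original widths (dots) against surrogate 95% CI bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    idx = range(len(per_song))
    ax.fill_between(idx, per_song["orig_ci_low"], per_song["orig_ci_high"],
                    alpha=0.3, label="surrogate 95% CI")
    ax.plot(idx, per_song["orig_width"], "ko", ms=4, label="original width")
    ax.set_xlabel("song")
    ax.set_ylabel(r"$h_{max} - h_{min}$")
    ax.legend(frameon=False)
    return ax


def plot_sd_distance_bars(per_song, pause_stat="mean", ax=None):
    """Paired SD-distance bars: original vs. average-rhythm per song."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    idx = range(len(per_song))
    width = 0.4
    ax.bar([i - width / 2 for i in idx], per_song["orig_sd_distance"],
           width, label="original")
    ax.bar([i + width / 2 for i in idx],
           per_song[f"avg_{pause_stat}_sd_distance"], width,
           label="average rhythm")
    ax.set_xlabel("song")
    ax.set_ylabel("SD-distance from surrogate mean")
    ax.legend(frameon=False)
    return ax
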