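"""Basic diagnostic plots for pipeline outputs."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sholl", "plot_xcorr", "plot_lri_ori"]


def plot_sholl(profiles, labels=None, ax=None):
    """Mean Sholl intersection profile per group.

    ``profiles`` is a list of :class:`~ca1quant.morphology.ShollProfile`;
    ``labels`` optionally groups them (one line per group).
    """
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    labels = labels if labels is not None else [""] * len(profiles)
    for group in sorted(set(labels)):
        members = [p for p, g in zip(profiles, labels) if g == group]
        width = max(len(p.intersections) for p in members)
        acc = np.zeros(width)
        for p in members:
            acc[: len(p.intersections)] += p.intersections
        radii = (np.arange(width) + 1) * float(members[0].radii[0])
        ax.plot(radii, acc / len(members), label=str(group) or None)
    ax.set_xlabel("radius (um)")
    ax.set_ylabel("intersections")
    if any(labels):
        ax.legend()
    return ax


def plot_xcorr(result, ax=None):
    """Cross-correlation curve with its peak lag marked."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(result.lags_ms, result.values)
    ax.axvline(result.lag_at_max_ms, ls="--", color="k")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("correlation (a.u.)")
    ax.set_title(f"peak at {result.lag_at_max_ms:+.2f} ms")
    return ax


def plot_lri_ori(features, labels=None, ax=None):
    """LRI/ORI scatter, the k-means classification plane."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    feats = np.asarray(features, dtype=float)
    labels = np.zeros(len(feats)) if labels is None else np.asarray(labels)
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(feats[sel, 0], feats[sel, 1], s=14, label=str(lab))
    ax.set_xlabel("LRI")
    ax.set_ylabel("ORI")
    if labels is not None:
        ax.legend()
    return ax
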