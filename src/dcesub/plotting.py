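"""Diagnostic plots: curves, AIF, probability maps, Haar coefficient spread."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_aif", "plot_curves", "plot_probability_slice", "plot_haar_spread"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_aif(aif, dt_seconds: float, ax=None):
    """Arterial enhancement curve with its onset sample and peak marked."""
    ax = _get_ax(ax)
    t = np.arange(len(aif.curve)) * dt_seconds
    ax.plot(t, aif.curve, lw=1.5)
    ax.axvline(aif.onset_index * dt_seconds, ls="--", color="grey", label="onset")
    ax.axhline(aif.peak_enhancement, ls=":", color="grey", label="peak")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta S / S_0$")
    ax.legend(frameon=False)
    return ax


def plot_curves(windows, dt_seconds: float, labels=None, n: int = 50, ax=None, seed: int = 0):
    """A random sample of normalized windows, colored by class if given."""
    ax = _get_ax(ax)
    w = np.asarray(windows)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(w), size=min(n, len(w)), replace=False)
    t = np.arange(w.shape[1]) * dt_seconds
    for i in pick:
        color = None
        if labels is not None:
            color = "tab:blue" if labels[i] == 0 else "tab:red"
        ax.plot(t, w[i], alpha=0.35, lw=0.8, color=color)
    ax.set_xlabel("time from onset (s)")
    ax.set_ylabel(r"$\Delta S_N$")
    return ax


def plot_probability_slice(prob_map, z: int, ax=None):
    """One axial slice of the posterior c-LBV probability map."""
    ax = _get_ax(ax)
    values = prob_map.values if hasattr(prob_map, "values") else np.asarray(prob_map)
    im = ax.imshow(values[:, :, z].T, origin="lower", vmin=0, vmax=1, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="P(c-LBV)")
    ax.set_title(f"slice z={z}")
    return ax


def plot_haar_spread(coefficients, ax=None):
    """Box plot of Haar coefficient distributions by global index."""
    ax = _get_ax(ax)
    c = np.asarray(coefficients)
    ax.boxplot([c[:, j] for j in range(c.shape[1])], showfliers=False)
    ax.set_xlabel("global coefficient index")
    ax.set_ylabel("coefficient value")
    return ax
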