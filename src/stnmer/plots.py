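"""Depth-normalized spectrogram and NRMS profile figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import NormalizedProfile

__all__ = ["plot_spectrogram", "plot_nrms_profile"]


def plot_spectrogram(
    profile: NormalizedProfile,
    fmin: float = 1.0,
    fmax: float = 200.0,
    ax=None,
    title: str = "",
):
    """Heat map of envelope power fractions over normalized depth.

    Use ``fmin=10, fmax=45`` for the zoomed beta-band view.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    fsel = (profile.freqs >= fmin) & (profile.freqs <= fmax)
    data = profile.spectrogram[:, fsel].T
    mesh = ax.pcolormesh(
        profile.grid,
        profile.freqs[fsel],
        data,
        shading="nearest",
        cmap="viridis",
    )
    ax.axvline(0.0, color="w", lw=0.8, ls="--")
    ax.axvline(1.0, color="w", lw=0.8, ls="--")
    ax.set_xlabel("normalized depth (0 = STN entry, 1 = exit)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    plt.colorbar(mesh, ax=ax, label="power fraction")
    return ax


def plot_nrms_profile(profiles: list[NormalizedProfile], ax=None, label: str = ""):
    """Group NRMS along the normalized trajectory (mean +/- SEM band)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    stack = np.vstack([p.nrms_values for p in profiles])
    mean = np.nanmean(stack, axis=0)
    n = np.sum(~np.isnan(stack), axis=0)
    sem = np.nanstd(stack, axis=0) / np.sqrt(np.maximum(n, 1))
    grid = profiles[0].grid
    ax.plot(grid, mean, label=label or None)
    ax.fill_between(grid, mean - sem, mean + sem, alpha=0.3)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("normalized depth")
    ax.set_ylabel("NRMS")
    if label:
        ax.legend()
    return ax
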