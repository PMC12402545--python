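"""Depth-normalized profiles and per-trajectory scalar metrics.

To pool trajectories with different recorded STN lengths, each pass is
mapped to a normalized coordinate ``x = (entry - depth) / (entry -
exit)`` so the STN spans ``x in [0, 1]``, and a pre-entrance segment
equal to half the STN length (``x in [-0.5, 0)``) is included. NRMS
and every envelope-spectrum column are linearly interpolated onto a
fixed grid; points outside a trajectory's coverage are missing (NaN),
never extrapolated. Group averages are pointwise means over available
trajectories.

Scalar metrics per trajectory:

* ``beta_ratio`` - mean beta-band (13-30 Hz) envelope-power fraction
  over DLOR sites divided by the mean over the pre-entrance
  (half-length) segment;
* ``mean_band_power`` - mean band fraction over the DLOR (beta and
  lower bands) or the whole STN (gamma, configurable);
* ``nrms_peak`` / ``nrms_auc`` - maximum NRMS inside the STN and the
  trapezoidal integral of NRMS over ``x in [0, 1]``;
* recorded STN/DLOR lengths and percent DLOR.

All metrics are defined on the sites themselves, not the interpolation
grid, so they are independent of the grid resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import TrajectoryProfile
from .segmentation import Segmentation, stn_lengths

__all__ = [
    "NormalizedProfile",
    "TrajectoryMetrics",
    "normalize_depths",
    "group_average",
    "beta_ratio",
    "mean_band_power",
    "nrms_peak_auc",
    "compute_trajectory_metrics",
    "metrics_table",
]


@dataclass
class NormalizedProfile:
    """A trajectory resampled onto the normalized-depth grid.

    ``grid`` runs over [-0.5, 1]: 0 is the STN entry, 1 the exit and
    negative values the pre-entrance segment. ``spectrogram`` is a
    (grid x frequency) matrix of envelope power fractions. ``counts``
    (present after :func:`group_average`) holds the number of
    trajectories contributing to each grid point.
    """

    grid: np.ndarray
    nrms_values: np.ndarray
    spectrogram: np.ndarray
    freqs: np.ndarray
    counts: np.ndarray | None = None
    trajectory_id: str = ""
    group: str = ""


@dataclass
class TrajectoryMetrics:
    """Scalar per-trajectory metrics with the group label attached."""

    trajectory_id: str
    group: str
    beta_ratio: float
    mean_band_power: dict[str, float]
    nrms_peak: float
    nrms_auc: float
    stn_length: float
    dlor_length: float
    percent_dlor: float
    seg_source: str = "detected"
    extras: dict = field(default_factory=dict)


def _normalized_x(depths: np.ndarray, seg: Segmentation) -> np.ndarray:
    span = seg.entry_depth - seg.exit_depth
    return (seg.entry_depth - depths) / span


def normalize_depths(
    profile: TrajectoryProfile,
    seg: Segmentation,
    n_grid: int = 151,
) -> NormalizedProfile:
    """Interpolate NRMS and the spectrogram onto the fixed [-0.5, 1] grid.

    Linear interpolation between sites; grid points outside the
    recorded coverage become NaN. If the recording does not reach back
    to half an STN length above entry, the pre-segment is truncated
    (with a warning) rather than extrapolated.
    """
    grid = np.linspace(-0.5, 1.0, n_grid)
    x = _normalized_x(profile.depths, seg)  # increasing along the pass
    if x[0] > -0.5 + 1e-9:
        warnings.warn(
            f"pre-entrance coverage starts at x={x[0]:.3f} > -0.5; "
            "pre-segment truncated",
            UserWarning,
        )
    nrms = np.interp(grid, x, profile.nrms, left=np.nan, right=np.nan)
    psd = profile.psd_matrix
    spec = np.empty((n_grid, psd.shape[1]))
    inside = (grid >= x[0] - 1e-12) & (grid <= x[-1] + 1e-12)
    for col in range(psd.shape[1]):
        spec[:, col] = np.interp(grid, x, psd[:, col])
    spec[~inside] = np.nan
    nrms[~inside] = np.nan
    return NormalizedProfile(
        grid=grid,
        nrms_values=nrms,
        spectrogram=spec,
        freqs=profile.psd_freqs,
        trajectory_id=profile.trajectory_id,
        group=profile.group,
    )


def group_average(profiles: list[NormalizedProfile]) -> NormalizedProfile:
    """Pointwise mean profile over a group, ignoring missing values."""
    if not profiles:
        raise ValueError("cannot average an empty list of profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.shape != grid.shape or not np.allclose(p.grid, grid):
            raise ValueError("all profiles must share the same grid")
    nrms_stack = np.vstack([p.nrms_values for p in profiles])
    spec_stack = np.stack([p.spectrogram for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        nrms_mean = np.nanmean(nrms_stack, axis=0)
        spec_mean = np.nanmean(spec_stack, axis=0)
    counts = np.sum(~np.isnan(nrms_stack), axis=0)
    return NormalizedProfile(
        grid=grid,
        nrms_values=nrms_mean,
        spectrogram=spec_mean,
        freqs=profiles[0].freqs,
        counts=counts,
        group=profiles[0].group,
    )


def _dlor_mask(profile: TrajectoryProfile, seg: Segmentation) -> np.ndarray:
    return np.array([l == "DLOR" for l in seg.labels])


def _stn_mask(profile: TrajectoryProfile, seg: Segmentation) -> np.ndarray:
    return np.array([l in ("DLOR", "VMNR") for l in seg.labels])


def _pre_segment_mask(profile: TrajectoryProfile, seg: Segmentation) -> np.ndarray:
    """Pre-entrance sites within half an STN length above entry."""
    depths = profile.depths
    half = 0.5 * (seg.entry_depth - seg.exit_depth)
    return (depths > seg.entry_depth) & (depths <= seg.entry_depth + half)


def beta_ratio(
    profile: TrajectoryProfile,
    seg: Segmentation,
    band: str = "beta",
) -> float:
    """DLOR beta power relative to the pre-entrance segment.

    Ratio of the mean beta-band envelope fraction over DLOR sites to
    the mean over pre-entrance sites within the half-length segment.
    Returns NaN when the DLOR is empty (undefined, reported missing).
    """
    frac = profile.band(band)
    dlor = _dlor_mask(profile, seg)
    pre = _pre_segment_mask(profile, seg)
    if not dlor.any():
        return float("nan")
    if not pre.any():
        raise ValueError("no pre-entrance sites within the half-length segment")
    denom = float(frac[pre].mean())
    if denom <= 0:
        raise ValueError("pre-entrance beta power is zero; ratio undefined")
    return float(frac[dlor].mean()) / denom


def mean_band_power(
    profile: TrajectoryProfile,
    seg: Segmentation,
    band: str,
    region: str = "dlor",
) -> float:
    """Mean envelope band fraction over a segmented region.

    ``region`` is ``'dlor'`` (the default for beta and lower bands) or
    ``'stn'`` (DLOR + VMNR; the default choice for gamma, whose
    broad-band activity characterizes the whole nucleus).
    """
    if region == "dlor":
        mask = _dlor_mask(profile, seg)
    elif region == "stn":
        mask = _stn_mask(profile, seg)
    else:
        raise ValueError(f"unknown region {region!r}; expected 'dlor' or 'stn'")
    if not mask.any():
        raise ValueError(f"region {region!r} contains no sites")
    return float(profile.band(band)[mask].mean())


def nrms_peak_auc(
    profile: TrajectoryProfile, seg: Segmentation
) -> tuple[float, float]:
    """Peak NRMS inside the STN and trapezoidal NRMS area over x in [0, 1].

    The peak is taken over sites with ``entry >= depth > exit``; the
    area integrates the piecewise-linear NRMS over the normalized STN
    extent, so a constant NRMS of c inside the STN gives an AUC of c.
    """
    depths = profile.depths
    stn = (depths <= seg.entry_depth) & (depths > seg.exit_depth)
    if not stn.any():
        raise ValueError("segmentation leaves no sites inside the STN")
    peak = float(profile.nrms[stn].max())
    x = _normalized_x(depths, seg)
    span = (x >= -1e-12) & (x <= 1.0 + 1e-12)
    auc = float(np.trapezoid(profile.nrms[span], x[span]))
    return peak, auc


def compute_trajectory_metrics(
    profile: TrajectoryProfile,
    seg: Segmentation,
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma"),
    gamma_region: str = "stn",
) -> TrajectoryMetrics:
    """All scalar metrics for one trajectory under one segmentation."""
    stn_len, dlor_len, pct = stn_lengths(seg)
    peak, auc = nrms_peak_auc(profile, seg)
    powers = {
        b: mean_band_power(
            profile, seg, b, region=gamma_region if b == "gamma" else "dlor"
        )
        for b in bands
    }
    return TrajectoryMetrics(
        trajectory_id=profile.trajectory_id,
        group=profile.group,
        beta_ratio=beta_ratio(profile, seg),
        mean_band_power=powers,
        nrms_peak=peak,
        nrms_auc=auc,
        stn_length=stn_len,
        dlor_length=dlor_len,
        percent_dlor=pct,
        seg_source=seg.source,
    )


def metrics_table(metrics: list[TrajectoryMetrics]) -> pd.DataFrame:
    """Cohort-level table: one row per trajectory, one column per metric."""
    rows = []
    for m in metrics:
        row = {
            "trajectory_id": m.trajectory_id,
            "group": m.group,
            "beta_ratio": m.beta_ratio,
            "nrms_peak": m.nrms_peak,
            "nrms_auc": m.nrms_auc,
            "stn_length_mm": m.stn_length,
            "dlor_length_mm": m.dlor_length,
            "percent_dlor": m.percent_dlor,
            "seg_source": m.seg_source,
        }
        for band, value in m.mean_band_power.items():
            row[f"mean_power_{band}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
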