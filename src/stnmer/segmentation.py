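"""STN border and subdomain detection from a trajectory profile.

Clinically, STN entry is recognized by a step-up in background noise
and high-density firing (a jump in NRMS) together with increased
low-frequency envelope power; the motor subdomain (DLOR) shows elevated
beta and lower-frequency envelope power; the non-motor subdomain (VMNR)
shows relatively more broad-band gamma; the exit is a drop of the noise
level back toward baseline.

The detector here is a self-contained left-to-right decoder: each site
emits three features (NRMS, a low-frequency envelope fraction
theta+alpha+beta, and a gamma fraction) modelled as Gaussians whose
moments are estimated from the profile itself (PRE moments from the
baseline sites, in-STN moments from robust quantiles of the
high-activity sites). Transitions are allowed only forward through
PRE -> DLOR -> VMNR -> POST, and the maximum-likelihood state path is
found by exhaustive change-point optimization (exact for this chain).
Boundaries are reported at the first site of each new state, so a
segment covers depths ``[entry, exit)`` half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import TrajectoryProfile

__all__ = [
    "Segmentation",
    "SegmentationParams",
    "segment_profile",
    "apply_manual_segmentation",
    "segmentation_from_ground_truth",
    "stn_lengths",
    "DegenerateProfileWarning",
]

STATES = ("PRE", "DLOR", "VMNR", "POST")


class DegenerateProfileWarning(UserWarning):
    """Raised when a profile shows no usable STN contrast."""


@dataclass
class Segmentation:
    """STN entry, DLOR->VMNR transition and exit for one trajectory.

    ``entry_depth`` is the first DLOR site, ``dlor_exit_depth`` the
    first VMNR site and ``exit_depth`` the first POST site; all three
    are depths of actual profile sites. ``source`` records whether the
    borders were detected, taken from simulation ground truth, or set
    manually (the expert-correction path).
    """

    entry_depth: float
    dlor_exit_depth: float
    exit_depth: float
    labels: list[str]
    source: str = "detected"
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.entry_depth > self.dlor_exit_depth >= self.exit_depth):
            raise ValueError("require entry > dlor_exit >= exit")
        order = {s: i for i, s in enumerate(STATES)}
        idx = [order[l] for l in self.labels]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("labels must be non-decreasing PRE->DLOR->VMNR->POST")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the border detector, with documented defaults."""

    n_baseline: int = 6            # top-of-track sites defining PRE moments
    low_band_names: tuple[str, ...] = ("theta", "alpha", "beta")
    gamma_band_name: str = "gamma"
    min_pre_sites: int = 3         # decoded PRE segment must keep >= this
    min_dlor_sites: int = 2        # avoid spurious zero-length motor regions
    min_vmnr_sites: int = 1
    min_post_sites: int = 1
    nrms_contrast_z: float = 2.0   # (mu_stn - mu_pre)/sd_pre below this => degenerate
    sd_floor_frac: float = 0.05    # relative floor on every emission SD
    low_contrast: float = 1.0      # weight of the spectral features (0 disables)


def _labels_from_bounds(depths: np.ndarray, i: int, j: int, k: int) -> list[str]:
    lab = ["PRE"] * len(depths)
    for t in range(i, j):
        lab[t] = "DLOR"
    for t in range(j, k):
        lab[t] = "VMNR"
    for t in range(k, len(depths)):
        lab[t] = "POST"
    return lab


def _gauss_loglik(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


def segment_profile(
    profile: TrajectoryProfile,
    params: SegmentationParams | None = None,
) -> Segmentation:
    """Decode STN borders from per-site NRMS and envelope-band features.

    Returns a :class:`Segmentation` with ``source='detected'``. When
    the profile shows no NRMS contrast (no detectable STN), the result
    is flagged ``degenerate`` and a :class:`DegenerateProfileWarning`
    is emitted; the returned labels are then all PRE except a minimal
    trailing segment, and boundary depths are not meaningful.
    """
    p = params or SegmentationParams()
    depths = profile.depths
    n = len(depths)
    min_total = p.min_pre_sites + p.min_dlor_sites + p.min_vmnr_sites + p.min_post_sites
    if n < max(min_total, p.n_baseline + 5):
        raise ValueError(f"profile too short to segment ({n} sites)")

    nrms = profile.nrms
    low = np.sum([profile.band(b) for b in p.low_band_names], axis=0)
    gam = profile.band(p.gamma_band_name)

    nb = min(p.n_baseline, n)
    mu_pre = float(np.mean(nrms[:nb]))
    sd_pre = max(float(np.std(nrms[:nb])), p.sd_floor_frac * mu_pre, 1e-6)

    high = nrms > mu_pre + p.nrms_contrast_z * sd_pre
    high[:nb] = False
    if high.sum() < p.min_dlor_sites + p.min_vmnr_sites:
        warnings.warn(
            "no NRMS contrast above baseline; segmentation is degenerate",
            DegenerateProfileWarning,
        )
        return _degenerate_result(profile, p)

    mu_stn = float(np.median(nrms[high]))
    mad = float(np.median(np.abs(nrms[high] - mu_stn)))
    sd_stn = max(1.4826 * mad, p.sd_floor_frac * mu_stn, 1e-6)

    # spectral moments: split the high-activity sites on their
    # low-frequency fraction to seed DLOR-like vs VMNR-like emissions
    low_high = low[high]
    gam_high = gam[high]
    split = float(np.median(low_high))
    upper = low_high >= split
    if 0 < upper.sum() < upper.size:
        mu_low_dlor = float(np.mean(low_high[upper]))
        mu_low_vmnr = float(np.mean(low_high[~upper]))
        mu_gam_dlor = float(np.mean(gam_high[upper]))
        mu_gam_vmnr = float(np.mean(gam_high[~upper]))
    else:  # all high sites spectrally identical
        mu_low_dlor = mu_low_vmnr = float(np.mean(low_high))
        mu_gam_dlor = mu_gam_vmnr = float(np.mean(gam_high))
    sd_low = max(float(np.std(low_high)), p.sd_floor_frac * max(split, 1e-3), 1e-6)
    sd_gam = max(float(np.std(gam_high)), p.sd_floor_frac * max(np.median(gam_high), 1e-3), 1e-6)
    mu_low_pre = float(np.mean(low[:nb]))
    mu_gam_pre = float(np.mean(gam[:nb]))

    # per-site, per-state emission log-likelihoods
    ll = np.empty((4, n))
    ll[0] = _gauss_loglik(nrms, mu_pre, sd_pre)
    ll[1] = _gauss_loglik(nrms, mu_stn, sd_stn)
    ll[2] = _gauss_loglik(nrms, mu_stn, sd_stn)
    ll[3] = ll[0]
    if p.low_contrast > 0:
        w = p.low_contrast
        ll[0] += w * (_gauss_loglik(low, mu_low_pre, sd_low)
                      + _gauss_loglik(gam, mu_gam_pre, sd_gam))
        ll[1] += w * (_gauss_loglik(low, mu_low_dlor, sd_low)
                      + _gauss_loglik(gam, mu_gam_dlor, sd_gam))
        ll[2] += w * (_gauss_loglik(low, mu_low_vmnr, sd_low)
                      + _gauss_loglik(gam, mu_gam_vmnr, sd_gam))
        ll[3] = ll[0]

    # exact maximum-likelihood change points for the left-to-right chain:
    # score(i,j,k) = sum_pre[:i] + sum_dlor[i:j] + sum_vmnr[j:k] + sum_post[k:]
    # separates into u(i) + v(j) + w(k) on cumulative sums.
    c = np.concatenate([[0.0], np.cumsum(ll[0])])          # PRE prefix
    cd = np.concatenate([[0.0], np.cumsum(ll[1])])
    cv = np.concatenate([[0.0], np.cumsum(ll[2])])
    cp = np.concatenate([[0.0], np.cumsum(ll[3])])
    u = c - cd                                             # index i
    v = cd - cv                                            # index j
    w = cv - cp                                            # index k (+ const cp[n])

    i_lo, i_hi = p.min_pre_sites, n - (p.min_dlor_sites + p.min_vmnr_sites + p.min_post_sites)
    best = None
    # prefix max of u and suffix max of w make this O(n)
    u_argmax = np.empty(n + 1, dtype=int)
    bi = i_lo
    for i in range(i_lo, i_hi + 1):
        if u[i] > u[bi]:
            bi = i
        u_argmax[i] = bi
    w_argmax = np.empty(n + 1, dtype=int)
    bk = n - p.min_post_sites
    for k in range(n - p.min_post_sites, 0, -1):
        if w[k] > w[bk]:
            bk = k
        w_argmax[k] = bk
    for j in range(i_lo + p.min_dlor_sites, n - p.min_vmnr_sites - p.min_post_sites + 1):
        i = u_argmax[j - p.min_dlor_sites]
        k = w_argmax[j + p.min_vmnr_sites]
        score = u[i] + v[j] + w[k]
        if best is None or score > best[0]:
            best = (score, i, j, k)
    assert best is not None
    _, i, j, k = best

    labels = _labels_from_bounds(depths, i, j, k)
    return Segmentation(
        entry_depth=float(depths[i]),
        dlor_exit_depth=float(depths[j]),
        exit_depth=float(depths[k]),
        labels=labels,
        source="detected",
    )


def _degenerate_result(
    profile: TrajectoryProfile, p: SegmentationParams
) -> Segmentation:
    n = len(profile)
    depths = profile.depths
    i = n - (p.min_dlor_sites + p.min_vmnr_sites + p.min_post_sites)
    j = i + p.min_dlor_sites
    k = j + p.min_vmnr_sites
    return Segmentation(
        entry_depth=float(depths[i]),
        dlor_exit_depth=float(depths[j]),
        exit_depth=float(depths[k]),
        labels=_labels_from_bounds(depths, i, j, k),
        source="detected",
        degenerate=True,
        warnings=["no NRMS contrast above baseline"],
    )


def _snap_index(depths: np.ndarray, depth: float) -> int:
    """Nearest profile site; ties break to the shallower (larger) depth."""
    dist = np.abs(depths - depth)
    best = np.min(dist)
    candidates = np.flatnonzero(dist <= best + 1e-12)
    return int(candidates[0])  # depths decrease, so first = shallowest


def apply_manual_segmentation(
    profile: TrajectoryProfile,
    entry_depth: float,
    dlor_exit_depth: float,
    exit_depth: float,
) -> Segmentation:
    """Expert-provided borders, snapped to the nearest profile sites."""
    if not (entry_depth > dlor_exit_depth >= exit_depth):
        raise ValueError("require entry > dlor_exit >= exit")
    depths = profile.depths
    lo, hi = depths.min(), depths.max()
    for name, d in (("entry", entry_depth), ("dlor_exit", dlor_exit_depth),
                    ("exit", exit_depth)):
        if not (lo <= d <= hi):
            raise ValueError(f"{name} depth {d} outside profile range [{lo}, {hi}]")
    i = _snap_index(depths, entry_depth)
    j = _snap_index(depths, dlor_exit_depth)
    k = _snap_index(depths, exit_depth)
    if not (i < j <= k):  # j == k permits an empty VMNR (dlor_exit == exit)
        raise ValueError("snapped borders are not properly ordered")
    return Segmentation(
        entry_depth=float(depths[i]),
        dlor_exit_depth=float(depths[j]),
        exit_depth=float(depths[k]),
        labels=_labels_from_bounds(depths, i, j, k),
        source="manual",
    )


def segmentation_from_ground_truth(profile: TrajectoryProfile, gt) -> Segmentation:
    """Segmentation snapped from simulation ground-truth borders."""
    seg = apply_manual_segmentation(
        profile, gt.entry_depth, gt.dlor_exit_depth, gt.exit_depth
    )
    seg.source = "ground_truth"
    return seg


def stn_lengths(seg: Segmentation) -> tuple[float, float, float]:
    """Recorded STN length, DLOR length and percent DLOR.

    ``stn_length = entry - exit`` (mm), ``dlor_length = entry -
    dlor_exit`` (mm), ``percent_dlor = 100 * dlor_length / stn_length``.
    """
    stn = seg.entry_depth - seg.exit_depth
    dlor = seg.entry_depth - seg.dlor_exit_depth
    return stn, dlor, 100.0 * dlor / stn
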