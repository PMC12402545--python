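"""Synthetic microelectrode-recording (MER) trajectories and cohorts.

The simulator emulates the signal structure the downstream analysis
assumes so every stage can be exercised and validated without patient
data:

* a step-up in broadband background noise at STN entry and a drop at
  exit (the entry/exit signature used clinically);
* high-density multi-unit firing inside the STN, modelled as summed
  Poisson spike trains convolved with a ~1 ms biphasic waveform;
* beta-band (13-30 Hz) modulation of the multi-unit firing rate
  confined to the dorsolateral oscillating region (DLOR) in PD-like
  subjects and absent in ET-like subjects;
* an internal-capsule-like baseline of six closely spaced sites at the
  top of the track, used downstream for RMS normalization.

Trajectory geometry follows the intraoperative protocol: recording
starts ~10 mm above the planned target, advances in 0.4 mm steps before
the STN and 0.1 mm steps within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .containers import MIN_SAMPLING_RATE, SiteRecording, Trajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_site",
    "simulate_trajectory",
    "simulate_cohort",
    "pd_config",
    "et_config",
    "compact_config",
    "spike_waveform",
]

State = Literal["PRE", "DLOR", "VMNR", "POST"]
STATES: tuple[str, ...] = ("PRE", "DLOR", "VMNR", "POST")

#: Spacing (mm) of the top-of-track baseline sites ("taken 0.1 mm apart").
BASELINE_STEP = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-MER signal and trajectory model.

    Depths are mm above the planned target; the electrode descends, so
    ``start_depth > entry_depth > exit_depth``. Rates are per-unit
    firing rates in spikes/s; ``n_units`` independent units are summed.
    Modulation depths are the relative amplitude ``m`` of the sinusoidal
    rate modulation ``lambda(t) = r (1 + m sin(2 pi f t))``.
    """

    sampling_rate: float = 44000.0       # Hz
    site_duration: float = 4.0           # s of analysed signal per site
    pre_stn_step: float = 0.4            # mm between sites before the STN
    in_stn_step: float = 0.1             # mm between sites inside the STN
    start_depth: float = 10.0            # mm above target, first site
    entry_depth: float = 4.0             # mm, dorsolateral STN border
    exit_depth: float = -2.0             # mm, ventral STN border
    dlor_fraction: float = 0.57          # fraction of STN length that is DLOR
    post_extent: float = 2.0             # mm of post-STN track simulated
    baseline_noise_sd: float = 1.0       # background noise SD outside STN
    stn_noise_gain: float = 2.0          # noise SD multiplier inside STN
    unit_rate_baseline: float = 5.0      # spikes/s per unit outside STN
    unit_rate_stn: float = 60.0          # spikes/s per unit inside STN
    n_units: int = 10
    spike_amplitude: float = 2.0         # peak waveform amplitude (noise-SD units)
    beta_mod_depth: float = 0.8          # DLOR rate modulation depth, in [0, 1]
    beta_freq: float = 20.0              # Hz, within 13-30
    tremor_mod_depth: float = 0.0        # optional 6-12 Hz rate modulation
    tremor_freq: float = 8.0             # Hz
    n_baseline_sites: int = 6            # closely spaced top-of-track sites
    entry_exit_jitter: float = 1.0       # mm, uniform cohort jitter of borders
    rate_cv: float = 0.2                 # log-normal CV of cohort rate jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.start_depth > self.entry_depth > self.exit_depth):
            raise ValueError("require start_depth > entry_depth > exit_depth")
        if not (0.0 < self.dlor_fraction < 1.0):
            raise ValueError("dlor_fraction must lie in (0, 1)")
        if self.sampling_rate < MIN_SAMPLING_RATE:
            raise ValueError(f"sampling_rate must be >= {MIN_SAMPLING_RATE} Hz")
        if self.site_duration <= 0:
            raise ValueError("site_duration must be positive")
        for name in ("unit_rate_baseline", "unit_rate_stn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("beta_mod_depth", "tremor_mod_depth"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.stn_noise_gain <= 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise parameters must be positive")

    @property
    def stn_length(self) -> float:
        return self.entry_depth - self.exit_depth

    @property
    def dlor_exit_depth(self) -> float:
        return self.entry_depth - self.dlor_fraction * self.stn_length


@dataclass
class GroundTruth:
    """True border depths and per-site region labels of a simulated pass.

    Region labels follow the electrode order PRE -> DLOR -> VMNR -> POST
    and are non-decreasing in that order along descending depth. A site
    exactly at a border depth belongs to the *new* region, except the
    entry site which is the first DLOR site.
    """

    entry_depth: float
    dlor_exit_depth: float
    exit_depth: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.entry_depth > self.dlor_exit_depth >= self.exit_depth):
            raise ValueError("require entry > dlor_exit >= exit")
        order = {s: i for i, s in enumerate(STATES)}
        idx = [order[l] for l in self.labels]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("labels must be non-decreasing PRE->DLOR->VMNR->POST")


def spike_waveform(sampling_rate: float, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike waveform, ~1 ms total width.

    Difference of two Gaussians (a sharp negative trough followed by a
    slower positive rebound), peak-normalized to ``amplitude``.
    """
    t = np.arange(0.0, 1.4e-3, 1.0 / sampling_rate)
    w = -np.exp(-0.5 * ((t - 0.4e-3) / 0.12e-3) ** 2) \
        + 0.55 * np.exp(-0.5 * ((t - 0.75e-3) / 0.22e-3) ** 2)
    return amplitude * w / np.max(np.abs(w))


def _modulated_spike_times(
    rate: float,
    duration: float,
    mods: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson event times by thinning.

    ``mods`` is a list of (depth m, frequency f) sinusoidal rate terms:
    lambda(t) = rate * max(0, 1 + sum_i m_i sin(2 pi f_i t)).
    """
    if rate <= 0:
        return np.empty(0)
    m_tot = sum(m for m, _ in mods)
    lam_max = rate * (1.0 + m_tot)
    n = rng.poisson(lam_max * duration)
    t = rng.uniform(0.0, duration, n)
    if m_tot > 0 and n:
        lam = 1.0 + sum(m * np.sin(2 * np.pi * f * t) for m, f in mods)
        keep = rng.uniform(0.0, 1.0 + m_tot, n) < np.maximum(lam, 0.0)
        t = t[keep]
    return t


def simulate_site(
    depth: float,
    state: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> SiteRecording:
    """Simulate one recording site in the given region state.

    The trace is Gaussian background noise (SD stepped up inside the
    STN) plus ``n_units`` summed Poisson spike trains convolved with a
    biphasic ~1 ms waveform. Firing-rate modulation is applied only in
    the DLOR: at ``beta_freq`` with depth ``beta_mod_depth`` and, if
    enabled, at ``tremor_freq`` with depth ``tremor_mod_depth``.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    fs = cfg.sampling_rate
    n = round(cfg.site_duration * fs)
    if n <= 0:
        raise ValueError("site duration must be positive")

    inside = state in ("DLOR", "VMNR")
    noise_sd = cfg.baseline_noise_sd * (cfg.stn_noise_gain if inside else 1.0)
    x = noise_sd * rng.standard_normal(n)

    unit_rate = cfg.unit_rate_stn if inside else cfg.unit_rate_baseline
    total_rate = unit_rate * cfg.n_units
    mods: list[tuple[float, float]] = []
    if state == "DLOR":
        if cfg.beta_mod_depth > 0:
            mods.append((cfg.beta_mod_depth, cfg.beta_freq))
        if cfg.tremor_mod_depth > 0:
            mods.append((cfg.tremor_mod_depth, cfg.tremor_freq))
    if total_rate > 0:
        times = _modulated_spike_times(total_rate, cfg.site_duration, mods, rng)
        if times.size:
            idx = np.minimum((times * fs).astype(np.int64), n - 1)
            w = spike_waveform(fs, cfg.spike_amplitude * cfg.baseline_noise_sd)
            # scatter-add one waveform per spike (cost ~ n_spikes, not n)
            flat_idx = (idx[:, None] + np.arange(w.size)).ravel()
            vals = np.tile(w, idx.size)
            buf = np.bincount(flat_idx, weights=vals, minlength=n + w.size)
            x += buf[:n]
    return SiteRecording(depth=depth, sampling_rate=fs, samples=x)


def _round_grid(v: float) -> float:
    # keep depths on a clean 1e-6 mm grid to avoid float drift in comparisons
    return round(v, 6)


def trajectory_depths(cfg: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Site depths and true region labels implied by a configuration.

    The track starts with ``n_baseline_sites`` sites at 0.1 mm spacing
    (the NRMS baseline), descends in ``pre_stn_step`` increments to the
    STN entry, crosses the STN in ``in_stn_step`` increments down to the
    exit depth inclusive, then continues ``post_extent`` mm below the
    exit in ``pre_stn_step`` increments. The site exactly at the exit
    depth is the first POST site (the noise step-down site).
    """
    depths: list[float] = []
    d = cfg.start_depth
    for _ in range(cfg.n_baseline_sites):
        depths.append(_round_grid(d))
        d -= BASELINE_STEP
    d = depths[-1] - cfg.pre_stn_step
    while d > cfg.entry_depth + 1e-9:
        depths.append(_round_grid(d))
        d -= cfg.pre_stn_step
    d = cfg.entry_depth
    while d > cfg.exit_depth + 1e-9:
        depths.append(_round_grid(d))
        d -= cfg.in_stn_step
    d = cfg.exit_depth
    stop = cfg.exit_depth - cfg.post_extent
    while d > stop - 1e-9:
        depths.append(_round_grid(d))
        d -= cfg.pre_stn_step

    dlor_exit = cfg.dlor_exit_depth
    labels = []
    for depth in depths:
        if depth > cfg.entry_depth + 1e-9:
            labels.append("PRE")
        elif depth > dlor_exit + 1e-9:
            labels.append("DLOR")
        elif depth > cfg.exit_depth + 1e-9:
            labels.append("VMNR")
        else:
            labels.append("POST")
    return np.array(depths), labels


def simulate_trajectory(
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
    *,
    trajectory_id: str = "",
    group: str = "",
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one electrode pass and return it with its ground truth."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))
    depths, labels = trajectory_depths(cfg)
    sites = [simulate_site(d, s, cfg, rng) for d, s in zip(depths, labels)]
    traj = Trajectory(
        sites=sites,
        trajectory_id=trajectory_id,
        group=group,
        meta={"config": cfg.__dict__.copy()},
    )
    gt = GroundTruth(
        entry_depth=cfg.entry_depth,
        dlor_exit_depth=_round_grid(cfg.dlor_exit_depth),
        exit_depth=cfg.exit_depth,
        labels=labels,
    )
    return traj, gt


def _jittered(cfg: SimConfig, rng: np.random.Generator) -> SimConfig:
    """Per-trajectory variability: uniform border jitter, log-normal rates."""
    j = cfg.entry_exit_jitter
    min_len = max(1.0, 4 * cfg.in_stn_step)
    for _ in range(100):
        entry = cfg.entry_depth + rng.uniform(-j, j)
        exit_ = cfg.exit_depth + rng.uniform(-j, j)
        baseline_end = cfg.start_depth - (cfg.n_baseline_sites - 1) * BASELINE_STEP
        if baseline_end - 0.1 > entry and entry - exit_ >= min_len:
            break
    else:  # pragma: no cover - only reachable with extreme jitter settings
        entry, exit_ = cfg.entry_depth, cfg.exit_depth
    sigma = math.sqrt(math.log(1.0 + cfg.rate_cv**2))
    mult = rng.lognormal(-0.5 * sigma**2, sigma, size=2)
    return replace(
        cfg,
        entry_depth=_round_grid(entry),
        exit_depth=_round_grid(exit_),
        unit_rate_stn=cfg.unit_rate_stn * mult[0],
        unit_rate_baseline=cfg.unit_rate_baseline * mult[1],
    )


def simulate_cohort(
    n_pd: int,
    n_et: int,
    cfg_pd: SimConfig | None = None,
    cfg_et: SimConfig | None = None,
    seed: int = 0,
) -> list[tuple[Trajectory, GroundTruth, str]]:
    """Simulate a labelled cohort of PD-like and ET-like trajectories.

    Each trajectory gets independent border jitter (uniform, +/-
    ``entry_exit_jitter`` mm) and firing-rate jitter (log-normal,
    ``rate_cv`` coefficient of variation). PD-like passes carry the
    beta-band rate modulation; ET-like passes have none.
    """
    if n_pd < 1 or n_et < 1:
        raise ValueError("need at least one trajectory per group")
    cfg_pd = pd_config() if cfg_pd is None else cfg_pd
    cfg_et = et_config() if cfg_et is None else cfg_et
    ss = np.random.SeedSequence(seed)
    out: list[tuple[Trajectory, GroundTruth, str]] = []
    specs = [("PD", cfg_pd)] * n_pd + [("ET", cfg_et)] * n_et
    for i, ((label, cfg), child) in enumerate(zip(specs, ss.spawn(len(specs)))):
        rng = np.random.default_rng(child)
        tcfg = _jittered(cfg, rng)
        traj, gt = simulate_trajectory(
            tcfg, rng, trajectory_id=f"{label.lower()}{i:03d}", group=label
        )
        out.append((traj, gt, label))
    return out


def pd_config(**overrides) -> SimConfig:
    """PD-like defaults: 6 mm STN, ~57% DLOR, strong beta modulation."""
    base = dict(
        entry_depth=4.0, exit_depth=-2.0, dlor_fraction=0.571,
        stn_noise_gain=2.0, beta_mod_depth=0.8,
    )
    base.update(overrides)
    return SimConfig(**base)


def et_config(**overrides) -> SimConfig:
    """ET-like defaults: 4.6 mm STN, ~55% DLOR, no beta modulation,
    weaker noise step-up (attenuated regional spiking activity)."""
    base = dict(
        entry_depth=3.0, exit_depth=-1.6, dlor_fraction=0.554,
        stn_noise_gain=1.5, beta_mod_depth=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def compact_config(base: SimConfig, *, stn_length: float = 2.0,
                   in_stn_step: float = 0.2) -> SimConfig:
    """Shrink a configuration for replicate-heavy simulation studies.

    Keeps the signal model (noise step, rates, modulation) but uses the
    minimum sampling rate, 3 s sites (the shortest supporting 1/3 Hz
    spectral bins), a shorter STN and a coarser in-STN grid. The track
    still covers a half-length pre-entrance segment plus the baseline.
    """
    entry = stn_length / 2.0
    exit_ = -stn_length / 2.0
    start = entry + stn_length / 2.0 + 0.4 + base.n_baseline_sites * 0.1
    return replace(
        base,
        sampling_rate=MIN_SAMPLING_RATE,
        site_duration=3.0,
        start_depth=_round_grid(start),
        entry_depth=entry,
        exit_depth=exit_,
        in_stn_step=in_stn_step,
        post_extent=0.8,
        entry_exit_jitter=0.2,
    )
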