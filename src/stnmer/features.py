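"""Per-site spiking-band features: RMS, NRMS, and envelope spectra.

The processing chain per site is:

1. zero-phase band-pass to the spiking band (300-6000 Hz);
2. RMS of the band-passed trace; per-trajectory normalization (NRMS) to
   the mean RMS of the first baseline sites (internal capsule);
3. full-wave rectification (absolute value), decimation to a 1 kHz
   envelope rate, mean removal, and a Welch spectrum with 1/3 Hz bins,
   expressed as fractions of total power so every site's spectrum sums
   to one and is independent of absolute signal amplitude;
4. band fractions (delta/theta/alpha/beta/gamma/tremor) as sums of the
   normalized spectrum over each band's bins.

Because the spectrum is normalized per site, all spectral quantities
are invariant to raw-voltage scaling; only the NRMS carries the (also
normalized) amplitude information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import SiteRecording, Trajectory

__all__ = [
    "DEFAULT_BANDS",
    "FeatureConfig",
    "SiteFeatures",
    "TrajectoryProfile",
    "bandpass_spiking",
    "compute_rms",
    "normalize_rms",
    "envelope_psd",
    "band_fraction",
    "beta_timeseries",
    "featurize_trajectory",
]

#: Conventional band edges (Hz) on the 1 kHz envelope; half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 100.0),
    "tremor": (6.0, 12.0),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Shared configuration for per-site feature extraction."""

    bp_low: float = 300.0          # Hz, spiking-band lower edge
    bp_high: float = 6000.0        # Hz, spiking-band upper edge
    envelope_fs: float = 1000.0    # Hz, rectified-envelope rate after decimation
    resolution: float = 1.0 / 3.0  # Hz, spectral bin width
    n_baseline: int = 5            # sites averaged for the NRMS denominator
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )


@dataclass
class SiteFeatures:
    """Features of one site: RMS, NRMS and the normalized envelope PSD."""

    depth: float
    rms: float
    nrms: float
    psd_freqs: np.ndarray
    psd_fractions: np.ndarray
    band_fractions: dict[str, float]


@dataclass
class TrajectoryProfile:
    """Per-site features stacked along depth for one electrode pass."""

    sites: list[SiteFeatures]
    baseline_rms: float
    subject: str = ""
    side: str = ""
    group: str = ""
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("profile must contain at least one site")
        if not np.all(np.diff(self.depths) < 0):
            raise ValueError("site depths must be strictly decreasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.sites])

    @property
    def nrms(self) -> np.ndarray:
        return np.array([s.nrms for s in self.sites])

    @property
    def psd_freqs(self) -> np.ndarray:
        return self.sites[0].psd_freqs

    @property
    def psd_matrix(self) -> np.ndarray:
        """Sites x frequency-bins matrix of power fractions."""
        return np.vstack([s.psd_fractions for s in self.sites])

    def band(self, name: str) -> np.ndarray:
        return np.array([s.band_fractions[name] for s in self.sites])

    def __len__(self) -> int:
        return len(self.sites)


def bandpass_spiking(
    rec: SiteRecording | np.ndarray,
    low: float = 300.0,
    high: float = 6000.0,
    fs: float | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass to the spiking band.

    Accepts a :class:`SiteRecording` or a raw array (then ``fs`` is
    required). The filter is a 4-pole Butterworth applied forward and
    backward, so the output has no phase distortion and the effective
    stop-band attenuation is doubled.
    """
    if isinstance(rec, SiteRecording):
        x, fs = rec.samples, rec.sampling_rate
    else:
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
        x = np.asarray(rec, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band edges ({low}, {high}) Hz inconsistent with fs={fs} Hz"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_rms(x: np.ndarray) -> float:
    """Root mean square of a sample sequence."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty sequence")
    return float(np.sqrt(np.mean(np.square(x))))


def normalize_rms(
    rms_by_site: list[tuple[float, float]],
    n_baseline: int = 5,
) -> list[tuple[float, float]]:
    """Normalize per-site RMS to the mean of the first baseline sites.

    The baseline sites are the first ``n_baseline`` (shallowest) sites
    of the pass, recorded 0.1 mm apart in the internal capsule before
    the STN. By construction the mean NRMS over those sites is 1.
    """
    if len(rms_by_site) < n_baseline:
        raise ValueError(
            f"need at least {n_baseline} sites, got {len(rms_by_site)}"
        )
    base = np.array([r for _, r in rms_by_site[:n_baseline]], dtype=float)
    if np.any(base <= 0):
        raise ValueError("baseline RMS values must be positive")
    mean_base = float(base.mean())
    return [(d, r / mean_base) for d, r in rms_by_site]


def rectified_envelope(
    filtered: np.ndarray, fs: float, envelope_fs: float = 1000.0
) -> np.ndarray:
    """Full-wave rectified multi-unit envelope, resampled to ``envelope_fs``.

    The rectified spiking-band signal carries the firing-density
    envelope; its oscillatory content of interest lies well below
    200 Hz, so the envelope is polyphase-resampled to 1 kHz before
    spectral analysis.
    """
    env = np.abs(np.asarray(filtered, dtype=float))
    if fs == envelope_fs:
        return env
    frac = Fraction(envelope_fs / fs).limit_denominator(10000)
    return signal.resample_poly(env, frac.numerator, frac.denominator)


def envelope_psd(
    filtered: np.ndarray,
    fs: float,
    resolution: float = 1.0 / 3.0,
    envelope_fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized power spectrum of the rectified spiking-band envelope.

    The envelope mean (the large DC component of a rectified signal,
    which carries no oscillation information) is removed before the
    Welch estimate, so the 0 Hz bin does not dominate the
    normalization. Windows are ``1/resolution`` seconds of Hamming with
    1 s hops (two windows for a 4 s site), giving bins of exactly
    ``resolution`` Hz. The spectrum is returned as fractions of total
    power: ``fractions.sum() == 1``.
    """
    env = rectified_envelope(filtered, fs, envelope_fs)
    nperseg = round(envelope_fs / resolution)
    if env.size < nperseg:
        raise ValueError(
            f"trace too short: {env.size / envelope_fs:.2f} s envelope, "
            f"need >= {1 / resolution:.2f} s for {resolution:.3g} Hz bins"
        )
    env = env - env.mean()
    hop = round(envelope_fs)  # 1 s hop between windows
    freqs, pxx = signal.welch(
        env,
        fs=envelope_fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=max(nperseg - hop, 0),
        detrend="constant",
    )
    total = pxx.sum()
    if total <= 0:
        # an identically-zero trace has no power to distribute
        return freqs, np.zeros_like(pxx)
    return freqs, pxx / total


def band_fraction(
    freqs: np.ndarray, fractions: np.ndarray, band: tuple[float, float]
) -> float:
    """Sum of power fractions over bins with ``low <= f < high``."""
    low, high = band
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(fractions[mask].sum())


def beta_timeseries(
    filtered: np.ndarray,
    fs: float,
    band: tuple[float, float] = (13.0, 30.0),
    envelope_fs: float = 1000.0,
) -> np.ndarray:
    """Beta-band component of the rectified envelope.

    Four-pole Butterworth band-pass (13-30 Hz) applied forward-backward
    to the mean-removed rectified envelope at ``envelope_fs``.
    """
    if envelope_fs < 100.0:
        raise ValueError("envelope rate must be >= 100 Hz")
    env = rectified_envelope(filtered, fs, envelope_fs)
    env = env - env.mean()
    sos = signal.butter(2, band, btype="bandpass", fs=envelope_fs, output="sos")
    return signal.sosfiltfilt(sos, env)


def featurize_site(rec: SiteRecording, cfg: FeatureConfig) -> SiteFeatures:
    """Features of a single site; NRMS is filled in at trajectory level."""
    filtered = bandpass_spiking(rec, cfg.bp_low, cfg.bp_high)
    rms = compute_rms(filtered)
    freqs, fractions = envelope_psd(
        filtered, rec.sampling_rate, cfg.resolution, cfg.envelope_fs
    )
    bands = {
        name: band_fraction(freqs, fractions, edges)
        for name, edges in cfg.bands.items()
    }
    return SiteFeatures(
        depth=rec.depth,
        rms=rms,
        nrms=np.nan,
        psd_freqs=freqs,
        psd_fractions=fractions,
        band_fractions=bands,
    )


def _featurize_batch(traj: Trajectory, cfg: FeatureConfig) -> list[SiteFeatures]:
    """Vectorized feature extraction when all sites share fs and length.

    Applies the identical chain as :func:`featurize_site` along axis 1
    of a sites x samples matrix; produces the same numbers, just with
    far less per-site overhead.
    """
    fs = traj.sampling_rate
    x = np.vstack([rec.samples for rec in traj.sites])
    sos = signal.butter(2, [cfg.bp_low, cfg.bp_high], btype="bandpass",
                        fs=fs, output="sos")
    # row-wise: sosfiltfilt's own n-D path is far slower than this loop
    filtered = np.empty_like(x)
    for i in range(x.shape[0]):
        filtered[i] = signal.sosfiltfilt(sos, x[i])
    rms = np.sqrt(np.mean(np.square(filtered), axis=1))
    env = np.abs(filtered)
    if fs != cfg.envelope_fs:
        frac = Fraction(cfg.envelope_fs / fs).limit_denominator(10000)
        env = signal.resample_poly(env, frac.numerator, frac.denominator, axis=1)
    env = env - env.mean(axis=1, keepdims=True)
    nperseg = round(cfg.envelope_fs / cfg.resolution)
    if env.shape[1] < nperseg:
        raise ValueError("trace too short for the requested spectral resolution")
    hop = round(cfg.envelope_fs)
    freqs, pxx = signal.welch(
        env, fs=cfg.envelope_fs, window="hamming", nperseg=nperseg,
        noverlap=max(nperseg - hop, 0), detrend="constant", axis=1,
    )
    totals = pxx.sum(axis=1, keepdims=True)
    totals[totals <= 0] = 1.0
    fractions = pxx / totals
    masks = {
        name: (freqs >= lo) & (freqs < hi) for name, (lo, hi) in cfg.bands.items()
    }
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"band {cfg.bands[name]} contains no frequency bins")
    feats = []
    for i, rec in enumerate(traj.sites):
        bands = {name: float(fractions[i, m].sum()) for name, m in masks.items()}
        feats.append(
            SiteFeatures(
                depth=rec.depth, rms=float(rms[i]), nrms=np.nan,
                psd_freqs=freqs, psd_fractions=fractions[i],
                band_fractions=bands,
            )
        )
    return feats


def featurize_trajectory(
    traj: Trajectory, cfg: FeatureConfig | None = None
) -> TrajectoryProfile:
    """Compute per-site features for a whole pass with one shared config."""
    cfg = cfg or FeatureConfig()
    lengths = {rec.samples.size for rec in traj.sites}
    rates = {rec.sampling_rate for rec in traj.sites}
    if len(lengths) == 1 and len(rates) == 1:
        feats = _featurize_batch(traj, cfg)
    else:
        feats = [featurize_site(rec, cfg) for rec in traj.sites]
    rms_by_site = [(f.depth, f.rms) for f in feats]
    normalized = normalize_rms(rms_by_site, cfg.n_baseline)
    for f, (_, nrms) in zip(feats, normalized):
        f.nrms = nrms
    baseline_rms = float(
        np.mean([f.rms for f in feats[: cfg.n_baseline]])
    )
    return TrajectoryProfile(
        sites=feats,
        baseline_rms=baseline_rms,
        subject=traj.subject,
        side=traj.side,
        group=traj.group,
        trajectory_id=traj.trajectory_id,
    )
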