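"""Core in-memory containers for depth-stamped microelectrode recordings.

A *site* is a single ~4 s voltage trace recorded at one depth along an
electrode pass; a *trajectory* is the ordered sequence of sites from
~10 mm above the surgical target plane down through (and past) the STN.
Depths are signed millimetres above the target plane and strictly
decrease along a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SiteRecording", "Trajectory"]

#: Minimum sampling rate (Hz) keeping the 6 kHz spiking-band edge below Nyquist.
MIN_SAMPLING_RATE = 12500.0


@dataclass
class SiteRecording:
    """One depth-stamped raw voltage trace from one microelectrode site.

    Parameters
    ----------
    depth : float
        Signed depth in mm above the planned target (negative = below).
    sampling_rate : float
        Sampling rate in Hz; must be >= 12.5 kHz so the 300-6000 Hz
        spiking band fits below Nyquist.
    samples : ndarray
        Raw voltage samples, arbitrary units.
    """

    depth: float
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sampling_rate < MIN_SAMPLING_RATE:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz below the minimum "
                f"{MIN_SAMPLING_RATE} Hz required for the 300-6000 Hz band"
            )

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass
class Trajectory:
    """Ordered site recordings for one electrode pass plus metadata.

    Sites are ordered by strictly decreasing depth (the electrode
    advances downward). ``group`` is a cohort label such as ``"PD"`` or
    ``"ET"``; group membership is always an input, never inferred.
    """

    sites: list[SiteRecording]
    subject: str = ""
    side: str = ""
    group: str = ""
    trajectory_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("trajectory must contain at least one site")
        depths = self.depths
        if not np.all(np.diff(depths) < 0):
            raise ValueError("site depths must be strictly decreasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.sites])

    @property
    def sampling_rate(self) -> float:
        return self.sites[0].sampling_rate

    def __len__(self) -> int:
        return len(self.sites)
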