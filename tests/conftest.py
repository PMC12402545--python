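import numpy as np
import pytest

import stnmer as sm
from stnmer.features import DEFAULT_BANDS, SiteFeatures, TrajectoryProfile


def make_profile(
    depths,
    nrms=None,
    band_fracs=None,
    n_bins=301,
    trajectory_id="synthetic-profile",
    group="",
):
    """Hand-constructed TrajectoryProfile for metric/segmentation tests.

    ``band_fracs`` maps band name -> per-site values; unspecified bands
    get a flat remainder. The per-site PSD is built so each requested
    band's bins sum exactly to the requested fraction (bins at 1/3 Hz
    from 0 to 100 Hz).
    """
    depths = np.asarray(depths, dtype=float)
    n = len(depths)
    nrms = np.ones(n) if nrms is None else np.asarray(nrms, dtype=float)
    freqs = np.arange(n_bins) / 3.0
    band_fracs = band_fracs or {}
    sites = []
    for i in range(n):
        fractions = np.zeros(n_bins)
        assigned = 0.0
        masks = []
        for name, values in band_fracs.items():
            lo, hi = DEFAULT_BANDS[name]
            mask = (freqs >= lo) & (freqs < hi)
            fractions[mask] = values[i] / mask.sum()
            assigned += values[i]
            masks.append(mask)
        rest = ~np.logical_or.reduce(masks) if masks else np.ones(n_bins, bool)
        fractions[rest] = (1.0 - assigned) / rest.sum()
        bands = {
            name: float(fractions[(freqs >= lo) & (freqs < hi)].sum())
            for name, (lo, hi) in DEFAULT_BANDS.items()
        }
        sites.append(
            SiteFeatures(
                depth=float(depths[i]),
                rms=float(nrms[i]),
                nrms=float(nrms[i]),
                psd_freqs=freqs,
                psd_fractions=fractions,
                band_fractions=bands,
            )
        )
    return TrajectoryProfile(
        sites=sites, baseline_rms=1.0, trajectory_id=trajectory_id, group=group
    )


@pytest.fixture(scope="session")
def compact_pd_cfg():
    return sm.compact_config(sm.pd_config())


@pytest.fixture(scope="session")
def compact_et_cfg():
    return sm.compact_config(sm.et_config())


@pytest.fixture(scope="session")
def pd_sim(compact_pd_cfg):
    """One simulated PD-like pass (trajectory, ground truth)."""
    return sm.simulate_trajectory(compact_pd_cfg, 1)


@pytest.fixture(scope="session")
def pd_profile(pd_sim):
    traj, _ = pd_sim
    return sm.featurize_trajectory(traj)
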