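"""HDF5 trajectory container and flat CSV tables.

No standard on-disk format exists for depth-sequenced microelectrode
recordings (vendor formats are proprietary), so trajectories are stored
in a small documented HDF5 schema::

    /                       attrs: schema_version
    /trajectories/<id>/     attrs: subject, side, group, sampling_rate, ...
        depths              (n_sites,) mm above target, strictly decreasing
        traces              (n_sites, n_samples) raw voltage
        features/           optional derived datasets (loadable without traces)
            rms, nrms       (n_sites,)
            psd_freqs       (n_bins,)
            psd_fractions   (n_sites, n_bins)

All flat outputs (features, segmentations, metrics, comparisons) are
plain CSV so they can be consumed outside Python.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SiteRecording, Trajectory
from .features import TrajectoryProfile
from .segmentation import Segmentation
from .stats import ComparisonResult

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "attach_features",
    "read_features",
    "features_frame",
    "write_features_csv",
    "segmentations_frame",
    "write_segmentations_csv",
    "comparisons_frame",
    "ground_truth_frame",
]

SCHEMA_VERSION = "stnmer-1"


def _traj_key(traj: Trajectory, index: int) -> str:
    if traj.trajectory_id:
        return traj.trajectory_id
    side = f"_{traj.side}" if traj.side else ""
    subject = traj.subject or f"traj{index:03d}"
    return f"{subject}{side}"


def write_container(path, trajectories: list[Trajectory]) -> None:
    """Write trajectories to an HDF5 container (round-trip safe)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        root = f.create_group("trajectories")
        for i, traj in enumerate(trajectories):
            key = _traj_key(traj, i)
            if key in root:
                raise ValueError(f"duplicate trajectory key {key!r}")
            g = root.create_group(key)
            g.attrs["subject"] = traj.subject
            g.attrs["side"] = traj.side
            g.attrs["group"] = traj.group
            g.attrs["sampling_rate"] = traj.sampling_rate
            if traj.meta:
                g.attrs["meta_json"] = json.dumps(traj.meta, default=str)
            g.create_dataset("depths", data=traj.depths)
            traces = np.vstack([s.samples for s in traj.sites])
            g.create_dataset("traces", data=traces, compression="gzip", shuffle=True)


def read_container(path) -> list[Trajectory]:
    """Read trajectories back from an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unknown container schema version {version!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        out = []
        for key in sorted(f["trajectories"]):
            g = f["trajectories"][key]
            if "sampling_rate" not in g.attrs:
                raise ValueError(f"trajectory {key!r} is missing sampling_rate")
            fs = float(g.attrs["sampling_rate"])
            depths = g["depths"][...]
            traces = g["traces"][...]
            sites = [
                SiteRecording(depth=float(d), sampling_rate=fs, samples=t)
                for d, t in zip(depths, traces)
            ]
            meta = json.loads(g.attrs["meta_json"]) if "meta_json" in g.attrs else {}
            out.append(
                Trajectory(
                    sites=sites,
                    subject=str(g.attrs.get("subject", "")),
                    side=str(g.attrs.get("side", "")),
                    group=str(g.attrs.get("group", "")),
                    trajectory_id=key,
                    meta=meta,
                )
            )
        return out


def attach_features(path, profiles: list[TrajectoryProfile]) -> None:
    """Store derived per-site features next to the raw traces."""
    with h5py.File(path, "r+") as f:
        for prof in profiles:
            g = f["trajectories"][prof.trajectory_id]
            if "features" in g:
                del g["features"]
            feat = g.create_group("features")
            feat.create_dataset("rms", data=[s.rms for s in prof.sites])
            feat.create_dataset("nrms", data=prof.nrms)
            feat.create_dataset("psd_freqs", data=prof.psd_freqs)
            feat.create_dataset("psd_fractions", data=prof.psd_matrix)
            feat.attrs["baseline_rms"] = prof.baseline_rms


def read_features(path, trajectory_id: str) -> dict[str, np.ndarray]:
    """Load derived features without touching the raw traces."""
    with h5py.File(path, "r") as f:
        g = f["trajectories"][trajectory_id]
        if "features" not in g:
            raise KeyError(f"no derived features stored for {trajectory_id!r}")
        feat = g["features"]
        return {
            "depths": g["depths"][...],
            "rms": feat["rms"][...],
            "nrms": feat["nrms"][...],
            "psd_freqs": feat["psd_freqs"][...],
            "psd_fractions": feat["psd_fractions"][...],
        }


def features_frame(profiles: list[TrajectoryProfile]) -> pd.DataFrame:
    """One row per site: id, depth, rms, nrms and each band fraction."""
    rows = []
    for prof in profiles:
        for s in prof.sites:
            row = {
                "trajectory_id": prof.trajectory_id,
                "group": prof.group,
                "depth_mm": s.depth,
                "rms": s.rms,
                "nrms": s.nrms,
            }
            for band, value in s.band_fractions.items():
                row[f"frac_{band}"] = value
            rows.append(row)
    return pd.DataFrame(rows)


def write_features_csv(path, profiles: list[TrajectoryProfile]) -> None:
    features_frame(profiles).to_csv(path, index=False)


def segmentations_frame(
    segs: dict[str, Segmentation]
) -> pd.DataFrame:
    rows = [
        {
            "trajectory_id": tid,
            "entry_mm": seg.entry_depth,
            "dlor_exit_mm": seg.dlor_exit_depth,
            "exit_mm": seg.exit_depth,
            "source": seg.source,
            "degenerate": seg.degenerate,
        }
        for tid, seg in segs.items()
    ]
    return pd.DataFrame(rows)


def write_segmentations_csv(path, segs: dict[str, Segmentation]) -> None:
    segmentations_frame(segs).to_csv(path, index=False)


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric,
            "test": r.test,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "alpha": r.alpha,
            "adjusted_alpha": r.adjusted_alpha,
            "significant": r.significant,
            "significant_adjusted": r.significant_adjusted,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def ground_truth_frame(cohort) -> pd.DataFrame:
    """Ground-truth sidecar table for a simulated cohort."""
    rows = [
        {
            "trajectory_id": traj.trajectory_id,
            "entry_mm": gt.entry_depth,
            "dlor_exit_mm": gt.dlor_exit_depth,
            "exit_mm": gt.exit_depth,
            "group": label,
        }
        for traj, gt, label in cohort
    ]
    return pd.DataFrame(rows)
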