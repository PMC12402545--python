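"""Cohort-level validation studies on synthetic data.

Each study exercises the full analysis chain on simulated cohorts and
returns summary numbers: spectral-peak recovery, STN border recovery,
PD-vs-ET beta-ratio discrimination, null calibration of the group
comparison, and the end-to-end demo cohort. They are used both by the
test suite and by the reproduction script.

Problem sizes are chosen to keep Monte-Carlo studies tractable on one
CPU: replicate-heavy studies run on ``compact_config`` trajectories
(12.5 kHz, 3 s sites, short STN), which preserve the signal model while
shrinking the per-trajectory cost; the border-recovery study keeps the
default trajectory geometry and contrast at the reduced sampling rate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .containers import MIN_SAMPLING_RATE
from .features import FeatureConfig, bandpass_spiking, envelope_psd, featurize_trajectory
from .metrics import beta_ratio, compute_trajectory_metrics
from .segmentation import segment_profile, segmentation_from_ground_truth
from .stats import compare
from .synthetic import (
    SimConfig,
    compact_config,
    et_config,
    pd_config,
    simulate_cohort,
    simulate_site,
    simulate_trajectory,
)

__all__ = [
    "beta_peak_recovery",
    "border_recovery",
    "beta_ratio_discrimination",
    "null_calibration",
    "length_recovery",
    "demo_cohort",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def beta_peak_recovery(
    n_seeds: int = 50,
    seed: int = 0,
    mod_freq: float = 20.0,
    mod_depth: float = 0.8,
) -> dict[str, float]:
    """Recover an injected envelope-modulation frequency from the PSD.

    Simulates DLOR sites (4 s at 44 kHz) whose multi-unit rate is
    modulated at ``mod_freq`` with depth ``mod_depth``, and locates the
    argmax of the normalized envelope spectrum over 5-45 Hz. Reports
    the median absolute error in 1/3 Hz bins and the within-one-bin
    hit rate.
    """
    cfg = SimConfig(beta_mod_depth=mod_depth, beta_freq=mod_freq)
    resolution = 1.0 / 3.0
    errors_bins = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        rec = simulate_site(0.5, "DLOR", cfg, rng)
        filt = bandpass_spiking(rec)
        freqs, fracs = envelope_psd(filt, cfg.sampling_rate, resolution)
        sel = (freqs >= 5.0) & (freqs <= 45.0)
        peak = freqs[sel][np.argmax(fracs[sel])]
        errors_bins.append(abs(peak - mod_freq) / resolution)
    errors_bins = np.array(errors_bins)
    return {
        "median_bin_error": float(np.median(errors_bins)),
        "hit_rate_within_1_bin": float(np.mean(errors_bins <= 1.0 + 1e-9)),
        "n_seeds": n_seeds,
    }


def _scaled_default(cfg: SimConfig) -> SimConfig:
    """Default geometry and contrast at the reduced sampling cost."""
    return replace(cfg, sampling_rate=MIN_SAMPLING_RATE, site_duration=3.0)


def border_recovery(n_traj: int = 50, seed: int = 0,
                    et_like: bool = False) -> dict[str, float]:
    """STN border detection errors on default-contrast trajectories.

    Simulates trajectories with the default geometry (entry 4 mm, exit
    -2 mm, 0.1 mm in-STN grid) and contrast, runs the detector, and
    reports median absolute entry/DLOR-exit/exit errors in mm.
    """
    cfg = _scaled_default(et_config() if et_like else pd_config())
    if et_like:
        cfg = replace(cfg, entry_depth=4.0, exit_depth=-2.0)
    errs = {"entry": [], "dlor_exit": [], "exit": []}
    for s in _child_seeds(seed, n_traj):
        traj, gt = simulate_trajectory(cfg, int(s))
        prof = featurize_trajectory(traj)
        seg = segment_profile(prof)
        errs["entry"].append(abs(seg.entry_depth - gt.entry_depth))
        errs["dlor_exit"].append(abs(seg.dlor_exit_depth - gt.dlor_exit_depth))
        errs["exit"].append(abs(seg.exit_depth - gt.exit_depth))
    return {
        "entry_median_error_mm": float(np.median(errs["entry"])),
        "dlor_exit_median_error_mm": float(np.median(errs["dlor_exit"])),
        "exit_median_error_mm": float(np.median(errs["exit"])),
        "n_trajectories": n_traj,
    }


def _cohort_beta_ratios(
    n_per_group: int, cfg_a: SimConfig, cfg_b: SimConfig, seed: int,
    feature_cfg: FeatureConfig,
) -> tuple[list[float], list[float]]:
    cohort = simulate_cohort(n_per_group, n_per_group, cfg_a, cfg_b, seed=seed)
    ratios: dict[str, list[float]] = {"PD": [], "ET": []}
    for traj, gt, label in cohort:
        prof = featurize_trajectory(traj, feature_cfg)
        seg = segmentation_from_ground_truth(prof, gt)
        ratios[label].append(beta_ratio(prof, seg))
    return ratios["PD"], ratios["ET"]


def beta_ratio_discrimination(
    n_reps: int = 100, n_per_group: int = 20, seed: int = 0,
) -> dict[str, float]:
    """PD-like vs ET-like beta-ratio separation over replicate cohorts.

    Each replicate simulates ``n_per_group`` PD-like (beta modulation
    0.8) and ET-like (no modulation) compact trajectories, computes
    per-trajectory beta ratios under ground-truth borders, and runs the
    two-sided Mann-Whitney comparison. Reports the fraction of
    replicates significant at 0.05 and the pooled group medians.
    """
    cfg_pd = compact_config(pd_config(), stn_length=1.6, in_stn_step=0.4)
    cfg_et = compact_config(et_config(), stn_length=1.6, in_stn_step=0.4)
    fcfg = FeatureConfig()
    n_sig = 0
    pd_all: list[float] = []
    et_all: list[float] = []
    for s in _child_seeds(seed, n_reps):
        pd_r, et_r = _cohort_beta_ratios(n_per_group, cfg_pd, cfg_et, int(s), fcfg)
        res = compare(pd_r, et_r, test="mann_whitney_u")
        n_sig += res.p_value < 0.05
        pd_all.extend(pd_r)
        et_all.extend(et_r)
    return {
        "significant_fraction": n_sig / n_reps,
        "pd_median_beta_ratio": float(np.median(pd_all)),
        "et_median_beta_ratio": float(np.median(et_all)),
        "n_replicates": n_reps,
        "n_per_group": n_per_group,
    }


def null_calibration(
    n_reps: int = 500, n_per_group: int = 10, seed: int = 0,
) -> dict[str, float]:
    """Type-I error of the beta-ratio comparison under the null.

    Both groups are ET-like (no beta modulation), on further-shortened
    compact trajectories (1.6 mm STN, 0.4 mm steps), so any rejection
    is a false positive. Reports the rejection rate at alpha = 0.05
    and its binomial standard error.
    """
    cfg = compact_config(et_config(), stn_length=1.6, in_stn_step=0.4)
    fcfg = FeatureConfig()
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        a, b = _cohort_beta_ratios(n_per_group, cfg, cfg, int(s), fcfg)
        res = compare(a, b, test="mann_whitney_u")
        rejections += res.p_value < 0.05
    rate = rejections / n_reps
    return {
        "rejection_rate": rate,
        "binomial_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
        "n_replicates": n_reps,
        "n_per_group": n_per_group,
    }


def length_recovery(n_per_group: int = 20, seed: int = 0) -> dict[str, float]:
    """Recorded STN/DLOR lengths under detected borders, default geometry.

    Simulates a cohort with the default trajectory geometry (6 mm
    PD-like / 4.6 mm ET-like STN with border jitter), detects borders,
    and reports the per-group median recorded lengths and percent DLOR.
    """
    cfg_pd = _scaled_default(pd_config())
    cfg_et = _scaled_default(et_config())
    cohort = simulate_cohort(n_per_group, n_per_group, cfg_pd, cfg_et, seed=seed)
    out: dict[str, list[float]] = {}
    for traj, _, label in cohort:
        prof = featurize_trajectory(traj)
        seg = segment_profile(prof)
        if seg.degenerate:
            continue
        from .segmentation import stn_lengths

        stn, dlor, pct = stn_lengths(seg)
        out.setdefault(f"{label}_stn", []).append(stn)
        out.setdefault(f"{label}_dlor", []).append(dlor)
        out.setdefault(f"{label}_pct", []).append(pct)
    return {
        "pd_median_stn_length_mm": float(np.median(out["PD_stn"])),
        "et_median_stn_length_mm": float(np.median(out["ET_stn"])),
        "pd_median_dlor_length_mm": float(np.median(out["PD_dlor"])),
        "et_median_dlor_length_mm": float(np.median(out["ET_dlor"])),
        "pd_median_percent_dlor": float(np.median(out["PD_pct"])),
        "et_median_percent_dlor": float(np.median(out["ET_pct"])),
        "n_per_group": n_per_group,
    }


def demo_cohort(seed: int = 7, n_per_group: int = 20) -> dict[str, float]:
    """End-to-end demo: detected borders, metrics and group comparisons.

    Simulates the demo cohort (PD-like with stronger STN noise gain),
    detects borders, computes all per-trajectory metrics and the
    group comparisons, and returns the headline numbers.
    """
    cfg_pd = compact_config(pd_config())
    cfg_et = compact_config(et_config())
    cohort = simulate_cohort(n_per_group, n_per_group, cfg_pd, cfg_et, seed=seed)
    rows: dict[str, list] = {"PD": [], "ET": []}
    for traj, gt, label in cohort:
        prof = featurize_trajectory(traj)
        seg = segment_profile(prof)
        if seg.degenerate:
            continue
        rows[label].append(compute_trajectory_metrics(prof, seg))

    def med(group: str, attr: str) -> float:
        return float(np.median([getattr(m, attr) for m in rows[group]]))

    def med_band(group: str, band: str) -> float:
        return float(np.median([m.mean_band_power[band] for m in rows[group]]))

    def pval(metric_fn) -> float:
        a = [metric_fn(m) for m in rows["PD"]]
        b = [metric_fn(m) for m in rows["ET"]]
        return compare(a, b, test="mann_whitney_u").p_value

    return {
        "pd_median_beta_ratio": med("PD", "beta_ratio"),
        "et_median_beta_ratio": med("ET", "beta_ratio"),
        "pd_median_beta_power": med_band("PD", "beta"),
        "et_median_beta_power": med_band("ET", "beta"),
        "pd_median_nrms_peak": med("PD", "nrms_peak"),
        "et_median_nrms_peak": med("ET", "nrms_peak"),
        "pd_median_nrms_auc": med("PD", "nrms_auc"),
        "et_median_nrms_auc": med("ET", "nrms_auc"),
        "beta_ratio_p": pval(lambda m: m.beta_ratio),
        "beta_power_p": pval(lambda m: m.mean_band_power["beta"]),
        "nrms_peak_p": pval(lambda m: m.nrms_peak),
        "nrms_auc_p": pval(lambda m: m.nrms_auc),
        "delta_power_p": pval(lambda m: m.mean_band_power["delta"]),
        "theta_power_p": pval(lambda m: m.mean_band_power["theta"]),
        "n_pd": len(rows["PD"]),
        "n_et": len(rows["ET"]),
    }
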