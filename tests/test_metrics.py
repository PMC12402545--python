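"""Depth normalization, group averaging and per-trajectory metrics."""

import numpy as np
import pytest

import stnmer as sm
from stnmer.metrics import (
    beta_ratio,
    group_average,
    mean_band_power,
    normalize_depths,
    nrms_peak_auc,
)
from stnmer.segmentation import Segmentation, apply_manual_segmentation

from conftest import make_profile


def _profile_and_seg(nrms_fn=None, band_fracs=None, entry=4.0, dlor_exit=1.0,
                     exit_=-2.0):
    depths = np.round(np.arange(7.0, -3.01, -0.25), 6)
    nrms = np.ones(depths.size) if nrms_fn is None else nrms_fn(depths)
    prof = make_profile(depths, nrms=nrms, band_fracs=band_fracs)
    seg = apply_manual_segmentation(prof, entry, dlor_exit, exit_)
    return prof, seg


class TestNormalizeDepths:
    def test_coordinate_arithmetic(self):
        prof, seg = _profile_and_seg()
        x = (seg.entry_depth - prof.depths) / (seg.entry_depth - seg.exit_depth)
        site = np.flatnonzero(prof.depths == 1.0)[0]
        assert x[site] == pytest.approx(0.5)
        start = np.flatnonzero(prof.depths == 7.0)[0]
        assert x[start] == pytest.approx(-0.5)

    def test_linear_interpolation_identity(self):
        # piecewise-linear NRMS in depth is reproduced exactly on the grid
        prof, seg = _profile_and_seg(nrms_fn=lambda d: 2.0 + 0.3 * d)
        norm = normalize_depths(prof, seg)
        expected_depth = seg.entry_depth - norm.grid * (
            seg.entry_depth - seg.exit_depth
        )
        assert np.allclose(norm.nrms_values, 2.0 + 0.3 * expected_depth, atol=1e-12)

    def test_no_extrapolation_outside_coverage(self):
        prof, seg = _profile_and_seg(exit_=-3.0)  # grid x=1 at the last site
        depths = prof.depths[prof.depths >= -1.0]
        short = make_profile(depths)
        seg2 = apply_manual_segmentation(short, 4.0, 1.0, -1.0)
        norm = normalize_depths(short, seg2)
        # sites stop at x=1 exactly; no NaN inside, none fabricated beyond
        assert not np.isnan(norm.nrms_values[(norm.grid >= -0.5) & (norm.grid <= 1)]).any()

    def test_truncated_pre_segment_warns(self):
        depths = np.round(np.arange(5.0, -3.01, -0.25), 6)
        prof = make_profile(depths)
        seg = apply_manual_segmentation(prof, 4.0, 1.0, -2.0)
        with pytest.warns(UserWarning, match="truncated"):
            norm = normalize_depths(prof, seg)
        assert np.isnan(norm.nrms_values[0])  # x=-0.5 not covered


class TestGroupAverage:
    def test_idempotent_on_identical_profiles(self):
        prof, seg = _profile_and_seg(nrms_fn=lambda d: 1.0 + 0.1 * np.abs(d))
        n1 = normalize_depths(prof, seg)
        avg = group_average([n1, n1])
        assert np.allclose(avg.nrms_values, n1.nrms_values, equal_nan=True)
        assert np.allclose(avg.spectrogram, n1.spectrogram, equal_nan=True)

    def test_linearity(self):
        prof, seg = _profile_and_seg(nrms_fn=lambda d: 1.0 + 0.05 * d)
        n1 = normalize_depths(prof, seg)
        n2 = normalize_depths(prof, seg)
        n2.nrms_values = 2.0 - n1.nrms_values
        avg = group_average([n1, n2])
        valid = ~np.isnan(avg.nrms_values)
        assert np.allclose(avg.nrms_values[valid], 1.0)

    def test_counts_recorded(self):
        prof, seg = _profile_and_seg()
        avg = group_average([normalize_depths(prof, seg)] * 3)
        assert avg.counts.max() == 3

    def test_errors(self):
        prof, seg = _profile_and_seg()
        n1 = normalize_depths(prof, seg)
        n2 = normalize_depths(prof, seg, n_grid=77)
        with pytest.raises(ValueError):
            group_average([])
        with pytest.raises(ValueError):
            group_average([n1, n2])


class TestBetaRatio:
    def test_identical_psds_give_unity(self):
        prof, seg = _profile_and_seg()
        assert beta_ratio(prof, seg) == pytest.approx(1.0)

    def test_doubled_dlor_beta_gives_two(self):
        def fracs(depths):
            return np.where((depths <= 4.0) & (depths > 1.0), 0.2, 0.1)

        depths = np.round(np.arange(7.0, -3.01, -0.25), 6)
        prof = make_profile(depths, band_fracs={"beta": fracs(depths)})
        seg = apply_manual_segmentation(prof, 4.0, 1.0, -2.0)
        assert beta_ratio(prof, seg) == pytest.approx(2.0)

    def test_matches_brute_force_on_simulated_profile(self, pd_sim, pd_profile):
        _, gt = pd_sim
        seg = sm.segmentation_from_ground_truth(pd_profile, gt)
        ratio = beta_ratio(pd_profile, seg)
        # independent recomputation from the per-site feature values
        half = 0.5 * (seg.entry_depth - seg.exit_depth)
        num, den = [], []
        for site, label in zip(pd_profile.sites, seg.labels):
            if label == "DLOR":
                num.append(site.band_fractions["beta"])
            if seg.entry_depth < site.depth <= seg.entry_depth + half:
                den.append(site.band_fractions["beta"])
        assert ratio == pytest.approx(np.mean(num) / np.mean(den), rel=1e-12)


class TestMeanBandPower:
    def test_constant_fraction(self):
        depths = np.round(np.arange(7.0, -3.01, -0.25), 6)
        prof = make_profile(depths, band_fracs={"beta": np.full(depths.size, 0.2)})
        seg = apply_manual_segmentation(prof, 4.0, 1.0, -2.0)
        assert mean_band_power(prof, seg, "beta") == pytest.approx(0.2)

    def test_single_site_region(self):
        prof, seg = _profile_and_seg(dlor_exit=3.75)  # one DLOR site at 4.0
        assert sum(l == "DLOR" for l in seg.labels) == 1
        site = prof.sites[list(seg.labels).index("DLOR")]
        assert mean_band_power(prof, seg, "theta") == pytest.approx(
            site.band_fractions["theta"]
        )

    def test_matches_sitewise_average(self, pd_sim, pd_profile):
        _, gt = pd_sim
        seg = sm.segmentation_from_ground_truth(pd_profile, gt)
        for band, region in (("beta", "dlor"), ("gamma", "stn")):
            val = mean_band_power(pd_profile, seg, band, region=region)
            wanted = ("DLOR",) if region == "dlor" else ("DLOR", "VMNR")
            ref = np.mean([
                s.band_fractions[band]
                for s, l in zip(pd_profile.sites, seg.labels)
                if l in wanted
            ])
            assert val == pytest.approx(ref, rel=1e-12)

    def test_unknown_region_rejected(self, pd_sim, pd_profile):
        _, gt = pd_sim
        seg = sm.segmentation_from_ground_truth(pd_profile, gt)
        with pytest.raises(ValueError):
            mean_band_power(pd_profile, seg, "beta", region="vmnr")


class TestNrmsPeakAuc:
    @pytest.mark.parametrize("level,expected", [(1.0, (1.0, 1.0)), (2.0, (2.0, 2.0))])
    def test_constant_nrms(self, level, expected):
        def nrms_fn(d):
            return np.where((d <= 4.0) & (d >= -2.0), level, 1.0)

        prof, seg = _profile_and_seg(nrms_fn=nrms_fn)
        peak, auc = nrms_peak_auc(prof, seg)
        assert (peak, auc) == pytest.approx(expected)

    def test_triangular_nrms(self):
        # rises 1 -> 3 -> 1 linearly across the STN: trapezoid area 2
        def nrms_fn(d):
            x = (4.0 - d) / 6.0
            tri = np.where(x <= 0.5, 1 + 4 * x, 3 - 4 * (x - 0.5))
            return np.where((x >= 0) & (x <= 1), tri, 1.0)

        prof, seg = _profile_and_seg(nrms_fn=nrms_fn)
        peak, auc = nrms_peak_auc(prof, seg)
        assert peak == pytest.approx(3.0)
        assert auc == pytest.approx(2.0)


class TestScaleInvariance:
    def test_metrics_invariant_to_raw_voltage_scaling(self, pd_sim, pd_profile):
        traj, gt = pd_sim
        from stnmer.containers import SiteRecording, Trajectory

        scaled = Trajectory(
            sites=[
                SiteRecording(s.depth, s.sampling_rate, 0.4 * s.samples)
                for s in traj.sites
            ],
            trajectory_id=traj.trajectory_id,
        )
        prof2 = sm.featurize_trajectory(scaled)
        seg1 = sm.segmentation_from_ground_truth(pd_profile, gt)
        seg2 = sm.segmentation_from_ground_truth(prof2, gt)
        m1 = sm.compute_trajectory_metrics(pd_profile, seg1)
        m2 = sm.compute_trajectory_metrics(prof2, seg2)
        assert m2.beta_ratio == pytest.approx(m1.beta_ratio, rel=1e-7)
        assert m2.nrms_peak == pytest.approx(m1.nrms_peak, rel=1e-9)
        assert m2.nrms_auc == pytest.approx(m1.nrms_auc, rel=1e-9)
        for band in m1.mean_band_power:
            assert m2.mean_band_power[band] == pytest.approx(
                m1.mean_band_power[band], rel=1e-7
            )
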