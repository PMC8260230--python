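"""Track kinematics: velocities, angles, profiles, longevity, ingression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from streakdyn import kinematics as kin
from streakdyn import synthetic as syn
from streakdyn.tracks import Region, Track, TrackSet


def _track(points, status="live", track_id=0, parent_id=None):
    t, x, y = map(np.asarray, zip(*points))
    return Track(track_id=track_id, parent_id=parent_id, t=t, x=x, y=y, status=status)


class TestVelocities:
    def test_convergence_is_positive_toward_midline(self):
        v = kin.velocities(_track([(0, 10, 0), (10, 0, 0)]))
        assert v["v_lm"].iloc[0] == pytest.approx(1.0)
        assert v["v_ap"].iloc[0] == pytest.approx(0.0)

    def test_divergence_is_negative_on_either_side(self):
        # moving away from the midline on the negative-x side
        v = kin.velocities(_track([(0, -10, 0), (10, -20, 50)]))
        assert v["v_lm"].iloc[0] == pytest.approx(-1.0)
        assert v["v_ap"].iloc[0] == pytest.approx(5.0)

    def test_constant_velocity_track_recovered_exactly(self):
        t = np.arange(0, 40, 4.0)
        tr = Track(0, None, t, -100 + 0.7 * t, 5 + 1.2 * t)  # v_lm = +0.7 (x<0 side)
        v = kin.velocities(tr)
        assert np.allclose(v["v_lm"], 0.7, atol=1e-9)
        assert np.allclose(v["v_ap"], 1.2, atol=1e-9)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            kin.velocities(_track([(0, 1, 1)]))


class TestMidlineAngle:
    @pytest.mark.parametrize(
        "v_lm,v_ap,deg", [(0, 3, 0.0), (2, 2, 45.0), (5, 0, 90.0), (-2, 2, 45.0)]
    )
    def test_reference_angles(self, v_lm, v_ap, deg):
        assert kin.midline_angle(v_lm, v_ap) == pytest.approx(deg)

    def test_zero_displacement_is_undefined(self):
        assert np.isnan(kin.midline_angle(0.0, 0.0))

    @given(
        v_lm=st.floats(-10, 10, allow_nan=False),
        v_ap=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_reflection_invariance(self, v_lm, v_ap):
        # mirroring the embryo (x -> -x flips v_lm's sign) leaves the angle alone
        a = kin.midline_angle(v_lm, v_ap)
        b = kin.midline_angle(-v_lm, v_ap)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestAngleFractions:
    def test_pure_ap_motion_all_below_45(self):
        ts = TrackSet([
            _track([(0, 50, 0), (4, 50, 8), (8, 50, 16)], track_id=i) for i in range(3)
        ])
        rep = kin.angle_fraction_report(ts)
        assert rep["frac_0_45"] == 1.0

    def test_boundary_angle_goes_to_upper_bin(self):
        ts = TrackSet([_track([(0, 8, 0), (4, 4, 4)])])  # |dx| == |dy| -> 45°
        rep = kin.angle_fraction_report(ts)
        assert rep["frac_45_90"] == 1.0

    def test_empty_region_raises(self):
        ts = TrackSet([_track([(0, 50, 0), (4, 50, 8)])])
        with pytest.raises(ValueError):
            kin.angle_fraction_report(ts, Region("far", y_min=1e6))

    def test_gradient_generator_splits_anterior_posterior(self):
        params = syn.TrackGenParams(
            n_cells=400, duration=120.0, frame_interval=4.0, node_speed=1.0,
            convergence_profile=lambda y: 0.1 + 2.9 * (np.asarray(y) / 1000.0),
            position_noise_sd=0.5, seed=7,
        )
        ts, _ = syn.generate_tracks(params)
        ant = kin.angle_fraction_report(ts, Region("anterior", y_max=300))
        post = kin.angle_fraction_report(ts, Region("posterior", y_min=700))
        assert ant["frac_0_45"] > ant["frac_45_90"]
        assert post["frac_45_90"] > post["frac_0_45"]


class TestRegistration:
    def test_stationary_node_is_identity(self):
        ts = TrackSet([_track([(0, 10, 5), (4, 12, 9)])])
        node = _track([(0, 0, 0), (10, 0, 0)], track_id=-1)
        out = kin.register_to_node(ts, node)
        assert np.allclose(out.tracks[0].x, [10, 12])
        assert np.allclose(out.tracks[0].y, [5, 9])

    def test_comoving_cell_becomes_stationary(self):
        node = _track([(0, 0, 0), (10, 0, 20)], track_id=-1)
        ts = TrackSet([_track([(0, 30, 100), (10, 30, 120)])])
        out = kin.register_to_node(ts, node)
        assert np.allclose(np.diff(out.tracks[0].y), 0.0)

    def test_round_trip_is_identity(self, gradient_tracks):
        (ts, _), _ = gradient_tracks
        node = _track([(0, 3, -7), (30, 10, 40), (60, -5, 100)], track_id=-1)
        reg = kin.register_to_node(ts, node)
        back = kin.register_to_node(reg, node, invert=True)
        for a, b in zip(ts, back):
            assert np.allclose(a.x, b.x, atol=1e-9)
            assert np.allclose(a.y, b.y, atol=1e-9)

    def test_no_extrapolation_outside_node_span(self):
        node = _track([(10, 0, 0), (20, 0, 10)], track_id=-1)
        ts = TrackSet([_track([(0, 1, 1), (15, 2, 2)])])
        with pytest.raises(ValueError):
            kin.register_to_node(ts, node)


class TestSpeedProfile:
    def test_recovers_programmed_convergence_gradient(self, gradient_tracks):
        (ts, _), slope_true = gradient_tracks
        prof = kin.speed_profile(ts, ap_bin_width=50.0, time_bin_width=30.0)
        sub = prof[prof["n"] >= 20]
        fit = stats.linregress(sub["ap_bin_center"], sub["v_lm_mean"])
        assert fit.slope == pytest.approx(slope_true, rel=0.10)

    def test_registered_comoving_tracks_have_zero_ap_speed(self):
        params = syn.TrackGenParams(
            n_cells=100, duration=60.0, frame_interval=4.0, node_speed=1.5,
            convergence_profile=0.3, position_noise_sd=0.0, seed=8,
        )
        ts, truth = syn.generate_tracks(params)
        reg = kin.register_to_node(ts, truth.node)
        prof = kin.speed_profile(reg, ap_bin_width=100.0, time_bin_width=60.0)
        assert np.allclose(prof["v_ap_mean"], 0.0, atol=1e-9)

    def test_single_sample_bin_reports_missing_sd(self):
        ts = TrackSet([_track([(0, 50, 0), (4, 49, 8)])])
        prof = kin.speed_profile(ts, ap_bin_width=50.0, time_bin_width=30.0)
        assert len(prof) == 1
        assert prof["n"].iloc[0] == 1
        assert np.isnan(prof["v_lm_sd"].iloc[0])

    def test_rejects_nonpositive_bins(self):
        ts = TrackSet([_track([(0, 50, 0), (4, 49, 8)])])
        with pytest.raises(ValueError):
            kin.speed_profile(ts, ap_bin_width=0.0)


class TestLongevity:
    def test_no_censoring_means_unit_ratios(self):
        ts = TrackSet([
            _track([(t, 10, 10) for t in range(0, 125, 5)][: 25], track_id=i)
            for i in range(4)
        ])
        rep = kin.track_longevity(ts, [Region("all")], t0=0.0)[0]
        assert rep.ratio_1h == 1.0 and rep.ratio_2h == 1.0

    def test_known_attrition_fractions(self):
        tracks = []
        for i in range(100):
            if i < 50:
                end = 125.0  # survives past 2 h
            elif i < 80:
                end = 90.0   # survives 1 h only
            else:
                end = 30.0   # gone before 1 h
            n = int(end // 5) + 1
            tracks.append(
                _track([(5.0 * j, 10, 10) for j in range(n)], track_id=i,
                       status="ingressed" if end < 125 else "live")
            )
        rep = kin.track_longevity(TrackSet(tracks), [Region("all")], t0=0.0)[0]
        assert rep.ratio_1h == pytest.approx(0.8)
        assert rep.ratio_2h == pytest.approx(0.5)

    def test_binomial_survival_oracle(self, hazard_tracks):
        ts, _ = hazard_tracks
        rep = kin.track_longevity(ts, [Region("all")], t0=0.0)[0]
        p1 = 0.95**15  # 15 four-minute frames in 1 h
        se = np.sqrt(p1 * (1 - p1) / rep.n_t0)
        assert abs(rep.ratio_1h - p1) < 3 * se
        assert rep.ratio_2h <= rep.ratio_1h  # never increases with horizon

    def test_lineage_survival_through_division(self):
        mother = _track([(0, 10, 10), (4, 10, 10)], status="divided", track_id=0)
        kid = Track(1, 0, t=[4.0, 8.0, 70.0], x=[10, 10, 10], y=[10, 10, 10])
        ts = TrackSet([mother, kid])
        with_lineage = kin.track_longevity(ts, [Region("all")], 0.0, lineage_survival=True)[0]
        without = kin.track_longevity(ts, [Region("all")], 0.0, lineage_survival=False)[0]
        # cohort = both tracks alive at t0=0 -> just the mother
        assert with_lineage.ratio_1h == 1.0
        assert without.ratio_1h == 0.0

    def test_empty_region_raises(self):
        ts = TrackSet([_track([(0, 10, 10), (4, 10, 10)])])
        with pytest.raises(ValueError):
            kin.track_longevity(ts, [Region("off", x_min=1e5)], t0=0.0)


class TestIngressionIntensity:
    def test_uniform_image_flat_fit(self):
        stack = np.full((3, 60, 60), 7.0)
        axis = np.array([[5, 30], [55, 30]])
        curve = kin.ingression_intensity(stack, axis, ap_bin_width=10, band_halfwidth=10)
        assert np.allclose(curve.fits["slope"], 0.0)
        assert curve.fits["r2"].isna().all()  # R² undefined on a flat profile

    def test_linear_gradient_recovered_within_5pct(self):
        rng = np.random.default_rng(0)
        a = 0.5
        H, W = 120, 80
        yy = np.arange(H)[:, None] * np.ones((1, W))
        stack = np.stack([
            (t + 1) * a * yy + 20 + rng.normal(0, (t + 1) * a * H / 30, (H, W))
            for t in range(4)
        ])
        axis = np.array([[2, 40], [117, 40]])
        curve = kin.ingression_intensity(stack, axis, ap_bin_width=10, band_halfwidth=20)
        for t in range(4):
            assert curve.fits["slope"].iloc[t] == pytest.approx((t + 1) * a, rel=0.05)
        # posteriorly increasing labeling over time -> slopes rise monotonically
        assert np.all(np.diff(curve.fits["slope"]) > 0)

    def test_too_few_bins_flagged_unfitted(self):
        stack = np.random.default_rng(1).random((2, 30, 30))
        axis = np.array([[10, 15], [18, 15]])
        curve = kin.ingression_intensity(stack, axis, ap_bin_width=50, band_halfwidth=5)
        assert not curve.fits["fitted"].any()


class TestInterdivisionTimes:
    def test_worked_interval(self):
        kid = Track(1, 0, t=np.arange(10, 56) * 6.0, x=np.zeros(46), y=np.zeros(46),
                    status="divided", frame=np.arange(10, 56))
        iv, cens = kin.interdivision_times(TrackSet([kid]))
        assert iv == [270.0]
        assert cens == 0

    def test_no_divisions_all_censored(self):
        kid = Track(1, 0, t=[0.0, 6.0], x=[0, 0], y=[0, 0], status="live")
        iv, cens = kin.interdivision_times(TrackSet([kid]))
        assert iv == [] and cens == 1

    def test_matches_censoring_aware_branching_oracle(self):
        # per-frame division probability p = dt/270; observed completed
        # intervals in a finite movie are censoring-biased, so the oracle
        # re-simulates the same branching bookkeeping directly
        params = syn.TrackGenParams(
            n_cells=50, duration=1000.0, frame_interval=6.0, node_speed=0.0,
            convergence_profile=0.0, division_rate_profile=60.0 / 270.0, seed=8,
        )
        ts, _ = syn.generate_tracks(params)
        iv, _ = kin.interdivision_times(ts)
        assert len(iv) >= 200

        # round(1000 / 6) + 1 = 168 samples; division checks at frames 0..166
        def oracle_mean(seed, n0=50, n_frames=168, p=6.0 / 270.0, dt=6.0):
            rng = np.random.default_rng(seed)
            births = [0] * n0
            out = []
            f = 0
            while births:
                nxt = []
                for b in births:
                    if b > n_frames:
                        continue
                    k = rng.geometric(p)  # frames until division
                    if b + k <= n_frames - 1:
                        # daughter's own division observed if before movie end
                        nxt.extend([b + k, b + k])
                        if b > 0:  # birth observed (not a founder)
                            out.append((k - 1) * dt)
                births = nxt
                f += 1
                if f > 10 * n_frames:
                    break
            return np.mean(out), len(out)

        means = [oracle_mean(s)[0] for s in range(20)]
        mu, sd = np.mean(means), np.std(means, ddof=1)
        se_obs = np.std(iv, ddof=1) / np.sqrt(len(iv))
        assert abs(np.mean(iv) - mu) < 3 * np.hypot(se_obs, sd)
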