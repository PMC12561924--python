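import numpy as np
import pytest
from conftest import make_synced_trial

from spheregaze import frames


class TestFramePoints:
    def test_head_rel_torso_difference(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=70.0, torso_yaw=50.0)
        ps = frames.frame_points(trial, "head_rel_torso")
        assert np.allclose(ps.lon, 20.0, atol=1e-9)

    def test_head_rel_torso_wraps(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=170.0, torso_yaw=-170.0)
        ps = frames.frame_points(trial, "head_rel_torso")
        assert np.allclose(ps.lon, -20.0, atol=1e-9)

    def test_difference_invariant_to_360(self):
        t = np.arange(0, 0.1, 0.004)
        a = frames.frame_points(make_synced_trial(t, head_yaw=30.0, torso_yaw=10.0), "head_rel_torso")
        b = frames.frame_points(make_synced_trial(t, head_yaw=390.0, torso_yaw=10.0), "head_rel_torso")
        assert np.allclose(a.lon, b.lon, atol=1e-9)

    def test_eyes_in_head_identity(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=45.0, eih_lon=0.0, eih_lat=0.0)
        ps = frames.frame_points(trial, "eyes_in_head")
        assert np.allclose(ps.lon, 0.0, atol=1e-9) and np.allclose(ps.lat, 0.0, atol=1e-9)

    def test_eyes_in_space_composes(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=30.0, eih_lon=10.0)
        ps = frames.frame_points(trial, "eyes_in_space")
        assert np.allclose(ps.lon, 40.0, atol=1e-9)

    def test_torso_frames_have_zero_latitude(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=0.0, torso_yaw=33.0, chair_yaw=12.0, posture="swivel")
        assert np.all(frames.frame_points(trial, "torso_in_space").lat == 0)
        trc = frames.frame_points(trial, "torso_rel_chair")
        assert np.allclose(trc.lon, 21.0, atol=1e-9)

    def test_chairless_trial_rejects_chair_frame(self):
        t = np.arange(0, 0.1, 0.004)
        trial = make_synced_trial(t, head_yaw=0.0, posture="sit")
        with pytest.raises(frames.FrameUnavailableError):
            frames.frame_points(trial, "torso_rel_chair")

    def test_unknown_frame(self):
        t = np.arange(0, 0.1, 0.004)
        with pytest.raises(ValueError, match="unknown frame"):
            frames.frame_points(make_synced_trial(t, 0.0), "eyes_in_chair")


class TestSpreadStats:
    def _sets(self, spec):
        return [
            frames.FramePointSet("eyes_in_space", np.asarray(lon, float),
                                 np.asarray(lat, float), subj, posture)
            for subj, posture, lon, lat in spec
        ]

    def test_identical_points_zero_spread(self):
        table = frames.spread_stats(self._sets([("s1", "sit", [5.0] * 10, [2.0] * 10)]))
        row = table.iloc[0]
        assert row.sd_lon == 0.0 and row.sd_lat == 0.0 and row.mean_lat == 2.0

    def test_two_point_sample_sd(self):
        table = frames.spread_stats(self._sets([("s1", "sit", [-10.0, 10.0], [0.0, 0.0])]))
        assert table.iloc[0].sd_lon == pytest.approx(np.sqrt(200.0))  # ddof=1

    def test_subject_pooling_matches_groupby_oracle(self):
        rng = np.random.default_rng(12)
        spec, pooled = [], {}
        for subj in ("a", "b", "c"):
            for k in range(3):
                lon = rng.normal(0, 50, 40)
                lat = rng.normal(0, 20, 40)
                spec.append((subj, "stand", lon, lat))
                pooled.setdefault(subj, ([], []))
                pooled[subj][0].append(lon)
                pooled[subj][1].append(lat)
        table = frames.spread_stats(self._sets(spec)).set_index("subject")
        for subj, (lons, lats) in pooled.items():
            assert table.loc[subj, "sd_lon"] == pytest.approx(
                np.std(np.concatenate(lons), ddof=1))
        cond = frames.condition_spreads(table.reset_index())
        assert cond.loc["stand", "sd_lon"] == pytest.approx(table["sd_lon"].mean())

    def test_insufficient_points_flagged(self):
        table = frames.spread_stats(self._sets([("s1", "sit", [1.0], [0.0])]))
        assert np.isnan(table.iloc[0].sd_lon)


class TestEquatorBias:
    def test_toy_table_matches_hand_formula(self):
        means = np.array([15.2, 16.8, 15.1, 16.4, 16.0])
        sets = [
            frames.FramePointSet("head_in_space", np.zeros(4), np.full(4, m), f"s{k}", "sit")
            for k, m in enumerate(means)
        ]
        subj_means, res = frames.equator_bias(sets)
        assert np.allclose(subj_means.to_numpy(), means)
        sd = means.std(ddof=1)
        t_hand = means.mean() / (sd / np.sqrt(5))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.d == pytest.approx(means.mean() / sd, rel=1e-12)
        assert res.d == pytest.approx(res.t / np.sqrt(5), rel=1e-12)

    def test_needs_two_subjects(self):
        sets = [frames.FramePointSet("head_in_space", np.zeros(4), np.ones(4), "s0", "sit")]
        with pytest.raises(ValueError):
            frames.equator_bias(sets)


class TestHeadDirectionSplit:
    def test_constructed_rightward_rotation(self):
        t = np.arange(0, 2, 0.004)
        trial = make_synced_trial(t, head_yaw=20.0 * t - 20.0, eih_lon=15.0)
        out = frames.split_by_head_direction(trial)
        assert len(out["leftward"].lon) == 0
        assert len(out["rightward"].lon) > 0.9 * len(t)
        assert np.allclose(out["rightward"].lon, 15.0, atol=0.2)

    def test_stationary_head_all_in_deadband(self):
        t = np.arange(0, 1, 0.004)
        trial = make_synced_trial(t, head_yaw=5.0)
        out = frames.split_by_head_direction(trial)
        assert len(out["rightward"].lon) == 0 and len(out["leftward"].lon) == 0


class TestBimodality:
    def test_two_gaussian_mixture(self):
        rng = np.random.default_rng(21)
        lons = np.concatenate([rng.normal(-12, 4, 4000), rng.normal(12, 4, 4000)])
        res = frames.detect_bimodality(lons)
        assert res["bimodal"]
        assert res["peak_left"] == pytest.approx(-12.0, abs=2.0)
        assert res["peak_right"] == pytest.approx(12.0, abs=2.0)

    def test_single_gaussian_unimodal(self):
        rng = np.random.default_rng(22)
        res = frames.detect_bimodality(rng.normal(0, 10, 5000))
        assert not res["bimodal"]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            frames.detect_bimodality(np.zeros(10))


class TestHeatmap:
    def test_point_mass_single_bin(self):
        ps = frames.FramePointSet("eyes_in_space", np.full(50, 10.2), np.full(50, -4.7))
        h = frames.heatmap(ps, 360, 180)
        assert h.sum() == pytest.approx(1.0)
        assert np.count_nonzero(h) == 1 and h.max() == pytest.approx(1.0)

    def test_normalized_after_smoothing(self):
        rng = np.random.default_rng(31)
        ps = frames.FramePointSet("eyes_in_space", rng.uniform(-180, 180, 2000),
                                  rng.uniform(-90, 90, 2000))
        h = frames.heatmap(ps, 90, 45, smoothing_deg=4.0)
        assert h.sum() == pytest.approx(1.0)

    def test_uniform_sphere_density_follows_cos_lat(self):
        rng = np.random.default_rng(32)
        pts = rng.normal(size=(300_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        from spheregaze.sphere import vec_to_lonlat

        lon, lat = vec_to_lonlat(pts)
        h = frames.heatmap(frames.FramePointSet("eyes_in_space", lon, lat), 36, 18)
        band = h.sum(axis=1)
        centers = np.linspace(-85, 85, 18)
        expected = np.cos(np.deg2rad(centers))
        expected /= expected.sum()
        assert np.allclose(band, expected, atol=0.004)
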