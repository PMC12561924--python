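import numpy as np
import pytest
from _oracles import haversine_deg, quat_to_matrix
from hypothesis import given, settings, strategies as st

from spheregaze import sphere


@pytest.fixture(scope="module")
def random_points():
    rng = np.random.default_rng(11)
    lon = rng.uniform(-180.0, 180.0, 1000)
    lat = np.rad2deg(np.arcsin(rng.uniform(-1.0, 1.0, 1000)))
    return lon, lat


class TestLonLatVec:
    @pytest.mark.parametrize("lon,lat,vec", [
        (0.0, 0.0, (1.0, 0.0, 0.0)),
        (0.0, 90.0, (0.0, 0.0, 1.0)),
        (-90.0, 0.0, (0.0, 1.0, 0.0)),  # negative longitude is leftward
    ])
    def test_axis_convention(self, lon, lat, vec):
        assert np.allclose(sphere.lonlat_to_vec(lon, lat), vec, atol=1e-12)

    def test_round_trip_examples(self):
        lon, lat = sphere.vec_to_lonlat(sphere.lonlat_to_vec(37.0, -12.0))
        assert abs(lon - 37.0) < 1e-9 and abs(lat + 12.0) < 1e-9

    def test_round_trip_random(self, random_points):
        lon, lat = random_points
        lon2, lat2 = sphere.vec_to_lonlat(sphere.lonlat_to_vec(lon, lat))
        assert np.allclose(lon2, lon, atol=1e-9)
        assert np.allclose(lat2, lat, atol=1e-9)

    def test_lon_wraps_identically(self, random_points):
        lon, lat = random_points
        v1 = sphere.lonlat_to_vec(lon, lat)
        v2 = sphere.lonlat_to_vec(lon + 360.0, lat)
        assert np.allclose(v1, v2, atol=1e-12)

    def test_pole_longitude_canonical(self):
        lon, lat = sphere.vec_to_lonlat([0.0, 0.0, -1.0])
        assert lon == 0.0 and lat == -90.0
        assert sphere.normalize_lonlat(123.0, 90.0) == (0.0, 90.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sphere.vec_to_lonlat([0.0, 0.0, 0.0])


@settings(derandomize=True, max_examples=200)
@given(
    lon=st.floats(-1e6, 1e6, allow_nan=False),
    lat=st.floats(-90.0, 90.0, allow_nan=False),
)
def test_normalize_lonlat_idempotent_and_wrapped(lon, lat):
    l1, p1 = sphere.normalize_lonlat(lon, lat)
    l2, p2 = sphere.normalize_lonlat(l1, p1)
    assert (l1, p1) == (l2, p2)
    assert -180.0 <= l1 < 180.0 and -90.0 <= p1 <= 90.0
    v1 = sphere.lonlat_to_vec(lon, lat)
    v2 = sphere.lonlat_to_vec(l1, p1)
    assert np.allclose(v1, v2, atol=1e-6)


class TestOrthodromic:
    def test_trivial_distances(self):
        assert sphere.orthodromic(0, 0, 0, 0) == 0.0
        assert abs(sphere.orthodromic(0, 0, 90, 0) - 90.0) < 1e-12

    def test_matches_haversine_oracle(self, random_points):
        lon, lat = random_points
        lon2, lat2 = np.roll(lon, 1), np.roll(lat, 1)
        ours = sphere.orthodromic(lon, lat, lon2, lat2)
        ref = haversine_deg(lon, lat, lon2, lat2)
        assert np.allclose(ours, ref, atol=1e-9)

    def test_metric_axioms_on_random_triples(self, random_points):
        lon, lat = random_points
        a = sphere.orthodromic(lon, lat, np.roll(lon, 1), np.roll(lat, 1))
        b = sphere.orthodromic(np.roll(lon, 1), np.roll(lat, 1), np.roll(lon, 2), np.roll(lat, 2))
        c = sphere.orthodromic(lon, lat, np.roll(lon, 2), np.roll(lat, 2))
        back = sphere.orthodromic(np.roll(lon, 1), np.roll(lat, 1), lon, lat)
        assert np.allclose(a, back, atol=1e-9)  # symmetry
        assert np.all(c <= a + b + 1e-9)  # triangle inequality
        assert sphere.orthodromic(12.0, 34.0, 12.0, 34.0) == 0.0


class TestIntegrateGaze:
    def test_identity_head_equals_projection(self, random_points):
        lon, lat = random_points
        v = sphere.lonlat_to_vec(lon[:50], lat[:50])
        glon, glat = sphere.integrate_gaze(v, np.tile([1.0, 0, 0, 0], (50, 1)))
        plon, plat = sphere.vec_to_lonlat(v)
        assert np.array_equal(glon, plon) and np.array_equal(glat, plat)

    def test_pure_yaw(self):
        q = sphere.yaw_pitch_quat(90.0)
        lon, lat = sphere.integrate_gaze([1.0, 0, 0], q)
        assert abs(lon - 90.0) < 1e-9 and abs(lat) < 1e-9

    def test_yaw_composition_matches_matrix_oracle(self):
        eye = sphere.lonlat_to_vec(10.0, 0.0)
        q = sphere.yaw_pitch_quat(30.0)
        lon, lat = sphere.integrate_gaze(eye, q)
        assert abs(lon - 40.0) < 1e-9 and abs(lat) < 1e-9
        rot = quat_to_matrix(*q)
        ref_lon, ref_lat = sphere.vec_to_lonlat(rot @ eye)
        assert abs(lon - ref_lon) < 1e-9 and abs(lat - ref_lat) < 1e-9

    def test_random_quaternions_match_matrix_oracle(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=(200, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        v = rng.normal(size=(200, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        lon, lat = sphere.integrate_gaze(v, q)
        for k in range(200):
            ref = quat_to_matrix(*q[k]) @ v[k]
            rlon, rlat = sphere.vec_to_lonlat(ref)
            assert abs(lon[k] - rlon) < 1e-8 and abs(lat[k] - rlat) < 1e-8

    def test_negated_quaternion_same_rotation(self):
        rng = np.random.default_rng(6)
        q = rng.normal(size=(50, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        v = rng.normal(size=(50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        a = sphere.integrate_gaze(v, q)
        b = sphere.integrate_gaze(v, -q)
        assert np.allclose(a[0], b[0]) and np.allclose(a[1], b[1])

    def test_bad_norms_rejected(self):
        with pytest.raises(ValueError):
            sphere.integrate_gaze([1.0, 0, 0], [2.0, 0, 0, 0])
        with pytest.raises(ValueError):
            sphere.integrate_gaze([3.0, 0, 0], [1.0, 0, 0, 0])


class TestCapFraction:
    def test_printed_value_at_3_degrees(self):
        assert round(sphere.cap_fraction(3.0), 5) == 0.06852

    def test_hemisphere_and_full_sphere(self):
        assert sphere.cap_fraction(90.0) == pytest.approx(50.0)
        assert sphere.cap_fraction(180.0) == pytest.approx(100.0)
        assert sphere.cap_fraction(0.0) == 0.0

    def test_strictly_increasing(self):
        theta = np.linspace(0.1, 179.9, 500)
        assert np.all(np.diff(sphere.cap_fraction(theta)) > 0)

    def test_matches_monte_carlo_cap_area(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(1_000_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        for theta in (10.0, 45.0, 120.0):
            p = np.mean(pts[:, 0] >= np.cos(np.deg2rad(theta)))
            se = np.sqrt(p * (1 - p) / len(pts))
            assert abs(sphere.cap_fraction(theta) / 100.0 - p) < 3 * se

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sphere.cap_fraction(-1.0)
        with pytest.raises(ValueError):
            sphere.cap_fraction(181.0)


class TestEquirectBin:
    def test_center_bin(self):
        assert sphere.equirect_bin(0.0, 0.0, 360, 180) == (180, 90)

    def test_wraparound_neighbors(self):
        i1, _ = sphere.equirect_bin(-180.0, 0.0, 360, 180)
        i2, _ = sphere.equirect_bin(179.999, 0.0, 360, 180)
        assert i1 == 0 and i2 == 359  # adjacent under wraparound

    def test_uniform_sample_follows_cos_lat(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        from spheregaze.sphere import vec_to_lonlat

        lon, lat = vec_to_lonlat(pts)
        _, i_lat = sphere.equirect_bin(lon, lat, 36, 18)
        counts = np.bincount(i_lat, minlength=18)
        edges = np.linspace(-90, 90, 19)
        expected = (np.sin(np.deg2rad(edges[1:])) - np.sin(np.deg2rad(edges[:-1]))) / 2.0
        assert np.allclose(counts / counts.sum(), expected, atol=4 * np.sqrt(expected.max() / 2e5))

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            sphere.equirect_bin(0.0, 0.0, 0, 10)
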