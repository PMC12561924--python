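"""Geometry on the unit view-sphere.

All positions on the sphere surrounding the observer are expressed as
longitude/latitude pairs in degrees, with longitude in [-180, 180) increasing
to the observer's right (east) and latitude in [-90, 90] increasing upward.
The matching Cartesian convention is right-handed with

* ``+x`` the forward axis (lon=0, lat=0),
* ``+z`` the up axis (lat=+90),
* ``+y`` the left axis (lon=-90, lat=0).

Head orientation is a unit quaternion in scalar-first order ``(w, x, y, z)``
mapping head-frame directions into world coordinates.  Distances between
points are always geodesic (orthodromic) central angles, never distances on
the equirectangular map, which is heavily distorted near the poles.

All public functions broadcast over leading array dimensions.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "normalize_lonlat",
    "lonlat_to_vec",
    "vec_to_lonlat",
    "yaw_pitch_quat",
    "quat_rotation",
    "integrate_gaze",
    "orthodromic",
    "cap_fraction",
    "equirect_bin",
    "wrap_degrees",
]

#: tolerated deviation of an ingested quaternion / unit vector from unit norm
NORM_TOL = 1e-3

_POLE_EPS = 1e-12


def wrap_degrees(angle):
    """Wrap angles (degrees) to the half-open interval [-180, 180)."""
    angle = np.asarray(angle, dtype=float)
    return (angle + 180.0) % 360.0 - 180.0


def normalize_lonlat(lon, lat):
    """Canonicalize longitude/latitude coordinates.

    Longitude is wrapped to [-180, 180).  At the poles (|lat| = 90) the
    longitude is degenerate and is canonicalized to 0 so that equal points
    compare equal.
    """
    lon = wrap_degrees(lon)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0 + 1e-9):
        raise ValueError("latitude outside [-90, 90]")
    lat = np.clip(lat, -90.0, 90.0)
    pole = np.abs(lat) >= 90.0 - _POLE_EPS
    lon = np.where(pole, 0.0, lon)
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def lonlat_to_vec(lon, lat):
    """Unit direction vector(s) for view-sphere coordinates in degrees.

    (0, 0) maps to the forward axis ``(1, 0, 0)`` and (0, 90) to the up
    axis ``(0, 0, 1)``; increasing longitude turns rightward.
    """
    lon, lat = normalize_lonlat(lon, lat)
    lam = np.deg2rad(lon)
    phi = np.deg2rad(lat)
    c = np.cos(phi)
    return np.stack([c * np.cos(lam), -c * np.sin(lam), np.sin(phi)], axis=-1)


def vec_to_lonlat(vec):
    """Longitude/latitude (degrees) where a direction vector meets the sphere.

    The input need not be normalized but must be nonzero.  Returns a tuple
    ``(lon, lat)``; scalars for a single vector, arrays otherwise.
    """
    vec = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(vec, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("cannot project a zero vector onto the sphere")
    v = vec / norm[..., None]
    lat = np.rad2deg(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(-v[..., 1], v[..., 0]))
    return normalize_lonlat(lon, lat)


def yaw_pitch_quat(yaw, pitch=0.0):
    """Scalar-first unit quaternion for a yaw-then-pitch head rotation.

    Positive yaw turns the head rightward (toward positive longitude),
    positive pitch tilts it upward; pitch is applied in the already-yawed
    frame, so the head-forward axis lands exactly at (yaw, pitch).
    """
    yaw = np.asarray(yaw, dtype=float)
    pitch = np.broadcast_to(np.asarray(pitch, dtype=float), yaw.shape)
    rot = Rotation.from_euler("ZY", np.stack([-yaw.ravel(), -pitch.ravel()], axis=-1), degrees=True)
    q = rot.as_quat()  # xyzw
    out = np.concatenate([q[:, 3:4], q[:, :3]], axis=-1)
    return out.reshape(yaw.shape + (4,)) if yaw.shape else out[0]


def quat_rotation(quat):
    """Build a :class:`scipy.spatial.transform.Rotation` from scalar-first quaternions.

    Quaternions are renormalized; a norm deviating from 1 by more than
    ``NORM_TOL`` raises ``ValueError``.  ``q`` and ``-q`` produce the same
    rotation.
    """
    q = np.asarray(quat, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > NORM_TOL):
        raise ValueError("quaternion norm deviates from 1 beyond tolerance")
    q = q / norm[..., None]
    xyzw = np.concatenate([q[..., 1:4], q[..., 0:1]], axis=-1)
    return Rotation.from_quat(xyzw.reshape(-1, 4)) if q.ndim > 1 else Rotation.from_quat(xyzw)


def integrate_gaze(eye_in_head, head_quat):
    """Combine eye-in-head direction(s) with head orientation(s) into gaze.

    Rotates the eye-in-head unit vector by the world-from-head quaternion and
    returns the eyes-in-space point as ``(lon, lat)`` in degrees.
    """
    v = np.asarray(eye_in_head, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(norm - 1.0) > NORM_TOL):
        raise ValueError("eye-in-head vector norm deviates from 1 beyond tolerance")
    v = v / norm[..., None]
    rot = quat_rotation(head_quat)
    world = rot.apply(v.reshape(-1, 3)).reshape(v.shape)
    return vec_to_lonlat(world)


def orthodromic(lon1, lat1, lon2, lat2):
    """Great-circle central angle between two view-sphere points, in degrees.

    Symmetric, zero iff the points coincide, and bounded by 180.  Computed
    through the numerically stable ``atan2(||v1 x v2||, v1 . v2)`` form.
    """
    v1 = lonlat_to_vec(lon1, lat1)
    v2 = lonlat_to_vec(lon2, lat2)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    return np.rad2deg(np.arctan2(cross, dot))


def orthodromic_vec(v1, v2):
    """Central angle (degrees) between unit vectors; see :func:`orthodromic`."""
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    return np.rad2deg(np.arctan2(cross, dot))


def cap_fraction(theta_deg):
    """Percent of the view-sphere covered by a spherical cap of radius ``theta_deg``.

    The cap of angular radius theta has area ``2*pi*(1-cos(theta))`` on the
    unit sphere and therefore covers ``50*(1-cos(theta))`` percent of it;
    3 degrees gives 0.06852 percent.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 180.0):
        raise ValueError("cap radius must lie in [0, 180] degrees")
    out = 50.0 * (1.0 - np.cos(np.deg2rad(theta)))
    return float(out) if out.ndim == 0 else out


def equirect_bin(lon, lat, n_lon, n_lat):
    """Uniform equirectangular bin indices ``(i_lon, i_lat)`` for a point.

    Longitude bins wrap at the +/-180 meridian: -180 and 180-eps fall into
    the first and last bin, which are neighbors under wraparound.  ``lat=90``
    is assigned to the last latitude band.
    """
    if n_lon < 1 or n_lat < 1:
        raise ValueError("bin counts must be >= 1")
    lon, lat = normalize_lonlat(lon, lat)
    i_lon = np.floor((np.asarray(lon) + 180.0) / 360.0 * n_lon).astype(int) % n_lon
    i_lat = np.minimum(np.floor((np.asarray(lat) + 90.0) / 180.0 * n_lat).astype(int), n_lat - 1)
    if i_lon.ndim == 0:
        return int(i_lon), int(i_lat)
    return i_lon, i_lat
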