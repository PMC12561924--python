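"""Spatial distributions of each effector frame.

The orienting system is a nested hierarchy: chair carries torso, torso
carries head, head carries eyes.  Each analysis frame expresses one link of
that chain as longitude/latitude points on the view-sphere:

``eyes_in_space``
    gaze - the eye-in-head vector rotated by the head orientation.
``head_in_space``
    the head-forward axis in world coordinates.
``torso_in_space`` / ``torso_rel_chair``
    torso yaw in world coordinates, or relative to the (swivel) chair;
    torso latitude is structurally zero - only yaw is tracked.
``head_rel_torso``
    head yaw minus torso yaw (neck rotation), latitude from head pitch.
``eyes_in_head``
    the raw eye direction in the head frame.

All angular differences are wrapped to [-180, 180).  Longitude spreads are
reported as linear (non-circular) standard deviations: trials start centered
at (0, 0) and observed spreads stay far from wrap saturation, where the
linear SD would lose meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .events import gaze_vectors
from .sphere import vec_to_lonlat, wrap_degrees

__all__ = [
    "FRAMES",
    "FramePointSet",
    "FrameUnavailableError",
    "frame_points",
    "head_lonlat",
    "spread_stats",
    "condition_spreads",
    "equator_bias",
    "split_by_head_direction",
    "head_yaw_velocity",
    "detect_bimodality",
    "heatmap",
]

FRAMES = (
    "eyes_in_space",
    "head_in_space",
    "torso_in_space",
    "torso_rel_chair",
    "head_rel_torso",
    "eyes_in_head",
)

#: sample SD everywhere: spreads are computed at the subject level first,
#: so the subject's pooled points are treated as a sample (ddof=1)
SD_DDOF = 1


class FrameUnavailableError(ValueError):
    """Requested reference frame does not exist for this trial's posture."""


@dataclass
class FramePointSet:
    frame: str
    lon: np.ndarray
    lat: np.ndarray
    subject_id: str | None = None
    posture: str | None = None
    weights: np.ndarray | None = None


def head_lonlat(trial):
    """Longitude/latitude of the head-forward axis for every sample."""
    from .sphere import quat_rotation

    fwd = quat_rotation(trial.head_quat).apply(np.array([1.0, 0.0, 0.0]))
    return vec_to_lonlat(fwd)


def frame_points(trial, frame: str) -> FramePointSet:
    """Project a synchronized trial into one of the effector frames."""
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}; choose from {FRAMES}")
    if not trial.synchronized:
        raise ValueError("trial must be synchronized")
    if frame == "eyes_in_space":
        lon, lat = vec_to_lonlat(gaze_vectors(trial))
    elif frame == "head_in_space":
        lon, lat = head_lonlat(trial)
    elif frame == "torso_in_space":
        lon = wrap_degrees(trial.torso_yaw)
        lat = np.zeros_like(lon)
    elif frame == "torso_rel_chair":
        if trial.chair_yaw is None:
            raise FrameUnavailableError(
                f"torso_rel_chair is undefined for posture {trial.posture!r} (no chair stream)"
            )
        lon = wrap_degrees(trial.torso_yaw - trial.chair_yaw)
        lat = np.zeros_like(lon)
    elif frame == "head_rel_torso":
        hlon, hlat = head_lonlat(trial)
        lon = wrap_degrees(hlon - trial.torso_yaw)
        lat = hlat
    else:  # eyes_in_head
        lon, lat = vec_to_lonlat(trial.eye_vec)
    return FramePointSet(frame, np.asarray(lon), np.asarray(lat), trial.subject_id, trial.posture)


def spread_stats(point_sets) -> pd.DataFrame:
    """Per subject x posture spread summary.

    Pools each subject's trials within a posture, then reports the linear
    standard deviations of longitude and latitude (ddof=``SD_DDOF``) and the
    mean latitude.  Cells with fewer than two points are flagged missing
    (NaN SDs).
    """
    buckets: dict[tuple, list] = {}
    frame = None
    for ps in point_sets:
        frame = ps.frame
        buckets.setdefault((ps.subject_id, ps.posture), []).append(ps)
    rows = []
    for (subj, posture), sets in sorted(buckets.items()):
        lon = np.concatenate([s.lon for s in sets])
        lat = np.concatenate([s.lat for s in sets])
        if len(lon) < 2:
            rows.append((subj, posture, np.nan, np.nan, np.nan, len(lon)))
            continue
        rows.append(
            (subj, posture, lon.std(ddof=SD_DDOF), lat.std(ddof=SD_DDOF), lat.mean(), len(lon))
        )
    df = pd.DataFrame(rows, columns=["subject", "posture", "sd_lon", "sd_lat", "mean_lat", "n_points"])
    df.attrs["frame"] = frame
    return df


def condition_spreads(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Condition-level values: mean over subjects of the subject-wise spreads."""
    return cell_table.groupby("posture")[["sd_lon", "sd_lat", "mean_lat"]].mean()


def equator_bias(point_sets):
    """Subject-wise mean latitude with a one-sample test against the equator.

    Returns ``(subject_means, result)`` where ``result`` comes from
    :func:`spheregaze.stats.one_sample_bias_test` (t, df, p, Cohen's d);
    requires at least two subjects.
    """
    from .stats import one_sample_bias_test

    by_subject: dict = {}
    for ps in point_sets:
        by_subject.setdefault(ps.subject_id, []).append(ps.lat)
    if len(by_subject) < 2:
        raise ValueError("equator_bias needs at least two subjects")
    means = pd.Series(
        {s: float(np.concatenate(v).mean()) for s, v in sorted(by_subject.items())}
    )
    return means, one_sample_bias_test(means.to_numpy())


def head_yaw_velocity(trial, smooth_ms: float = 100.0) -> np.ndarray:
    """Smoothed head yaw angular velocity (deg/s) on the trial timebase."""
    hlon, _ = head_lonlat(trial)
    yaw = np.rad2deg(np.unwrap(np.deg2rad(hlon)))
    t = trial.t
    vel = np.gradient(yaw, t)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    w = max(int(round(smooth_ms / 1000.0 / dt)), 1)
    kernel = np.ones(w) / w
    return np.convolve(vel, kernel, mode="same")


def split_by_head_direction(trial, deadband_deg_s: float = 5.0, smooth_ms: float = 100.0):
    """Condition eyes-in-head points on the direction of head movement.

    Samples are assigned by the sign of the smoothed head yaw velocity;
    samples within the dead-band (|velocity| <= ``deadband_deg_s``) count as
    "head not moving" and are excluded.  Returns a dict with keys
    ``rightward`` and ``leftward`` holding :class:`FramePointSet` objects.
    """
    vel = head_yaw_velocity(trial, smooth_ms)
    eih = frame_points(trial, "eyes_in_head")
    out = {}
    for name, mask in (("rightward", vel > deadband_deg_s), ("leftward", vel < -deadband_deg_s)):
        out[name] = FramePointSet(
            "eyes_in_head", eih.lon[mask], eih.lat[mask], trial.subject_id, trial.posture
        )
    return out


def detect_bimodality(lons, min_points: int = 100, prominence_frac: float = 0.2, grid_step: float = 0.5):
    """Find opposite-sign side peaks in a longitude distribution.

    A kernel-density estimate of the longitudes is evaluated on a regular
    grid and its modes are extracted with a topographic-prominence criterion:
    a mode counts only if it rises by at least ``prominence_frac`` of the
    global maximum above the saddles that separate it from higher terrain
    (shoulders and sampling wiggles are ignored).  The distribution is
    bimodal when two such modes lie on opposite signs of the zero meridian.
    Returns a dict with ``peak_left``, ``peak_right`` (degrees; NaN when
    absent) and ``bimodal``.
    """
    from scipy.signal import find_peaks

    lons = np.asarray(lons, dtype=float)
    if len(lons) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(lons)}")
    grid = np.arange(-180.0, 180.0 + grid_step, grid_step)
    dens = gaussian_kde(lons)(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    order = peaks[np.argsort(dens[peaks])[::-1]]
    primary = order[0]
    opposite = [p for p in order[1:] if np.sign(grid[p]) * np.sign(grid[primary]) < 0]
    result = {
        "peak_left": np.nan,
        "peak_right": np.nan,
        "bimodal": False,
        "peaks": [(float(grid[p]), float(dens[p] / dens.max())) for p in order],
    }
    if opposite:
        secondary = opposite[0]
        left, right = sorted((grid[primary], grid[secondary]))
        result.update(peak_left=float(left), peak_right=float(right), bimodal=True)
    else:
        key = "peak_right" if grid[primary] >= 0 else "peak_left"
        result[key] = float(grid[primary])
    return result


def heatmap(point_set: FramePointSet, n_lon: int = 360, n_lat: int = 180, smoothing_deg: float = 0.0):
    """Equirectangular density grid of a point set, normalized to sum 1.

    Counts are binned on a uniform lon/lat grid (rows = latitude bands from
    -90 to 90, columns = longitude from -180 to 180).  Optional Gaussian
    smoothing wraps around the longitude axis.  Note the equirectangular map
    over-represents the poles; treat densities per bin, not per solid angle.
    """
    lon = wrap_degrees(point_set.lon)
    h, _, _ = np.histogram2d(
        point_set.lat,
        lon,
        bins=[n_lat, n_lon],
        range=[[-90.0, 90.0], [-180.0, 180.0]],
        weights=point_set.weights,
    )
    if smoothing_deg > 0:
        sigma = (smoothing_deg / (180.0 / n_lat), smoothing_deg / (360.0 / n_lon))
        h = ndimage.gaussian_filter(h, sigma=sigma, mode=("nearest", "wrap"))
    total = h.sum()
    return h / total if total > 0 else h
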