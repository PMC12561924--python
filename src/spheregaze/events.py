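"""Fixation and saccade detection on the eyes-in-space stream.

Fixations are found with a dispersion-threshold (I-DT) scheme adapted to the
sphere: a fixation is a maximal left-to-right window of gaze samples whose
largest pairwise orthodromic distance stays within a dispersion threshold
(default 3 degrees) and whose duration reaches a minimum (default 80 ms).
Using the geodesic max-pairwise extent instead of the classic planar
horizontal+vertical extent avoids distortion near the poles.  The fixation
centroid is the renormalized vector mean of its member samples, which is
immune to longitude wraparound.

Saccades are defined between successive fixation centroids; candidates whose
inter-fixation gap exceeds a maximum duration (default 300 ms) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import orthodromic, quat_rotation, vec_to_lonlat

__all__ = [
    "Fixation",
    "Saccade",
    "gaze_vectors",
    "detect_fixations",
    "derive_saccades",
    "verify_fixation",
]

DEFAULT_DISPERSION_DEG = 3.0
DEFAULT_MIN_DUR_MS = 80.0
DEFAULT_MAX_SACC_DUR_MS = 300.0


@dataclass(frozen=True)
class Fixation:
    lon: float
    lat: float
    t_start: float
    t_end: float
    i_start: int
    i_end: int  # inclusive sample index

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


@dataclass(frozen=True)
class Saccade:
    origin: tuple[float, float]
    target: tuple[float, float]
    t_start: float
    t_end: float
    amplitude: float

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


def gaze_vectors(trial) -> np.ndarray:
    """Eyes-in-space unit vectors of a synchronized trial."""
    if not trial.synchronized:
        raise ValueError("trial must be synchronized before gaze integration")
    rot = quat_rotation(trial.head_quat)
    return rot.apply(trial.eye_vec)


def _centroid(vecs: np.ndarray) -> tuple[float, float]:
    m = vecs.mean(axis=0)
    lon, lat = vec_to_lonlat(m)
    return float(lon), float(lat)


def _detect_segment(t, vec, i0, i1, cos_thr, min_dur_s, out):
    """Greedy I-DT over the sample range [i0, i1)."""
    i = i0
    while i < i1:
        # smallest j >= i whose window spans the minimum duration
        j = i + int(np.searchsorted(t[i:i1], t[i] + min_dur_s, side="left"))
        if j >= i1:
            return
        w = vec[i : j + 1]
        gram = w @ w.T
        min_dot = gram.min()
        if min_dot < cos_thr:
            i += 1
            continue
        while j + 1 < i1:
            dots = vec[i : j + 1] @ vec[j + 1]
            d = dots.min()
            if min(min_dot, d) < cos_thr:
                break
            min_dot = min(min_dot, d)
            j += 1
        lon, lat = _centroid(vec[i : j + 1])
        out.append(Fixation(lon, lat, float(t[i]), float(t[j]), i, j))
        i = j + 1


def detect_fixations(
    t,
    vec,
    dispersion_deg: float = DEFAULT_DISPERSION_DEG,
    min_dur_ms: float = DEFAULT_MIN_DUR_MS,
    valid=None,
):
    """Detect fixations in a time-ordered gaze stream.

    Parameters
    ----------
    t, vec
        Sample times (s) and eyes-in-space unit vectors, shape (n,) / (n, 3).
    dispersion_deg
        Maximum pairwise orthodromic distance permitted within a fixation.
    min_dur_ms
        Minimum window duration (t_end - t_start) for emission.
    valid
        Optional boolean mask; invalid samples (blinks, dropouts) split
        candidate windows and are never interpolated across.

    Returns a time-ordered, non-overlapping list of :class:`Fixation`.
    An empty stream yields an empty list.
    """
    t = np.asarray(t, dtype=float)
    vec = np.asarray(vec, dtype=float)
    if len(t) == 0:
        return []
    cos_thr = np.cos(np.deg2rad(dispersion_deg))
    min_dur_s = min_dur_ms / 1000.0
    out: list[Fixation] = []
    if valid is None:
        _detect_segment(t, vec, 0, len(t), cos_thr, min_dur_s, out)
    else:
        valid = np.asarray(valid, dtype=bool)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], valid.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            _detect_segment(t, vec, int(a), int(b), cos_thr, min_dur_s, out)
    return out


def derive_saccades(fixations, max_dur_ms: float = DEFAULT_MAX_SACC_DUR_MS):
    """Saccades between successive fixations, dropping over-long gaps.

    One candidate per adjacent fixation pair; candidates whose gap exceeds
    ``max_dur_ms`` are ignored.  Amplitude is the orthodromic distance
    between the two centroids.  Fewer than two fixations yield no saccades.
    """
    out: list[Saccade] = []
    for a, b in zip(fixations[:-1], fixations[1:]):
        gap_ms = (b.t_start - a.t_end) * 1000.0
        if gap_ms > max_dur_ms:
            continue
        amp = float(orthodromic(a.lon, a.lat, b.lon, b.lat))
        out.append(Saccade((a.lon, a.lat), (b.lon, b.lat), a.t_end, b.t_start, amp))
    return out


def verify_fixation(fix: Fixation, t, vec, dispersion_deg=DEFAULT_DISPERSION_DEG, min_dur_ms=DEFAULT_MIN_DUR_MS) -> bool:
    """Independently re-check a fixation's duration and dispersion invariants."""
    if fix.duration_ms < min_dur_ms - 1e-9:
        return False
    w = np.asarray(vec)[fix.i_start : fix.i_end + 1]
    gram = np.clip(w @ w.T, -1.0, 1.0)
    max_pair = np.rad2deg(np.arccos(gram.min()))
    return bool(max_pair <= dispersion_deg + 1e-9)
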