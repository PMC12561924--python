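"""Temporal coordination of eyes, head, and torso.

Two analyses: (1) eyes-in-head eccentricity - the angular deviation of the
eye direction from the head-forward axis - time-locked to saccade onsets,
which shows the head catching up with the eyes during fixations (eccentricity
decays to a posture-dependent minimum at the moment the next saccade starts,
then jumps); and (2) the latency between head and torso rotation onsets,
which captures the ordered recruitment eyes -> head -> torso.

Rotation onsets use a speed-threshold detector with hysteresis: an onset is
the time the smoothed angular speed first exceeds an upper threshold,
accepted only when the ensuing movement accumulates a minimum displacement
before the speed falls back below a lower threshold (which also prevents
double triggers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import orthodromic_vec

__all__ = [
    "EccentricityProfile",
    "OnsetDelay",
    "eccentricity_series",
    "saccade_locked_segments",
    "profile_from_segments",
    "lock_to_saccade_starts",
    "detect_rotation_onsets",
    "head_torso_delay",
]

DEFAULT_WINDOW_MS = (-400.0, 200.0)
DEFAULT_BIN_MS = 4.0
DEFAULT_VEL_THRESH = 10.0  # deg/s, onset trigger
DEFAULT_HYST_THRESH = 5.0  # deg/s, movement-end threshold
DEFAULT_MIN_MOVE_DEG = 5.0
DEFAULT_SMOOTH_MS = 50.0
DEFAULT_MAX_PAIR_GAP_MS = 500.0

_FORWARD = np.array([1.0, 0.0, 0.0])


@dataclass
class EccentricityProfile:
    offsets_ms: np.ndarray
    mean_ecc: np.ndarray
    ci95: np.ndarray
    min_ecc: float
    n_events: int
    n_skipped: int = 0

    @property
    def empty(self) -> bool:
        return self.n_events == 0


@dataclass
class OnsetDelay:
    head_onsets: np.ndarray
    torso_onsets: np.ndarray
    delays_ms: np.ndarray  # signed, torso minus head, one per matched pair

    @property
    def empty(self) -> bool:
        return len(self.delays_ms) == 0

    @property
    def mean_delay_ms(self) -> float:
        return float(np.mean(self.delays_ms)) if len(self.delays_ms) else float("nan")


def eccentricity_series(trial) -> np.ndarray:
    """Per-sample eyes-in-head eccentricity (degrees).

    The angular magnitude of the eye-in-head direction away from the
    head-forward axis, i.e. the orthodromic distance of the eyes-in-head
    point from (0, 0).  Invariant to any global rotation of the scene.
    """
    v = trial.eye_vec / np.linalg.norm(trial.eye_vec, axis=1, keepdims=True)
    return orthodromic_vec(v, _FORWARD)


def saccade_locked_segments(t, ecc, saccades, window_ms=DEFAULT_WINDOW_MS, bin_ms=DEFAULT_BIN_MS):
    """Extract per-event eccentricity segments around each saccade start.

    Returns ``(offsets_ms, matrix, n_skipped)`` where ``matrix`` has one row
    per usable saccade, sampled by interpolation on the offset grid.  Events
    whose window leaves the trial bounds are skipped and counted.
    """
    t = np.asarray(t, dtype=float)
    ecc = np.asarray(ecc, dtype=float)
    offsets = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    rows, skipped = [], 0
    for s in saccades:
        lo = s.t_start + offsets[0] / 1000.0
        hi = s.t_start + offsets[-1] / 1000.0
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            skipped += 1
            continue
        rows.append(np.interp(s.t_start + offsets / 1000.0, t, ecc))
    matrix = np.array(rows) if rows else np.empty((0, len(offsets)))
    return offsets, matrix, skipped


def profile_from_segments(offsets_ms, matrix, n_skipped=0) -> EccentricityProfile:
    """Average event segments into a profile with a between-event 95% CI.

    ``min_ecc`` is the minimum of the event-averaged curve at or before
    offset zero (the saccade start), matching where the head has caught up
    most.  Zero events yield an explicitly empty profile (NaN curve).
    """
    n = len(matrix)
    if n == 0:
        nan = np.full(len(offsets_ms), np.nan)
        return EccentricityProfile(np.asarray(offsets_ms), nan, nan, float("nan"), 0, n_skipped)
    mean = matrix.mean(axis=0)
    if n > 1:
        ci = 1.96 * matrix.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        ci = np.zeros_like(mean)
    pre = offsets_ms <= 0
    return EccentricityProfile(
        np.asarray(offsets_ms), mean, ci, float(mean[pre].min()), n, n_skipped
    )


def lock_to_saccade_starts(t, ecc, saccades, window_ms=DEFAULT_WINDOW_MS, bin_ms=DEFAULT_BIN_MS):
    """Saccade-locked eccentricity profile for a single trial."""
    offsets, matrix, skipped = saccade_locked_segments(t, ecc, saccades, window_ms, bin_ms)
    return profile_from_segments(offsets, matrix, skipped)


def _smooth(x, w):
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_rotation_onsets(
    t,
    yaw,
    vel_thresh: float = DEFAULT_VEL_THRESH,
    hyst_thresh: float = DEFAULT_HYST_THRESH,
    min_move_deg: float = DEFAULT_MIN_MOVE_DEG,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> np.ndarray:
    """Rotation onset times of a yaw series (seconds).

    The yaw is unwrapped, differentiated, and the speed boxcar-smoothed over
    ``smooth_ms``.  An upward crossing of ``vel_thresh`` opens a movement;
    the movement closes when the speed falls below ``hyst_thresh`` and is
    kept only if the net yaw displacement over it reaches ``min_move_deg``.
    Because the boxcar is centered, the smoothed speed reacts half a window
    before the movement itself; reported onset times compensate by
    ``smooth_ms/2``.  A constant series yields no onsets.
    """
    t = np.asarray(t, dtype=float)
    if len(t) < 3:
        return np.empty(0)
    yaw_u = np.rad2deg(np.unwrap(np.deg2rad(np.asarray(yaw, dtype=float))))
    dt = float(np.median(np.diff(t)))
    vel = np.gradient(yaw_u, t)
    w = max(int(round(smooth_ms / 1000.0 / dt)), 1)
    speed = np.abs(_smooth(vel, w))
    onsets = []
    i, n = 1, len(t)
    while i < n:
        if speed[i] >= vel_thresh and speed[i - 1] < vel_thresh:
            j = i
            while j + 1 < n and speed[j + 1] >= hyst_thresh:
                j += 1
            if abs(yaw_u[j] - yaw_u[i]) >= min_move_deg:
                onsets.append(t[i] + 0.5 * smooth_ms / 1000.0)
            i = j + 1
        else:
            i += 1
    return np.asarray(onsets)


def head_torso_delay(head_onsets, torso_onsets, max_pair_gap_ms: float = DEFAULT_MAX_PAIR_GAP_MS) -> OnsetDelay:
    """Pair torso onsets with preceding head onsets and report signed delays.

    Each torso onset is matched to the nearest head onset at or before it
    within ``max_pair_gap_ms``; each head onset is used at most once, and
    unpaired onsets on either side are dropped.  Delays are torso minus head
    in milliseconds; an empty pairing is flagged through ``OnsetDelay.empty``.
    """
    head = np.sort(np.asarray(head_onsets, dtype=float))
    torso = np.sort(np.asarray(torso_onsets, dtype=float))
    delays = []
    used = -1
    for tt in torso:
        k = int(np.searchsorted(head, tt, side="right")) - 1
        if k <= used:
            continue
        gap_ms = (tt - head[k]) * 1000.0
        if 0.0 <= gap_ms <= max_pair_gap_ms:
            delays.append(gap_ms)
            used = k
    return OnsetDelay(head, torso, np.asarray(delays))
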