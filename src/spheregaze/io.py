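"""Trial logs, manifests, and multi-rate stream synchronization.

A trial couples two native streams: the eye tracker samples eye-in-head unit
direction vectors at a nominal 250 Hz, while the headset/body trackers sample
the head orientation quaternion plus torso (and, in the swivel posture, chair)
yaw at a nominal 90 Hz.  Before any world-coordinate analysis the two streams
are resampled onto a common timebase; by default the eye timestamps, so that
no eye-event timing is degraded.

Log dialect
-----------
One CSV per trial with header ``stream,t,ex,ey,ez,qw,qx,qy,qz,torso_yaw,chair_yaw``.
Rows tagged ``eye`` carry ``t,ex,ey,ez``; rows tagged ``body`` carry
``t,qw..qz,torso_yaw`` and optionally ``chair_yaw`` (empty for sit/stand,
where the chair is structurally stationary).  A JSON manifest lists the trial
files with subject/posture/stimulus metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .sphere import NORM_TOL, wrap_degrees

__all__ = [
    "Trial",
    "TrialLoadError",
    "StreamGapError",
    "read_trial_log",
    "write_trial_log",
    "read_manifest",
    "write_manifest",
    "load_experiment",
    "synchronize",
]

POSTURES = ("sit", "swivel", "stand")
STIMULUS_TYPES = ("indoor", "outdoor")

LOG_COLUMNS = ["stream", "t", "ex", "ey", "ez", "qw", "qx", "qy", "qz", "torso_yaw", "chair_yaw"]


class TrialLoadError(ValueError):
    """Structured failure while parsing or validating a trial log."""


class StreamGapError(ValueError):
    """A gap in a native stream exceeds the allowed maximum."""


@dataclass
class Trial:
    """One 10-second viewing trial with its orientation streams.

    Before synchronization ``t_eye``/``eye_vec`` and ``t_body``/``head_quat``/
    ``torso_yaw``/``chair_yaw`` live on their native timebases; afterwards all
    signals share the common timestamps ``t_eye`` (and ``t_body is t_eye``).
    ``chair_yaw`` is None except in the swivel posture.  Quaternions are
    scalar-first, yaws in degrees with positive values to the right.
    """

    subject_id: str
    posture: str
    stimulus_type: str
    t_eye: np.ndarray
    eye_vec: np.ndarray
    t_body: np.ndarray
    head_quat: np.ndarray
    torso_yaw: np.ndarray
    chair_yaw: np.ndarray | None = None
    synchronized: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        if self.stimulus_type not in STIMULUS_TYPES:
            raise ValueError(f"unknown stimulus type {self.stimulus_type!r}")

    @property
    def duration(self) -> float:
        if len(self.t_eye) == 0:
            return 0.0
        lo = min(self.t_eye[0], self.t_body[0])
        hi = max(self.t_eye[-1], self.t_body[-1])
        return float(hi - lo)

    @property
    def t(self) -> np.ndarray:
        """Common timebase (only defined once synchronized)."""
        if not self.synchronized:
            raise ValueError("trial is not synchronized; call synchronize() first")
        return self.t_eye


def _check_monotone(t: np.ndarray, stream: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TrialLoadError(
            f"non-monotone timestamps in {stream} stream at row index {int(bad[0]) + 1}"
        )


def _validate_trial(trial: Trial, max_invalid_frac: float = 0.05) -> Trial:
    _check_monotone(trial.t_eye, "eye")
    _check_monotone(trial.t_body, "body")
    enorm = np.linalg.norm(trial.eye_vec, axis=1)
    qnorm = np.linalg.norm(trial.head_quat, axis=1)
    bad_e = np.abs(enorm - 1.0) > NORM_TOL
    bad_q = np.abs(qnorm - 1.0) > NORM_TOL
    n_bad = int(bad_e.sum() + bad_q.sum())
    n_tot = len(enorm) + len(qnorm)
    if n_tot and n_bad / n_tot > max_invalid_frac:
        first = int(np.argmax(bad_e)) if bad_e.any() else int(np.argmax(bad_q))
        raise TrialLoadError(
            f"{n_bad}/{n_tot} samples fail unit-norm validation (first bad row {first})"
        )
    trial.eye_vec = trial.eye_vec / enorm[:, None]
    trial.head_quat = trial.head_quat / qnorm[:, None]
    return trial


def read_trial_log(path, subject_id: str, posture: str, stimulus_type: str) -> Trial:
    """Parse one trial CSV and return a validated (unsynchronized) trial.

    Raises :class:`TrialLoadError` naming the offending row for missing
    columns, non-monotone time, or more than 5% invalid samples.
    """
    path = Path(path)
    eye_rows, body_rows = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != LOG_COLUMNS:
            raise TrialLoadError(f"{path}: missing or malformed header; expected {LOG_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            tag = row[0]
            try:
                if tag == "eye":
                    eye_rows.append([float(row[1]), float(row[2]), float(row[3]), float(row[4])])
                elif tag == "body":
                    chair = float(row[10]) if row[10] != "" else np.nan
                    body_rows.append(
                        [float(row[1])] + [float(x) for x in row[5:10]] + [chair]
                    )
                else:
                    raise TrialLoadError(f"{path}: unknown stream tag {tag!r} at row {i}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, TrialLoadError):
                    raise
                raise TrialLoadError(f"{path}: malformed row {i}: {exc}") from exc
    if not eye_rows or not body_rows:
        raise TrialLoadError(f"{path}: trial log must contain both eye and body rows")
    eye = np.asarray(eye_rows)
    body = np.asarray(body_rows)
    chair = body[:, 6]
    trial = Trial(
        subject_id=subject_id,
        posture=posture,
        stimulus_type=stimulus_type,
        t_eye=eye[:, 0],
        eye_vec=eye[:, 1:4],
        t_body=body[:, 0],
        head_quat=body[:, 1:5],
        torso_yaw=body[:, 5],
        chair_yaw=None if np.isnan(chair).all() else chair,
    )
    return _validate_trial(trial)


def write_trial_log(trial: Trial, path) -> None:
    """Write a trial's native streams in the log dialect (inverse of reading)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_COLUMNS)
        for t, v in zip(trial.t_eye, trial.eye_vec):
            w.writerow(["eye", repr(float(t)), repr(float(v[0])), repr(float(v[1])),
                        repr(float(v[2])), "", "", "", "", "", ""])
        chair = trial.chair_yaw
        for i, (t, q, ty) in enumerate(zip(trial.t_body, trial.head_quat, trial.torso_yaw)):
            c = "" if chair is None else repr(float(chair[i]))
            w.writerow(["body", repr(float(t)), "", "", "",
                        repr(float(q[0])), repr(float(q[1])), repr(float(q[2])),
                        repr(float(q[3])), repr(float(ty)), c])


def write_manifest(entries, path) -> None:
    """Write a JSON manifest: a list of {file, subject_id, posture, stimulus_type}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"trials": list(entries)}, fh, indent=1)


def read_manifest(path):
    with open(path) as fh:
        data = json.load(fh)
    return data["trials"]


def load_experiment(manifest_path):
    """Yield validated trials listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    for entry in read_manifest(manifest_path):
        p = manifest_path.parent / entry["file"]
        yield read_trial_log(p, entry["subject_id"], entry["posture"], entry["stimulus_type"])


def _interp_yaw(t_out, t_in, yaw):
    """Linear interpolation of a wrapped angle series, unwrapped across +/-180."""
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(yaw)))
    out = np.interp(t_out, t_in, unwrapped)
    return wrap_degrees(out)


def synchronize(trial: Trial, target_rate: float | None = None, max_gap_s: float = 0.1) -> Trial:
    """Resample all signals of a trial onto a common timebase.

    By default the eye timestamps (the highest-rate stream) are the common
    timebase; pass ``target_rate`` (Hz) for a fixed uniform grid instead.
    Head quaternions are interpolated by slerp, torso/chair yaw linearly after
    unwrapping across the +/-180 meridian, and eye vectors linearly with
    renormalization.  Edges are clamped to the nearest native sample.
    Synchronizing an already-synchronized trial at the same timebase is a
    no-op.  A gap larger than ``max_gap_s`` in either stream raises
    :class:`StreamGapError`.
    """
    for t_s, name in ((trial.t_eye, "eye"), (trial.t_body, "body")):
        if len(t_s) > 1:
            gaps = np.diff(t_s)
            k = int(np.argmax(gaps))
            if gaps[k] > max_gap_s:
                raise StreamGapError(
                    f"{name} stream gap of {gaps[k]:.4f} s at t={t_s[k]:.4f} s exceeds {max_gap_s} s"
                )

    if target_rate is None:
        t_out = trial.t_eye.copy()
    else:
        t0 = max(trial.t_eye[0], trial.t_body[0])
        t1 = min(trial.t_eye[-1], trial.t_body[-1])
        n = max(int(np.floor((t1 - t0) * target_rate)) + 1, 1)
        t_out = t0 + np.arange(n) / target_rate

    # eye vectors: linear interpolation + renormalization, edges clamped
    tq = np.clip(t_out, trial.t_eye[0], trial.t_eye[-1])
    ev = np.empty((len(t_out), 3))
    for k in range(3):
        ev[:, k] = np.interp(tq, trial.t_eye, trial.eye_vec[:, k])
    ev /= np.linalg.norm(ev, axis=1, keepdims=True)

    # head quaternions: slerp on the body timebase, edges clamped
    tb = np.clip(t_out, trial.t_body[0], trial.t_body[-1])
    if len(trial.t_body) > 1:
        xyzw = np.concatenate([trial.head_quat[:, 1:4], trial.head_quat[:, 0:1]], axis=1)
        # enforce sign continuity so slerp takes the short arc
        for i in range(1, len(xyzw)):
            if np.dot(xyzw[i], xyzw[i - 1]) < 0:
                xyzw[i] = -xyzw[i]
        slerp = Slerp(trial.t_body, Rotation.from_quat(xyzw))
        q_out = slerp(tb).as_quat()
        quat = np.concatenate([q_out[:, 3:4], q_out[:, :3]], axis=1)
    else:
        quat = np.repeat(trial.head_quat, len(t_out), axis=0)

    torso = _interp_yaw(tb, trial.t_body, trial.torso_yaw)
    chair = None if trial.chair_yaw is None else _interp_yaw(tb, trial.t_body, trial.chair_yaw)

    return replace(
        trial,
        t_eye=t_out,
        eye_vec=ev,
        t_body=t_out,
        head_quat=quat,
        torso_yaw=np.asarray(torso),
        chair_yaw=None if chair is None else np.asarray(chair),
        synchronized=True,
    )
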