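import numpy as np
import pytest

from spheregaze import synth
from spheregaze.io import Trial
from spheregaze.sphere import yaw_pitch_quat


@pytest.fixture(scope="session")
def profiles():
    return synth.default_profiles()


@pytest.fixture(scope="session")
def gen_config():
    return synth.GeneratorConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Generator configuration with measurement noise switched off."""
    return synth.GeneratorConfig(
        eye_noise_deg=0.0, head_noise_deg=0.0, torso_noise_deg=0.0,
        chair_noise_deg=0.0, delay_noise_ms=0.0,
    )


def make_synced_trial(t, head_yaw, head_pitch=None, eih_lon=None, eih_lat=None,
                      torso_yaw=None, chair_yaw=None, posture="stand",
                      subject="s00", stimulus="indoor"):
    """Build an already-synchronized trial from yaw/pitch series (degrees)."""
    from spheregaze.sphere import lonlat_to_vec

    t = np.asarray(t, dtype=float)
    head_yaw = np.broadcast_to(np.asarray(head_yaw, dtype=float), t.shape)
    head_pitch = np.zeros_like(t) if head_pitch is None else np.broadcast_to(
        np.asarray(head_pitch, dtype=float), t.shape)
    eih_lon = np.zeros_like(t) if eih_lon is None else np.broadcast_to(
        np.asarray(eih_lon, dtype=float), t.shape)
    eih_lat = np.zeros_like(t) if eih_lat is None else np.broadcast_to(
        np.asarray(eih_lat, dtype=float), t.shape)
    torso = np.zeros_like(t) if torso_yaw is None else np.broadcast_to(
        np.asarray(torso_yaw, dtype=float), t.shape)
    quat = np.atleast_2d(yaw_pitch_quat(head_yaw, head_pitch))
    return Trial(
        subject_id=subject, posture=posture, stimulus_type=stimulus,
        t_eye=t, eye_vec=lonlat_to_vec(eih_lon, eih_lat),
        t_body=t, head_quat=quat, torso_yaw=np.asarray(torso, dtype=float),
        chair_yaw=None if chair_yaw is None else np.broadcast_to(
            np.asarray(chair_yaw, dtype=float), t.shape).astype(float),
        synchronized=True,
    )
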