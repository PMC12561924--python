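"""End-to-end per-trial analysis and condition-level aggregation.

Glue that runs a trial through synchronization, gaze integration, fixation
and saccade detection, exploration metrics, frame projections, and the
coordination analyses, and pools the products per posture condition.  Every
step is the corresponding module's public operation; nothing here adds
analysis logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coordination, events, exploration, frames
from .io import synchronize

__all__ = ["TrialProducts", "process_trial", "condition_recovery", "trial_metrics_table"]


@dataclass
class TrialProducts:
    trial: object
    fixations: list
    saccades: list
    gaze_lon: np.ndarray
    gaze_lat: np.ndarray
    ecc_segments: np.ndarray  # events x offsets eccentricity matrix
    ecc_offsets: np.ndarray
    delays_ms: np.ndarray
    exploration: exploration.TrialExploration | None


def process_trial(trial, dispersion_deg=events.DEFAULT_DISPERSION_DEG,
                  min_dur_ms=events.DEFAULT_MIN_DUR_MS,
                  max_sacc_dur_ms=events.DEFAULT_MAX_SACC_DUR_MS,
                  with_coverage: bool = False,
                  coverage_resolution: int = exploration.DEFAULT_GRID_CELLS) -> TrialProducts:
    """Run the full event/coordination pipeline on one (raw) trial.

    Coverage is optional because the grid union is by far the most expensive
    step when processing thousands of trials.
    """
    trial = trial if trial.synchronized else synchronize(trial)
    gvec = events.gaze_vectors(trial)
    fixations = events.detect_fixations(trial.t, gvec, dispersion_deg, min_dur_ms)
    saccades = events.derive_saccades(fixations, max_sacc_dur_ms)
    from .sphere import vec_to_lonlat

    glon, glat = vec_to_lonlat(gvec)
    ecc = coordination.eccentricity_series(trial)
    offsets, segs, _ = coordination.saccade_locked_segments(trial.t, ecc, saccades)
    hlon, _ = frames.head_lonlat(trial)
    head_on = coordination.detect_rotation_onsets(trial.t, hlon)
    torso_on = coordination.detect_rotation_onsets(trial.t, trial.torso_yaw)
    delays = coordination.head_torso_delay(head_on, torso_on).delays_ms
    expl = None
    if with_coverage:
        expl = exploration.trial_exploration(fixations, saccades,
                                             resolution=coverage_resolution)
    return TrialProducts(trial, fixations, saccades, np.asarray(glon),
                         np.asarray(glat), segs, offsets, delays, expl)


def trial_metrics_table(products) -> pd.DataFrame:
    """Trial-level metric rows suitable for :func:`spheregaze.stats.aggregate`."""
    rows = []
    for p in products:
        t = p.trial
        durs = [f.duration_ms for f in p.fixations]
        rows.append({
            "subject": t.subject_id,
            "posture": t.posture,
            "stimulus_type": t.stimulus_type,
            "n_fixations": len(p.fixations),
            "mean_fix_dur_ms": float(np.mean(durs)) if durs else np.nan,
            "total_distance": exploration.total_distance(p.saccades),
            "coverage": p.exploration.coverage if p.exploration else np.nan,
            "sd_lon": float(np.std(p.gaze_lon, ddof=1)),
        })
    return pd.DataFrame(rows)


def condition_recovery(products_by_posture: dict) -> pd.DataFrame:
    """Recover the headline condition parameters from processed trials.

    For each posture: subject-then-condition averaged longitude spreads of
    eyes-in-space and torso-in-space, the event-pooled saccade-locked
    eccentricity minimum, and the event-pooled mean head-to-torso onset
    delay.
    """
    rows = []
    for posture, prods in products_by_posture.items():
        gaze_sets = [frames.FramePointSet("eyes_in_space", p.gaze_lon, p.gaze_lat,
                                          p.trial.subject_id, posture) for p in prods]
        torso_sets = [frames.frame_points(p.trial, "torso_in_space") for p in prods]
        sd_gaze = frames.condition_spreads(frames.spread_stats(gaze_sets))
        sd_torso = frames.condition_spreads(frames.spread_stats(torso_sets))
        segs = np.vstack([p.ecc_segments for p in prods if len(p.ecc_segments)])
        profile = coordination.profile_from_segments(prods[0].ecc_offsets, segs)
        delays = np.concatenate([p.delays_ms for p in prods])
        rows.append({
            "posture": posture,
            "gaze_sd_lon": float(sd_gaze.loc[posture, "sd_lon"]),
            "gaze_mean_lat": float(sd_gaze.loc[posture, "mean_lat"]),
            "torso_sd_lon": float(sd_torso.loc[posture, "sd_lon"]),
            "ecc_min": profile.min_ecc,
            "delay_ms": float(np.mean(delays)) if len(delays) else np.nan,
            "n_events": int(profile.n_events),
            "n_delay_pairs": int(len(delays)),
        })
    return pd.DataFrame(rows).set_index("posture")
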