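"""Velocity-based saccade and blink detection on gaze traces.

Detection smooths position with a Savitzky-Golay local polynomial,
differentiates it, and opens an event where 2-D speed crosses a main
threshold (default 30 deg/s).  Event edges are then refined outward to a
lower onset threshold so that the reported onset approximates the true
start of the movement rather than the instant the main threshold was
crossed.  Trials are excluded per the measurement protocol: blinks,
anticipatory saccades (latency < 60 ms), absent target-directed saccades,
and incorrect responses — in that precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import GazeTrace, TrialRecord


class TraceFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float  # from stimulus onset; T1 when target-directed
    offset_ms: float
    amplitude_deg: float
    peak_velocity_dps: float

    @property
    def duration_ms(self) -> float:  # T2
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TrialOculomotor:
    trial_id: int
    t1_ms: float | None
    t2_ms: float | None
    excluded: bool
    exclusion_reason: str  # blink | anticipatory | no_saccade | incorrect_response | none

    @property
    def saccade_end_ms(self) -> float | None:
        if self.t1_ms is None or self.t2_ms is None:
            return None
        return self.t1_ms + self.t2_ms


def detect_blinks(trace: GazeTrace, guard_ms: float = 50.0) -> list[tuple[float, float]]:
    """Blink intervals: maximal invalid-sample runs ± a guard, merged."""
    invalid = ~np.asarray(trace.valid, dtype=bool)
    if not invalid.any():
        return []
    t = trace.t
    step = 1000.0 / trace.sample_rate
    edges = np.diff(invalid.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if invalid[0]:
        starts.insert(0, 0)
    if invalid[-1]:
        ends.append(len(invalid))
    intervals = [
        (t[s] - guard_ms, t[e - 1] + step + guard_ms) for s, e in zip(starts, ends)
    ]
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _speed(trace: GazeTrace, window: int, polyorder: int = 2) -> np.ndarray:
    """2-D gaze speed (deg/s) from Savitzky-Golay differentiation.

    NaN gaps (blinks) are linearly bridged before filtering; events falling
    inside blink guards are vetoed downstream so the bridge never surfaces.
    """
    dt = 1.0 / trace.sample_rate

    def clean(a):
        a = np.asarray(a, dtype=float)
        bad = ~np.isfinite(a)
        if bad.any():
            a = a.copy()
            idx = np.arange(len(a))
            if bad.all():
                return np.zeros_like(a)
            a[bad] = np.interp(idx[bad], idx[~bad], a[~bad])
        return a

    window = min(window, len(trace.t) - (1 - len(trace.t) % 2))
    vx = savgol_filter(clean(trace.x), window, polyorder, deriv=1, delta=dt)
    vy = savgol_filter(clean(trace.y), window, polyorder, deriv=1, delta=dt)
    return np.hypot(vx, vy)


def detect_saccades(
    trace: GazeTrace,
    velocity_threshold_dps: float = 30.0,
    min_duration_ms: float = 8.0,
    onset_threshold_dps: float = 10.0,
    smooth_window: int | None = None,
    blink_guard_ms: float = 50.0,
) -> list[SaccadeEvent]:
    """Detect saccades in one trace.

    Events open where smoothed 2-D speed exceeds ``velocity_threshold_dps``,
    are extended outward while speed stays above ``onset_threshold_dps``,
    and are discarded if shorter than ``min_duration_ms`` or overlapping a
    blink guard interval.  Amplitude is the Euclidean onset-to-offset
    displacement of the smoothed position.  The default smoothing window
    spans 11 ms (11 samples at 1000 Hz), scaled to the sample rate.
    """
    if smooth_window is None:
        smooth_window = max(5, int(round(11 * trace.sample_rate / 1000.0)) | 1)
    t = np.asarray(trace.t, dtype=float)
    if len(t) < smooth_window + 2:
        raise TraceFormatError("trace too short for saccade detection")
    step = 1000.0 / trace.sample_rate
    if not np.allclose(np.diff(t), step, atol=1e-6):
        raise TraceFormatError("non-uniform timestamps")
    if trace.sample_rate < 250:
        raise TraceFormatError("sample rate below 250 Hz is not supported")

    speed = _speed(trace, smooth_window)
    blinks = detect_blinks(trace, guard_ms=blink_guard_ms)
    above = speed > velocity_threshold_dps
    if not above.any():
        return []

    # maximal runs above the main threshold
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))

    # refine edges outward to the lower threshold, then merge overlaps
    refined = []
    for s, e in zip(starts, ends):
        while s > 0 and speed[s - 1] > onset_threshold_dps:
            s -= 1
        while e < len(speed) and speed[e] > onset_threshold_dps:
            e += 1
        if refined and s <= refined[-1][1]:
            refined[-1] = (refined[-1][0], max(refined[-1][1], e))
        else:
            refined.append((s, e))

    xs = savgol_filter(np.nan_to_num(np.asarray(trace.x, float)), min(smooth_window, len(t) - 1), 3)
    ys = savgol_filter(np.nan_to_num(np.asarray(trace.y, float)), min(smooth_window, len(t) - 1), 3)

    events = []
    for s, e in refined:
        onset, offset = t[s], t[min(e, len(t) - 1)]
        if offset - onset < min_duration_ms:
            continue
        if any(onset < hi and offset > lo for lo, hi in blinks):
            continue
        i1 = min(e, len(t) - 1)
        amp = float(np.hypot(xs[i1] - xs[s], ys[i1] - ys[s]))
        events.append(
            SaccadeEvent(
                onset_ms=float(onset),
                offset_ms=float(offset),
                amplitude_deg=amp,
                peak_velocity_dps=float(np.max(speed[s : e + 1])),
            )
        )
    return events


def extract_trial_metrics(
    trace: GazeTrace,
    trial: TrialRecord,
    anticipatory_cutoff_ms: float = 60.0,
    **detect_kwargs,
) -> TrialOculomotor:
    """Per-trial T1/T2 with exclusion bookkeeping.

    T1/T2 come from the first detected saccade toward the target side with
    amplitude at least half the eccentricity (vetoes microsaccades).
    Exclusion precedence: blink > anticipatory > no_saccade >
    incorrect_response; exclusions are data, not errors.
    """
    if detect_blinks(trace):
        return TrialOculomotor(trial.trial_id, None, None, True, "blink")

    events = detect_saccades(trace, **detect_kwargs)
    target = None
    for ev in events:
        i0 = int(round(ev.onset_ms / (1000.0 / trace.sample_rate)))
        i1 = int(round(ev.offset_ms / (1000.0 / trace.sample_rate)))
        i0 = np.clip(i0, 0, len(trace.x) - 1)
        i1 = np.clip(i1, 0, len(trace.x) - 1)
        dx = trace.x[i1] - trace.x[i0]
        if np.sign(dx) == trial.target_side and ev.amplitude_deg >= trial.eccentricity / 2:
            target = ev
            break

    if target is not None and target.onset_ms < anticipatory_cutoff_ms:
        return TrialOculomotor(
            trial.trial_id, target.onset_ms, target.duration_ms, True, "anticipatory"
        )
    if target is None:
        return TrialOculomotor(trial.trial_id, None, None, True, "no_saccade")
    if not trial.correct:
        return TrialOculomotor(
            trial.trial_id, target.onset_ms, target.duration_ms, True, "incorrect_response"
        )
    return TrialOculomotor(trial.trial_id, target.onset_ms, target.duration_ms, False, "none")


def metrics_to_frame(metrics: list[TrialOculomotor]):
    import pandas as pd

    return pd.DataFrame(
        {
            "trial_id": [m.trial_id for m in metrics],
            "t1_ms": [m.t1_ms for m in metrics],
            "t2_ms": [m.t2_ms for m in metrics],
            "saccade_end_ms": [m.saccade_end_ms for m in metrics],
            "excluded": [int(m.excluded) for m in metrics],
            "reason": [m.exclusion_reason for m in metrics],
        }
    )
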