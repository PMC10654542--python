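"""Epoch-level behavioral summary statistics from trajectory recordings.

Time averages over irregularly sampled signals use the trapezium rule with
linear interpolation at window edges.  Escape-dependent measures are missing
(NaN / None) whenever no escape was initiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .simulate import EventLog, TrajectoryRecording

__all__ = [
    "FeatureConfig",
    "EpochSummary",
    "MalformedLogError",
    "time_average_trapezium",
    "classify_outcome",
    "detect_escape_initiation",
    "interrupted_escape",
    "min_distances",
    "escape_speed_stats",
    "orientation_cosine",
    "visual_scanning_rate",
    "fruit_picking_rate",
    "summarize_epoch",
]


class MalformedLogError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and windows of the feature extractors."""

    initiation_radius: float = 0.5  # m from the fruit-picking position
    min_outward: float = 0.3  # s of sustained outward motion
    smooth_window: float = 0.1  # s moving average before speed statistics
    appear_window: float = 1.5  # s after threat appearance (short condition)
    min_epoch_duration: float = 12.5
    scanning_tracker: str = "head"  # head | gaze
    shelter_position: tuple = (0.0, -2.5)
    # orientation/speed windows start at escape initiation (not appearance)
    escape_window_from_initiation: bool = True


def time_average_trapezium(times, values, window) -> float:
    """Trapezoidal time average of an irregular sample over ``window``.

    The window is intersected with the sampled span, endpoint values are
    linearly interpolated, and the integral is divided by the intersected
    length.  Fewer than two samples (after intersection) yield NaN.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        return math.nan
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    a, b = float(window[0]), float(window[1])
    a = max(a, t[0])
    b = min(b, t[-1])
    if b <= a:
        return math.nan
    inside = (t > a) & (t < b)
    tt = np.concatenate(([a], t[inside], [b]))
    vv = np.concatenate(([np.interp(a, t, v)], v[inside], [np.interp(b, t, v)]))
    return float(np.trapezoid(vv, tt) / (b - a))


def classify_outcome(event_log: EventLog) -> str:
    terminal = [
        x
        for x in (
            event_log.contact_time,
            event_log.magical_force_time,
            event_log.shelter_entry_time,
        )
        if x is not None
    ]
    if len(terminal) > 1:
        raise MalformedLogError("multiple terminal events in one epoch")
    if event_log.contact_time is not None or event_log.magical_force_time is not None:
        return "virtual_death"
    if event_log.shelter_entry_time is not None:
        return "escape_to_shelter"
    return "survived"


def _reference_time(event_log: EventLog) -> Optional[float]:
    if event_log.threat_appearance_time is not None:
        return event_log.threat_appearance_time
    return event_log.reference_time


def detect_escape_initiation(
    recording: TrajectoryRecording,
    event_log: EventLog,
    radius: float = 0.5,
    min_outward: float = 0.3,
    fruit_position: Optional[tuple] = None,
) -> tuple[bool, float]:
    """First sustained movement of the head away from the fruit-picking spot.

    Returns ``(flag, absolute time)``; the time is NaN when no initiation
    was detected.  The fruit position defaults to the head position at the
    first sample (the participant starts at the bush).  Initiation requires
    the distance from the bush to exceed ``radius`` while the radial
    velocity stays outward for ``min_outward`` seconds (or until the
    recording ends).
    """
    ref = _reference_time(event_log)
    if ref is None:
        raise ValueError("neither appearance nor reference time defined")
    t = recording.t
    if len(t) < 2:
        return False, math.nan
    fruit = np.asarray(
        fruit_position if fruit_position is not None else recording.head_pos[0]
    )
    dist = np.linalg.norm(recording.head_pos - fruit, axis=1)
    vel = np.diff(dist) / np.diff(t)  # outward radial velocity, per interval

    n = len(t)
    for i in range(n):
        if t[i] < ref or dist[i] <= radius:
            continue
        # sustained outward motion on [t_i, t_i + min_outward]
        horizon = min(t[i] + min_outward, t[-1])
        j = i
        sustained = True
        while j < n - 1 and t[j] < horizon:
            if vel[j] <= 0:
                sustained = False
                break
            j += 1
        if sustained:
            return True, float(t[i])
    return False, math.nan


def interrupted_escape(initiated: bool, outcome: str) -> Optional[bool]:
    """True for an initiated escape that did not end in shelter entry."""
    if not initiated:
        return None
    return outcome != "escape_to_shelter"


def min_distances(
    recording: TrajectoryRecording, shelter_position: tuple = (0.0, -2.5)
) -> tuple[float, float]:
    """(min participant-threat distance, min participant-shelter distance)."""
    shelter = np.asarray(shelter_position, dtype=float)
    d_shelter = float(np.min(np.linalg.norm(recording.head_pos - shelter, axis=1)))
    d = np.linalg.norm(recording.threat_pos - recording.head_pos, axis=1)
    d = d[np.isfinite(d)]
    d_threat = float(np.min(d)) if len(d) else math.nan
    return d_threat, d_shelter


def _speeds(recording: TrajectoryRecording, smooth_window: float) -> tuple[np.ndarray, np.ndarray]:
    t = recording.t
    p = recording.head_pos
    n = len(t)
    if n < 3:
        return t, np.full(n, math.nan)
    v = np.empty(n)
    v[1:-1] = np.linalg.norm(p[2:] - p[:-2], axis=1) / (t[2:] - t[:-2])
    v[0] = np.linalg.norm(p[1] - p[0]) / (t[1] - t[0])
    v[-1] = np.linalg.norm(p[-1] - p[-2]) / (t[-1] - t[-2])
    if smooth_window > 0:
        dt_med = float(np.median(np.diff(t)))
        k = max(1, int(round(smooth_window / dt_med)))
        if k > 1:
            kernel = np.ones(k) / k
            v = np.convolve(np.pad(v, (k // 2, k - 1 - k // 2), mode="edge"), kernel, "valid")
    return t, v


def escape_speed_stats(
    recording: TrajectoryRecording,
    initiation_time: float,
    end_time: float,
    smooth_window: float = 0.1,
) -> tuple[float, float]:
    """(peak, mean) head speed over the escape window.

    Speeds come from central finite differences smoothed by a moving
    average; the mean uses the trapezium rule over the window.
    """
    if initiation_time is None or not math.isfinite(initiation_time):
        return math.nan, math.nan
    t, v = _speeds(recording, smooth_window)
    mask = (t >= initiation_time) & (t <= end_time)
    if mask.sum() < 2:
        return math.nan, math.nan
    peak = float(np.max(v[mask]))
    mean = time_average_trapezium(t, v, (initiation_time, end_time))
    return peak, mean


def _forward(recording: TrajectoryRecording, tracker: str) -> np.ndarray:
    if tracker in ("head", "gaze"):  # gaze channel aliases the head vector
        return recording.head_forward
    if tracker == "pelvis":
        return recording.pelvis_forward
    raise ValueError(f"unknown tracker {tracker!r}")


def orientation_cosine(recording: TrajectoryRecording, tracker: str, window) -> float:
    """Time-averaged cosine between a forward vector and the threat direction.

    1 is facing the threat, -1 facing directly away.  Samples without a
    visible threat or with a degenerate forward vector are skipped.
    """
    fwd = _forward(recording, tracker)
    rel = recording.threat_pos - recording.head_pos
    norms = np.linalg.norm(rel, axis=1)
    fnorms = np.linalg.norm(fwd, axis=1)
    valid = np.isfinite(norms) & (norms > 0) & (fnorms > 0)
    if valid.sum() < 2:
        return math.nan
    with np.errstate(invalid="ignore"):
        cos = np.einsum("ij,ij->i", fwd, rel) / (norms * fnorms)
    return time_average_trapezium(recording.t[valid], cos[valid], window)


def visual_scanning_rate(recording: TrajectoryRecording, tracker: str, window) -> float:
    """Cumulative angle (degrees) swept by the forward vector, per second.

    The full angle between consecutive forward vectors is summed over the
    window and divided by the time actually spanned by the samples inside
    it, making the measure robust to sampling density.
    """
    fwd = _forward(recording, tracker)
    t = recording.t
    a, b = float(window[0]), float(window[1])
    mask = (t >= a) & (t <= b)
    if mask.sum() < 2:
        return math.nan
    f = fwd[mask]
    tt = t[mask]
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    dots = np.clip(np.einsum("ij,ij->i", f[:-1], f[1:]), -1.0, 1.0)
    total = float(np.sum(np.degrees(np.arccos(dots))))
    span = float(tt[-1] - tt[0])
    if span <= 0:
        return math.nan
    return total / span


def fruit_picking_rate(event_log: EventLog, window) -> float:
    """Picks per second within a half-open window [a, b)."""
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ValueError("window duration must be positive")
    n = sum(1 for x in event_log.fruit_pick_times if a <= x < b)
    return n / (b - a)


@dataclass
class EpochSummary:
    """The per-epoch summary statistics of the behavioral analysis."""

    outcome: str
    initiated_escape: bool
    escape_initiation_time: float  # s after appearance/reference; NaN if none
    interrupted_escape: Optional[bool]
    min_dist_shelter: float
    min_dist_threat: float
    peak_speed: float
    mean_speed: float
    body_orient_appear: float
    body_orient_escape: float
    head_orient_appear: float
    head_orient_escape: float
    fruit_rate_appear: float
    fruit_rate_escape: float
    scan_appear: float
    scan_escape: float
    fruit_rate_to_min_duration: float
    magical_force_death: bool
    reference_time_used: float

    ESCAPE_FIELDS = (
        "escape_initiation_time",
        "interrupted_escape",
        "peak_speed",
        "mean_speed",
        "body_orient_escape",
        "head_orient_escape",
        "fruit_rate_escape",
        "scan_escape",
    )

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_epoch(
    recording: TrajectoryRecording,
    event_log: EventLog,
    config: Optional[FeatureConfig] = None,
) -> EpochSummary:
    """Compute every epoch-level summary statistic for one recording/log pair.

    The appearance window is the ``appear_window`` (1.5 s) after threat
    appearance; the escape window runs from escape initiation until shelter
    entry or epoch end, whichever is earlier.  No-threat epochs anchor the
    appearance window at the log's pre-drawn reference time.
    """
    cfg = config if config is not None else FeatureConfig()
    outcome = classify_outcome(event_log)
    ref = _reference_time(event_log)
    if ref is None:
        raise MalformedLogError("event log has neither appearance nor reference time")

    initiated, t_init = detect_escape_initiation(
        recording, event_log, cfg.initiation_radius, cfg.min_outward
    )
    end = event_log.epoch_end_time
    if event_log.shelter_entry_time is not None:
        end = min(end, event_log.shelter_entry_time)

    appear_win = (ref, ref + cfg.appear_window)
    d_threat, d_shelter = min_distances(recording, cfg.shelter_position)

    if initiated:
        esc_win = (t_init, end) if cfg.escape_window_from_initiation else (ref, end)
        peak, mean = escape_speed_stats(recording, t_init, end, cfg.smooth_window)
        body_esc = orientation_cosine(recording, "pelvis", esc_win)
        head_esc = orientation_cosine(recording, "head", esc_win)
        esc_len = esc_win[1] - esc_win[0]
        fruit_esc = (
            fruit_picking_rate(event_log, esc_win) if esc_len > 0 else math.nan
        )
        scan_esc = visual_scanning_rate(recording, cfg.scanning_tracker, esc_win)
        init_rel = t_init - ref
        interrupted = interrupted_escape(True, outcome)
    else:
        peak = mean = body_esc = head_esc = fruit_esc = scan_esc = math.nan
        init_rel = math.nan
        interrupted = None

    return EpochSummary(
        outcome=outcome,
        initiated_escape=initiated,
        escape_initiation_time=init_rel,
        interrupted_escape=interrupted,
        min_dist_shelter=d_shelter,
        min_dist_threat=d_threat,
        peak_speed=peak,
        mean_speed=mean,
        body_orient_appear=orientation_cosine(recording, "pelvis", appear_win),
        body_orient_escape=body_esc,
        head_orient_appear=orientation_cosine(recording, "head", appear_win),
        head_orient_escape=head_esc,
        fruit_rate_appear=fruit_picking_rate(event_log, appear_win),
        fruit_rate_escape=fruit_esc,
        scan_appear=visual_scanning_rate(recording, cfg.scanning_tracker, appear_win),
        scan_escape=scan_esc,
        fruit_rate_to_min_duration=fruit_picking_rate(
            event_log, (ref, ref + cfg.min_epoch_duration)
        ),
        magical_force_death=event_log.magical_force_time is not None,
        reference_time_used=float(ref),
    )
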