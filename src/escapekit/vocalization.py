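"""Threshold-based vocalization detection in epoch audio.

The detector counts samples whose rectified amplitude exceeds a volume
threshold and flags the clip when the supra-threshold duration strictly
exceeds a time threshold.  Calibration is a constrained grid search (miss
rate at most ``max_miss``, then fewest false alarms), validated by k-fold
Monte-Carlo cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AudioClip",
    "DetectionThresholds",
    "CVResult",
    "BurstSpec",
    "InfeasibleCalibrationError",
    "detect_event",
    "confusion_rates",
    "grid_search_calibrate",
    "monte_carlo_cv",
    "synth_audio",
    "default_volume_grid",
    "default_time_grid",
]


class InfeasibleCalibrationError(RuntimeError):
    """No threshold tuple satisfies the miss-rate constraint."""


@dataclass
class AudioClip:
    """A mono waveform with an optional voiced/unvoiced label."""

    sample_rate: float
    samples: np.ndarray
    label: str = "unknown"  # voiced | unvoiced | unknown

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass(frozen=True)
class DetectionThresholds:
    volume_threshold: float  # amplitude, arbitrary units
    time_threshold: float  # seconds

    def __post_init__(self) -> None:
        if self.volume_threshold <= 0 or self.time_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CVResult:
    mean_miss_rate: float
    mean_false_alarm_rate: float
    per_rep_miss: np.ndarray
    per_rep_false_alarm: np.ndarray
    n_infeasible: int = 0


def detect_event(clip: AudioClip, thresholds: DetectionThresholds) -> bool:
    """True when the supra-threshold duration strictly exceeds the time threshold.

    Amplitude is rectified (|x|) before comparison; both comparisons are
    strict.
    """
    if len(clip.samples) == 0:
        return False
    count = int(np.sum(np.abs(clip.samples) > thresholds.volume_threshold))
    return count / clip.sample_rate > thresholds.time_threshold


def _supra_durations(clips: Sequence[AudioClip], volume: float) -> np.ndarray:
    return np.array(
        [np.sum(np.abs(c.samples) > volume) / c.sample_rate for c in clips]
    )


def confusion_rates(
    clips: Sequence[AudioClip],
    labels: Sequence[str],
    thresholds: DetectionThresholds,
) -> tuple[float, float]:
    """(miss rate over voiced clips, false-alarm rate over unvoiced clips)."""
    labels = list(labels)
    if len(labels) != len(clips):
        raise ValueError("labels and clips differ in length")
    if any(lab not in ("voiced", "unvoiced") for lab in labels):
        raise ValueError("labels must be 'voiced' or 'unvoiced'")
    pos = [c for c, lab in zip(clips, labels) if lab == "voiced"]
    neg = [c for c, lab in zip(clips, labels) if lab == "unvoiced"]
    if not pos or not neg:
        raise ValueError("need at least one voiced and one unvoiced clip")
    miss = sum(1 for c in pos if not detect_event(c, thresholds)) / len(pos)
    fa = sum(1 for c in neg if detect_event(c, thresholds)) / len(neg)
    return miss, fa


def default_volume_grid(clips: Sequence[AudioClip], n: int = 20) -> np.ndarray:
    """Log-spaced volume grid spanning the data's rectified amplitude range."""
    peak = max(float(np.max(np.abs(c.samples), initial=0.0)) for c in clips)
    if peak <= 0:
        peak = 1.0
    return np.geomspace(peak / 1000.0, peak, n)


def default_time_grid() -> np.ndarray:
    return np.arange(0.01, 0.201, 0.01)


def _duration_matrix(clips: Sequence[AudioClip], volume_grid: np.ndarray) -> np.ndarray:
    """Supra-threshold duration (s) per clip (rows) and volume level (cols)."""
    out = np.empty((len(clips), len(volume_grid)))
    for i, c in enumerate(clips):
        a = np.sort(np.abs(c.samples))
        # count of samples strictly above each volume level, via binary search
        counts = len(a) - np.searchsorted(a, volume_grid, side="right")
        out[i] = counts / c.sample_rate
    return out


def _grid_rates(labels, durations, time_grid):
    """Miss/FA for every grid tuple from a precomputed duration matrix."""
    is_pos = np.array([lab == "voiced" for lab in labels])
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    # det[clip, vol, time] = duration strictly exceeds the time threshold
    det = durations[:, :, None] > time_grid[None, None, :]
    miss = np.sum(~det[is_pos], axis=0) / n_pos
    fa = np.sum(det[~is_pos], axis=0) / n_neg
    return miss, fa


def _pick(volume_grid, time_grid, miss, fa, feasible) -> DetectionThresholds:
    # lowest FA among feasible tuples; ties broken by the largest volume
    # threshold, then the largest time threshold (conservative detector)
    best = None
    for i in range(len(volume_grid)):
        for j in range(len(time_grid)):
            if not feasible[i, j]:
                continue
            key = (fa[i, j], -volume_grid[i], -time_grid[j])
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    return DetectionThresholds(float(volume_grid[i]), float(time_grid[j]))


def grid_search_calibrate(
    clips: Sequence[AudioClip],
    labels: Sequence[str],
    volume_grid: Optional[Sequence[float]] = None,
    time_grid: Optional[Sequence[float]] = None,
    max_miss: float = 0.05,
) -> DetectionThresholds:
    """Constrained grid search: miss rate <= ``max_miss``, then fewest false alarms.

    Raises :class:`InfeasibleCalibrationError` when no tuple satisfies the
    miss constraint.
    """
    vg = np.asarray(
        default_volume_grid(clips) if volume_grid is None else volume_grid, dtype=float
    )
    tg = np.asarray(default_time_grid() if time_grid is None else time_grid, dtype=float)
    if len(vg) == 0 or len(tg) == 0:
        raise ValueError("grids must be non-empty")
    miss, fa = _grid_rates(labels, _duration_matrix(clips, vg), tg)
    feasible = miss <= max_miss
    if not feasible.any():
        raise InfeasibleCalibrationError(
            f"no threshold tuple reaches miss rate <= {max_miss}"
        )
    return _pick(vg, tg, miss, fa, feasible)


def _least_miss_tuple(labels, durations, vg, tg) -> DetectionThresholds:
    miss, fa = _grid_rates(labels, durations, tg)
    feasible = miss <= miss.min()
    return _pick(vg, tg, miss, fa, feasible)


def monte_carlo_cv(
    clips: Sequence[AudioClip],
    labels: Sequence[str],
    k: int = 5,
    reps: int = 1000,
    max_miss: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    volume_grid: Optional[Sequence[float]] = None,
    time_grid: Optional[Sequence[float]] = None,
) -> CVResult:
    """k-fold Monte-Carlo cross-validation of the calibrated detector.

    Each repetition holds out 1/k of the clips at random (unstratified),
    calibrates on the remainder, and scores the holdout.  Repetitions where
    calibration is infeasible fall back to the least-miss tuple (counted in
    ``n_infeasible``).
    """
    labels = list(labels)
    n = len(clips)
    n_pos = sum(1 for lab in labels if lab == "voiced")
    if n_pos < k or (n - n_pos) < k:
        raise ValueError(f"need at least {k} clips of each label")
    if rng is None:
        rng = np.random.default_rng()
    vg = np.asarray(
        default_volume_grid(clips) if volume_grid is None else volume_grid, dtype=float
    )
    tg = np.asarray(default_time_grid() if time_grid is None else time_grid, dtype=float)

    n_hold = max(1, n // k)
    durations = _duration_matrix(clips, vg)
    lab_arr = np.array(labels)
    misses, fas = [], []
    n_infeasible = 0
    for _ in range(reps):
        idx = rng.permutation(n)
        hold, train = idx[:n_hold], idx[n_hold:]
        ho_labels = lab_arr[hold]
        if "voiced" not in ho_labels or "unvoiced" not in ho_labels:
            # holdout must contain both classes to define both rates
            continue
        tr_miss, tr_fa = _grid_rates(lab_arr[train], durations[train], tg)
        feasible = tr_miss <= max_miss
        if not feasible.any():
            n_infeasible += 1
            feasible = tr_miss <= tr_miss.min()
        thr = _pick(vg, tg, tr_miss, tr_fa, feasible)
        iv = int(np.searchsorted(vg, thr.volume_threshold))
        it = int(np.searchsorted(tg, thr.time_threshold))
        det = durations[hold, iv] > tg[it]
        pos = ho_labels == "voiced"
        misses.append(float(np.sum(~det[pos]) / pos.sum()))
        fas.append(float(np.sum(det[~pos]) / (~pos).sum()))
    misses = np.asarray(misses)
    fas = np.asarray(fas)
    return CVResult(
        mean_miss_rate=float(misses.mean()),
        mean_false_alarm_rate=float(fas.mean()),
        per_rep_miss=misses,
        per_rep_false_alarm=fas,
        n_infeasible=n_infeasible,
    )


@dataclass(frozen=True)
class BurstSpec:
    """Amplitude/duration law for voiced bursts."""

    amplitude: float = 2500.0  # a.u., on top of background noise
    duration: tuple = (0.08, 0.4)  # uniform draw, seconds
    max_bursts: int = 2


def synth_audio(
    n: int,
    event_spec: Optional[BurstSpec] = None,
    noise_sd: float = 500.0,
    rng: Optional[np.random.Generator] = None,
    sample_rate: float = 8000.0,
    clip_duration: float = 2.0,
    voiced_fraction: float = 0.5,
) -> tuple[list, list]:
    """Generate labeled clips: Gaussian background, plus bursts when voiced.

    Returns ``(clips, labels)``.  Voiced clips contain 1..max_bursts
    sinusoidal bursts of the specified amplitude and duration on top of the
    noise floor; labels are exact by construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    spec = event_spec if event_spec is not None else BurstSpec()
    if rng is None:
        rng = np.random.default_rng()
    n_samp = int(round(sample_rate * clip_duration))
    n_voiced = int(round(n * voiced_fraction))
    clips, labels = [], []
    for i in range(n):
        voiced = i < n_voiced
        x = rng.normal(0.0, noise_sd, n_samp)
        if voiced:
            for _ in range(int(rng.integers(1, spec.max_bursts + 1))):
                dur = rng.uniform(*spec.duration)
                width = max(1, int(round(dur * sample_rate)))
                start = int(rng.integers(0, max(1, n_samp - width)))
                tt = np.arange(width) / sample_rate
                f0 = rng.uniform(200.0, 900.0)
                env = np.sin(np.pi * np.arange(width) / width)
                x[start : start + width] += spec.amplitude * env * np.sin(
                    2 * np.pi * f0 * tt
                )
        clips.append(AudioClip(sample_rate, x, "voiced" if voiced else "unvoiced"))
        labels.append("voiced" if voiced else "unvoiced")
    order = rng.permutation(n)
    return [clips[i] for i in order], [labels[i] for i in order]
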