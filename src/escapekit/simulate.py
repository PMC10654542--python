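"""Synthetic epoch simulation: threat and participant motion under a scenario.

Produces trajectory recordings (head/pelvis pose plus threat position, at a
VR-like frame rate with optional timestamp jitter) and discrete event logs
with the structure the feature-extraction stage expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .kinematics import (
    KinematicParams,
    ScenarioSpec,
    ThreatSpec,
    generate_epoch_scenario,
    heading_to_vector,
)

__all__ = [
    "DelayLaw",
    "ScanPolicy",
    "AgentPolicy",
    "TrajectoryRecording",
    "EventLog",
    "ConfigError",
    "DEFAULT_THREATS",
    "EffectSpec",
    "Cohort",
    "simulate_threat_path",
    "simulate_epoch",
    "medusa_force",
    "generate_cohort",
]

DEFAULT_DT = 1.0 / 90.0  # VR frame rate
CONTACT_RADIUS = 0.4
DOOR_BLOCK_RADIUS = 1.0
SHELTER_RADIUS = 0.5
MIN_PICK_GAP = 1.0  # holding a hand over a fruit takes 1 s


class ConfigError(ValueError):
    """Inconsistent policy/scenario configuration."""


@dataclass(frozen=True)
class DelayLaw:
    """A small distribution spec for reaction/initiation delays (seconds).

    ``kind`` is one of ``constant``, ``uniform``, ``normal`` (truncated at
    zero).  ``a``/``b`` are (value,) / (low, high) / (mean, sd).
    """

    kind: str = "constant"
    a: float = 0.0
    b: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return float(self.a)
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        if self.kind == "normal":
            return float(max(0.0, rng.normal(self.a, self.b)))
        raise ValueError(f"unknown delay law {self.kind!r}")


@dataclass(frozen=True)
class ScanPolicy:
    """Head-scanning behavior: baseline sweep rate plus a post-appearance burst."""

    base_rate: float = 10.0  # deg/s cumulative sweep
    burst_rate: float = 40.0
    burst_duration: float = 1.5
    frequency: float = 1.0  # Hz of the sinusoidal sweep


def _orientation_weight(mode) -> float:
    if mode == "toward" or mode == "toward-threat":
        return 1.0
    if mode == "away":
        return -1.0
    w = float(mode)
    if not -1.0 <= w <= 1.0:
        raise ConfigError("orientation blend weight must lie in [-1, 1]")
    return w


@dataclass
class AgentPolicy:
    """Configurable stand-in for participant behavior in one epoch."""

    initiation_delay_law: DelayLaw = field(default_factory=DelayLaw)
    escape_speed: float = 2.0
    escape_target: str = "shelter"  # shelter | flee | none
    interrupt_rule: bool = False  # abort escape when the threat diverts
    body_orientation_mode: object = "away"  # toward | away | blend weight
    head_scan: ScanPolicy = field(default_factory=ScanPolicy)
    fruit_pick_rate: float = 0.8  # picks/s while at the bush
    vocalize_probability: float = 0.0
    hands_up: bool = False
    force_shield_awareness: bool = False

    def __post_init__(self) -> None:
        if self.escape_speed < 0:
            raise ConfigError("escape_speed must be non-negative")
        if not 0.0 <= self.vocalize_probability <= 1.0:
            raise ConfigError("vocalize_probability must lie in [0, 1]")
        if self.escape_target not in ("shelter", "flee", "none"):
            raise ConfigError(f"unknown escape target {self.escape_target!r}")
        _orientation_weight(self.body_orientation_mode)


@dataclass
class TrajectoryRecording:
    """Per-epoch pose time series; threat position is NaN before appearance."""

    t: np.ndarray
    head_pos: np.ndarray
    head_forward: np.ndarray
    pelvis_pos: np.ndarray
    pelvis_forward: np.ndarray
    threat_pos: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("head_pos", "head_forward", "pelvis_pos", "pelvis_forward", "threat_pos"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def truncate(self, t_max: float) -> "TrajectoryRecording":
        keep = self.t <= t_max + 1e-12
        return TrajectoryRecording(
            self.t[keep],
            self.head_pos[keep],
            self.head_forward[keep],
            self.pelvis_pos[keep],
            self.pelvis_forward[keep],
            self.threat_pos[keep],
        )


@dataclass
class EventLog:
    """Discrete events of one epoch; times in seconds from epoch start."""

    threat_appearance_time: Optional[float]
    epoch_end_time: float
    outcome: str  # escape_to_shelter | survived | virtual_death
    fruit_pick_times: list = field(default_factory=list)
    shelter_entry_time: Optional[float] = None
    contact_time: Optional[float] = None
    magical_force_time: Optional[float] = None
    force_shield: bool = False
    hands_up_signaled: bool = False
    medusa: bool = False
    vocalized: bool = False
    reference_time: Optional[float] = None  # anchor for no-threat epochs

    def __post_init__(self) -> None:
        terminal = [
            x for x in (self.shelter_entry_time, self.contact_time, self.magical_force_time)
            if x is not None
        ]
        if len(terminal) > 1:
            raise ValueError("at most one terminal event may be set")
        for x in terminal + list(self.fruit_pick_times):
            if x > self.epoch_end_time + 1e-9:
                raise ValueError("event times must not exceed epoch_end_time")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EventLog":
        return cls(**d)


def _rotate(vec: tuple, deg: float) -> tuple:
    # rotation about the vertical axis; positive angles turn toward +x
    # (consistent with heading_to_vector)
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    x, y = vec
    return (c * x + s * y, -s * x + c * y)


class _ThreatMover:
    """Stateful threat integrator for one scenario, clocked from appearance."""

    def __init__(self, spec: ScenarioSpec):
        self.spec = spec
        self.pos = [spec.initial_threat_position[0], spec.initial_threat_position[1]]
        self.speed = abs(spec.threat.speed)
        fx, fy = spec.fruit_position_2d
        dx, dy = fx - self.pos[0], fy - self.pos[1]
        n = math.hypot(dx, dy)
        base = (dx / n, dy / n) if n > 0 else (0.0, -1.0)
        # ballistic rock: fixed heading for the whole epoch, with the divert
        # condition realized as a +/-5 degree offset of that heading
        self.ballistic_dir = _rotate(base, spec.heading_offset) if not spec.threat.is_chasing else None
        self.approach_dir = base
        self.halted = False

    def step(self, rel_t: float, participant_pos: tuple, dt: float) -> None:
        if self.halted or self.speed == 0.0:
            return
        spec = self.spec
        if self.ballistic_dir is not None:
            d = self.ballistic_dir
        elif (
            spec.behavior == "divert"
            and spec.divert_onset_time is not None
            and rel_t >= spec.divert_onset_time
        ):
            d = heading_to_vector(spec.divert_heading)
            d = (float(d[0]), float(d[1]))
        elif (
            spec.behavior == "attack"
            and spec.chase_onset_time is not None
            and rel_t >= spec.chase_onset_time
        ):
            dx = participant_pos[0] - self.pos[0]
            dy = participant_pos[1] - self.pos[1]
            n = math.hypot(dx, dy)
            d = (dx / n, dy / n) if n > 1e-9 else (0.0, 0.0)
        else:
            # straight approach toward the fruit-picking position (and
            # beyond, for a non-diverting pre-chase segment)
            d = self.approach_dir
        self.pos[0] += self.speed * d[0] * dt
        self.pos[1] += self.speed * d[1] * dt


def simulate_threat_path(
    spec: ScenarioSpec,
    participant_path: Callable[[float], tuple],
    dt: float,
    duration: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the threat's motion alone, clocked from its appearance.

    ``participant_path`` maps time-since-appearance to a 2-D position (the
    pursuit target once chasing starts).  Returns (times, positions).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = 1.5 * spec.nominal_approach_time
    mover = _ThreatMover(spec)
    times, positions = [], []
    t = 0.0
    while t <= duration + 1e-12:
        times.append(t)
        positions.append((mover.pos[0], mover.pos[1]))
        mover.step(t, tuple(participant_path(t)), dt)
        t += dt
    return np.asarray(times), np.asarray(positions)


def simulate_epoch(
    spec: Optional[ScenarioSpec],
    policy: AgentPolicy,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    *,
    max_duration: Optional[float] = None,
    contact_radius: float = CONTACT_RADIUS,
    door_block_radius: float = DOOR_BLOCK_RADIUS,
    shelter_radius: float = SHELTER_RADIUS,
    force_shield: bool = False,
    hands_up_signaled: bool = False,
    medusa: bool = False,
    timestamp_jitter: float = 0.0,
    params: Optional[KinematicParams] = None,
) -> tuple[TrajectoryRecording, EventLog]:
    """Simulate one epoch under a scenario and a participant policy.

    ``spec=None`` simulates a no-threat epoch: the participant forages for
    the whole duration and a reference anchor time is drawn from the
    appearance-delay law.  Timestamps are laid out at ``dt`` with optional
    uniform jitter (fraction of dt, < 0.5) on interior samples.
    """
    if not 0.0 < dt <= 0.1:
        raise ValueError("dt must lie in (0, 0.1]")
    if policy.hands_up and not hands_up_signaled:
        raise ConfigError("policy raises hands but the scenario does not signal hands-up")
    if not 0.0 <= timestamp_jitter < 0.5:
        raise ValueError("timestamp_jitter must lie in [0, 0.5)")

    p = params if params is not None else KinematicParams()
    fruit = (0.0, p.fruit_position) if spec is None else spec.fruit_position_2d
    shelter = (0.0, p.shelter_position) if spec is None else spec.shelter_position_2d
    delay_lo, delay_hi = (1.0, 11.0) if spec is None else spec.appearance_delay_law
    min_duration = 12.5 if spec is None else spec.min_epoch_duration

    appearance = None if spec is None else float(rng.uniform(delay_lo, delay_hi))
    reference = float(rng.uniform(delay_lo, delay_hi)) if spec is None else None
    initiation_delay = policy.initiation_delay_law.sample(rng)
    if max_duration is None:
        tail = 0.0 if spec is None else spec.nominal_approach_time + 2.0
        max_duration = max(min_duration, (appearance or 0.0) + tail)

    # fruit picks: renewal process with a 1 s minimum inter-pick gap
    picks = []
    if policy.fruit_pick_rate > 0:
        tp = 0.0
        while True:
            tp += max(MIN_PICK_GAP, rng.exponential(1.0 / policy.fruit_pick_rate))
            if tp > max_duration:
                break
            picks.append(tp)

    vocalized = bool(rng.uniform() < policy.vocalize_probability)
    w = _orientation_weight(policy.body_orientation_mode)
    orient_offset = math.degrees(math.acos(w))  # cosine of the offset recovers w
    scan = policy.head_scan
    mover = _ThreatMover(spec) if spec is not None else None

    px, py = fruit
    escaping = False
    escape_start_t = None
    interrupted = False
    hands_raised = False
    escape_dir = None
    esc_speed = policy.escape_speed

    ts, heads, head_fs, pelvis_fs, threats = [], [], [], [], []
    outcome = None
    shelter_entry_time = contact_time = None
    end_time = None

    n_steps = int(math.ceil(max_duration / dt)) + 1
    for i in range(n_steps):
        t = i * dt
        threat_visible = appearance is not None and t >= appearance
        rel = t - appearance if threat_visible else None

        # --- participant update -------------------------------------------
        if appearance is not None and t >= appearance + initiation_delay:
            if hands_up_signaled and policy.hands_up:
                if not hands_raised:
                    hands_raised = True
                    if mover is not None:
                        mover.halted = True  # threat stops attacking
            elif policy.escape_target != "none" and not escaping and not interrupted:
                escaping = True
                if escape_start_t is None:
                    escape_start_t = t
                if policy.escape_target == "shelter":
                    escape_dir = None  # re-aim at shelter each step
                else:  # flee directly away from the threat
                    tx, ty = mover.pos if mover is not None else fruit
                    dx, dy = px - tx, py - ty
                    n = math.hypot(dx, dy)
                    escape_dir = (dx / n, dy / n) if n > 0 else (0.0, -1.0)
        if (
            escaping
            and policy.interrupt_rule
            and spec is not None
            and spec.behavior == "divert"
            and spec.divert_onset_time is not None
            and rel is not None
            and rel >= spec.divert_onset_time
        ):
            escaping = False
            interrupted = True
        if escaping:
            if policy.escape_target == "shelter":
                dx, dy = shelter[0] - px, shelter[1] - py
                n = math.hypot(dx, dy)
                d = (dx / n, dy / n) if n > 1e-9 else (0.0, 0.0)
            else:
                d = escape_dir
            px += esc_speed * d[0] * dt
            py += esc_speed * d[1] * dt

        # --- orientation ---------------------------------------------------
        if threat_visible and mover is not None:
            dx, dy = mover.pos[0] - px, mover.pos[1] - py
            n = math.hypot(dx, dy)
            toward = (dx / n, dy / n) if n > 1e-9 else (0.0, 1.0)
            body_f = _rotate(toward, orient_offset)
        else:
            dx, dy = fruit[0] - px, fruit[1] - py
            n = math.hypot(dx, dy)
            body_f = (dx / n, dy / n) if n > 1e-9 else (0.0, 1.0)
        anchor = appearance if appearance is not None else reference
        if anchor is not None and anchor <= t < anchor + scan.burst_duration:
            rate = scan.base_rate + scan.burst_rate
        else:
            rate = scan.base_rate
        amp = rate / (4.0 * scan.frequency) if scan.frequency > 0 else 0.0
        yaw = amp * math.sin(2.0 * math.pi * scan.frequency * t)
        head_f = _rotate(body_f, yaw)

        ts.append(t)
        heads.append((px, py))
        head_fs.append(head_f)
        pelvis_fs.append(body_f)
        threats.append(tuple(mover.pos) if threat_visible else (math.nan, math.nan))

        # --- termination ---------------------------------------------------
        if threat_visible and not force_shield:
            if math.hypot(mover.pos[0] - px, mover.pos[1] - py) <= contact_radius:
                outcome, contact_time, end_time = "virtual_death", t, t
                break
        if math.hypot(shelter[0] - px, shelter[1] - py) <= shelter_radius:
            if (
                threat_visible
                and math.hypot(mover.pos[0] - shelter[0], mover.pos[1] - shelter[1])
                <= door_block_radius
                and not force_shield
            ):
                outcome, contact_time, end_time = "virtual_death", t, t
            else:
                outcome, shelter_entry_time, end_time = "escape_to_shelter", t, t
            break

        # --- threat update -------------------------------------------------
        if threat_visible and mover is not None:
            mover.step(rel, (px, py), dt)

    if outcome is None:
        outcome = "survived"
        end_time = ts[-1]

    t_arr = np.asarray(ts)
    if timestamp_jitter > 0 and len(t_arr) > 2:
        jit = rng.uniform(-timestamp_jitter, timestamp_jitter, size=len(t_arr) - 2) * dt
        t_arr = t_arr.copy()
        t_arr[1:-1] += jit

    recording = TrajectoryRecording(
        t=t_arr,
        head_pos=np.asarray(heads),
        head_forward=_normalize_rows(np.asarray(head_fs)),
        pelvis_pos=np.asarray(heads),
        pelvis_forward=_normalize_rows(np.asarray(pelvis_fs)),
        threat_pos=np.asarray(threats),
    )
    log = EventLog(
        threat_appearance_time=appearance,
        epoch_end_time=float(end_time),
        outcome=outcome,
        fruit_pick_times=[
            x
            for x in picks
            if x <= end_time and (escape_start_t is None or x < escape_start_t)
        ],
        shelter_entry_time=shelter_entry_time,
        contact_time=contact_time,
        force_shield=force_shield,
        hands_up_signaled=hands_up_signaled,
        medusa=medusa,
        vocalized=vocalized,
        reference_time=reference,
    )
    if medusa:
        medusa_force(recording, log)
    return recording, log


def _normalize_rows(a: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(a, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return a / n


def medusa_force(
    recording: TrajectoryRecording,
    event_log: EventLog,
    cos_threshold: float = math.cos(math.radians(30.0)),
    min_dwell: float = 0.1,
) -> tuple[bool, Optional[float]]:
    """First sustained look at the threat triggers the lethal magical force.

    Scans head orientation after threat appearance; if the cosine toward
    the threat stays >= ``cos_threshold`` for at least ``min_dwell``
    seconds, the event log is amended in place: the epoch is cut at the
    trigger time with outcome ``virtual_death``.
    """
    app = event_log.threat_appearance_time
    if app is None:
        return False, None
    t = recording.t
    rel = recording.threat_pos - recording.head_pos
    norms = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cos = np.einsum("ij,ij->i", recording.head_forward, rel) / np.where(norms > 0, norms, 1.0)
    ok = (t >= app) & np.isfinite(norms) & (norms > 0) & (cos >= cos_threshold)

    run_start = None
    for i in range(len(t)):
        if ok[i]:
            if run_start is None:
                run_start = t[i]
            if t[i] - run_start >= min_dwell:
                trigger = run_start + min_dwell
                event_log.magical_force_time = float(trigger)
                event_log.outcome = "virtual_death"
                event_log.epoch_end_time = float(trigger)
                event_log.shelter_entry_time = None
                event_log.contact_time = None
                event_log.fruit_pick_times = [
                    x for x in event_log.fruit_pick_times if x <= trigger
                ]
                return True, float(trigger)
        else:
            run_start = None
    return False, None


# ---------------------------------------------------------------------------
# cohort generation

#: default threat roster; per-threat speeds are free configuration (the
#: published per-threat speeds live in supplementary material)
DEFAULT_THREATS = {
    "elephant": ThreatSpec("elephant", speed=-5.0, is_chasing=True, is_faster_than_participant=True),
    "bear": ThreatSpec("bear", speed=-4.0, is_chasing=True, is_faster_than_participant=True),
    "human": ThreatSpec("human", speed=-3.5, is_chasing=True, is_faster_than_participant=True),
    "dog": ThreatSpec("dog", speed=-3.0, is_chasing=True, is_faster_than_participant=True),
    "snake": ThreatSpec("snake", speed=-1.2, is_chasing=True),
    "spider": ThreatSpec("spider", speed=-0.8, is_chasing=True),
    "rock": ThreatSpec("rock", speed=-3.0, is_chasing=False, is_faster_than_participant=True),
}


def _threat_class(threat: ThreatSpec, participant_speed: float = 2.0) -> str:
    return "fast" if abs(threat.speed) > abs(participant_speed) else "slow"


@dataclass
class EffectSpec:
    """Condition-level means and between-subject structure for a cohort.

    Per-condition means feed policy parameters; between-subject SDs are
    realized as subject-level offsets (the random intercepts); loadings
    link latent subject traits to questionnaire scores.
    """

    initiation_delay_by_tti: dict = field(
        default_factory=lambda: {"short": 1.3, "long": 2.9}
    )
    escape_speed_by_class: dict = field(
        default_factory=lambda: {"fast": 1.9, "slow": 1.4}
    )
    body_orient_by_class: dict = field(
        default_factory=lambda: {"fast": -0.3, "slow": 0.2}
    )
    between_subject_sd: dict = field(
        default_factory=lambda: {"initiation_delay": 0.4, "escape_speed": 0.15, "body_orient": 0.1}
    )
    noise_sd: dict = field(
        default_factory=lambda: {"initiation_delay": 0.25, "escape_speed": 0.1, "body_orient": 0.05}
    )
    # score name -> (latent trait, loading, residual sd); traits are the
    # standardized subject offsets of the named policy parameter
    questionnaire_loadings: dict = field(
        default_factory=lambda: {
            "fearfulness": ("initiation_delay", -0.8, 0.6),
            "spider_fear": ("initiation_delay", -0.5, 0.85),
            "sensation_seeking": ("body_orient", 0.7, 0.7),
            "disgust": ("initiation_delay", 0.0, 1.0),
        }
    )
    sex_effect: dict = field(default_factory=lambda: {"initiation_delay": -0.2})
    vocalize_probability: float = 0.15
    fruit_pick_rate: float = 0.9


@dataclass
class CohortEpoch:
    subject_id: int
    spec: ScenarioSpec
    recording: TrajectoryRecording
    log: EventLog


@dataclass
class Cohort:
    epochs: list
    subjects: "object"  # pandas.DataFrame: subject_id, sex, questionnaire scores


def default_design(threats: Optional[Sequence[str]] = None) -> list:
    """Full threat x time-to-impact x behavior factorial cell list."""
    names = list(DEFAULT_THREATS) if threats is None else list(threats)
    return [
        (name, tti, behavior)
        for name in names
        for tti in ("short", "long")
        for behavior in ("attack", "divert")
    ]


def generate_cohort(
    n_subjects: int,
    design: Optional[Sequence] = None,
    effect_spec: Optional[EffectSpec] = None,
    seed: int = 0,
    *,
    epochs_per_cell: int = 1,
    dt: float = DEFAULT_DT,
    threats: Optional[dict] = None,
    timestamp_jitter: float = 0.0,
    max_duration: Optional[float] = None,
) -> Cohort:
    """Simulate a balanced factorial cohort with subject random intercepts.

    Every subject contributes ``epochs_per_cell`` epochs to every design
    cell.  Reproducible: the same seed yields an identical cohort.
    """
    import pandas as pd

    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    es = effect_spec if effect_spec is not None else EffectSpec()
    cells = list(design) if design is not None else default_design()
    roster = dict(DEFAULT_THREATS if threats is None else threats)
    rng = np.random.default_rng(seed)

    epochs = []
    subject_rows = []
    for sid in range(1, n_subjects + 1):
        z = {k: rng.normal() for k in ("initiation_delay", "escape_speed", "body_orient")}
        sex = int(rng.integers(0, 2))  # 1 = female
        scores = {}
        for name, (trait, loading, res_sd) in es.questionnaire_loadings.items():
            scores[name] = loading * z[trait] + rng.normal(0.0, res_sd)
        subject_rows.append({"subject_id": sid, "sex": sex, **scores})

        for threat_name, tti, behavior in cells:
            threat = roster[threat_name]
            cls = _threat_class(threat)
            for _ in range(epochs_per_cell):
                spec = generate_epoch_scenario(
                    threat, behavior, tti, rng, seed=seed
                )
                mean_delay = (
                    es.initiation_delay_by_tti[tti]
                    + es.between_subject_sd["initiation_delay"] * z["initiation_delay"]
                    + es.sex_effect.get("initiation_delay", 0.0) * sex
                )
                delay = max(
                    0.05, rng.normal(mean_delay, es.noise_sd["initiation_delay"])
                )
                speed = max(
                    0.1,
                    es.escape_speed_by_class[cls]
                    + es.between_subject_sd["escape_speed"] * z["escape_speed"]
                    + rng.normal(0.0, es.noise_sd["escape_speed"]),
                )
                orient = float(
                    np.clip(
                        es.body_orient_by_class[cls]
                        + es.between_subject_sd["body_orient"] * z["body_orient"]
                        + rng.normal(0.0, es.noise_sd["body_orient"]),
                        -1.0,
                        1.0,
                    )
                )
                policy = AgentPolicy(
                    initiation_delay_law=DelayLaw("constant", delay),
                    escape_speed=speed,
                    escape_target="shelter",
                    body_orientation_mode=orient,
                    fruit_pick_rate=es.fruit_pick_rate,
                    vocalize_probability=es.vocalize_probability,
                )
                recording, log = simulate_epoch(
                    spec,
                    policy,
                    rng,
                    dt=dt,
                    timestamp_jitter=timestamp_jitter,
                    max_duration=max_duration,
                )
                epochs.append(CohortEpoch(sid, spec, recording, log))

    return Cohort(epochs=epochs, subjects=pd.DataFrame(subject_rows))
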