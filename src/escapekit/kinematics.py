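"""Scenario geometry: threat placement realizing a prescribed time-to-impact.

All quantities live in a 2-D horizontal plane.  The forward axis (``y``) is
the direction the participant naturally faces; the lateral axis (``x``) is
perpendicular.  Along the forward axis the shelter sits on the negative side
and the fruit bush on the positive side (defaults -2.5 m / +2.5 m).  Angles
are measured in degrees about the vertical axis, relative to the forward
axis; a heading of ``theta`` maps to the unit vector
``(sin(theta), cos(theta))``, so +90 deg points to the participant's right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KinematicParams",
    "ThreatSpec",
    "BehaviorSchedule",
    "ScenarioSpec",
    "FastPlacementError",
    "UndefinedTimeError",
    "DEFAULT_TTI_MAP",
    "heading_to_vector",
    "fast_threat_initial_position",
    "slow_threat_initial_position",
    "nominal_approach_time",
    "behavior_schedule",
    "generate_epoch_scenario",
    "verify_time_to_impact",
]

#: default mapping of the categorical time-to-impact condition to seconds
DEFAULT_TTI_MAP = {"short": 1.5, "long": 5.0}

APPROACH_ANGLES = (-45.0, 0.0, 45.0)


class FastPlacementError(ValueError):
    """Fast-threat placement requested for a threat not faster than the participant."""


class UndefinedTimeError(ValueError):
    """Approach time undefined (zero threat speed)."""


def heading_to_vector(theta_deg: float) -> np.ndarray:
    """Unit vector for a heading in degrees about the vertical axis."""
    t = math.radians(theta_deg)
    return np.array([math.sin(t), math.cos(t)])


@dataclass(frozen=True)
class KinematicParams:
    """Signed 1-D constants of the escape geometry.

    ``participant_speed`` is signed toward the shelter (negative with the
    default sign convention).  ``escape_time`` is always derived, never
    stored independently.
    """

    shelter_position: float = -2.5
    fruit_position: float = 2.5
    participant_speed: float = -2.0
    plan_time: float = 1.5

    def __post_init__(self) -> None:
        if abs(self.shelter_position - self.fruit_position) <= 0:
            raise ValueError("shelter and fruit positions must differ")
        if self.plan_time <= 0:
            raise ValueError("plan_time must be positive")

    @property
    def escape_time(self) -> float:
        """Time for the participant to run fruit -> shelter at the assumed speed."""
        if self.participant_speed == 0:
            raise ValueError("participant_speed must be nonzero")
        return (self.shelter_position - self.fruit_position) / self.participant_speed


@dataclass(frozen=True)
class ThreatSpec:
    """A threat's identity and movement capabilities.

    ``speed`` is signed toward the participant (negative along the forward
    axis with the default convention).
    """

    name: str
    speed: float
    is_chasing: bool = True
    is_faster_than_participant: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.speed):
            raise ValueError("threat speed must be finite")
        if self.name == "rock" and self.is_chasing:
            raise ValueError("a ballistic rock cannot chase")


@dataclass(frozen=True)
class BehaviorSchedule:
    """Timing of the threat's behavior switches within its approach."""

    chase_onset_time: Optional[float] = None
    divert_onset_time: Optional[float] = None
    divert_heading: Optional[float] = None
    heading_offset: float = 0.0


def fast_threat_initial_position(
    params: KinematicParams, threat: ThreatSpec, *, strict: bool = True
) -> float:
    """Signed initial threat position for a threat faster than the participant.

    Places the threat so that, if the participant initiates escape exactly
    ``plan_time`` after threat appearance, both arrive at the shelter
    simultaneously::

        S_T = S_esc - V_T * ((S_esc - S_P) / V_P + T_plan)

    With ``strict=True`` a speed-ordering violation raises
    :class:`FastPlacementError`; ``strict=False`` evaluates the formula
    regardless (useful for degenerate checks).
    """
    if params.participant_speed == 0:
        raise ValueError("participant_speed must be nonzero")
    if strict and abs(threat.speed) <= abs(params.participant_speed):
        raise FastPlacementError(
            f"fast placement requires |V_T| > |V_P| "
            f"(got {abs(threat.speed)} <= {abs(params.participant_speed)})"
        )
    return params.shelter_position - threat.speed * (
        (params.shelter_position - params.fruit_position) / params.participant_speed
        + params.plan_time
    )


def slow_threat_initial_position(params: KinematicParams, threat: ThreatSpec) -> float:
    """Signed initial position for a slow or non-chasing threat.

    The threat reaches the fruit-picking position exactly ``plan_time``
    after appearing::

        S_T = S_P - V_T * T_plan
    """
    return params.fruit_position - threat.speed * params.plan_time


def nominal_approach_time(path_length, threat_speed: float) -> float:
    """Time for the threat to cover its approach path at constant speed.

    ``path_length`` may be a scalar distance or a sequence of segment
    lengths (angled approaches preserve total distance, so segments sum).
    """
    if isinstance(path_length, (Sequence, np.ndarray)):
        total = float(np.sum(np.asarray(path_length, dtype=float)))
    else:
        total = float(path_length)
    speed = abs(threat_speed)
    if speed == 0:
        raise UndefinedTimeError("approach time undefined for zero threat speed")
    if total < 0:
        raise ValueError("path length must be non-negative")
    return total / speed


def behavior_schedule(
    behavior: str,
    approach_angle: float,
    approach_time: float,
    rng: np.random.Generator,
    *,
    is_rock: bool = False,
    chase_fraction: float = 0.75,
    divert_fraction: float = 0.20,
) -> BehaviorSchedule:
    """Build the chase/divert schedule for one approach.

    Attack: chasing begins after 75% of the approach time.  Divert: the
    heading changes after 20% of the approach time; a left (-45 deg)
    approach diverts right (+90), a right (+45) approach diverts left
    (-90), and a center approach diverts to -110 or +110 with equal
    probability.  A ballistic rock never changes heading mid-path; its
    divert is a +/-5 deg offset of the initial heading.
    """
    if behavior == "attack":
        if is_rock:
            return BehaviorSchedule()
        return BehaviorSchedule(chase_onset_time=chase_fraction * approach_time)
    if behavior == "divert":
        if is_rock:
            offset = float(rng.choice([-5.0, 5.0]))
            return BehaviorSchedule(heading_offset=offset)
        if approach_angle == -45.0:
            heading = 90.0
        elif approach_angle == 45.0:
            heading = -90.0
        elif approach_angle == 0.0:
            heading = float(rng.choice([-110.0, 110.0]))
        else:
            raise ValueError(f"approach angle {approach_angle} not in {APPROACH_ANGLES}")
        return BehaviorSchedule(
            divert_onset_time=divert_fraction * approach_time, divert_heading=heading
        )
    raise ValueError(f"unknown behavior {behavior!r}")


@dataclass
class ScenarioSpec:
    """Full geometric and temporal description of one epoch's threat encounter."""

    threat: ThreatSpec
    behavior: str
    tti_condition: str
    time_to_impact: float
    approach_angle: float
    initial_threat_position: tuple[float, float]
    fruit_position_2d: tuple[float, float]
    shelter_position_2d: tuple[float, float]
    nominal_approach_time: float
    chase_onset_time: Optional[float] = None
    divert_onset_time: Optional[float] = None
    divert_heading: Optional[float] = None
    heading_offset: float = 0.0
    appearance_delay_law: tuple[float, float] = (1.0, 11.0)
    min_epoch_duration: float = 12.5
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threat"] = asdict(self.threat)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["threat"] = ThreatSpec(**d["threat"])
        for key in ("initial_threat_position", "fruit_position_2d", "shelter_position_2d"):
            d[key] = tuple(d[key])
        d["appearance_delay_law"] = tuple(d["appearance_delay_law"])
        return cls(**d)

    @property
    def fruit_shelter_distance(self) -> float:
        return float(
            np.linalg.norm(
                np.asarray(self.fruit_position_2d) - np.asarray(self.shelter_position_2d)
            )
        )


def _uses_fast_rule(params: KinematicParams, threat: ThreatSpec) -> bool:
    # boundary |V_T| == |V_P| routed to the slow rule (Eq-6 is singular-adjacent)
    return threat.is_chasing and abs(threat.speed) > abs(params.participant_speed)


def generate_epoch_scenario(
    threat: ThreatSpec,
    behavior: str,
    tti_condition: str,
    rng: np.random.Generator,
    *,
    params: Optional[KinematicParams] = None,
    tti_map: Optional[dict] = None,
    approach_angle: Optional[float] = None,
    seed: Optional[int] = None,
) -> ScenarioSpec:
    """Generate a fully populated, serializable scenario for one epoch.

    Placement is routed to the fast rule when the threat chases and is
    strictly faster than the participant, otherwise to the slow rule.
    """
    tti_map = dict(DEFAULT_TTI_MAP if tti_map is None else tti_map)
    if tti_condition not in tti_map:
        raise ValueError(f"unknown tti condition {tti_condition!r}")
    plan_time = tti_map[tti_condition]
    base = params if params is not None else KinematicParams()
    p = KinematicParams(
        shelter_position=base.shelter_position,
        fruit_position=base.fruit_position,
        participant_speed=base.participant_speed,
        plan_time=plan_time,
    )

    if _uses_fast_rule(p, threat):
        s_t = fast_threat_initial_position(p, threat)
    else:
        s_t = slow_threat_initial_position(p, threat)

    if approach_angle is None:
        approach_angle = float(rng.choice(APPROACH_ANGLES))
    elif approach_angle not in APPROACH_ANGLES:
        raise ValueError(f"approach angle must be one of {APPROACH_ANGLES}")

    fruit_2d = (0.0, p.fruit_position)
    shelter_2d = (0.0, p.shelter_position)
    # threat sits beyond the fruit at its placement distance, along the
    # approach direction; angled placement preserves the path length
    dist = abs(s_t - p.fruit_position)
    direction = heading_to_vector(approach_angle)
    threat_2d = tuple(np.asarray(fruit_2d) + dist * direction)

    t_approach = nominal_approach_time(dist, threat.speed)
    sched = behavior_schedule(
        behavior,
        approach_angle,
        t_approach,
        rng,
        is_rock=not threat.is_chasing,
    )
    return ScenarioSpec(
        threat=threat,
        behavior=behavior,
        tti_condition=tti_condition,
        time_to_impact=plan_time,
        approach_angle=approach_angle,
        initial_threat_position=(float(threat_2d[0]), float(threat_2d[1])),
        fruit_position_2d=fruit_2d,
        shelter_position_2d=shelter_2d,
        nominal_approach_time=t_approach,
        chase_onset_time=sched.chase_onset_time,
        divert_onset_time=sched.divert_onset_time,
        divert_heading=sched.divert_heading,
        heading_offset=sched.heading_offset,
        seed=seed,
    )


def verify_time_to_impact(spec: ScenarioSpec, params: Optional[KinematicParams] = None) -> float:
    """Recover the realized time-to-impact of a generated scenario.

    For fast chasing threats this inverts the simultaneous-arrival
    condition at the shelter; for slow or ballistic threats it is the
    threat's travel time to the fruit-picking position.
    """
    p = params if params is not None else KinematicParams()
    dist = float(
        np.linalg.norm(
            np.asarray(spec.initial_threat_position) - np.asarray(spec.fruit_position_2d)
        )
    )
    # signed placement on the forward axis: the threat starts on the fruit
    # side, beyond the fruit bush
    sign = 1.0 if p.fruit_position > p.shelter_position else -1.0
    s_t = p.fruit_position + sign * dist
    if _uses_fast_rule(p, spec.threat):
        return (p.shelter_position - s_t) / spec.threat.speed - p.escape_time
    return dist / abs(spec.threat.speed)
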