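"""Protocol, course and run configuration.

The default course is a closed 3.8 km trail loop with 200 m of vertical gain,
divided into 23 sections separated by waypoints.  Each section carries a
terrain surface, a slope class and a nominal gait activity; three short
sections are obstacle crossings (gates).  One protocol "lap" is a traversal of
the loop followed by a 10-minute seated cognitive-load block, repeated hourly
until the configured number of laps is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Surface(str, Enum):
    TARSEAL = "tarseal"
    GRAVEL = "gravel"
    DIRT = "dirt"
    MUD = "mud"
    GRASS = "grass"
    BOULDERS = "boulders"


class SlopeClass(str, Enum):
    FLAT = "flat"
    UP = "up"
    DOWN = "down"


class NominalActivity(str, Enum):
    RUN = "run"
    WALK = "walk"
    OBSTACLE = "obstacle"


class Obstacle(str, Enum):
    OPEN_GATE = "open_gate"
    CLIMB_GATE = "climb_gate"


#: Composite activity vocabulary: gait class crossed with slope class, the
#: seated block, and the two one-off obstacle crossings.
COMPOSITE_ACTIVITIES = (
    "run",
    "run_up",
    "run_down",
    "walk",
    "walk_up",
    "walk_down",
    "sit",
    "open_gate",
    "climb_gate",
)


@dataclass(frozen=True)
class Waypoint:
    lat: float
    lon: float
    alt: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lat, self.lon, self.alt)


@dataclass(frozen=True)
class SectionSpec:
    """One course section between two waypoints."""

    waypoint_start: Waypoint
    waypoint_end: Waypoint
    surface: Surface
    slope_class: SlopeClass
    nominal_activity: NominalActivity
    length_m: float
    climb_m: float = 0.0
    obstacle: Optional[Obstacle] = None

    def __post_init__(self) -> None:
        if self.waypoint_start == self.waypoint_end:
            raise ValueError("section waypoints must be distinct")
        if self.length_m <= 0:
            raise ValueError("section length must be positive")


@dataclass
class ProtocolConfig:
    """Session-level protocol parameters.

    ``n_laps`` is the number of hourly load cycles (course traversal plus
    seated block); the default four-lap session is the reference synthetic
    condition used throughout the tests.
    """

    n_laps: int = 4
    lap_distance_m: float = 3800.0
    lap_climb_m: float = 200.0
    sections: list[SectionSpec] = field(default_factory=lambda: default_course())
    accel_rate_hz: float = 100.0
    ecg_rate_hz: float = 250.0
    gps_rate_hz: float = 1.0
    sit_duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_laps < 1:
            raise ValueError("n_laps must be >= 1")
        for name in ("accel_rate_hz", "ecg_rate_hz", "gps_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.sections:
            raise ValueError("course must contain at least one section")
        first = self.sections[0].waypoint_start
        last = self.sections[-1].waypoint_end
        if first != last:
            raise ValueError("course sections must form a closed loop")


# (length_m, surface, slope, nominal activity, obstacle, climb_m)
# Lengths sum to 3800 m; climbs sum to +200 m and descents to -200 m so the
# loop closes in altitude as well as position.
_DEFAULT_SECTION_TABLE = [
    (250, Surface.TARSEAL, SlopeClass.FLAT, NominalActivity.RUN, None, 0),
    (300, Surface.GRAVEL, SlopeClass.UP, NominalActivity.RUN, None, 40),
    (150, Surface.DIRT, SlopeClass.FLAT, NominalActivity.WALK, None, 0),
    (180, Surface.DIRT, SlopeClass.UP, NominalActivity.WALK, None, 30),
    (5, Surface.DIRT, SlopeClass.FLAT, NominalActivity.OBSTACLE, Obstacle.OPEN_GATE, 0),
    (280, Surface.DIRT, SlopeClass.UP, NominalActivity.RUN, None, 40),
    (120, Surface.GRASS, SlopeClass.UP, NominalActivity.WALK, None, 20),
    (80, Surface.BOULDERS, SlopeClass.UP, NominalActivity.WALK, None, 15),
    (6, Surface.DIRT, SlopeClass.FLAT, NominalActivity.OBSTACLE, Obstacle.CLIMB_GATE, 0),
    (250, Surface.GRAVEL, SlopeClass.UP, NominalActivity.RUN, None, 35),
    (100, Surface.MUD, SlopeClass.FLAT, NominalActivity.WALK, None, 0),
    (150, Surface.DIRT, SlopeClass.UP, NominalActivity.RUN, None, 20),
    (300, Surface.GRAVEL, SlopeClass.DOWN, NominalActivity.RUN, None, -50),
    (30, Surface.BOULDERS, SlopeClass.DOWN, NominalActivity.WALK, None, -5),
    (280, Surface.DIRT, SlopeClass.DOWN, NominalActivity.RUN, None, -45),
    (200, Surface.GRASS, SlopeClass.DOWN, NominalActivity.RUN, None, -35),
    (150, Surface.GRAVEL, SlopeClass.FLAT, NominalActivity.RUN, None, 0),
    (5, Surface.DIRT, SlopeClass.FLAT, NominalActivity.OBSTACLE, Obstacle.OPEN_GATE, 0),
    (250, Surface.DIRT, SlopeClass.DOWN, NominalActivity.RUN, None, -40),
    (150, Surface.MUD, SlopeClass.DOWN, NominalActivity.RUN, None, -25),
    (200, Surface.TARSEAL, SlopeClass.FLAT, NominalActivity.RUN, None, 0),
    (150, Surface.GRASS, SlopeClass.FLAT, NominalActivity.WALK, None, 0),
    (214, Surface.TARSEAL, SlopeClass.FLAT, NominalActivity.RUN, None, 0),
]

_BASE_LAT = -36.9540
_BASE_LON = 174.4800
_BASE_ALT = 50.0
_M_PER_DEG_LAT = 111320.0


def _loop_waypoint(cum_dist: float, loop_length: float, cum_alt: float) -> Waypoint:
    """Place a waypoint on a circular loop of the given total length."""
    radius = loop_length / (2.0 * math.pi)
    theta = 2.0 * math.pi * cum_dist / loop_length
    x = radius * math.cos(theta) - radius  # start at (0, 0)
    y = radius * math.sin(theta)
    lat = _BASE_LAT + y / _M_PER_DEG_LAT
    lon = _BASE_LON + x / (_M_PER_DEG_LAT * math.cos(math.radians(_BASE_LAT)))
    return Waypoint(lat=lat, lon=lon, alt=_BASE_ALT + cum_alt)


def default_course() -> list[SectionSpec]:
    """Build the default 23-section loop as a list of :class:`SectionSpec`."""
    loop_length = float(sum(row[0] for row in _DEFAULT_SECTION_TABLE))
    sections: list[SectionSpec] = []
    cum_d, cum_a = 0.0, 0.0
    start = _loop_waypoint(0.0, loop_length, 0.0)
    for length, surface, slope, activity, obstacle, climb in _DEFAULT_SECTION_TABLE:
        next_d = cum_d + length
        next_a = cum_a + climb
        # close the loop exactly on the final waypoint
        if next_d >= loop_length - 1e-9:
            end = _loop_waypoint(0.0, loop_length, 0.0)
        else:
            end = _loop_waypoint(next_d, loop_length, next_a)
        sections.append(
            SectionSpec(
                waypoint_start=start,
                waypoint_end=end,
                surface=surface,
                slope_class=slope,
                nominal_activity=activity,
                length_m=float(length),
                climb_m=float(climb),
                obstacle=obstacle,
            )
        )
        start = end
        cum_d, cum_a = next_d, next_a
    return sections


#: Locomotion speed by (nominal activity, slope class), m/s.  Chosen to give a
#: ~32 min self-paced traversal of the 3.8 km loop, i.e. an hourly cycle with
#: the 10 min seated block and rest.
SECTION_SPEEDS_M_S = {
    (NominalActivity.RUN, SlopeClass.FLAT): 3.0,
    (NominalActivity.RUN, SlopeClass.UP): 2.0,
    (NominalActivity.RUN, SlopeClass.DOWN): 3.2,
    (NominalActivity.WALK, SlopeClass.FLAT): 1.3,
    (NominalActivity.WALK, SlopeClass.UP): 1.0,
    (NominalActivity.WALK, SlopeClass.DOWN): 1.1,
}

#: Fixed obstacle-crossing durations, seconds.
OBSTACLE_DURATION_S = {Obstacle.OPEN_GATE: 12.0, Obstacle.CLIMB_GATE: 25.0}

#: Nominal gait cadence by activity, steps/min.  Walk sits inside the
#: (100, 150) band and run above 150 so the cadence classifier can recover
#: the generated schedule.
NOMINAL_CADENCE_SPM = {NominalActivity.RUN: 165.0, NominalActivity.WALK: 112.0}
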