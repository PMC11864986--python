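"""Visual stimulus protocol and kernel-convolved stimulus regressors.

The protocol reproduces the fixed sequence used for tectal two-photon
imaging: a forward grating, eight circling-dot presentations (clockwise /
anticlockwise x smooth / saltatory, the four-stimulus set shown twice), a
second grating, a whole-field OFF luminance ramp, an ON ramp after a dark
delay, and two looming disks. Presentations are separated by a 20 s
inter-trial interval except for the two looms (60 s apart).

Each of the eight stimulus classes yields one regressor: a boxcar covering
all presentations of that class, convolved causally with an exponential
decay kernel ``exp(-t/tau)`` that mimics nuclear GCaMP6s off-kinetics
(tau = 7 s by default), then scaled to unit maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

#: Fixed regressor column order. Both grating presentations share one
#: column, each dot variant aggregates its two presentations, and the two
#: looms share one column, giving exactly eight regressors.
STIM_CLASSES = (
    "grating",
    "dot_cw_smooth",
    "dot_acw_smooth",
    "dot_cw_saltatory",
    "dot_acw_saltatory",
    "off_ramp",
    "on_ramp",
    "loom",
)

GRATING_DURATION_S = 20.0
RAMP_DURATION_S = 2.0
LOOM_DURATION_S = 0.083  # 0.6 deg -> 110 deg expansion in 83 ms
DEFAULT_TAU_S = 7.0


@dataclass(frozen=True)
class DotGeometry:
    """Geometry of the circling-dot stimulus (projector plane, mm)."""

    traj_radius_mm: float = 18.0
    speed_mm_s: float = 5.0
    dot_diameter_mm: float = 4.0


@dataclass(frozen=True)
class StimulusEvent:
    stim_class: str
    onset: float
    duration: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusProtocol:
    events: list[StimulusEvent]
    total_duration: float
    iti: float = 20.0
    loom_interval: float = 60.0

    def events_of(self, stim_class: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.stim_class == stim_class]

    def to_json(self) -> str:
        return json.dumps(
            {
                "iti": self.iti,
                "loom_interval": self.loom_interval,
                "total_duration": self.total_duration,
                "events": [asdict(e) for e in self.events],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        events = [StimulusEvent(**e) for e in d["events"]]
        return cls(
            events=events,
            total_duration=d["total_duration"],
            iti=d["iti"],
            loom_interval=d["loom_interval"],
        )


@dataclass
class RegressorMatrix:
    """Time x 8 matrix of unit-max stimulus regressors."""

    values: np.ndarray
    frame_rate: float
    tau: float
    stim_classes: tuple[str, ...] = STIM_CLASSES

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, stim_class: str) -> np.ndarray:
        return self.values[:, self.stim_classes.index(stim_class)]

    def to_dataframe(self):
        import pandas as pd

        t = np.arange(self.n_frames) / self.frame_rate
        df = pd.DataFrame(self.values, columns=list(self.stim_classes))
        df.insert(0, "time_s", t)
        return df


def dot_kinematics(geometry: DotGeometry = DotGeometry()) -> dict:
    """Kinematic quantities of one dot revolution.

    Returns revolution duration (s), angular speed (deg/s) and the dot's
    angular diameter (deg) as seen from the trajectory centre, where the
    fish is positioned.
    """
    if min(geometry.traj_radius_mm, geometry.speed_mm_s, geometry.dot_diameter_mm) <= 0:
        raise ValueError("dot geometry values must all be positive")
    revolution = 2.0 * math.pi * geometry.traj_radius_mm / geometry.speed_mm_s
    angular_speed = 360.0 / revolution
    angular_diameter = math.degrees(
        2.0 * math.atan((geometry.dot_diameter_mm / 2.0) / geometry.traj_radius_mm)
    )
    return {
        "revolution_duration": revolution,
        "angular_speed": angular_speed,
        "angular_diameter": angular_diameter,
    }


#: Presentation order of the four dot variants; the whole set repeats twice.
_DOT_SET = (
    "dot_cw_smooth",
    "dot_acw_smooth",
    "dot_cw_saltatory",
    "dot_acw_saltatory",
)


def build_protocol(
    frame_rate: float = 5.0,
    iti: float = 20.0,
    loom_interval: float = 60.0,
    geometry: DotGeometry = DotGeometry(),
) -> StimulusProtocol:
    """Build the fixed stimulus sequence.

    Sequence: grating, dots (4 variants x 2 repeats), grating, OFF ramp,
    ON ramp, loom x 2. Consecutive presentations are separated by ``iti``
    seconds, except the two looms which are ``loom_interval`` apart. The
    first presentation starts after one ``iti`` of baseline and the
    protocol ends one ``iti`` after the last offset, so with ``iti=0`` the
    total duration equals the sum of event durations.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    dot_duration = dot_kinematics(geometry)["revolution_duration"]
    # sub-frame events (the loom) are rounded up to one frame
    loom_dur = max(LOOM_DURATION_S, 1.0 / frame_rate)

    events: list[StimulusEvent] = []
    t = iti

    def push(stim_class: str, duration: float, gap_after: float) -> None:
        nonlocal t
        events.append(StimulusEvent(stim_class, t, duration))
        t += duration + gap_after

    push("grating", GRATING_DURATION_S, iti)
    for rep in range(2):
        for name in _DOT_SET:
            push(name, dot_duration, iti)
    push("grating", GRATING_DURATION_S, iti)
    push("off_ramp", RAMP_DURATION_S, iti)  # 20 s dark delay before ON ramp
    push("on_ramp", RAMP_DURATION_S, iti)
    push("loom", loom_dur, loom_interval)
    push("loom", loom_dur, iti)

    return StimulusProtocol(
        events=events, total_duration=t, iti=iti, loom_interval=loom_interval
    )


def build_regressors(
    protocol: StimulusProtocol,
    frame_rate: float = 5.0,
    tau: float = DEFAULT_TAU_S,
) -> RegressorMatrix:
    """Convolve per-class stimulus boxcars with an exponential decay kernel.

    For each of the eight stimulus classes a boxcar is 1 during every
    presentation window of that class and 0 elsewhere (events shorter than
    one frame still cover one frame). The boxcar is convolved causally with
    ``exp(-t/tau)`` and the column is scaled to unit maximum; the
    normalization cancels in R^2 and rescales regression slopes uniformly.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")

    n_frames = int(np.ceil(protocol.total_duration * frame_rate))
    dt = 1.0 / frame_rate
    # kernel truncated where it has decayed to < 1e-12 of its peak
    n_kernel = max(2, int(np.ceil(-math.log(1e-12) * tau / dt)))
    kernel = np.exp(-np.arange(n_kernel) * dt / tau)

    values = np.zeros((n_frames, len(STIM_CLASSES)))
    for j, stim_class in enumerate(STIM_CLASSES):
        events = protocol.events_of(stim_class)
        if not events:
            raise ValueError(f"protocol contains no events of class {stim_class!r}")
        boxcar = np.zeros(n_frames)
        for ev in events:
            i0 = int(round(ev.onset * frame_rate))
            i1 = max(i0 + 1, int(round(ev.offset * frame_rate)))
            boxcar[i0:min(i1, n_frames)] = 1.0
        col = np.convolve(boxcar, kernel)[:n_frames]
        values[:, j] = col / col.max()

    return RegressorMatrix(values=values, frame_rate=frame_rate, tau=tau)
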