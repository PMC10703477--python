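"""Stride and gait analysis from annotated limb-position events.

The gait cycle is decomposed classically: stance from heel-strike to the
next toe-off, swing from toe-off to the next ipsilateral heel-strike, so
stance + swing = stride.  Events are first-class inputs (frame indices into
an element) mirroring interactive marking; :func:`detect_events_heuristic`
is a programmatic convenience, not the primary route.

Heel-strike must open every cycle.  Optional events refine the cycle: a
heel-off inside stance gives the heel-down duration, and a maximum toe-lift
inside swing gives the toe-lift height, duration and speed.

A two-phase variant (cycle entry / cycle mid events) covers cyclic
movements without a stance, such as the power and return strokes of rodent
swimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Element
from .errors import DetectionError, OrderingError, ValidationError

__all__ = [
    "GaitEvent",
    "GaitCycle",
    "GaitDiagram",
    "EVENT_TYPES",
    "validate_events",
    "compute_cycles",
    "step_parameters",
    "gait_diagram",
    "two_phase_cycles",
    "detect_events_heuristic",
]

EVENT_TYPES = ("heel_strike", "toe_off", "heel_off", "max_toe_lift",
               "cycle_entry", "cycle_mid")
SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class GaitEvent:
    """One annotated limb position: type, side, frame index and time."""

    type: str
    side: str
    frame: int
    time: float
    coords: tuple | None = None

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown gait event type {self.type!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")


def events_from_frames(e: Element, marks, side: str = "left",
                       poi: str | None = None) -> list:
    """Build GaitEvents from (type, frame) pairs against an element's clock."""
    out = []
    for typ, frame in marks:
        frame = int(frame)
        if not 0 <= frame < e.n_frames:
            raise ValidationError(f"frame {frame} outside element range")
        coords = None
        if poi is not None:
            coords = tuple(e.poi(poi).coords[frame])
        out.append(GaitEvent(typ, side, frame, float(e.times[frame]), coords))
    return sorted(out, key=lambda ev: ev.time)


@dataclass
class GaitCycle:
    """Parameters of one stride (heel-strike to next ipsilateral heel-strike)."""

    side: str
    t_start: float
    stance_duration: float
    swing_duration: float
    stride_duration: float
    stride_length: float
    heel_down_duration: float | None = None
    toe_lift_height: float | None = None
    toe_lift_duration: float | None = None
    toe_lift_speed: float | None = None


def validate_events(events, side: str):
    """Group one side's events into cycles delimited by heel-strikes.

    Each cycle must contain exactly one toe-off after its opening
    heel-strike, optionally one heel-off before the toe-off and one
    max-toe-lift after it.  The first event of the side must be a
    heel-strike (the mandated cycle start).
    """
    evs = sorted([ev for ev in events if ev.side == side], key=lambda ev: ev.time)
    if not evs:
        raise ValidationError(f"no events for side {side!r}")
    if evs[0].type != "heel_strike":
        raise OrderingError(
            f"side {side!r}: the first event must be a heel_strike, "
            f"got {evs[0].type!r} at t={evs[0].time:g}"
        )
    hs = [ev for ev in evs if ev.type == "heel_strike"]
    if len(hs) < 2:
        raise ValidationError(f"side {side!r}: need >= 2 heel_strikes for a cycle")
    cycles = []
    for open_hs, close_hs in zip(hs[:-1], hs[1:]):
        inside = [ev for ev in evs if open_hs.time < ev.time < close_hs.time]
        tos = [ev for ev in inside if ev.type == "toe_off"]
        if len(tos) != 1:
            raise OrderingError(
                f"side {side!r}: cycle starting t={open_hs.time:g} has "
                f"{len(tos)} toe_offs, expected exactly 1"
            )
        to = tos[0]
        hos = [ev for ev in inside if ev.type == "heel_off"]
        if len(hos) > 1 or (hos and not hos[0].time < to.time):
            raise OrderingError(
                f"side {side!r}: heel_off must occur once, between the "
                f"heel_strike and toe_off of its cycle"
            )
        mtls = [ev for ev in inside if ev.type == "max_toe_lift"]
        if len(mtls) > 1 or (mtls and not mtls[0].time > to.time):
            raise OrderingError(
                f"side {side!r}: max_toe_lift must occur once, inside the swing"
            )
        cycles.append({
            "heel_strike": open_hs,
            "toe_off": to,
            "next_heel_strike": close_hs,
            "heel_off": hos[0] if hos else None,
            "max_toe_lift": mtls[0] if mtls else None,
        })
    return cycles


_AX = {"x": 0, "y": 1, "z": 2}


def compute_cycles(e: Element, events, side: str, heel_poi: str = "heel",
                   toe_poi: str = "toe", progression_axis: str = "x",
                   vertical_axis: str = "y") -> list:
    """Per-cycle gait parameters from a validated event stream.

    Stride length is the progression-axis displacement of the heel POI
    between successive heel-strikes; the toe-lift height is the vertical
    coordinate of the toe POI at max-toe-lift relative to toe-off.
    """
    heel = e.poi(heel_poi)
    toe = e.poi(toe_poi)
    pax = _AX[progression_axis]
    vax = _AX[vertical_axis]
    out = []
    for cyc in validate_events(events, side):
        hs, to, nhs = cyc["heel_strike"], cyc["toe_off"], cyc["next_heel_strike"]
        stance = to.time - hs.time
        swing = nhs.time - to.time
        stride_t = nhs.time - hs.time
        stride_len = abs(heel.coords[nhs.frame, pax] - heel.coords[hs.frame, pax])
        heel_down = cyc["heel_off"].time - hs.time if cyc["heel_off"] else None
        tl_h = tl_d = tl_v = None
        if cyc["max_toe_lift"] is not None:
            mtl = cyc["max_toe_lift"]
            tl_h = float(toe.coords[mtl.frame, vax] - toe.coords[to.frame, vax])
            tl_d = mtl.time - to.time
            tl_v = tl_h / tl_d if tl_d > 0 else None
        out.append(GaitCycle(
            side=side, t_start=hs.time,
            stance_duration=float(stance), swing_duration=float(swing),
            stride_duration=float(stride_t), stride_length=float(stride_len),
            heel_down_duration=heel_down,
            toe_lift_height=tl_h, toe_lift_duration=tl_d, toe_lift_speed=tl_v,
        ))
    return out


def step_parameters(e: Element, events, heel_poi: str = "heel",
                    progression_axis: str = "x") -> list:
    """Step duration and size: each heel-strike paired with the next
    contralateral heel-strike.

    For strictly alternating gaits, left->right and right->left step
    durations sum to the stride duration.
    """
    pax = _AX[progression_axis]
    hs = sorted([ev for ev in events if ev.type == "heel_strike"
                 and ev.side in ("left", "right")], key=lambda ev: ev.time)
    sides = {ev.side for ev in hs}
    if sides != {"left", "right"}:
        raise ValidationError("step parameters need heel-strikes on both sides")
    # heel_poi may be one shared label or a {"left": ..., "right": ...} map
    if isinstance(heel_poi, str):
        heel = {s: e.poi(heel_poi) for s in ("left", "right")}
    else:
        heel = {s: e.poi(heel_poi[s]) for s in ("left", "right")}
    steps = []
    for ev in hs:
        nxt = next((o for o in hs if o.time > ev.time and o.side != ev.side), None)
        if nxt is None:
            continue
        x0 = heel[ev.side].coords[ev.frame, pax]
        x1 = heel[nxt.side].coords[nxt.frame, pax]
        steps.append({
            "from_side": ev.side,
            "t_start": ev.time,
            "step_duration": float(nxt.time - ev.time),
            "step_size": float(abs(x1 - x0)),
        })
    return steps


@dataclass
class GaitDiagram:
    """Stance intervals per side and their bilateral overlap."""

    left: list                  # [t_hs, t_to) pairs
    right: list
    overlap: list


def _stance_intervals(events, side) -> list:
    out = []
    for cyc in validate_events(events, side):
        out.append((cyc["heel_strike"].time, cyc["toe_off"].time))
    # a trailing heel_strike..toe_off beyond the last full cycle is kept too
    evs = sorted([ev for ev in events if ev.side == side], key=lambda ev: ev.time)
    last_hs = max((ev for ev in evs if ev.type == "heel_strike"),
                  key=lambda ev: ev.time)
    trailing_to = [ev for ev in evs if ev.type == "toe_off" and ev.time > last_hs.time]
    if trailing_to:
        out.append((last_hs.time, trailing_to[0].time))
    return out


def gait_diagram(events) -> GaitDiagram:
    """Stance intervals for both sides plus the double-support overlap."""
    left = _stance_intervals(events, "left")
    right = _stance_intervals(events, "right")
    overlap = []
    for l0, l1 in left:
        for r0, r1 in right:
            lo, hi = max(l0, r0), min(l1, r1)
            if lo < hi:  # zero-length intersections discarded
                overlap.append((lo, hi))
    return GaitDiagram(left, right, sorted(overlap))


def two_phase_cycles(entry_times, mid_times) -> list:
    """Two-phase cycle decomposition (e.g. swim power/return strokes).

    ``entry_times`` mark cycle starts, ``mid_times`` the internal phase
    boundary; they must strictly alternate starting with an entry.  Each
    complete cycle yields phase1 = entry->mid and phase2 = mid->next entry.
    """
    entries = sorted(float(t) for t in entry_times)
    mids = sorted(float(t) for t in mid_times)
    if not entries:
        return []
    if mids and mids[0] < entries[0]:
        raise OrderingError("a cycle-mid event precedes the first cycle entry")
    out = []
    for e0, e1 in zip(entries[:-1], entries[1:]):
        inside = [m for m in mids if e0 < m < e1]
        if len(inside) != 1:
            raise OrderingError(
                f"cycle [{e0:g}, {e1:g}] has {len(inside)} mid events, expected 1"
            )
        m = inside[0]
        out.append({"t_start": e0, "phase1_duration": m - e0,
                    "phase2_duration": e1 - m})
    return out


def detect_events_heuristic(e: Element, heel_poi: str = "heel",
                            toe_poi: str = "toe", side: str = "left",
                            height_frac: float = 0.05,
                            speed_frac: float = 0.1,
                            progression_axis: str = "x",
                            vertical_axis: str = "y") -> list:
    """Heuristic gait-event detector (convenience; verify against the data).

    A foot POI is "grounded" while its height is within ``height_frac`` of
    its minimum (relative to its range) AND its progression speed is below
    ``speed_frac`` of its maximum.  Heel-strikes are onsets of grounded
    runs of the heel, toe-offs the ends of grounded runs of the toe, and
    max-toe-lift the highest toe sample within each swing.
    """
    pax, vax = _AX[progression_axis], _AX[vertical_axis]
    t = e.times

    def grounded(poi):
        y = poi.coords[:, vax]
        rng = y.max() - y.min()
        if rng == 0:
            raise DetectionError(
                f"POI {poi.label!r} has constant height; annotate events manually"
            )
        v = np.abs(np.diff(poi.coords[:, pax]) / np.diff(t))
        v = np.append(v, v[-1])  # pad forward-difference speed to n samples
        low = y <= y.min() + height_frac * rng
        slow = v <= speed_frac * v.max()
        return low & slow

    g_heel = grounded(e.poi(heel_poi))
    g_toe = grounded(e.poi(toe_poi))
    marks = []
    on = np.nonzero(g_heel & ~np.roll(g_heel, 1))[0]
    on = on[on > 0]
    if g_heel[0]:  # recording opens mid-stance: treat the start as the strike
        on = np.concatenate([[0], on])
    for i in on:
        marks.append(("heel_strike", int(i)))
    off = np.nonzero(~g_toe & np.roll(g_toe, 1))[0]
    off = off[off > 0]
    for i in off:
        marks.append(("toe_off", int(i)))
    if not marks:
        raise DetectionError("no gait events found; annotate events manually")
    events = events_from_frames(e, marks, side=side)
    # max toe lift inside each swing (toe_off -> next heel_strike)
    toe_y = e.poi(toe_poi).coords[:, vax]
    extra = []
    tos = [ev for ev in events if ev.type == "toe_off"]
    hss = [ev for ev in events if ev.type == "heel_strike"]
    for to in tos:
        nhs = next((h for h in hss if h.time > to.time), None)
        if nhs is None:
            continue
        lo, hi = to.frame, nhs.frame
        if hi - lo > 1:
            apex = lo + int(np.argmax(toe_y[lo:hi]))
            extra.append(("max_toe_lift", apex))
    if extra:
        events = sorted(events + events_from_frames(e, extra, side=side),
                        key=lambda ev: ev.time)
    return events
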