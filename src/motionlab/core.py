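"""Shared domain types and time-base utilities.

Everything here is unit-agnostic: times and coordinates are stored exactly as
imported, and derived quantities inherit the source units (coordinates in mm
and time in seconds give speeds in mm/s).  Vertical is the y axis, increasing
upward; data exported from image-coordinate trackers (y down) should be
converted with :func:`motionlab.preprocess.invert_axis` before gait analysis.

Missing samples are carried as an explicit boolean mask (never magic numbers)
so that tracking dropouts survive round trips losslessly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np

from .errors import TimeBaseError, ValidationError

__all__ = [
    "PointTrajectory",
    "Element",
    "SignalTrace",
    "Session",
    "build_element",
    "common_time_base",
    "rescale_time",
]


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class PointTrajectory:
    """One tracked point of interest: a time series of 2D or 3D positions.

    Parameters
    ----------
    label : str
        Name of the tracked landmark (used to label tables and plots).
    times : array of shape (n,)
        Timestamps in the source time unit, strictly increasing.
    coords : array of shape (n, d), d in {2, 3}
        Positions in the source length unit.
    missing : bool array of shape (n,), optional
        True where the sample is invalid/absent.  Missing samples are
        excluded from all statistics and propagate through derivatives.
    """

    label: str
    times: np.ndarray
    coords: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"coords must have shape (n, 2) or (n, 3), got {self.coords.shape}"
            )
        if len(self.times) != len(self.coords):
            raise ValidationError(
                f"POI {self.label!r}: {len(self.times)} timestamps vs "
                f"{len(self.coords)} coordinate rows"
            )
        if len(self.times) == 0:
            raise ValidationError(f"POI {self.label!r} is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"POI {self.label!r}: times must be strictly increasing")
        if self.missing is None:
            self.missing = ~np.all(np.isfinite(self.coords), axis=1)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.times.shape:
                raise ValidationError(f"POI {self.label!r}: missing mask length mismatch")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "PointTrajectory":
        return PointTrajectory(
            self.label, self.times.copy(), self.coords.copy(), self.missing.copy()
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PointTrajectory):
            return NotImplemented
        return (
            self.label == other.label
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.coords[~self.missing], other.coords[~other.missing])
            and np.array_equal(self.missing, other.missing)
        )


@dataclass
class Element:
    """A named, ordered chain of POIs sharing one time base.

    The POI order defines stick-figure connectivity (e.g. hip-knee-ankle-
    heel-toe).  Elements are the unit of preprocessing, stick diagrams and
    animation; every preprocessing operation returns a new element and
    appends one entry to ``history``.
    """

    name: str
    pois: list
    history: list = field(default_factory=list)
    display_only: bool = False

    def __post_init__(self):
        if not self.pois:
            raise ValidationError(f"element {self.name!r} needs at least one POI")
        t0 = self.pois[0].times
        d0 = self.pois[0].dim
        for p in self.pois[1:]:
            if p.dim != d0:
                raise ValidationError(
                    f"element {self.name!r}: POI {p.label!r} has dimension "
                    f"{p.dim}, expected {d0}"
                )
            if not common_time_base(t0, p.times):
                raise TimeBaseError(
                    f"element {self.name!r}: POI {p.label!r} has a different time base"
                )

    @property
    def times(self) -> np.ndarray:
        return self.pois[0].times

    @property
    def dim(self) -> int:
        return self.pois[0].dim

    @property
    def n_frames(self) -> int:
        return self.pois[0].n

    @property
    def labels(self) -> list:
        return [p.label for p in self.pois]

    def poi(self, label: str) -> PointTrajectory:
        for p in self.pois:
            if p.label == label:
                return p
        raise ValidationError(f"element {self.name!r} has no POI {label!r}")

    def copy(self, name: str | None = None) -> "Element":
        return Element(
            name or self.name,
            [p.copy() for p in self.pois],
            history=copy.deepcopy(self.history),
            display_only=self.display_only,
        )

    def with_history(self, op: str, **params) -> "Element":
        """Return self after appending one processing-history entry."""
        self.history.append({"op": op, "params": params})
        return self

    def __eq__(self, other) -> bool:
        if not isinstance(other, Element):
            return NotImplemented
        return (
            self.name == other.name
            and len(self.pois) == len(other.pois)
            and all(a == b for a, b in zip(self.pois, other.pois))
        )


class SignalTrace:
    """One electrophysiology or sensor channel, uniformly or raggedly sampled.

    The original samples are kept in ``raw_values`` (read-only) so any chain
    of processing steps can be reverted; ``meta`` records each applied
    operation with its parameters.
    """

    def __init__(self, label, times, values, meta=None, raw_values=None, raw_times=None):
        self.label = str(label)
        self.times = _as_1d(times, "times")
        self.values = _as_1d(values, "values")
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"signal {self.label!r}: {len(self.times)} timestamps vs "
                f"{len(self.values)} values"
            )
        if len(self.times) == 0:
            raise ValidationError(f"signal {self.label!r} is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"signal {self.label!r}: times must be strictly increasing")
        self.meta = list(meta) if meta is not None else []
        rv = np.array(self.values if raw_values is None else raw_values, dtype=float)
        rv.setflags(write=False)
        self.raw_values = rv
        rt = np.array(self.times if raw_times is None else raw_times, dtype=float)
        rt.setflags(write=False)
        self.raw_times = rt

    @property
    def n(self) -> int:
        return len(self.values)

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        if self.n < 2:
            return True
        dt = np.diff(self.times)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * abs(dt[0])))

    @property
    def fs(self) -> float:
        """Sampling rate; requires uniform sampling."""
        from .errors import ContractError

        if not self.is_uniform():
            raise ContractError(
                f"signal {self.label!r} is not uniformly sampled; "
                "use set_time_base or resample first"
            )
        if self.n < 2:
            raise ValidationError("sampling rate undefined for a single sample")
        return 1.0 / (self.times[1] - self.times[0])

    def derive(self, values, op: str, times=None, **params) -> "SignalTrace":
        """New trace with one more history entry; raw samples carried over."""
        return SignalTrace(
            self.label,
            self.times if times is None else times,
            values,
            meta=self.meta + [{"op": op, "params": params}],
            raw_values=self.raw_values,
            raw_times=self.raw_times,
        )

    def revert(self) -> "SignalTrace":
        """Drop all processing and return the original signal."""
        return SignalTrace(self.label, self.raw_times, self.raw_values, meta=[])

    def copy(self) -> "SignalTrace":
        return SignalTrace(
            self.label, self.times.copy(), self.values.copy(),
            meta=copy.deepcopy(self.meta),
            raw_values=self.raw_values, raw_times=self.raw_times,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrace):
            return NotImplemented
        return (
            self.label == other.label
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.raw_values, other.raw_values)
            and self.meta == other.meta
        )

    def __repr__(self) -> str:
        return f"SignalTrace({self.label!r}, n={self.n})"


@dataclass
class Session:
    """Serializable container of all inputs and analysis products."""

    elements: dict = field(default_factory=dict)
    signals: dict = field(default_factory=dict)
    gait: Any = None  # list of gait events, optional
    products: dict = field(default_factory=dict)
    units_note: str = ""

    def add_element(self, e: Element) -> None:
        if e.name in self.elements:
            raise ValidationError(f"duplicate element name {e.name!r}")
        self.elements[e.name] = e

    def add_signal(self, s: SignalTrace) -> None:
        if s.label in self.signals:
            raise ValidationError(f"duplicate signal label {s.label!r}")
        self.signals[s.label] = s

    @property
    def empty(self) -> bool:
        return not (self.elements or self.signals or self.gait or self.products)


def build_element(name: str, trajectories: list) -> Element:
    """Assemble POIs into an element, checking a shared time base.

    The list order defines stick connectivity.  Raises a
    :class:`~motionlab.errors.TimeBaseError` naming the first POI whose time
    array differs from the first trajectory's.
    """
    if not trajectories:
        raise ValidationError("an element needs at least one POI")
    ref = trajectories[0]
    for p in trajectories[1:]:
        if p.dim != ref.dim:
            raise ValidationError(
                f"POI {p.label!r} is {p.dim}D but {ref.label!r} is {ref.dim}D"
            )
        if not common_time_base(ref.times, p.times):
            raise TimeBaseError(
                f"POI {p.label!r} does not share the time base of {ref.label!r}"
            )
    return Element(name, list(trajectories))


def common_time_base(a, b, tol: float = 1e-9) -> bool:
    """True iff two time arrays have equal length and agree within ``tol``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("time arrays must be non-empty")
    if a.shape != b.shape:
        return False
    return bool(np.max(np.abs(a - b)) <= tol)


def rescale_time(x: Union[Element, SignalTrace], factor: float):
    """Multiply all timestamps by ``factor`` (e.g. 0.001 for ms -> s).

    Coordinates/values are untouched; the same type is returned.
    """
    if not factor > 0:
        raise ValidationError(f"time scale factor must be positive, got {factor}")
    if isinstance(x, Element):
        out = x.copy()
        for p in out.pois:
            p.times = p.times * factor
        return out.with_history("rescale_time", factor=factor)
    if isinstance(x, SignalTrace):
        return x.derive(x.values.copy(), "rescale_time", times=x.times * factor,
                        factor=factor)
    raise ValidationError(f"cannot rescale object of type {type(x).__name__}")
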