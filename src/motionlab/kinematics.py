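"""Kinematic quantities, joint angles, descriptive statistics, stick
diagrams, occupancy heatmaps and path length.

Speeds are forward differences, v_i = (p_{i+1} - p_i) / (t_{i+1} - t_i),
matching the frame-to-frame "instant speed" of manual video tracking tools;
a linear coordinate therefore gives a constant speed and zero acceleration,
and a parabolic one a linearly increasing speed and a constant acceleration.
Accelerations divide successive speed differences by the half-span of the
two intervals involved: a_i = 2 (v_{i+1} - v_i) / (t_{i+2} - t_i), which
reduces to dv/dt for uniform sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Element, PointTrajectory
from .errors import ContractError, ValidationError

__all__ = [
    "KinematicSeries",
    "AngleSeries",
    "DescriptiveStats",
    "StickDiagram",
    "Heatmap",
    "kinematics",
    "joint_angle",
    "describe",
    "stick_diagram",
    "occupancy_heatmap",
    "path_length",
]


@dataclass
class KinematicSeries:
    """Per-POI derivative quantities.

    Speed arrays have n-1 samples (one per interval, timestamped at the
    interval midpoint); acceleration arrays have n-2.  With
    ``absolute=True`` component speeds/accelerations are magnitudes.
    Intervals touching a missing position sample are NaN.
    """

    label: str
    speed_times: np.ndarray
    step_displacement: np.ndarray      # per-interval |dp|
    cumulative_path: np.ndarray        # running sum of |dp|
    component_speed: np.ndarray        # (n-1, d)
    speed_magnitude: np.ndarray
    accel_times: np.ndarray
    component_accel: np.ndarray        # (n-2, d)
    accel_magnitude: np.ndarray
    absolute: bool
    axes: str = "xy"

    @property
    def path_length(self) -> float:
        return float(np.nansum(self.step_displacement))


def kinematics(e: Element, absolute: bool = False) -> list:
    """Compute speeds, accelerations and path lengths for every POI.

    Display-only (downsampled) elements are rejected: their kinematics
    would depend on the display stride, not the movement.
    """
    if e.display_only:
        raise ContractError(
            "display-only element: kinematics must run on the full-rate data"
        )
    if e.n_frames < 3:
        raise ValidationError("kinematics needs at least 3 samples")
    t = e.times
    if np.any(np.diff(t) <= 0):
        raise ValidationError("duplicate or decreasing timestamps")
    out = []
    axes = "xyz"[: e.dim]
    for p in e.pois:
        coords = np.where(p.missing[:, None], np.nan, p.coords)
        dt = np.diff(t)
        dp = np.diff(coords, axis=0)
        v = dp / dt[:, None]
        step = np.linalg.norm(dp, axis=1)
        vmag = step / dt
        span = t[2:] - t[:-2]
        a = 2.0 * np.diff(v, axis=0) / span[:, None]
        amag = np.linalg.norm(a, axis=1)
        if absolute:
            v = np.abs(v)
            a = np.abs(a)
        out.append(KinematicSeries(
            label=p.label,
            speed_times=0.5 * (t[:-1] + t[1:]),
            step_displacement=step,
            cumulative_path=np.nancumsum(step),
            component_speed=v,
            speed_magnitude=vmag,
            accel_times=0.5 * (t[:-2] + t[2:]),
            component_accel=a,
            accel_magnitude=amag,
            absolute=absolute,
            axes=axes,
        ))
    return out


@dataclass
class AngleSeries:
    """Interior angle at vertex ``b`` between segments b->a and b->c."""

    a: str
    b: str
    c: str
    times: np.ndarray
    values: np.ndarray     # NaN where undefined (zero-length segment/missing)
    unit: str = "degrees"

    def to_radians(self) -> "AngleSeries":
        if self.unit == "radians":
            return self
        return AngleSeries(self.a, self.b, self.c, self.times,
                           np.deg2rad(self.values), "radians")


def joint_angle(e: Element, a: str, b: str, c: str, unit: str = "degrees") -> AngleSeries:
    """Per-frame interior angle at POI ``b``, in [0, 180] degrees.

    theta = atan2(|u x v|, u . v) with u = A - B, v = C - B; unsigned, so
    0 deg means the flanking points coincide directionally and 180 deg means
    collinear extension.  Frames where either segment has zero length (or a
    point is missing) yield NaN rather than an error.
    """
    if len({a, b, c}) != 3:
        raise ValidationError("joint_angle needs three distinct POI labels")
    if unit not in ("degrees", "radians"):
        raise ValidationError(f"unit must be 'degrees' or 'radians', got {unit!r}")
    pa, pb, pc = e.poi(a), e.poi(b), e.poi(c)
    u = pa.coords - pb.coords
    v = pc.coords - pb.coords
    dot = np.sum(u * v, axis=1)
    if e.dim == 2:
        cross = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    else:
        cross = np.linalg.norm(np.cross(u, v), axis=1)
    theta = np.arctan2(cross, dot)
    bad = (np.linalg.norm(u, axis=1) == 0) | (np.linalg.norm(v, axis=1) == 0)
    bad |= pa.missing | pb.missing | pc.missing
    theta = np.where(bad, np.nan, theta)
    if unit == "degrees":
        theta = np.rad2deg(theta)
    return AngleSeries(a, b, c, e.times.copy(), theta, unit)


@dataclass
class DescriptiveStats:
    n: int
    min: float
    max: float
    time_of_min: float | None
    time_of_max: float | None
    mean: float
    median: float
    mode: float
    std: float

    def as_dict(self) -> dict:
        return dict(n=self.n, min=self.min, max=self.max,
                    time_of_min=self.time_of_min, time_of_max=self.time_of_max,
                    mean=self.mean, median=self.median, mode=self.mode,
                    std=self.std)


def describe(values, times=None, mode_precision: int = 6) -> DescriptiveStats:
    """Descriptive statistics of a series, ignoring NaN samples.

    The mode is the most frequent value after rounding to
    ``mode_precision`` decimals; ties resolve to the smallest value.  The
    standard deviation is the sample (n-1) form, 0 by convention for n=1.
    """
    x = np.asarray(values, dtype=float)
    t = None if times is None else np.asarray(times, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        raise ValidationError("describe needs at least one finite value")
    xv = x[ok]
    rounded = np.round(xv, mode_precision)
    uniq, counts = np.unique(rounded, return_counts=True)
    mode = float(uniq[counts == counts.max()].min())
    imin, imax = int(np.argmin(xv)), int(np.argmax(xv))
    tv = t[ok] if t is not None else None
    return DescriptiveStats(
        n=int(ok.sum()),
        min=float(xv.min()), max=float(xv.max()),
        time_of_min=None if tv is None else float(tv[imin]),
        time_of_max=None if tv is None else float(tv[imax]),
        mean=float(xv.mean()), median=float(np.median(xv)), mode=mode,
        std=float(xv.std(ddof=1)) if len(xv) > 1 else 0.0,
    )


@dataclass
class StickDiagram:
    """Per-frame polylines over the element's POI order (display object).

    Normalization anchors a reference POI by subtracting its displacement
    from frame 0 on the selected axes; it affects only this diagram, never
    the kinematics of the underlying element.
    """

    times: np.ndarray
    frames: np.ndarray          # (n_frames, n_poi, d)
    labels: list
    reference: str | None = None
    axes: tuple = ()


def stick_diagram(e: Element, normalize_poi: str | None = None,
                  normalize_axes=("x", "y")) -> StickDiagram:
    """Build the stick diagram: one polyline per frame in POI order."""
    if len(e.pois) < 2:
        raise ValidationError("a stick diagram needs at least 2 POIs")
    frames = np.stack([p.coords for p in e.pois], axis=1)  # (n, n_poi, d)
    axes_used: tuple = ()
    if normalize_poi is not None:
        ref = e.poi(normalize_poi)
        ax_idx = []
        for ax in normalize_axes:
            if ax not in "xyz"[: e.dim]:
                raise ValidationError(f"axis {ax!r} not available in {e.dim}D")
            ax_idx.append("xyz".index(ax))
        disp = ref.coords - ref.coords[0]  # displacement from frame 0
        frames = frames.copy()
        for ax in ax_idx:
            frames[:, :, ax] -= disp[:, ax][:, None]
        axes_used = tuple(normalize_axes)
    return StickDiagram(e.times.copy(), frames, e.labels, normalize_poi, axes_used)


@dataclass
class Heatmap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray          # (nx, ny)
    extent: tuple               # (xmin, xmax, ymin, ymax)


def occupancy_heatmap(traj: PointTrajectory, nx: int = 20, ny: int = 20,
                      extent=None, plane=(0, 1)) -> Heatmap:
    """2D histogram of where a POI spends its time.

    The default extent is the data bounding box with the right/top edges
    inclusive, so every non-missing sample is counted exactly once.
    """
    if nx < 1 or ny < 1:
        raise ValidationError("heatmap needs nx, ny >= 1")
    i, j = plane
    x = traj.coords[~traj.missing, i]
    y = traj.coords[~traj.missing, j]
    if extent is not None:
        xmin, xmax, ymin, ymax = map(float, extent)
        if xmax <= xmin or ymax <= ymin:
            raise ValidationError("heatmap extent must have positive area")
    else:
        xmin, xmax = float(x.min()), float(x.max())
        ymin, ymax = float(y.min()), float(y.max())
        # degenerate data (stationary point) still bins into one cell
        if xmax == xmin:
            xmax = xmin + 1.0
        if ymax == ymin:
            ymax = ymin + 1.0
    counts, xe, ye = np.histogram2d(x, y, bins=[nx, ny],
                                    range=[[xmin, xmax], [ymin, ymax]])
    return Heatmap(xe, ye, counts, (xmin, xmax, ymin, ymax))


def path_length(traj: PointTrajectory) -> float:
    """Total distance travelled: sum of |p_{i+1} - p_i| over valid intervals."""
    if traj.n < 2:
        raise ValidationError("path length needs at least 2 samples")
    coords = np.where(traj.missing[:, None], np.nan, traj.coords)
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return float(np.nansum(steps))
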