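"""Coordinate cleaning and multi-camera reconciliation.

Every operation is pure: it returns a new :class:`~motionlab.core.Element`
with exactly one entry appended to its processing history, leaving the input
untouched.  Geometric operations (shift, rotate, invert) are isometries and
preserve all inter-POI distances; kinematic magnitudes are therefore
invariant under them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Element, PointTrajectory, SignalTrace
from .errors import ContractError, ValidationError

__all__ = [
    "OutlierReport",
    "replace_outliers",
    "smooth",
    "invert_axis",
    "shift",
    "rotate",
    "scale",
    "auto_align",
    "trim",
    "downsample_view",
    "stitch",
    "split",
]

_AXES = {"x": 0, "y": 1, "z": 2}
_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class OutlierFlag:
    poi: str
    axis: str
    indices: np.ndarray
    replacements: np.ndarray


@dataclass
class OutlierReport:
    """Which samples were flagged per POI/axis and what replaced them."""

    method: str
    mad_k: float
    flags: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return sum(len(f.indices) for f in self.flags)


def _mad_outliers(x: np.ndarray, mad_k: float) -> np.ndarray:
    """Indices where |x - median| > mad_k * 1.4826 * MAD."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return np.array([], dtype=int)
    return np.nonzero(np.abs(x - med) > mad_k * 1.4826 * mad)[0]


def _replace(x: np.ndarray, bad: np.ndarray, method: str, w: int) -> np.ndarray:
    """Fill flagged samples from the surrounding good ones."""
    out = x.copy()
    good = np.setdiff1d(np.arange(len(x)), bad)
    if good.size == 0:
        raise ValidationError("cannot replace outliers: no valid samples left")
    if method == "interpolation":
        out[bad] = np.interp(bad, good, x[good])
    elif method == "nearest":
        for i in bad:
            out[i] = x[good[np.argmin(np.abs(good - i))]]
    elif method == "previous":
        for i in bad:
            prev = good[good < i]
            out[i] = x[prev[-1]] if prev.size else x[good[0]]
    elif method == "mean_window":
        half = w // 2
        for i in bad:
            near = good[(good >= i - half) & (good <= i + half)]
            if near.size == 0:  # widen until a neighbor is found
                near = good[[np.argmin(np.abs(good - i))]]
            out[i] = float(np.mean(x[near]))
    else:
        raise ValidationError(f"unknown replacement method {method!r}")
    return out


def replace_outliers(e: Element, mad_k: float = 3.0, method: str = "interpolation",
                     window: int = 5):
    """Detect and replace outlier coordinates, per POI and per axis.

    The detector is the robust median +/- ``mad_k`` x scaled-MAD rule
    (scale factor 1.4826 makes MAD consistent with the standard deviation
    for Gaussian data).  Samples already flagged missing are replaced too
    and unflagged in the result.  An all-constant axis (MAD 0) yields no
    flags and a warning.

    Returns ``(element, OutlierReport)``.
    """
    if method == "mean_window" and (window % 2 == 0 or window < 3):
        raise ValidationError(f"mean-window width must be odd and >= 3, got {window}")
    out = e.copy()
    report = OutlierReport(method=method, mad_k=float(mad_k))
    axis_names = "xyz"[: e.dim]
    for p in out.pois:
        finite = ~p.missing
        if finite.sum() < 3:
            raise ValidationError(f"POI {p.label!r}: need >= 3 valid samples per axis")
        for ax in range(p.dim):
            col = p.coords[:, ax]
            vals = col[finite]
            bad_local = _mad_outliers(vals, mad_k)
            if bad_local.size == 0 and np.median(np.abs(vals - np.median(vals))) == 0 \
                    and not np.all(vals == vals[0]):
                warnings.warn(
                    f"POI {p.label!r} axis {axis_names[ax]}: MAD is zero, "
                    "outlier detection skipped"
                )
            bad = np.union1d(np.nonzero(finite)[0][bad_local], np.nonzero(p.missing)[0])
            if bad.size == 0:
                continue
            filled = col.copy()
            filled[p.missing] = np.nan
            # replacement operates on the finite scaffold
            work = np.where(np.isfinite(filled), filled, np.nan)
            ok = np.nonzero(~np.isnan(work))[0]
            work[np.isnan(work)] = np.interp(np.nonzero(np.isnan(work))[0], ok, work[ok])
            repl = _replace(work, bad, method, window)
            p.coords[:, ax] = repl
            report.flags.append(
                OutlierFlag(p.label, axis_names[ax], bad, repl[bad].copy())
            )
        p.missing[:] = False
    return out.with_history("replace_outliers", mad_k=mad_k, method=method), report


def _window_apply(x: np.ndarray, w: int, fn) -> np.ndarray:
    """Centered window of width w; edges shrink to the available neighbors."""
    n = len(x)
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = fn(x[lo:hi])
    return out


def smooth(e: Element, method: str = "moving_mean", window: int = 5) -> Element:
    """Smooth each axis of each POI with a centered window.

    ``method`` is one of ``moving_mean``, ``moving_median`` or ``rms``.
    Edge samples use shrinking windows so no data is fabricated beyond the
    trajectory ends.
    """
    fns = {
        "moving_mean": np.mean,
        "moving_median": np.median,
        "rms": lambda v: float(np.sqrt(np.mean(v ** 2))),
    }
    if method not in fns:
        raise ValidationError(f"unknown smoothing method {method!r}")
    if window % 2 == 0 or window < 3:
        raise ValidationError(f"window must be odd and >= 3, got {window}")
    if window > e.n_frames:
        raise ValidationError(f"window {window} exceeds {e.n_frames} samples")
    out = e.copy()
    for p in out.pois:
        for ax in range(p.dim):
            p.coords[:, ax] = _window_apply(p.coords[:, ax], window, fns[method])
    return out.with_history("smooth", method=method, window=window)


def invert_axis(e: Element, axis: str = "x", pivot: float | None = None) -> Element:
    """Mirror one coordinate axis about ``pivot`` (default: midpoint of the
    axis range over all POIs).  Used to reconcile mirror-image cameras or to
    convert image coordinates (y down) to the Cartesian up-positive frame."""
    if axis not in _AXES or _AXES[axis] >= e.dim:
        raise ValidationError(f"axis must be one of x/y/z within dimension {e.dim}")
    ax = _AXES[axis]
    if pivot is None:
        vals = np.concatenate([p.coords[~p.missing, ax] for p in e.pois])
        pivot = 0.5 * (vals.min() + vals.max())
    out = e.copy()
    for p in out.pois:
        p.coords[:, ax] = 2.0 * pivot - p.coords[:, ax]
    return out.with_history("invert_axis", axis=axis, pivot=float(pivot))


def shift(e: Element, offset) -> Element:
    """Translate all POIs by a constant offset vector."""
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (e.dim,):
        raise ValidationError(f"offset must have {e.dim} components")
    out = e.copy()
    for p in out.pois:
        p.coords = p.coords + offset
    return out.with_history("shift", offset=offset.tolist())


def _centroid(e: Element) -> np.ndarray:
    pts = np.concatenate([p.coords[~p.missing] for p in e.pois])
    return pts.mean(axis=0)


def rotate(e: Element, angle_deg: float, center=None, plane: str = "xy") -> Element:
    """Rotate all POIs by ``angle_deg`` (counterclockwise) in ``plane``
    about ``center`` (default: element centroid)."""
    if plane not in _PLANES:
        raise ValidationError(f"plane must be one of {sorted(_PLANES)}")
    i, j = _PLANES[plane]
    if max(i, j) >= e.dim:
        raise ValidationError(f"plane {plane!r} needs 3D data")
    c = _centroid(e) if center is None else np.asarray(center, dtype=float)
    th = np.deg2rad(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    out = e.copy()
    for p in out.pois:
        u = p.coords[:, i] - c[i]
        v = p.coords[:, j] - c[j]
        p.coords[:, i] = c[i] + cos * u - sin * v
        p.coords[:, j] = c[j] + sin * u + cos * v
    return out.with_history("rotate", angle_deg=float(angle_deg), plane=plane,
                            center=list(map(float, c)))


def scale(e: Element, factor: float, center=None) -> Element:
    """Isotropic scaling about ``center`` (default: element centroid);
    corrects perspective size mismatch between cameras."""
    if not factor > 0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    c = _centroid(e) if center is None else np.asarray(center, dtype=float)
    out = e.copy()
    for p in out.pois:
        p.coords = c + factor * (p.coords - c)
    return out.with_history("scale", factor=float(factor), center=list(map(float, c)))


def auto_align(moving: Element, reference: Element, poi: str, at_time: float) -> Element:
    """Translate ``moving`` so the named POI coincides with the same POI of
    ``reference`` at the sample nearest ``at_time``."""
    pm = moving.poi(poi)
    pr = reference.poi(poi)
    im = int(np.argmin(np.abs(pm.times - at_time)))
    ir = int(np.argmin(np.abs(pr.times - at_time)))
    offset = pr.coords[ir] - pm.coords[im]
    out = shift(moving, offset)
    out.history[-1] = {"op": "auto_align",
                       "params": {"poi": poi, "at_time": float(at_time),
                                  "offset": offset.tolist()}}
    return out


def trim(x, t0: float, t1: float):
    """Keep samples with t0 <= t <= t1 (closed interval); Element or
    SignalTrace."""
    if not t0 < t1:
        raise ValidationError(f"need t0 < t1, got {t0} >= {t1}")
    if isinstance(x, SignalTrace):
        keep = (x.times >= t0) & (x.times <= t1)
        if not keep.any():
            raise ValidationError(f"trim [{t0}, {t1}] leaves no samples")
        return x.derive(x.values[keep], "trim", times=x.times[keep], t0=t0, t1=t1)
    keep = (x.times >= t0) & (x.times <= t1)
    if not keep.any():
        raise ValidationError(f"trim [{t0}, {t1}] leaves no samples")
    out = Element(
        x.name,
        [PointTrajectory(p.label, p.times[keep], p.coords[keep], p.missing[keep])
         for p in x.pois],
        history=list(x.history),
        display_only=x.display_only,
    )
    return out.with_history("trim", t0=float(t0), t1=float(t1))


def downsample_view(e: Element, keep_every: int) -> Element:
    """Every k-th sample, tagged display-only.

    The result is for plotting/animation only and is rejected by the
    kinematics module; downsampling never alters analysed data.
    """
    k = int(keep_every)
    if k < 1:
        raise ValidationError(f"keep_every must be >= 1, got {keep_every}")
    sl = slice(None, None, k)
    out = Element(
        e.name,
        [PointTrajectory(p.label, p.times[sl], p.coords[sl], p.missing[sl])
         for p in e.pois],
        history=list(e.history),
        display_only=True,
    )
    return out.with_history("downsample_view", keep_every=k)


def split(e: Element, t: float):
    """Cut an element at time ``t``: samples before ``t`` and from ``t`` on."""
    before = (e.times < t)
    after = ~before
    if not before.any() or not after.any():
        raise ValidationError(f"split time {t} is not interior to the element")
    mk = lambda sel: Element(
        e.name,
        [PointTrajectory(p.label, p.times[sel], p.coords[sel], p.missing[sel])
         for p in e.pois],
    )
    return mk(before), mk(after)


def stitch(base: Element, patch: Element, transition_time: float,
           offset=None, rotation: float = 0.0, rotation_center=None) -> Element:
    """Join two recordings of the same POIs from cameras on one side.

    The patch is rotated (about ``rotation_center``, default its centroid)
    then translated by ``offset``; the output is base samples strictly
    before ``transition_time`` followed by transformed patch samples from
    ``transition_time`` on.
    """
    if base.labels != patch.labels or base.dim != patch.dim:
        raise ValidationError("stitch requires identical POI sets and dimension")
    if patch.times[-1] < transition_time:
        raise ValidationError("patch does not reach the transition time")
    moved = patch
    if rotation != 0.0:
        moved = rotate(moved, rotation, center=rotation_center)
    if offset is not None and np.any(np.asarray(offset, dtype=float) != 0):
        moved = shift(moved, offset)
    keep_b = base.times < transition_time
    keep_p = moved.times >= transition_time
    if not keep_b.any() or not keep_p.any():
        raise ValidationError("transition time leaves one side empty")
    tb = base.times[keep_b]
    tp = moved.times[keep_p]
    if tp[0] <= tb[-1]:
        raise ValidationError("stitched times would not be strictly increasing")
    dt_med = float(np.median(np.diff(base.times)))
    if tp[0] - tb[-1] > 2.0 * dt_med:
        warnings.warn(
            f"time gap of {tp[0] - tb[-1]:g} at the transition exceeds twice "
            f"the median sampling interval ({dt_med:g})"
        )
    pois = []
    for pb, pp in zip(base.pois, moved.pois):
        pois.append(PointTrajectory(
            pb.label,
            np.concatenate([pb.times[keep_b], pp.times[keep_p]]),
            np.concatenate([pb.coords[keep_b], pp.coords[keep_p]]),
            np.concatenate([pb.missing[keep_b], pp.missing[keep_p]]),
        ))
    out = Element(base.name, pois, history=list(base.history))
    return out.with_history("stitch", transition_time=float(transition_time),
                            offset=None if offset is None else list(map(float, offset)),
                            rotation=float(rotation))
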