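"""File-based rendering: stick diagrams, heatmaps, gait diagrams, time
series, cyclograms and animation export.

The correctness surface is the exported geometry, not pixels: SVG output
is written directly (one ``<polyline>`` per stick frame, one ``<rect>``
per gait interval) with a documented affine viewport transform, so tests
can parse shapes and coordinates back out.  Raster output goes through
matplotlib/PIL.  Rendering never mutates analysis data; a 2D element gets
its constant placeholder third coordinate only here, never in kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .errors import ValidationError

__all__ = ["RenderSpec", "render_stick", "render_heatmap", "render_gait",
           "render_series", "render_cyclogram", "export_animation"]

_PALETTE = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


@dataclass
class RenderSpec:
    """Output options shared by all renderers."""

    format: str = "svg"            # svg, png, gif, frames
    width: int = 640
    height: int = 480
    line_width: float = 1.5
    markers: bool = True
    marker_radius: float = 2.5
    colors: list = field(default_factory=lambda: list(_PALETTE))
    rate: float = 25.0             # animation playback fps
    azimuth: float = -60.0         # 3D perspective
    elevation: float = 30.0
    padding: float = 0.05

    def __post_init__(self):
        if self.format not in ("svg", "png", "gif", "frames"):
            raise ValidationError(f"unsupported render format {self.format!r}")
        if not self.rate > 0:
            raise ValidationError("playback rate must be positive")


class _Viewport:
    """Affine map from data coordinates to SVG pixel coordinates (y down)."""

    def __init__(self, xs, ys, spec: RenderSpec):
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        x0, x1 = np.nanmin(xs), np.nanmax(xs)
        y0, y1 = np.nanmin(ys), np.nanmax(ys)
        if x1 == x0:
            x1 = x0 + 1.0
        if y1 == y0:
            y1 = y0 + 1.0
        px = spec.padding * spec.width
        py = spec.padding * spec.height
        self.sx = (spec.width - 2 * px) / (x1 - x0)
        self.sy = (spec.height - 2 * py) / (y1 - y0)
        self.x0, self.y1 = x0, y1
        self.px, self.py = px, py

    def map(self, x, y):
        return (self.px + (np.asarray(x) - self.x0) * self.sx,
                self.py + (self.y1 - np.asarray(y)) * self.sy)


def _svg_doc(spec: RenderSpec, body: list) -> str:
    head = (f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{spec.width}" height="{spec.height}">')
    return "\n".join([head] + body + ["</svg>"])


def _write(path, text: str) -> Path:
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path


def _project(frames: np.ndarray, spec: RenderSpec) -> np.ndarray:
    """Reduce (n, k, d) coordinates to 2D for drawing (simple orthographic
    azimuth/elevation projection for 3D)."""
    if frames.shape[-1] == 2:
        return frames
    az = np.deg2rad(spec.azimuth)
    el = np.deg2rad(spec.elevation)
    x, y, z = frames[..., 0], frames[..., 1], frames[..., 2]
    u = x * np.cos(az) + y * np.sin(az)
    v = z * np.cos(el) - (y * np.cos(az) - x * np.sin(az)) * np.sin(el)
    return np.stack([u, v], axis=-1)


def render_stick(sd, path, spec: RenderSpec | None = None) -> Path:
    """Render a stick diagram: one polyline per frame, vertices in POI order."""
    spec = spec or RenderSpec()
    frames = np.asarray(sd.frames, dtype=float)
    if frames.size == 0:
        raise ValidationError("empty stick diagram")
    pts = _project(frames, spec)
    if spec.format == "png":
        return _render_stick_png(pts, path, spec)
    vp = _Viewport(pts[..., 0], pts[..., 1], spec)
    body = []
    nf = len(pts)
    for i, frame in enumerate(pts):
        color = spec.colors[0]
        shade = 0.25 + 0.75 * (i + 1) / nf  # later frames darker
        xs, ys = vp.map(frame[:, 0], frame[:, 1])
        pt_str = " ".join(f"{x:.3f},{y:.3f}" for x, y in zip(xs, ys))
        body.append(f'<polyline points="{pt_str}" fill="none" '
                    f'stroke="{color}" stroke-opacity="{shade:.3f}" '
                    f'stroke-width="{spec.line_width}"/>')
        if spec.markers:
            for k, (x, y) in enumerate(zip(xs, ys)):
                c = spec.colors[k % len(spec.colors)]
                body.append(f'<circle cx="{x:.3f}" cy="{y:.3f}" '
                            f'r="{spec.marker_radius}" fill="{c}"/>')
    return _write(path, _svg_doc(spec, body))


def _render_stick_png(pts, path, spec: RenderSpec) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(spec.width / 100, spec.height / 100), dpi=100)
    for frame in pts:
        ax.plot(frame[:, 0], frame[:, 1], "-", lw=spec.line_width,
                color=spec.colors[0], alpha=0.6)
    ax.set_aspect("equal")
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_heatmap(h, path, spec: RenderSpec | None = None) -> Path:
    """Render an occupancy heatmap: one rect per bin shaded by count (svg)
    or an image (png)."""
    spec = spec or RenderSpec()
    counts = np.asarray(h.counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("empty heatmap")
    if spec.format == "png":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.imshow(counts.T, origin="lower", extent=h.extent, aspect="auto")
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    vmax = counts.max() or 1.0
    vp = _Viewport(h.x_edges, h.y_edges, spec)
    body = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            x0, y0 = vp.map(h.x_edges[i], h.y_edges[j + 1])
            x1, y1 = vp.map(h.x_edges[i + 1], h.y_edges[j])
            v = counts[i, j] / vmax
            body.append(f'<rect x="{x0:.3f}" y="{y0:.3f}" '
                        f'width="{x1 - x0:.3f}" height="{y1 - y0:.3f}" '
                        f'fill="#d62728" fill-opacity="{v:.4f}"/>')
    return _write(path, _svg_doc(spec, body))


def render_gait(gd, path, spec: RenderSpec | None = None) -> Path:
    """Render a gait diagram: one rect per stance interval per side, plus
    one per bilateral overlap (left red, right green, overlap gray)."""
    spec = spec or RenderSpec()
    rows = [("left", gd.left, "#d62728"), ("right", gd.right, "#2ca02c"),
            ("overlap", gd.overlap, "#7f7f7f")]
    all_iv = gd.left + gd.right + gd.overlap
    if not all_iv:
        raise ValidationError("empty gait diagram")
    t0 = min(iv[0] for iv in all_iv)
    t1 = max(iv[1] for iv in all_iv)
    span = (t1 - t0) or 1.0
    body = []
    row_h = spec.height / 4
    for r, (name, ivs, color) in enumerate(rows):
        y = spec.height * 0.1 + r * row_h
        for a, b in ivs:
            x = spec.width * 0.05 + (a - t0) / span * spec.width * 0.9
            w = (b - a) / span * spec.width * 0.9
            body.append(f'<rect x="{x:.3f}" y="{y:.3f}" width="{w:.3f}" '
                        f'height="{row_h * 0.8:.3f}" fill="{color}"/>')
        body.append(f'<text x="2" y="{y + row_h * 0.5:.1f}" '
                    f'font-size="12">{escape(name)}</text>')
    return _write(path, _svg_doc(spec, body))


def render_series(series_list, path, spec: RenderSpec | None = None,
                  labels=None) -> Path:
    """Render (times, values) pairs as line plots (matplotlib)."""
    spec = spec or RenderSpec(format="png")
    if not series_list:
        raise ValidationError("no series to render")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for k, (t, v) in enumerate(series_list):
        lbl = labels[k] if labels else None
        ax.plot(t, v, lw=spec.line_width,
                color=spec.colors[k % len(spec.colors)], label=lbl)
    if labels:
        ax.legend()
    ax.set_xlabel("time")
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_cyclogram(pairs, path, spec: RenderSpec | None = None) -> Path:
    """Render an angle-angle loop."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValidationError("empty cyclogram")
    return render_series([(pairs[:, 0], pairs[:, 1])], path, spec)


def export_animation(e, path, spec: RenderSpec | None = None,
                     third_coord: float = 0.0) -> Path:
    """Export an element as an animated GIF or a numbered PNG frame
    sequence: one frame per sample.

    2D elements get the constant ``third_coord`` for perspective rendering
    only; it never enters any calculation.
    """
    from PIL import Image, ImageDraw

    spec = spec or RenderSpec(format="gif")
    if e.n_frames < 2:
        raise ValidationError("animation needs at least 2 frames")
    frames = np.stack([p.coords for p in e.pois], axis=1)  # (n, k, d)
    if frames.shape[-1] == 2 and third_coord != 0.0:
        frames = np.concatenate(
            [frames, np.full(frames.shape[:2] + (1,), third_coord)], axis=-1)
    pts = _project(frames, spec)
    vp = _Viewport(pts[..., 0], pts[..., 1], spec)
    images = []
    for frame in pts:
        img = Image.new("RGB", (spec.width, spec.height), "white")
        draw = ImageDraw.Draw(img)
        xs, ys = vp.map(frame[:, 0], frame[:, 1])
        coords = list(zip(xs.tolist(), ys.tolist()))
        if len(coords) > 1:
            draw.line(coords, fill=(31, 119, 180), width=max(1, int(spec.line_width)))
        if spec.markers:
            r = spec.marker_radius
            for x, y in coords:
                draw.ellipse([x - r, y - r, x + r, y + r], fill=(214, 39, 40))
        images.append(img)
    path = Path(path)
    if spec.format == "frames":
        path.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(images):
            img.save(path / f"frame_{i:05d}.png")
        return path
    images[0].save(path, save_all=True, append_images=images[1:],
                   duration=int(1000 / spec.rate), loop=0)
    return path
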