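"""Readers and writers: delimited text, spreadsheets, pose-estimation CSV
and the session archive.

Tables are column-wise with timestamps in the first column and values
after; header text labels POIs/channels in every downstream table and
plot.  The session archive is an open zip container holding a JSON
manifest plus one CSV payload per dataset, so a saved session is
diffable and loads back losslessly (floats are written with 17
significant digits, which round-trips IEEE doubles exactly).
"""

from __future__ import annotations

import csv
import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Element, PointTrajectory, Session, SignalTrace
from .errors import FileFormatError, ValidationError
from .gait import GaitEvent

__all__ = [
    "RawTable",
    "read_table",
    "table_to_element",
    "read_deeplabcut",
    "read_signal_table",
    "read_events_csv",
    "write_events_csv",
    "write_tables",
    "save_session",
    "load_session",
]

_FLOAT_FMT = "%.17g"
_ARCHIVE_VERSION = 1
_DELIMS = [",", ";", "\t"]


@dataclass
class RawTable:
    """A parsed column-wise table: headers plus equal-length numeric columns.

    Non-numeric cells inside the data region become NaN (missing)."""

    headers: list
    columns: list          # list of float arrays
    source: str

    @property
    def n_rows(self) -> int:
        return len(self.columns[0]) if self.columns else 0


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text[:4096], delimiters="".join(_DELIMS)).delimiter
    except csv.Error:
        first = text.splitlines()[0] if text.splitlines() else ""
        counts = {d: first.count(d) for d in _DELIMS}
        best = max(counts, key=counts.get)
        return best if counts[best] else ","


def _rows_to_table(rows: list, source: str, decimal: str = ".") -> RawTable:
    if not rows:
        raise FileFormatError(f"{source}: empty table")
    headers = [str(h).strip() for h in rows[0]]
    ncol = len(headers)
    data_rows = rows[1:]
    for k, row in enumerate(data_rows, start=2):
        if len(row) != ncol:
            raise FileFormatError(
                f"{source}: row {k} has {len(row)} fields, expected {ncol}"
            )
    cols = []
    for j in range(ncol):
        raw = [str(r[j]) for r in data_rows]
        if decimal != ".":
            raw = [v.replace(decimal, ".") for v in raw]
        cols.append(pd.to_numeric(pd.Series(raw), errors="coerce").to_numpy(float))
    return RawTable(headers, cols, source)


def read_table(path, dialect: str | None = None, decimal: str = ".") -> RawTable:
    """Read a delimited text file or spreadsheet into a RawTable.

    The delimiter of text files is auto-detected among comma, semicolon and
    tab; pass ``decimal=","`` for European exports (never auto-detected, to
    avoid ambiguity with semicolon delimiters).
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xls", ".xlsx") else "csv"
    if dialect == "xlsx":
        df = pd.read_excel(path, header=0)
        rows = [list(df.columns)] + df.astype(object).values.tolist()
        return _rows_to_table(rows, str(path), decimal)
    text = path.read_text(encoding="utf-8-sig")
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(_io.StringIO(text), delimiter=delim) if r]
    return _rows_to_table(rows, str(path), decimal)


def table_to_element(tbl: RawTable, name: str = "element", layout: str = "xy",
                     poi_labels=None) -> Element:
    """Interpret a RawTable as (time, x1, y1[, z1], x2, y2[, z2], ...).

    POI labels come from the x-column headers unless ``poi_labels`` is
    given.  Rows with any non-finite coordinate are flagged missing.
    """
    d = {"xy": 2, "xyz": 3}.get(layout)
    if d is None:
        raise ValidationError(f"layout must be 'xy' or 'xyz', got {layout!r}")
    ncoord = len(tbl.columns) - 1
    if ncoord <= 0 or ncoord % d != 0:
        raise ValidationError(
            f"{tbl.source}: {ncoord} coordinate columns not divisible by {d}"
        )
    n_poi = ncoord // d
    times = tbl.columns[0]
    pois = []
    for k in range(n_poi):
        j0 = 1 + k * d
        coords = np.column_stack(tbl.columns[j0:j0 + d])
        if poi_labels is not None:
            label = poi_labels[k]
        else:
            label = tbl.headers[j0] or f"poi_{k + 1}"
            # exported tables name columns label_x/label_y/label_z
            if label.lower().endswith(("_x", "_y", "_z")):
                label = label[:-2]
        pois.append(PointTrajectory(label, times, coords))
    return Element(name, pois)


def read_deeplabcut(path, fps: float, likelihood_min: float = 0.0) -> Element:
    """Read a pose-estimation CSV (three header rows: scorer / bodyparts /
    coords; first column frame index; per-bodypart x, y[, z], likelihood).

    Times are frame_index / fps; samples with likelihood below
    ``likelihood_min`` are flagged missing (default 0 keeps everything).
    """
    if not fps > 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FileFormatError(f"{path}: not a pose-estimation CSV ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FileFormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    frames = pd.to_numeric(df.index, errors="coerce").to_numpy(float)
    times = frames / fps
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    pois = []
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        axes = [ax for ax in ("x", "y", "z") if ax in sub.columns]
        if len(axes) < 2:
            raise FileFormatError(f"{path}: bodypart {bp!r} lacks x/y columns")
        coords = np.column_stack([sub[ax].to_numpy(float) for ax in axes])
        missing = ~np.all(np.isfinite(coords), axis=1)
        if "likelihood" in sub.columns:
            lik = sub["likelihood"].to_numpy(float)
            missing |= lik < likelihood_min
        pois.append(PointTrajectory(bp, times, coords, missing))
    return Element(Path(path).stem, pois)


def read_signal_table(path, dialect: str | None = None, decimal: str = ".") -> list:
    """Read a (time, channel, channel, ...) table into SignalTraces."""
    tbl = read_table(path, dialect, decimal)
    if len(tbl.columns) < 2:
        raise FileFormatError(f"{tbl.source}: a signal table needs >= 2 columns")
    times = tbl.columns[0]
    out = []
    for k, (head, col) in enumerate(zip(tbl.headers[1:], tbl.columns[1:]), start=1):
        out.append(SignalTrace(head or f"channel_{k}", times, col))
    return out


def _element_frame(e: Element) -> pd.DataFrame:
    data = {"time": e.times}
    for p in e.pois:
        for ax_i, ax in enumerate("xyz"[: p.dim]):
            data[f"{ax}_{p.label}"] = p.coords[:, ax_i]
        data[f"missing_{p.label}"] = p.missing.astype(int)
    return pd.DataFrame(data)


def _element_from_frame(name: str, df: pd.DataFrame) -> Element:
    times = df["time"].to_numpy(float)
    labels, seen = [], set()
    for col in df.columns:
        if col.startswith("x_") and col[2:] not in seen:
            labels.append(col[2:])
            seen.add(col[2:])
    pois = []
    for label in labels:
        axes = [ax for ax in "xyz" if f"{ax}_{label}" in df.columns]
        coords = np.column_stack([df[f"{ax}_{label}"].to_numpy(float) for ax in axes])
        missing = df[f"missing_{label}"].to_numpy(bool) \
            if f"missing_{label}" in df.columns else None
        pois.append(PointTrajectory(label, times, coords, missing))
    return Element(name, pois)


def _product_frame(value) -> pd.DataFrame | None:
    if isinstance(value, pd.DataFrame):
        return value
    if isinstance(value, np.ndarray):
        return pd.DataFrame(np.atleast_2d(value))
    if isinstance(value, dict) and all(np.isscalar(v) for v in value.values()):
        return pd.DataFrame([value])
    return None


def _element_export_frame(e: Element) -> pd.DataFrame:
    """Re-importable schema (t, label_x, label_y, ...); missing -> NaN."""
    data = {"t": e.times}
    for p in e.pois:
        coords = np.where(p.missing[:, None], np.nan, p.coords)
        for ax_i, ax in enumerate("xyz"[: p.dim]):
            data[f"{p.label}_{ax}"] = coords[:, ax_i]
    return pd.DataFrame(data)


def write_tables(session: Session, out_dir, dialect: str = "csv") -> list:
    """Export every element, signal and tabular product to its own file
    (or its own sheet, for the xlsx dialect).  Element files use the
    importable (t, label_x, label_y, ...) schema; numeric values
    round-trip within 1e-12 relative (text dialects use 17 significant
    digits)."""
    if session.empty:
        raise ValidationError("session is empty: nothing to export")
    if dialect not in ("csv", "txt", "xlsx"):
        raise ValidationError(f"dialect must be csv/txt/xlsx, got {dialect!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {}
    for name, e in session.elements.items():
        frames[f"element_{name}"] = _element_export_frame(e)
    for label, s in session.signals.items():
        frames[f"signal_{label}"] = pd.DataFrame({"time": s.times, label: s.values})
    for name, v in session.products.items():
        df = _product_frame(v)
        if df is not None:
            frames[f"product_{name}"] = df
    written = []
    if dialect == "xlsx":
        path = out_dir / "session.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            for name, df in frames.items():
                df.to_excel(xw, sheet_name=name[:31], index=False)
        written.append(path)
    else:
        sep = "," if dialect == "csv" else "\t"
        ext = ".csv" if dialect == "csv" else ".txt"
        for name, df in frames.items():
            path = out_dir / f"{name}{ext}"
            df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
            written.append(path)
    return written


def _signal_csv(times, values) -> str:
    df = pd.DataFrame({"time": np.asarray(times), "value": np.asarray(values)})
    return df.to_csv(index=False, float_format=_FLOAT_FMT)


def save_session(session: Session, path) -> Path:
    """Save all elements, signals, gait events and products to one archive.

    The archive is ZIP(manifest.json + one CSV per dataset); loading it
    back reproduces every field exactly, including missing masks, raw
    signal copies and processing history.
    """
    path = Path(path)
    manifest = {"version": _ARCHIVE_VERSION, "units_note": session.units_note,
                "elements": {}, "signals": {}, "gait": None, "products": {}}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, e in session.elements.items():
            fname = f"elements/{name}.csv"
            manifest["elements"][name] = {
                "file": fname,
                "labels": e.labels,
                "history": e.history,
                "display_only": e.display_only,
            }
            zf.writestr(fname, _element_frame(e).to_csv(index=False,
                                                        float_format=_FLOAT_FMT))
        for label, s in session.signals.items():
            fname = f"signals/{label}.csv"
            rawname = f"signals/{label}.raw.csv"
            manifest["signals"][label] = {"file": fname, "raw_file": rawname,
                                          "meta": s.meta}
            zf.writestr(fname, _signal_csv(s.times, s.values))
            zf.writestr(rawname, _signal_csv(s.raw_times, s.raw_values))
        if session.gait is not None:
            manifest["gait"] = [
                {"type": ev.type, "side": ev.side, "frame": ev.frame,
                 "time": ev.time,
                 "coords": None if ev.coords is None else list(ev.coords)}
                for ev in session.gait
            ]
        for name, v in session.products.items():
            try:
                manifest["products"][name] = json.loads(
                    json.dumps(v, default=_jsonify))
            except TypeError:
                raise ValidationError(
                    f"product {name!r} is not serializable; export it via "
                    "write_tables instead"
                )
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_session(path) -> Session:
    """Load a session archive written by :func:`save_session`."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise FileFormatError(f"{path}: not a session archive ({exc})") from exc
    with zf:
        if "manifest.json" not in zf.namelist():
            raise FileFormatError(f"{path}: archive has no manifest.json")
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("version")
        if version != _ARCHIVE_VERSION:
            raise FileFormatError(
                f"{path}: unsupported archive version {version!r} "
                f"(this build reads version {_ARCHIVE_VERSION})"
            )
        session = Session(units_note=manifest.get("units_note", ""))
        for name, info in manifest["elements"].items():
            df = pd.read_csv(_io.BytesIO(zf.read(info["file"])),
                             float_precision="round_trip")
            e = _element_from_frame(name, df)
            e.history = info["history"]
            e.display_only = info["display_only"]
            session.elements[name] = e
        for label, info in manifest["signals"].items():
            df = pd.read_csv(_io.BytesIO(zf.read(info["file"])),
                             float_precision="round_trip")
            raw = pd.read_csv(_io.BytesIO(zf.read(info["raw_file"])),
                              float_precision="round_trip")
            session.signals[label] = SignalTrace(
                label, df["time"].to_numpy(float), df["value"].to_numpy(float),
                meta=info["meta"],
                raw_values=raw["value"].to_numpy(float),
                raw_times=raw["time"].to_numpy(float),
            )
        if manifest.get("gait") is not None:
            session.gait = [
                GaitEvent(ev["type"], ev["side"], ev["frame"], ev["time"],
                          None if ev["coords"] is None else tuple(ev["coords"]))
                for ev in manifest["gait"]
            ]
        session.products = manifest.get("products", {})
    return session


def read_events_csv(path, e: Element | None = None) -> list:
    """Read a gait-event annotation CSV with columns (type, side, frame
    [, time]); times are filled from the element's clock when given."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("type", "side", "frame"):
        if need not in cols:
            raise FileFormatError(f"{path}: events CSV needs a {need!r} column")
    out = []
    for _, row in df.iterrows():
        frame = int(row[cols["frame"]])
        if e is not None:
            time = float(e.times[frame])
        elif "time" in cols:
            time = float(row[cols["time"]])
        else:
            raise FileFormatError(f"{path}: no time column and no element given")
        out.append(GaitEvent(str(row[cols["type"]]), str(row[cols["side"]]),
                             frame, time))
    return sorted(out, key=lambda ev: ev.time)


def write_events_csv(events, path) -> Path:
    path = Path(path)
    pd.DataFrame([{"type": ev.type, "side": ev.side, "frame": ev.frame,
                   "time": ev.time} for ev in events]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    return path
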