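"""Image and annotation I/O.

Containers for calibrated images, movies, axon traces and polygon ROIs,
plus readers/writers for multi-page TIFF (with sidecar JSON calibration),
the package's JSON/CSV ROI dialect, and read-only import of ImageJ
``.roi``/``.zip`` annotations.

Coordinate convention
---------------------
All coordinates are 0-based ``(x, y)`` pairs where ``x`` is the column
index and ``y`` the row index, referring to pixel *centers*.  ImageJ ROIs
store 0-based pixel-corner coordinates; on import they are shifted by
-0.5 px on both axes to land on pixel centers.
"""

from __future__ import annotations

import csv
import io as _io
import json
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Image2D",
    "MovieStack",
    "AxonTrace",
    "PolygonROI",
    "CalibrationError",
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_rois",
    "write_rois",
    "read_imagej_roi",
]

POLYGON_LABELS = ("curl", "swelling", "swelling_with_curl")


class CalibrationError(ValueError):
    """Raised when pixel size / frame interval are missing and not supplied."""


@dataclass
class Image2D:
    """A single calibrated fluorescence frame.

    Attributes
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity values; must be finite.
    pixel_size_um : float
        Physical pixel size in micrometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D.pixels must be 2-D (rows, cols)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D.pixels must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class MovieStack:
    """A calibrated time-lapse stack (T, rows, cols)."""

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("MovieStack.frames must be 3-D (T, rows, cols)")
        if self.frames.shape[0] < 2:
            raise ValueError("MovieStack requires T >= 2 frames")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    def frame(self, t: int) -> Image2D:
        return Image2D(self.frames[t], self.pixel_size_um)


@dataclass
class AxonTrace:
    """Polyline medial axis of one axon, soma end first.

    Vertices are ``(x, y)`` pixel coordinates (float); arclength is the
    sum of Euclidean segment lengths scaled by ``pixel_size_um``.
    """

    vertices: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("AxonTrace.vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise ValueError("AxonTrace requires >= 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ValueError("AxonTrace has coincident consecutive vertices")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def segment_lengths_px(self) -> np.ndarray:
        return np.hypot(*np.diff(self.vertices, axis=0).T)

    @property
    def arclength_px(self) -> float:
        return float(self.segment_lengths_px.sum())

    @property
    def arclength_um(self) -> float:
        return self.arclength_px * self.pixel_size_um

    @property
    def cumulative_arclength_px(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths_px)])

    def point_at_arclength_um(self, s_um):
        """Interpolate (x, y) at arclength ``s_um`` (scalar or array) from the soma end."""
        s_px = np.asarray(s_um, dtype=float) / self.pixel_size_um
        cum = self.cumulative_arclength_px
        x = np.interp(s_px, cum, self.vertices[:, 0])
        y = np.interp(s_px, cum, self.vertices[:, 1])
        return np.stack([x, y], axis=-1)

    def reversed(self) -> "AxonTrace":
        return AxonTrace(self.vertices[::-1].copy(), self.pixel_size_um)


@dataclass
class PolygonROI:
    """A simple polygon annotation with a biological label."""

    vertices: np.ndarray
    label: str = "curl"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("PolygonROI.vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("PolygonROI requires >= 3 vertices")
        if self.label not in POLYGON_LABELS:
            raise ValueError(
                f"unknown polygon label {self.label!r}; expected one of {POLYGON_LABELS}"
            )
        if not _ShapelyPolygon(self.vertices).is_valid:
            raise ValueError("PolygonROI must be a simple (non-self-intersecting) polygon")


# ---------------------------------------------------------------------------
# TIFF stacks + sidecar calibration
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_calibration(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_stack(path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> MovieStack:
    """Read a multi-page TIFF as a :class:`MovieStack`.

    Calibration is taken from the sidecar JSON ``<path>.json``
    (``{"pixel_size_um": ..., "frame_interval_s": ...}``) unless passed
    explicitly; missing calibration is an error, never assumed.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        raise ValueError("movie requires T >= 2 frames; got a single page")
    meta = _load_calibration(path)
    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    frame_interval_s = (frame_interval_s if frame_interval_s is not None
                        else meta.get("frame_interval_s"))
    if pixel_size_um is None:
        raise CalibrationError(f"no pixel_size_um for {path}; supply it or a sidecar JSON")
    if frame_interval_s is None:
        raise CalibrationError(f"no frame_interval_s for {path}; supply it or a sidecar JSON")
    return MovieStack(frames, float(pixel_size_um), float(frame_interval_s))


def write_stack(stack: MovieStack, path) -> None:
    """Write a movie as multi-page TIFF plus sidecar JSON calibration."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
    }))


def read_image(path, pixel_size_um: float | None = None) -> Image2D:
    """Read a single-frame TIFF as :class:`Image2D` (sidecar or explicit calibration)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ValueError(f"expected a single-page TIFF, got shape {pixels.shape}")
    if pixel_size_um is None:
        pixel_size_um = _load_calibration(path).get("pixel_size_um")
    if pixel_size_um is None:
        raise CalibrationError(f"no pixel_size_um for {path}; supply it or a sidecar JSON")
    return Image2D(pixels, float(pixel_size_um))


def write_image(image: Image2D, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.pixels, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({"pixel_size_um": image.pixel_size_um}))


# ---------------------------------------------------------------------------
# ROI dialect (JSON / CSV) and ImageJ import
# ---------------------------------------------------------------------------

def write_rois(path, traces: list[AxonTrace] = (), polygons: list[PolygonROI] = ()) -> None:
    """Write traces and polygons to the JSON ROI dialect."""
    payload = {
        "traces": [
            {"points": t.vertices.tolist(), "pixel_size_um": t.pixel_size_um}
            for t in traces
        ],
        "polygons": [
            {"label": p.label, "points": p.vertices.tolist()} for p in polygons
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_rois(path, pixel_size_um: float | None = None
              ) -> tuple[list[AxonTrace], list[PolygonROI]]:
    """Read annotations from ROI JSON/CSV or an ImageJ ``.roi``/``.zip``.

    JSON dialect: ``{"traces": [{"points": [[x, y], ...]}],
    "polygons": [{"label": ..., "points": ...}]}``.  CSV dialect: columns
    ``roi_id, kind, label, x, y`` with one vertex per row.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return _read_rois_json(path, pixel_size_um)
    if suffix == ".csv":
        return _read_rois_csv(path, pixel_size_um)
    if suffix == ".roi":
        return _collect_imagej([read_imagej_roi(path.read_bytes())], pixel_size_um)
    if suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(read_imagej_roi(zf.read(name)))
        return _collect_imagej(rois, pixel_size_um)
    raise ValueError(f"unsupported ROI file type: {path.suffix}")


def _require_pixel_size(pixel_size_um, source) -> float:
    if pixel_size_um is None:
        raise CalibrationError(f"no pixel_size_um for traces in {source}")
    return float(pixel_size_um)


def _read_rois_json(path: Path, pixel_size_um):
    payload = json.loads(Path(path).read_text())
    traces = []
    for entry in payload.get("traces", []):
        px = entry.get("pixel_size_um", pixel_size_um)
        traces.append(AxonTrace(np.asarray(entry["points"], dtype=float),
                                _require_pixel_size(px, path)))
    polygons = [
        PolygonROI(np.asarray(entry["points"], dtype=float),
                   entry.get("label", "curl"))
        for entry in payload.get("polygons", [])
    ]
    return traces, polygons


def _read_rois_csv(path: Path, pixel_size_um):
    groups: dict[tuple, list] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["roi_id"], row["kind"], row.get("label", ""))
            groups.setdefault(key, []).append((float(row["x"]), float(row["y"])))
    traces, polygons = [], []
    for (_, kind, label), pts in groups.items():
        if kind == "trace":
            traces.append(AxonTrace(np.asarray(pts), _require_pixel_size(pixel_size_um, path)))
        elif kind == "polygon":
            polygons.append(PolygonROI(np.asarray(pts), label or "curl"))
        else:
            raise ValueError(f"unknown ROI kind {kind!r} in {path}")
    return traces, polygons


# ImageJ .roi binary layout (RoiDecoder.java): magic "Iout", int16 version,
# uint8 type at offset 6, int16 top/left/bottom/right at 8..16, uint16 n at
# 16, int16 x/y coords relative to (left, top) starting at offset 64.
_IJ_POLYGON, _IJ_FREEHAND, _IJ_POLYLINE, _IJ_FREELINE = 0, 7, 6, 4
_IJ_TYPES = {
    _IJ_POLYGON: "polygon",
    _IJ_FREEHAND: "polygon",
    _IJ_POLYLINE: "line",
    _IJ_FREELINE: "line",
}


def read_imagej_roi(data: bytes) -> tuple[str, np.ndarray]:
    """Decode an ImageJ ``.roi`` blob to ``(kind, (N, 2) float vertices)``.

    Supports polygon/freehand (closed) and segmented/freehand line types
    only; other subtypes raise.  Coordinates are shifted by -0.5 px per the
    package's pixel-center convention.
    """
    if data[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _IJ_TYPES:
        raise ValueError(f"unsupported ImageJ ROI subtype {roi_type}; "
                         "only polygon/freehand/polyline are supported")
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">H", data[16:18])
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return _IJ_TYPES[roi_type], np.stack([xs - 0.5, ys - 0.5], axis=1)


def _collect_imagej(rois, pixel_size_um):
    traces, polygons = [], []
    for kind, pts in rois:
        if kind == "line":
            traces.append(AxonTrace(pts, _require_pixel_size(pixel_size_um, "ImageJ ROI")))
        else:
            polygons.append(PolygonROI(pts, "curl"))
    return traces, polygons
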