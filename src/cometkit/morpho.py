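"""Axon morphometrics: length, curl area, the MT disorganisation index, swellings.

The MT disorganisation index (MDI) normalises the summed area of
disorganised MT curling to the area the axon would occupy if its
microtubules were perfectly bundled: the traced axon length times a
reference axon diameter (0.5 um by default)::

    MDI = sum(curl areas) / (axon length * reference diameter)

Swelling counts are annotation-driven: each axonal swelling is an operator
polygon labelled ``swelling`` or ``swelling_with_curl`` (the latter counts
toward both tallies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .io import AxonTrace, PolygonROI

__all__ = ["MDIResult", "SwellingCounts", "axon_length", "polygon_area", "mdi",
           "swelling_counts"]


@dataclass
class MDIResult:
    axon_length_um: float
    curl_area_um2: float
    reference_diameter_um: float
    mdi: float


@dataclass
class SwellingCounts:
    n_axons: int
    n_swellings: int
    n_swellings_with_curl: int
    swellings_per_axon: float
    swellings_with_curl_per_axon: float


def axon_length(trace: AxonTrace) -> float:
    """Axon length in um: summed Euclidean segment lengths of the trace."""
    length = trace.arclength_um
    if not length > 0:
        raise ValueError("degenerate trace: zero arclength")
    return length


def shoelace_area_px(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon given as (N, 2) vertices."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    return abs(float(cross.sum())) / 2.0


def polygon_area(poly: PolygonROI, pixel_size_um: float) -> float:
    """Polygon area in um^2 (shoelace formula scaled by the pixel size)."""
    if not _ShapelyPolygon(poly.vertices).is_valid:
        raise ValueError("polygon is self-intersecting")
    return shoelace_area_px(poly.vertices) * pixel_size_um**2


def mdi(curl_polys: list[PolygonROI], trace: AxonTrace,
        reference_diameter_um: float = 0.5) -> MDIResult:
    """MT disorganisation index for one axon.

    Areas of all curl polygons are summed before dividing by
    (axon length x reference diameter).
    """
    length = axon_length(trace)
    area = sum(polygon_area(p, trace.pixel_size_um) for p in curl_polys)
    return MDIResult(
        axon_length_um=length,
        curl_area_um2=area,
        reference_diameter_um=reference_diameter_um,
        mdi=area / (length * reference_diameter_um),
    )


def swelling_counts(annotations: list[PolygonROI], n_axons: int) -> SwellingCounts:
    """Count swellings (total and with MT curling) over ``n_axons`` axons.

    ``swelling_with_curl`` annotations count as swellings too.
    """
    if n_axons <= 0:
        raise ValueError("n_axons must be positive")
    labels = [p.label for p in annotations]
    bad = [l for l in labels if l not in ("swelling", "swelling_with_curl")]
    if bad:
        raise ValueError(f"unexpected labels for swelling counting: {bad}")
    n_with_curl = labels.count("swelling_with_curl")
    n_total = len(labels)
    return SwellingCounts(
        n_axons=n_axons,
        n_swellings=n_total,
        n_swellings_with_curl=n_with_curl,
        swellings_per_axon=n_total / n_axons,
        swellings_with_curl_per_axon=n_with_curl / n_axons,
    )
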