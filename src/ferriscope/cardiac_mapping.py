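"""16-segment left-ventricular T2* mapping.

The LV myocardium is partitioned per the AHA standardized model: 6
equiangular segments in the basal and mid short-axis slices, 4 in the
apical slice (16 segments total, numbered basal 1-6, mid 7-12, apical
13-16).  Segments are sectors around the myocardial centroid, counted
counterclockwise from a reference angle (the anterior RV insertion in
clinical practice; here an explicit input, default 90 degrees = anterior).
Each segment's ROI-mean decay is fitted with the model-selection rule of
:mod:`ferriscope.relaxometry`; the global heart T2* is the plain mean of
the 16 segmental values, and segments at or below 20 ms count as low
(normal is strictly greater than 20 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.draw import polygon2mask

from ferriscope.relaxometry import EchoSeries, RelaxFit, select_fit

__all__ = [
    "MyocardialContours",
    "CardiacT2StarMap",
    "segment_masks",
    "build_heart_map",
    "count_low_segments",
    "LOW_SEGMENT_THRESHOLD_MS",
    "SEGMENTS_PER_SLICE",
]

#: Conservative normal cut-off: T2* > 20 ms is normal, <= 20 ms is low.
LOW_SEGMENT_THRESHOLD_MS = 20.0

SEGMENTS_PER_SLICE = {"basal": 6, "mid": 6, "apical": 4}


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _is_simple(pts: np.ndarray) -> bool:
    n = len(pts)
    for i in range(n):
        a1, a2 = pts[i], pts[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(a1, a2, pts[j], pts[(j + 1) % n]):
                return False
    return True


@dataclass(frozen=True)
class MyocardialContours:
    """Endo- and epicardial contours of one short-axis slice.

    Contours are ordered ``[x, y]`` point lists in pixel units; both must be
    simple polygons with the endocardial contour strictly inside the
    epicardial one.  ``reference_angle`` (degrees, mathematical convention:
    0 = +x, counterclockwise positive) sets the angular origin of segment 1.
    """

    slice_level: Literal["basal", "mid", "apical"]
    endocardium: np.ndarray
    epicardium: np.ndarray
    reference_angle: float = 90.0

    def __init__(self, slice_level: str, endocardium: Sequence[Sequence[float]],
                 epicardium: Sequence[Sequence[float]], reference_angle: float = 90.0) -> None:
        if slice_level not in SEGMENTS_PER_SLICE:
            raise ValueError(f"slice_level must be one of {sorted(SEGMENTS_PER_SLICE)}")
        endo = np.asarray(endocardium, dtype=float)
        epi = np.asarray(epicardium, dtype=float)
        for name, c in (("endocardium", endo), ("epicardium", epi)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise ValueError(f"{name} must be an (n, 2) array with n >= 3")
            if not _is_simple(c):
                raise ValueError(f"{name} contour is self-intersecting")
        if abs(_polygon_area(endo)) >= abs(_polygon_area(epi)):
            raise ValueError("endocardial contour must lie strictly inside the epicardial one")
        object.__setattr__(self, "slice_level", slice_level)
        object.__setattr__(self, "endocardium", endo)
        object.__setattr__(self, "epicardium", epi)
        object.__setattr__(self, "reference_angle", float(reference_angle))

    @property
    def n_segments(self) -> int:
        return SEGMENTS_PER_SLICE[self.slice_level]


@dataclass(frozen=True)
class CardiacT2StarMap:
    """Sixteen segmental T2* values with the derived global metrics."""

    segment_values: np.ndarray           # ms, AHA order: basal 1-6, mid 7-12, apical 13-16
    global_value: float                  # ms, mean of the 16 segments
    n_low_segments: int                  # count of segments <= 20 ms
    correction_applied: bool
    fits: tuple[RelaxFit, ...] = ()

    def to_dict(self) -> dict:
        return {
            "segment_t2star_ms": [float(v) for v in self.segment_values],
            "global_t2star_ms": self.global_value,
            "n_low_segments": self.n_low_segments,
            "correction_applied": self.correction_applied,
        }


def _contour_mask(contour: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    # polygon2mask expects (row, col) = (y, x) vertex order
    return polygon2mask(grid_shape, contour[:, ::-1])


def segment_masks(contours: MyocardialContours,
                  grid_shape: tuple[int, int]) -> list[np.ndarray]:
    """Equiangular segment masks over the myocardium of one slice.

    Myocardial pixels (inside the epicardial, outside the endocardial
    contour) are assigned to 6 (basal/mid) or 4 (apical) angular sectors
    around the myocardial centroid, starting at ``reference_angle`` and
    proceeding counterclockwise.  The masks are disjoint and cover the
    myocardial mask exactly.
    """
    epi = _contour_mask(contours.epicardium, grid_shape)
    endo = _contour_mask(contours.endocardium, grid_shape)
    myo = epi & ~endo
    if not myo.any():
        raise ValueError("empty myocardium on the supplied grid")

    yy, xx = np.nonzero(myo)
    cy, cx = yy.mean(), xx.mean()
    # mathematical angle convention on image axes: +x right, +y up would flip
    # rows; rows grow downward, so negate dy to keep counterclockwise positive
    theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))
    rel = np.mod(theta - contours.reference_angle, 360.0)

    n_seg = contours.n_segments
    width = 360.0 / n_seg
    bins = np.minimum((rel // width).astype(int), n_seg - 1)

    masks = []
    for k in range(n_seg):
        m = np.zeros(grid_shape, dtype=bool)
        sel = bins == k
        m[yy[sel], xx[sel]] = True
        masks.append(m)
    return masks


def count_low_segments(values: Sequence[float],
                       threshold_ms: float = LOW_SEGMENT_THRESHOLD_MS) -> int:
    """Number of segments with low T2*.

    Normal is strictly above the threshold, so a value exactly at 20 ms
    counts as low.
    """
    return int(np.sum(np.asarray(values, dtype=float) <= threshold_ms))


def build_heart_map(segment_series: Sequence[EchoSeries],
                    correction: Sequence[float] | None = None,
                    heavy_iron_t2star_threshold: float = 10.0) -> CardiacT2StarMap:
    """Fit the 16 segmental decays and assemble the cardiac T2* map.

    ``segment_series`` must hold exactly 16 ROI-mean decay curves in AHA
    order.  ``correction`` is an optional per-segment multiplicative factor
    (susceptibility-artifact correction hook; default identity).  Each
    segment is fitted with :func:`ferriscope.relaxometry.select_fit`; the
    global value is the arithmetic mean of the (corrected) segmental values
    and ``n_low_segments`` counts values at or below 20 ms.
    """
    if len(segment_series) != 16:
        raise ValueError(f"expected 16 segment series, got {len(segment_series)}")
    if correction is not None:
        corr = np.asarray(correction, dtype=float)
        if corr.shape != (16,):
            raise ValueError("correction must supply exactly 16 factors")
        if np.any(corr <= 0):
            raise ValueError("correction factors must be positive")
    else:
        corr = np.ones(16)

    fits = tuple(select_fit(s, heavy_iron_t2star_threshold) for s in segment_series)
    values = np.array([f.t2star for f in fits]) * corr
    return CardiacT2StarMap(
        segment_values=values,
        global_value=float(values.mean()),
        n_low_segments=count_low_segments(values),
        correction_applied=correction is not None,
        fits=fits,
    )
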