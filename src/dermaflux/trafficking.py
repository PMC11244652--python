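"""Quantification of circulating T-cell retention and infiltration.

Deterministic re-implementation of a manual ImageJ workflow: frames are
rescaled to 8-bit, thresholded (Otsu by default) into binary masks, connected
components above a minimum area become cell detections, and retention is the
count of cells inside a region of interest relative to a baseline frame.
Infiltration depth is scored with a Euclidean distance transform from the
vessel mask.

Cells are *not* tracked across frames: retention is a count ratio per frame,
so detaching cells and newly arriving cells trade off against each other.
Touching cells merge into one component (no watershed), matching simple
mask-based counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure
from skimage.filters import threshold_otsu

#: default minimum detection area, in pixel^2 units (converted via pixel size)
DEFAULT_MIN_AREA_PX2 = 4.0


class QuantError(ValueError):
    """Invalid input to a quantification step."""


@dataclass(frozen=True)
class RegionOfInterest:
    """A labelled simple polygon in physical (um) coordinates.

    Coordinate convention: origin top-left, x to the right, y increasing
    downward.  Containment is evaluated at pixel/cell centers.
    """

    label: str
    vertices_um: np.ndarray  # (N, 2) array of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_um, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise QuantError(f"ROI {self.label!r}: need >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices_um", v)
        poly = ShapelyPolygon(v)
        if not poly.is_simple or poly.area == 0:
            raise QuantError(f"ROI {self.label!r}: polygon must be simple with nonzero area")

    @classmethod
    def rectangle(cls, label: str, x0: float, y0: float, x1: float, y1: float) -> "RegionOfInterest":
        return cls(label, np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))

    def as_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices_um)

    def contains_points(self, points_um: np.ndarray) -> np.ndarray:
        """Boolean inclusion test for an (N, 2) array of (x, y) points in um."""
        points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
        return MplPath(self.vertices_um).contains_points(points_um)

    def raster_mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the polygon."""
        h, w = shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        pts = np.column_stack(
            [(cols.ravel() + 0.5) * pixel_size_um, (rows.ravel() + 0.5) * pixel_size_um]
        )
        return self.contains_points(pts).reshape(h, w)


@dataclass
class ImageStack:
    """Time-lapse frames with physical calibration."""

    frames: np.ndarray          # (T, H, W)
    timestamps_s: np.ndarray    # (T,)
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise QuantError("frames must be a (T, H, W) array")
        if len(self.timestamps_s) != len(self.frames):
            raise QuantError(
                f"{len(self.frames)} frames but {len(self.timestamps_s)} timestamps"
            )
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise QuantError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise QuantError("pixel size must be > 0")


@dataclass
class CellDetections:
    """Connected-component detections for one frame."""

    centroids_um: np.ndarray   # (N, 2) (x, y)
    areas_um2: np.ndarray      # (N,)

    @property
    def count(self) -> int:
        return len(self.centroids_um)


@dataclass
class RetentionResult:
    """Counts and retention percentage relative to a baseline frame."""

    label: str
    times_min: np.ndarray
    counts: np.ndarray
    retention_pct: np.ndarray
    baseline_index: int


@dataclass
class InfiltrationResult:
    """Per-cell distances (um) from the nearest vessel, with summary stats."""

    distances_um: np.ndarray
    excluded_in_lumen: int = 0

    @property
    def count(self) -> int:
        return len(self.distances_um)

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.distances_um)) if self.count else float("nan")

    @property
    def max_um(self) -> float:
        return float(np.max(self.distances_um)) if self.count else float("nan")


def rescale_to_8bit(frame: np.ndarray) -> np.ndarray:
    """Min-max rescale a frame to uint8 [0, 255]; constant frames map to 0."""
    frame = np.asarray(frame, dtype=float)
    lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        return np.zeros(frame.shape, dtype=np.uint8)
    return np.round((frame - lo) / (hi - lo) * 255.0).astype(np.uint8)


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    return_threshold: bool = False,
):
    """Rescale a frame to 8-bit and threshold it into a binary mask.

    ``method='otsu'`` derives the threshold from the 8-bit histogram;
    ``method='fixed'`` uses ``threshold`` (on the 8-bit scale).  The mask is
    ``img > threshold``.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise QuantError("empty frame")
    img8 = rescale_to_8bit(frame)
    if method == "otsu":
        if img8.min() == img8.max():
            raise QuantError(
                "constant-intensity frame: Otsu threshold undefined; "
                "use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(img8))
    elif method == "fixed":
        if threshold is None:
            raise QuantError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise QuantError(f"unknown threshold method {method!r}")
    mask = img8 > thr
    return (mask, thr) if return_threshold else mask


def detect_cells(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float | None = None,
) -> CellDetections:
    """Count 8-connected components with area >= ``min_area_um2`` as cells.

    Default minimum area is 4 px^2 expressed in um^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size_um <= 0:
        raise QuantError("pixel size must be > 0")
    if min_area_um2 is None:
        min_area_um2 = DEFAULT_MIN_AREA_PX2 * pixel_size_um**2
    labels = measure.label(mask, connectivity=2)
    centroids, areas = [], []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * pixel_size_um**2
        if area_um2 >= min_area_um2:
            r, c = prop.centroid
            centroids.append(((c + 0.5) * pixel_size_um, (r + 0.5) * pixel_size_um))
            areas.append(area_um2)
    if centroids:
        return CellDetections(np.array(centroids), np.array(areas))
    return CellDetections(np.empty((0, 2)), np.empty(0))


def retention_timeseries(
    stack: ImageStack,
    roi: RegionOfInterest,
    baseline_index: int = 0,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_um2: float | None = None,
) -> RetentionResult:
    """Per-frame ROI cell counts as a percentage of the baseline frame count.

    retention_pct(t) = 100 * N_roi(t) / N_roi(t_baseline).  Raises if the
    baseline frame has no detections inside the ROI.
    """
    counts = []
    for frame in stack.frames:
        det = detect_cells(
            binarize(frame, method=method, threshold=threshold),
            stack.pixel_size_um,
            min_area_um2,
        )
        if det.count:
            inside = roi.contains_points(det.centroids_um)
            counts.append(int(inside.sum()))
        else:
            counts.append(0)
    counts = np.asarray(counts)
    n0 = counts[baseline_index]
    if n0 == 0:
        raise QuantError(
            f"ROI {roi.label!r}: zero cells in baseline frame {baseline_index}; "
            "retention denominator undefined"
        )
    return RetentionResult(
        label=roi.label,
        times_min=stack.timestamps_s / 60.0,
        counts=counts,
        retention_pct=100.0 * counts / n0,
        baseline_index=baseline_index,
    )


def zone_retention(
    stack: ImageStack,
    zones: Sequence[RegionOfInterest],
    baseline_index: int = 0,
    **detection_kwargs,
) -> dict[str, RetentionResult | None]:
    """Retention per shear zone; zones must be pairwise non-overlapping.

    A zone with zero baseline detections is reported as ``None`` (undefined)
    without affecting the others.
    """
    polys = [z.as_shapely() for z in zones]
    for i in range(len(zones)):
        for j in range(i + 1, len(zones)):
            if polys[i].intersection(polys[j]).area > 0:
                raise QuantError(
                    f"zones {zones[i].label!r} and {zones[j].label!r} overlap"
                )
    out: dict[str, RetentionResult | None] = {}
    for zone in zones:
        try:
            out[zone.label] = retention_timeseries(
                stack, zone, baseline_index, **detection_kwargs
            )
        except QuantError:
            out[zone.label] = None
    return out


def relative_decrease(p_early: float, p_late: float) -> float:
    """Percentage decrease between an early and a late retention value."""
    if p_early <= 0:
        raise QuantError("p_early must be > 0")
    return 100.0 * (p_early - p_late) / p_early


def nearest_vessel_distance_map(vessel_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Per-pixel Euclidean distance (um) to the nearest vessel pixel."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise QuantError("vessel mask is empty")
    return ndimage.distance_transform_edt(~vessel_mask) * pixel_size_um


def infiltration_analysis(
    cell_mask: np.ndarray,
    vessel_mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float | None = None,
) -> InfiltrationResult:
    """Distance of each infiltrated cell from the nearest vessel.

    Cells whose centroid falls on the vessel mask (intralumenal) are excluded
    from the infiltrated count; a centroid exactly on the vessel boundary
    scores distance 0.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    dist_map = nearest_vessel_distance_map(vessel_mask, pixel_size_um)
    det = detect_cells(np.asarray(cell_mask, dtype=bool), pixel_size_um, min_area_um2)
    distances, in_lumen = [], 0
    for x_um, y_um in det.centroids_um:
        r = min(max(int(y_um / pixel_size_um), 0), vessel_mask.shape[0] - 1)
        c = min(max(int(x_um / pixel_size_um), 0), vessel_mask.shape[1] - 1)
        if vessel_mask[r, c]:
            in_lumen += 1
        else:
            distances.append(dist_map[r, c])
    return InfiltrationResult(
        distances_um=np.asarray(distances, dtype=float),
        excluded_in_lumen=in_lumen,
    )
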