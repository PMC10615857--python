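"""Per-object 2D morphometrics for TEM-section label maps.

Measurement conventions
-----------------------
* Object identity is the label value; connected components within one
  label are not split.  Masks derived by thresholding should be labelled
  with 8-connectivity upstream (see :func:`relabel_components`).
* Interior holes (e.g. cristae lumens) are filled before measuring the
  organelle profile, so "area" is the area of the outline.
* Perimeter is the arc length of the lightly smoothed 0.5-level
  marching-squares contour (see :func:`boundary_length_px`).  ImageJ's
  estimator differs; parity with ImageJ-derived numbers is within a few
  percent only.
* "Length" is the maximum Feret (caliper) diameter over the convex hull
  of the object's pixel corners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import find_contours, regionprops

from .core import NM_PER_UM, LabelMap, LabelMapError

EIGHT_CONN_2D = np.ones((3, 3), dtype=bool)


@dataclass
class MitoRecord2D:
    object_id: int
    area_um2: float
    perimeter_um: float
    circularity: float
    feret_length_um: float
    aspect_ratio: float
    centroid_yx_px: tuple[float, float] = (float("nan"), float("nan"))


def relabel_components(mask: np.ndarray) -> np.ndarray:
    """Label a binary mask into objects with 8-connectivity."""
    lab, _ = ndimage.label(mask, structure=EIGHT_CONN_2D)
    return lab


def boundary_length_px(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Perimeter of a binary mask in pixel units (isotropic pixels).

    Estimated as the arc length of the 0.5-level marching-squares
    contour after a short circular moving average of the vertices.  The
    smoothing removes the staircase bias of the raw digital contour:
    discs are recovered to ~0.3% and axis-aligned rectangles to ~2%
    (raw contours overestimate discs by ~6%; 4-direction Crofton
    underestimates rectangles by ~5%).
    """
    total = 0.0
    padded = np.pad(mask, 1).astype(float)
    for contour in find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        if closed:
            contour = contour[:-1]
        n = len(contour)
        if n > smooth_window >= 3:
            half = smooth_window // 2
            kernel = np.ones(smooth_window) / smooth_window
            wrapped = np.concatenate([contour[-half:], contour, contour[:half]])
            contour = np.column_stack(
                [np.convolve(wrapped[:, k], kernel, mode="valid") for k in range(2)]
            )
        if closed and len(contour) > 1:
            contour = np.vstack([contour, contour[:1]])
        total += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return total


def circularity(area_um2: float, perimeter_um: float) -> float:
    """Circularity index 4*pi*A/P^2; 1.0 for an ideal circle.

    Discretization can push the value slightly above 1; values are
    returned as computed (a warning is emitted above 1.05).
    """
    if area_um2 <= 0 or perimeter_um <= 0:
        raise ValueError("area and perimeter must be positive")
    c = 4.0 * np.pi * area_um2 / perimeter_um**2
    if c > 1.05:
        warnings.warn(
            f"circularity {c:.3f} > 1.05 — likely a very small or thin object",
            stacklevel=2,
        )
    return float(c)


def feret_diameter_px(mask: np.ndarray) -> float:
    """Maximum caliper diameter over the convex hull of pixel corners.

    Each foreground pixel (r, c) contributes its four corners
    (r±0.5, c±0.5); the Feret length is the largest pairwise distance
    between hull vertices, in pixel units (isotropic pixels assumed).
    """
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (coords[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    corners = np.unique(corners, axis=0)
    if coords.shape[0] == 1:
        return float(np.sqrt(2.0))
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except Exception:  # degenerate (collinear) point sets
        pts = corners
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


def _require_isotropic_2d(map_: LabelMap) -> float:
    cal = map_.calibration
    if not np.isclose(cal.px_x_nm, cal.px_y_nm):
        warnings.warn(
            "anisotropic 2D pixels: perimeter/Feret estimates use the x pitch",
            stacklevel=3,
        )
    return cal.px_x_nm


def measure_objects_2d(map_: LabelMap, fill_holes: bool = True) -> list[MitoRecord2D]:
    """Measure every labelled object in a 2D map.

    Returns one :class:`MitoRecord2D` per positive label, with area in
    μm², contour perimeter in μm, circularity, max Feret length in μm
    and the second-moment aspect ratio.
    """
    if map_.dims != 2:
        raise LabelMapError("measure_objects_2d requires a 2D label map")
    ids = map_.object_ids()
    if ids.size == 0:
        raise LabelMapError("label map contains no objects")
    px_nm = _require_isotropic_2d(map_)
    px_area_um2 = map_.calibration.pixel_area_nm2 / NM_PER_UM**2
    px_um = px_nm / NM_PER_UM

    records = []
    for oid in ids:
        mask = map_.mask(int(oid))
        if fill_holes:
            mask = ndimage.binary_fill_holes(mask)
        n_px = int(mask.sum())
        area_um2 = n_px * px_area_um2
        perim_um = boundary_length_px(mask) * px_um
        feret_um = feret_diameter_px(mask) * px_um
        props = regionprops(mask.astype(np.uint8))[0]
        minor = props.axis_minor_length
        major = props.axis_major_length
        aspect = float(major / minor) if minor > 0 else float("inf")
        circ = circularity(area_um2, perim_um) if perim_um > 0 else float("nan")
        records.append(
            MitoRecord2D(
                object_id=int(oid),
                area_um2=area_um2,
                perimeter_um=perim_um,
                circularity=circ,
                feret_length_um=feret_um,
                aspect_ratio=aspect,
                centroid_yx_px=tuple(props.centroid),
            )
        )
    return records


def count_density(map_: LabelMap, region_area_um2: float) -> float:
    """Objects per μm² of the stated region area."""
    if region_area_um2 <= 0:
        raise ValueError("region_area_um2 must be positive")
    return map_.n_objects / region_area_um2


def area_histogram(
    records: list[MitoRecord2D], bin_edges: np.ndarray
) -> tuple[np.ndarray, int]:
    """Histogram object areas into left-closed, right-open bins.

    The final bin is closed on both sides (numpy convention).  Returns
    ``(counts, n_out_of_range)``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with length >= 2")
    areas = np.array([r.area_um2 for r in records], dtype=float)
    counts, _ = np.histogram(areas, bins=edges)
    out_of_range = int(areas.size - counts.sum())
    return counts, out_of_range


def records_to_frame(records: list[MitoRecord2D], image: str = ""):
    """Tidy per-object table matching the CSV output contract."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "image": image,
                "object_id": r.object_id,
                "area_um2": r.area_um2,
                "perimeter_um": r.perimeter_um,
                "circularity": r.circularity,
                "feret_length_um": r.feret_length_um,
                "aspect_ratio": r.aspect_ratio,
            }
            for r in records
        ]
    )
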