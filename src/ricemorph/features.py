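"""The nine dimensionless morpho-colorimetric grain descriptors.

Five morphometric descriptors — box-counting fractal dimension (FD),
circularity (Cir = 4*pi*A/P^2), aspect ratio (AR = major/minor axis of the
moment-equivalent ellipse), extent (Ext = A / bounding-box area) and the
batch-normalized area–perimeter ratio index
(APIdx = [(A/P) − (A/P)min] / (A/P)max) — plus four colorimetric ones:
the mean CIELab L, a, b over the grain's pixels and the yellowness index
YI = 142.86*b/L.  All are dimensionless or color-scale quantities, so the
camera-to-sample distance does not matter.

APIdx is normalized within one image's batch of grains: the grain with the
smallest A/P in the image scores exactly 0 and the maximum is strictly
below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2lab
from skimage.measure import find_contours, regionprops, label as cc_label

from .specs import FEATURE_NAMES
from .synthetic import YELLOWNESS_COEF

#: Columns of a feature table, in order.
TABLE_COLUMNS = ("grain_id", *FEATURE_NAMES, "class_id")

#: Non-feature columns tolerated in tables fed to the classifier.
METADATA_COLUMNS = frozenset(
    {"grain_id", "class_id", "image_id", "centroid_row", "centroid_col", "stage"}
)


@dataclass
class GrainGeometry:
    """Raw pixel-space shape measurements for one grain."""

    A: float  # area, px
    P: float  # perimeter, px
    major: float  # major axis of the moment-equivalent ellipse, px
    minor: float
    bbox_area: float
    centroid: tuple[float, float]  # (row, col)


def _perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Perimeter as the length of the traced sub-pixel contour polygon(s).

    The raw marching-squares polygon zig-zags at the pixel scale and runs
    about 5% long on smooth shapes (a digital disk would score Cir ~0.91);
    a short circular moving average over the contour vertices removes the
    digitization zig-zag while leaving shape-scale structure intact, so a
    large digital disk measures Cir ~0.99.
    """
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        if closed:
            contour = contour[:-1]
        if len(contour) > smooth_window:
            contour = np.column_stack(
                [
                    ndi.uniform_filter1d(contour[:, k], size=smooth_window, mode="wrap")
                    for k in (0, 1)
                ]
            )
        pts = np.vstack([contour, contour[:1]]) if closed else contour
        seg = np.diff(pts, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def measure_geometry(labels: np.ndarray, grain_id: int) -> GrainGeometry:
    """Measure area, perimeter, moment-ellipse axes and bounding box.

    ``labels`` is an integer label map; raises ``KeyError`` if ``grain_id``
    is absent.
    """
    mask = labels == grain_id
    if not mask.any():
        raise KeyError(f"grain_id {grain_id} not present in label map")
    props = regionprops(mask.astype(np.uint8))[0]
    rmin, cmin, rmax, cmax = props.bbox
    return GrainGeometry(
        A=float(props.area),
        P=_perimeter(mask[rmin:rmax, cmin:cmax]),
        major=float(props.axis_major_length),
        minor=float(props.axis_minor_length),
        bbox_area=float((rmax - rmin) * (cmax - cmin)),
        centroid=(float(props.centroid[0]), float(props.centroid[1])),
    )


def circularity(g: GrainGeometry) -> float:
    """Degree of roundness, 4*pi*A/P^2; 1 for a perfect circle."""
    if g.P <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * g.A / g.P**2


def aspect_ratio(g: GrainGeometry) -> float:
    """Major-to-minor axis ratio (>= 1)."""
    if g.minor <= 0:
        raise ValueError("minor axis must be positive")
    return g.major / g.minor


def extent(g: GrainGeometry) -> float:
    """Grain area over axis-aligned bounding-box area, in (0, 1]."""
    if g.bbox_area <= 0:
        raise ValueError("bounding-box area must be positive")
    return g.A / g.bbox_area


def api_index(geometries: Sequence[GrainGeometry] | Iterable[float]) -> np.ndarray:
    """Batch-normalized area-perimeter ratio index for one image's grains.

    APIdx_i = [(A/P)_i − min_j (A/P)_j] / max_j (A/P)_j, with min and max
    taken over the supplied batch.  Requires at least two grains.
    """
    items = list(geometries)
    if items and isinstance(items[0], GrainGeometry):
        ap = np.array([g.A / g.P for g in items], dtype=float)
    else:
        ap = np.asarray(items, dtype=float)
    if ap.size < 2:
        raise ValueError("APIdx needs a batch of at least two grains")
    if ap.max() <= 0:
        raise ValueError("largest A/P must be positive")
    return (ap - ap.min()) / ap.max()


def fractal_dimension(grain_mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a filled grain silhouette.

    The mask is cropped to its bounding box and zero-padded to a square of
    side 2^m (at least 64); occupied boxes N(s) are counted for box sides
    s = 1, 2, 4, ..., 2^(m-1), and FD is the least-squares slope of
    log N(s) against log(1/s).  A plane-filling silhouette gives 2, a thin
    curve gives 1; at finite resolution bold compact grains score higher
    than slender ones.
    """
    mask = np.asarray(grain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty grain mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = cropped.shape
    if max(h, w) < 8:
        raise ValueError(f"grain too small for box counting: {h}x{w} px")
    side = 1 << max(6, int(np.ceil(np.log2(max(h, w)))))
    grid = np.zeros((side, side), dtype=bool)
    grid[:h, :w] = cropped
    sizes = [1 << k for k in range(int(np.log2(side)))]
    counts = []
    for s in sizes:
        boxes = grid.reshape(side // s, s, side // s, s).any(axis=(1, 3))
        counts.append(int(boxes.sum()))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)
    return float(slope)


def grain_color(
    image: np.ndarray, labels: np.ndarray, grain_id: int
) -> tuple[float, float, float]:
    """Mean CIELab (D65, 2 deg observer) color over one grain's pixels."""
    mask = labels == grain_id
    if not mask.any():
        raise KeyError(f"grain_id {grain_id} not present in label map")
    rmin, rmax = np.flatnonzero(mask.any(axis=1))[[0, -1]]
    cmin, cmax = np.flatnonzero(mask.any(axis=0))[[0, -1]]
    patch = image[rmin : rmax + 1, cmin : cmax + 1]
    lab = rgb2lab(patch.astype(np.float64) / 255.0)
    sel = mask[rmin : rmax + 1, cmin : cmax + 1]
    L, a, b = lab[sel].mean(axis=0)
    return float(L), float(a), float(b)


def yellowness_index(L: float, b: float) -> float:
    """Yellowness index YI = 142.86 * b / L (requires L > 0)."""
    if L <= 0:
        raise ValueError(f"CIELab L must be positive for YI, got {L}")
    return YELLOWNESS_COEF * b / L


def extract_features(image: np.ndarray, labels) -> pd.DataFrame:
    """Extract all nine descriptors for every grain in a labeled image.

    ``labels`` may be a :class:`~ricemorph.segmentation.LabeledRegions` or a
    plain integer label map.  Returns one row per grain with columns
    grain_id, FD, Cir, AR, Ext, APIdx, L, a, b, YI, class_id (class_id is
    NA here; fill it from ground truth or leave absent for deployment),
    plus the grain centroid for downstream matching/annotation.
    """
    label_map = getattr(labels, "labels", labels)
    ids = [p.label for p in regionprops(label_map)]
    if not ids:
        return pd.DataFrame(
            columns=list(TABLE_COLUMNS) + ["centroid_row", "centroid_col"]
        )
    lab_image = rgb2lab(image.astype(np.float64) / 255.0)
    records = []
    geoms = []
    for p in regionprops(label_map):
        rmin, cmin, rmax, cmax = p.bbox
        grain_mask = p.image
        geom = GrainGeometry(
            A=float(p.area),
            P=_perimeter(grain_mask),
            major=float(p.axis_major_length),
            minor=float(p.axis_minor_length),
            bbox_area=float((rmax - rmin) * (cmax - cmin)),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
        )
        geoms.append(geom)
        L, a, b = lab_image[rmin:rmax, cmin:cmax][grain_mask].mean(axis=0)
        records.append(
            {
                "grain_id": p.label,
                "FD": fractal_dimension(grain_mask),
                "Cir": circularity(geom),
                "AR": aspect_ratio(geom),
                "Ext": extent(geom),
                "L": float(L),
                "a": float(a),
                "b": float(b),
                "YI": yellowness_index(float(L), float(b)),
                "centroid_row": geom.centroid[0],
                "centroid_col": geom.centroid[1],
            }
        )
    table = pd.DataFrame(records)
    if len(geoms) >= 2:
        table["APIdx"] = api_index(geoms)
    else:
        table["APIdx"] = 0.0
    table["class_id"] = pd.NA
    return table[list(TABLE_COLUMNS) + ["centroid_row", "centroid_col"]]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV or XLSX depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)
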