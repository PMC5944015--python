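"""Whole-plant silhouette phenotypes and side-view selection.

Three scale-invariant holistic traits are computed from binary plant masks:

* bi-angular convex-hull area ratio  BA_CH_R = Area_CH(0 deg) / Area_CH(90 deg)
  — informs on plant rotation / phyllotaxy;
* plant aspect ratio  PAR = Height_BR(side) / Diameter_MEC(top)
  — distinguishes narrow from wide leaf extent at controlled height;
* plant aerial density  PAD = Plant_Tpx / Area_CH
  — pixel count over hull area, a compactness / biomass proxy.

For each imaging day the side view with the larger convex-hull area is
selected for architecture analysis (ties resolve to 0 deg). Hull area uses
the convex polygon of foreground pixel centers, so continuous-geometry
comparisons carry a discretization tolerance of about 2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError

from .errors import EmptyInputError, InvalidArgumentError


@dataclass(frozen=True)
class ShapeMetrics:
    hull_area: float
    br_height: float
    mec_diameter: float
    plant_pixels: int


def shape_metrics(mask: np.ndarray) -> ShapeMetrics:
    """Convex-hull area, bounding-rectangle height, MEC diameter, pixel count."""
    mask = np.asarray(mask, dtype=bool)
    pts_rc = np.argwhere(mask)
    if len(pts_rc) == 0:
        raise EmptyInputError("empty mask")
    plant_pixels = len(pts_rc)
    br_height = float(pts_rc[:, 0].max() - pts_rc[:, 0].min() + 1)
    pts_xy = pts_rc[:, ::-1].astype(float)
    try:
        hull = ConvexHull(pts_xy)
        hull_area = float(hull.volume)  # 2-D "volume" is the polygon area
        hull_pts = pts_xy[hull.vertices]
    except QhullError:  # collinear / degenerate point set
        hull_area = 0.0
        hull_pts = pts_xy
    mec_diameter = 2.0 * float(
        shapely.minimum_bounding_radius(shapely.MultiPoint(hull_pts))
    )
    return ShapeMetrics(hull_area, br_height, mec_diameter, plant_pixels)


def select_view(area0: float, area90: float) -> int:
    """Angle (0 or 90) of the view with the larger convex-hull area; tie -> 0."""
    if area0 < 0 or area90 < 0:
        raise InvalidArgumentError("areas must be >= 0")
    if area0 == 0 and area90 == 0:
        raise EmptyInputError("both views are empty")
    return 90 if area90 > area0 else 0


def bi_angular_chr(area0: float, area90: float) -> float:
    """Convex-hull area at 0 deg over convex-hull area at 90 deg."""
    if area90 == 0:
        raise ZeroDivisionError("convex-hull area at 90 deg is zero")
    return area0 / area90


def plant_aspect_ratio(br_height_side: float, mec_diameter_top: float) -> float:
    """Side-view bounding-rectangle height over top-view MEC diameter."""
    if mec_diameter_top == 0:
        raise ZeroDivisionError("top-view MEC diameter is zero")
    return br_height_side / mec_diameter_top


def plant_aerial_density(plant_pixels: int, hull_area: float) -> float:
    """Plant pixel count over convex-hull area."""
    if hull_area == 0:
        raise ZeroDivisionError("convex-hull area is zero")
    return plant_pixels / hull_area
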