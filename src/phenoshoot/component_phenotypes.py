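"""Per-leaf and per-stem geometric phenotypes.

Each detected leaf (the junction -> tip skeleton path) is summarized by a
least-squares polynomial fit of the dependent on the independent image
coordinate — the independent axis being the one with the greater extent
along the path, so near-vertical leaves are fitted as x(y). From the fitted
curve p and the junction-tip chord the module derives:

* leaf length — the arc-length integral of p between junction and tip;
* junction-tip distance — the Euclidean chord length;
* curvature K = |p''| / (1 + p'^2)^(3/2), reported at the leaf apex (path
  point farthest from the chord) and at the mid-leaf point (1-based index
  floor(n/2) of the n-point path);
* leaf-junction angle — the angle between the tangent at the collar and
  the chord, folded into [0, pi/2];
* integral leaf-skeleton area — |integral of (p - chord)| between the two
  abscissae, a leaf-drooping indicator.

The stem axis is the regression line through the junction coordinates with
the horizontal coordinate regressed on the vertical one, so a perfectly
vertical stem has slope 0 and stem angle phi = |atan(slope)| measures the
deviation from vertical (an early lodging signal). All angles are radians;
all lengths are pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import (
    DegenerateLeafError,
    InsufficientJunctionsError,
    InsufficientPointsError,
    UndefinedChordError,
)
from .skeleton_graph import PlantGraph, extract_stem, leaf_edges

DEFAULT_MAX_ORDER = 6

#: Path length near the collar excluded from the curve fit, in units of the
#: mask stroke half-width. Inside the stem/leaf stroke overlap the skeleton
#: shortcuts across the wedge between the two center-lines, flattening the
#: steep start of the leaf; points within this zone would bias the fit.
JUNCTION_TRIM_FACTOR = 2.5

XY = "xy"  # dependent y fitted as a function of x
YX = "yx"  # dependent x fitted as a function of y


@dataclass
class FittedCurve:
    """Polynomial fit of a leaf path in one of the two axis orientations.

    The polynomial is stored over the centered, scaled abscissa
    ``u = (x - offset) / scale`` (``u`` roughly in [-1, 1]); raw pixel
    abscissae up to several hundred would make powers beyond 4 numerically
    meaningless. Evaluation and derivatives are exposed in original
    coordinates.
    """

    coeffs: np.ndarray  # highest power first, over u
    offset: float
    scale: float
    orientation: str
    order: int
    rms_residual: float

    @property
    def poly(self) -> np.poly1d:
        """Polynomial over the internal abscissa ``u``."""
        return np.poly1d(self.coeffs)

    def _u(self, x):
        return (np.asarray(x, dtype=float) - self.offset) / self.scale

    def __call__(self, x):
        return self.poly(self._u(x))

    def deriv1(self, x):
        """d(dependent)/d(abscissa) in original coordinates."""
        return self.poly.deriv()(self._u(x)) / self.scale

    def deriv2(self, x):
        return self.poly.deriv(2)(self._u(x)) / self.scale**2


@dataclass
class LeafGeometry:
    """One leaf's skeleton path with its fitted curve.

    ``junction`` and ``tip`` are (x, y) pixel coordinates; ``path`` is the
    ordered junction -> tip point array (n, 2).
    """

    leaf_rank: int
    junction: tuple[float, float]
    tip: tuple[float, float]
    path: np.ndarray
    curve: FittedCurve = field(default=None)

    @property
    def n_points(self) -> int:
        return len(self.path)

    def indep(self, point) -> float:
        """The fit-frame abscissa of an (x, y) point."""
        return float(point[0] if self.curve.orientation == XY else point[1])

    def dep(self, point) -> float:
        return float(point[1] if self.curve.orientation == XY else point[0])


def fit_leaf_curve(
    path: np.ndarray, max_order: int = DEFAULT_MAX_ORDER, orientation: str | None = None
) -> FittedCurve:
    """Least-squares polynomial fit of a leaf path.

    The independent axis is the axis of greater extent along the path
    (override with ``orientation``); the order is
    ``min(max_order, n_points - 1, n_distinct_abscissae - 1)``.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 3:
        raise InsufficientPointsError(
            f"need >= 3 points to fit a leaf, got {len(path)}"
        )
    if orientation is None:
        ext = path.max(axis=0) - path.min(axis=0)
        orientation = XY if ext[0] >= ext[1] else YX
    if orientation == XY:
        x, w = path[:, 0], path[:, 1]
    else:
        x, w = path[:, 1], path[:, 0]
    order = max(1, min(max_order, len(path) - 1, len(np.unique(x)) - 1))
    offset = float(x.mean())
    scale = float(max(np.ptp(x) / 2.0, 1.0))
    u = (x - offset) / scale
    coeffs = np.polyfit(u, w, order)
    resid = np.poly1d(coeffs)(u) - w
    rms = float(np.sqrt(np.mean(resid**2)))
    return FittedCurve(coeffs=coeffs, offset=offset, scale=scale,
                       orientation=orientation, order=order, rms_residual=rms)


def leaf_geometry_from_record(
    record: dict,
    max_order: int = DEFAULT_MAX_ORDER,
    junction_trim: float = 0.0,
) -> LeafGeometry:
    """Build a :class:`LeafGeometry` from a :func:`~phenoshoot.skeleton_graph.leaf_edges` record.

    ``junction_trim`` excludes the first that many pixels of path arc (the
    collar mixing zone) from the curve fit; the stored path, endpoints and
    integration bounds are unaffected.
    """
    path_xy = np.array([(c, r) for (r, c) in record["path"]], dtype=float)
    geom = LeafGeometry(
        leaf_rank=record.get("leaf_rank") or 0,
        junction=tuple(path_xy[0]),
        tip=tuple(path_xy[-1]),
        path=path_xy,
    )
    fit_points = path_xy
    if junction_trim > 0 and len(path_xy) > 3:
        arc = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(path_xy, axis=0).T))]
        )
        keep = arc >= junction_trim
        if keep.sum() >= max(8, max_order + 2):
            fit_points = path_xy[keep]
    geom.curve = fit_leaf_curve(fit_points, max_order=max_order)
    return geom


def leaf_geometries(graph: PlantGraph, max_order: int = DEFAULT_MAX_ORDER) -> list[LeafGeometry]:
    """Fitted geometry for every LEAF edge of a typed plant graph.

    Uses the graph's estimated stroke half-width to discount the collar
    mixing zone from each fit.
    """
    trim = JUNCTION_TRIM_FACTOR * (graph.stroke_radius or 0.0)
    return [leaf_geometry_from_record(rec, max_order=max_order,
                                      junction_trim=trim)
            for rec in leaf_edges(graph)]


def anchor_to_stem(
    geom: LeafGeometry,
    stem_path_xy: np.ndarray,
    max_extension: float = 12.0,
    snap_distance: float = 3.0,
) -> LeafGeometry:
    """Re-anchor the leaf's junction at the fitted curve's stem crossing.

    The skeleton branch node sits a few pixels up the stem from the true
    collar (the stroke-overlap wedge shortcut), which pivots the
    junction-tip chord and biases chord-referenced phenotypes. The fitted
    curve is followed from the branch node toward the stem for up to
    ``max_extension`` px of abscissa; if it passes within ``snap_distance``
    of the stem path, the junction moves to the closest approach. Returns
    the geometry (modified in place) for chaining.
    """
    stem = np.asarray(stem_path_xy, dtype=float)
    if len(stem) == 0:
        return geom
    uj = geom.indep(geom.junction)
    ut = geom.indep(geom.tip)
    if uj == ut:
        return geom
    direction = -1.0 if ut > uj else 1.0  # away from the tip
    us = np.linspace(uj, uj + direction * max_extension, 40)
    w = geom.curve(us)
    pts = (np.column_stack([us, w]) if geom.curve.orientation == XY
           else np.column_stack([w, us]))
    from scipy.spatial import cKDTree

    d, _ = cKDTree(stem).query(pts)
    i = int(np.argmin(d))  # the curve's closest approach to the stem
    new_junction = (float(pts[i, 0]), float(pts[i, 1]))
    if d[i] <= snap_distance and math.dist(new_junction, geom.junction) <= max_extension:
        geom.junction = new_junction
    return geom


# ---------------------------------------------------------------------------
# Leaf measurements
# ---------------------------------------------------------------------------


def leaf_length(geom: LeafGeometry) -> float:
    """Arc length of the fitted curve between junction and tip abscissae."""
    a = geom.indep(geom.junction)
    b = geom.indep(geom.tip)
    if a == b:
        raise DegenerateLeafError(
            "junction and tip share the independent coordinate; "
            "the fit orientation should have flipped"
        )
    val, _ = quad(lambda x: math.hypot(1.0, geom.curve.deriv1(x)),
                  min(a, b), max(a, b), epsrel=1e-6, limit=200)
    return float(val)


def junction_tip_distance(junction, tip) -> float:
    """Straight-line distance between collar and tip."""
    return math.dist(junction, tip)


def curvature_at(curve: FittedCurve, x: float) -> float:
    """Curvature K = |p''| / (1 + p'^2)^(3/2) at abscissa ``x`` (K=0 for lines)."""
    if curve.order < 2:
        return 0.0
    d1 = curve.deriv1(x)
    d2 = curve.deriv2(x)
    return float(abs(d2) / (1.0 + d1 * d1) ** 1.5)


def radius_of_curvature(curve: FittedCurve, x: float) -> float:
    """1 / K; infinite on straight segments."""
    k = curvature_at(curve, x)
    return math.inf if k == 0 else 1.0 / k


def chord_distances(geom: LeafGeometry) -> np.ndarray:
    """|perpendicular distance| of every path point from the junction-tip chord."""
    (x1, y1), (x2, y2) = geom.junction, geom.tip
    denom = math.hypot(y2 - y1, x2 - x1)
    if denom == 0:
        raise UndefinedChordError("junction and tip coincide")
    x0 = geom.path[:, 0]
    y0 = geom.path[:, 1]
    return np.abs((y2 - y1) * x0 - (x2 - x1) * y0 + x2 * y1 - y2 * x1) / denom


@dataclass
class ApexResult:
    points: np.ndarray  # (k, 2) all points attaining the maximal distance
    distance: float
    degenerate: bool  # straight leaf: every point lies on the chord


def leaf_apex(geom: LeafGeometry, rel_tol: float = 1e-9) -> ApexResult:
    """All path points at maximal |distance| from the junction-tip chord.

    Straight leaves (all distances ~ 0) are flagged degenerate and return
    the whole path.
    """
    if geom.n_points < 3:
        raise InsufficientPointsError("need >= 3 path points for an apex")
    d = chord_distances(geom)
    dmax = float(d.max())
    if dmax <= 1e-9:
        return ApexResult(points=geom.path.copy(), distance=0.0, degenerate=True)
    at_max = d >= dmax * (1.0 - rel_tol)
    return ApexResult(points=geom.path[at_max], distance=dmax, degenerate=False)


def mid_leaf(geom: LeafGeometry) -> tuple[float, float]:
    """The point on the fitted curve at the mid-path abscissa.

    Mid-path index b = floor(n/2) (1-based, clamped to >= 1) of the n-point
    skeleton path; the returned point is evaluated on the fitted curve at
    that point's abscissa.
    """
    n = geom.n_points
    b = max(1, n // 2)
    pt = geom.path[b - 1]
    u = geom.indep(pt)
    w = float(geom.curve(u))
    return (u, w) if geom.curve.orientation == XY else (w, u)


def angle_between_slopes(m1: float, m2: float) -> float:
    """|atan((m2 - m1) / (1 + m1 m2))|, with the perpendicular case -> pi/2."""
    if math.isinf(m1) and math.isinf(m2):
        return 0.0
    if math.isinf(m1):
        return math.pi / 2 - abs(math.atan(m2))
    if math.isinf(m2):
        return math.pi / 2 - abs(math.atan(m1))
    denom = 1.0 + m1 * m2
    if denom == 0.0:
        return math.pi / 2
    return abs(math.atan((m2 - m1) / denom))


def leaf_junction_angle(geom: LeafGeometry) -> float:
    """Angle between the collar tangent of the fitted leaf and the chord."""
    (x1, y1), (x2, y2) = geom.junction, geom.tip
    if (x1, y1) == (x2, y2):
        raise UndefinedChordError("junction and tip coincide")
    du = float(geom.curve.deriv1(geom.indep(geom.junction)))
    if geom.curve.orientation == XY:
        m1 = du
    else:  # dx/dy -> dy/dx
        m1 = math.inf if du == 0 else 1.0 / du
    m2 = math.inf if x2 == x1 else (y2 - y1) / (x2 - x1)
    return angle_between_slopes(m1, m2)


def integral_leaf_skeleton_area(geom: LeafGeometry) -> float:
    """|Area| enclosed between the fitted leaf curve and the junction-tip chord.

    Computed by exact polynomial integration of p - f between the junction
    and tip abscissae, f being the chord in the fit frame.
    """
    a = geom.indep(geom.tip)
    b = geom.indep(geom.junction)
    if a == b:
        raise DegenerateLeafError("tip and junction share the abscissa")
    wa = geom.dep(geom.tip)
    wb = geom.dep(geom.junction)
    slope = (wa - wb) / (a - b)
    # work over the fit's internal abscissa u; dx = scale * du
    curve = geom.curve
    ua, ub = curve._u(a), curve._u(b)
    slope_u = slope * curve.scale
    chord_u = np.poly1d([slope_u, wb - slope_u * ub])
    anti = (curve.poly - chord_u).integ()
    return float(abs(anti(ub) - anti(ua)) * curve.scale)


def mid_leaf_curvature(geom: LeafGeometry, method: str = "analytic") -> float:
    """Curvature at the mid-leaf point.

    ``analytic`` evaluates K from the fitted polynomial at the mid-leaf
    abscissa. ``finite_difference`` is the chord-circle alternative: the
    circumcircle through the mid-leaf path point and its two neighbors
    (Menger curvature), which estimates the same quantity directly from
    pixels.
    """
    n = geom.n_points
    b = max(1, n // 2)
    if method == "analytic":
        u = geom.indep(geom.path[b - 1])
        return curvature_at(geom.curve, u)
    if method != "finite_difference":
        raise ValueError(f"unknown method {method!r}")
    if n < 3:
        raise InsufficientPointsError("finite-difference curvature needs >= 3 points")
    i = min(max(b - 1, 1), n - 2)
    p0, p1, p2 = geom.path[i - 1], geom.path[i], geom.path[i + 1]
    area2 = abs(
        (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
    )
    d01 = math.dist(p0, p1)
    d12 = math.dist(p1, p2)
    d02 = math.dist(p0, p2)
    if d01 * d12 * d02 == 0:
        return 0.0
    return 2.0 * area2 / (d01 * d12 * d02)


def apex_curvature(geom: LeafGeometry) -> float:
    """Curvature at the (first) leaf apex abscissa; 0 for straight leaves."""
    apex = leaf_apex(geom)
    if apex.degenerate:
        return 0.0
    u = geom.indep(apex.points[0])
    return curvature_at(geom.curve, u)


# ---------------------------------------------------------------------------
# Stem measurements
# ---------------------------------------------------------------------------


def stem_angle(junctions) -> float:
    """Deviation of the stem axis from vertical, in radians.

    The stem axis is the least-squares line through the junction (x, y)
    coordinates with x regressed on y, so phi = 0 means perfectly vertical.
    """
    pts = np.asarray(junctions, dtype=float)
    if len(pts) < 2:
        raise InsufficientJunctionsError(
            f"stem angle needs >= 2 junctions, got {len(pts)}"
        )
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) == 0:
        return math.pi / 2
    slope = np.polyfit(y, x, 1)[0]
    return float(abs(math.atan(slope)))


@dataclass
class StemGeometry:
    junctions: list[tuple[float, float]]
    stem_angle: float | None
    stem_height: float
    inter_junction_distances: list[float]


def measure_stem(graph: PlantGraph) -> StemGeometry:
    """Stem record from a typed plant graph: junctions bottom-up, angle, height."""
    junctions_rc, path = extract_stem(graph)
    junctions = [(c, r) for (r, c) in junctions_rc]
    angle = stem_angle(junctions) if len(junctions) >= 2 else None
    rows = [r for (r, c) in path]
    height = float(max(rows) - min(rows)) if path else 0.0
    dists = [math.dist(a, b) for a, b in zip(junctions, junctions[1:])]
    return StemGeometry(junctions, angle, height, dists)


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------


def measure_leaf(geom: LeafGeometry) -> dict:
    """All six component phenotypes of one leaf, as a flat record."""
    apex = leaf_apex(geom)
    return {
        "leaf_rank": geom.leaf_rank,
        "leaf_length": leaf_length(geom),
        "junction_tip_distance": junction_tip_distance(geom.junction, geom.tip),
        "apex_curvature": apex_curvature(geom),
        "mid_leaf_curvature": mid_leaf_curvature(geom),
        "leaf_junction_angle": leaf_junction_angle(geom),
        "integral_area": integral_leaf_skeleton_area(geom),
        "apex_points": [tuple(map(float, p)) for p in apex.points],
        "fit_rms_residual": geom.curve.rms_residual,
        "junction_x": geom.junction[0],
        "junction_y": geom.junction[1],
        "tip_x": geom.tip[0],
        "tip_y": geom.tip[1],
    }


def measure_plant(
    graph: PlantGraph, max_order: int = DEFAULT_MAX_ORDER
) -> tuple[list[dict], StemGeometry]:
    """Component records for every leaf plus the stem geometry.

    Each leaf's junction is re-anchored to the stem path before chord-based
    phenotypes are computed (see :func:`anchor_to_stem`).
    """
    _, stem_path = extract_stem(graph)
    stem_xy = np.array([(c, r) for (r, c) in stem_path], dtype=float)
    leaves = []
    for geom in leaf_geometries(graph, max_order=max_order):
        try:
            anchor_to_stem(geom, stem_xy)
            leaves.append(measure_leaf(geom))
        except (DegenerateLeafError, UndefinedChordError):
            continue  # unmeasurable degenerate leaf; counted but not measured
    return leaves, measure_stem(graph)
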