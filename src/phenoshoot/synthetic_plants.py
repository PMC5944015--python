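"""Deterministic generator of maize-like plant image sequences with exact truth.

The generator emulates the data a side-view greenhouse imaging chamber
produces during the vegetative stage of maize: one plant per frame on a
fixed homogeneous background, a near-vertical stem, and leaves that emerge
sequentially at junctions (collars) on alternating sides of the stem and
elongate daily until reaching their mature length.

Every leaf center-line is a quadratic Bezier curve anchored at its junction,
so each rendered leaf carries closed-form truth values that downstream
measurements can be scored against:

* arc length — the curve is scaled so its arc length equals the scheduled
  leaf length exactly;
* junction-tip chord — Euclidean distance between the Bezier endpoints;
* enclosed area between curve and chord — ``2/3`` of the area of the
  control triangle (a classical property of quadratic Beziers).

Rendering is a disk dilation of the 1-px center-line (default stroke 5 px)
with the plant colored inside the segmentation module's default HSV plant
band and the background outside it.

A biological note on the stem top: the visible "stem" of young maize is the
rolled pseudostem, whose top is where the newest leaf diverges. The stem is
therefore rendered exactly up to the topmost emerged junction; it elongates
as leaves emerge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree
from skimage.color import hsv2rgb
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .errors import InvalidArgumentError
from .gt_eval import GroundTruthPlant, LeafAnnotation

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class LeafSpec:
    """Growth schedule and shape of one leaf.

    ``junction_height`` is the distance (px) along the stem from the base to
    the collar. ``arch`` (1/px) bends the leaf progressively as it elongates;
    ``droop`` (unitless, in [0, 1)) lowers the chord relative to the initial
    tangent elevation ``base_angle`` (radians above horizontal).
    """

    emergence_day: int
    side: str
    junction_height: float
    elongation_rate: float
    max_length: float
    arch: float
    droop: float
    base_angle: float = 1.0

    def __post_init__(self):
        if self.emergence_day < 1:
            raise InvalidArgumentError("emergence_day must be >= 1")
        if self.max_length <= 0:
            raise InvalidArgumentError("max_length must be > 0")
        if self.side not in (LEFT, RIGHT):
            raise InvalidArgumentError(f"side must be left/right, got {self.side!r}")
        if self.arch < 0:
            raise InvalidArgumentError("arch must be >= 0")

    def length_on(self, day: int) -> float:
        """Scheduled leaf length on ``day`` (0 before emergence)."""
        if day < self.emergence_day:
            return 0.0
        return min(self.max_length,
                   self.elongation_rate * (day - self.emergence_day + 1))


@dataclass(frozen=True)
class PlantSpec:
    """Full deterministic description of one synthetic plant."""

    plant_id: str
    leaf_specs: tuple[LeafSpec, ...]
    stem_growth_rate: float = 12.0
    image_size: tuple[int, int] = (420, 560)
    base_position: tuple[int, int] = (390, 280)
    stroke_width: int = 5
    plant_color: tuple[float, float, float] = (0.33, 0.55, 0.55)
    background_color: tuple[float, float, float] = (0.60, 0.25, 0.92)
    stem_tilt: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rows, _ = self.image_size
        if not rows * 2 // 3 <= self.base_position[0] < rows:
            raise InvalidArgumentError("base must sit in the bottom third")
        if self.stroke_width < 3:
            raise InvalidArgumentError("stroke_width must be >= 3")
        days = [l.emergence_day for l in self.leaf_specs]
        if days != sorted(days):
            raise InvalidArgumentError("leaf_specs must be sorted by emergence_day")

    @property
    def stem_direction(self) -> tuple[float, float]:
        """Unit vector (x, y-up) of the stem axis."""
        return (math.sin(self.stem_tilt), math.cos(self.stem_tilt))

    def junction_xy(self, leaf: LeafSpec) -> tuple[float, float]:
        """Collar position in local (x, y-up) coordinates relative to the base."""
        dx, dy = self.stem_direction
        return (leaf.junction_height * dx, leaf.junction_height * dy)


@dataclass(frozen=True)
class LeafTruth:
    """Closed-form per-leaf truth for one rendered day."""

    rank: int
    length: float
    chord: float
    enclosed_area: float
    collar_xy: tuple[int, int]  # image (x=col, y=row)
    tip_xy: tuple[int, int]


@dataclass
class RenderedFrame:
    """One rendered imaging day: raster, mask, and matching ground truth."""

    day: int
    rgb: np.ndarray
    mask: np.ndarray
    truth: GroundTruthPlant
    leaf_truth: list[LeafTruth]
    stem_angle_true: float


# ---------------------------------------------------------------------------
# Leaf center-line geometry (quadratic Bezier)
# ---------------------------------------------------------------------------

_CTRL_FRACTION = 0.4  # control point sits at 0.4 of the chord scale


def _bezier(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[..., None]
    return ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2)


def _bezier_arclength(p0, p1, p2) -> float:
    d0 = 2 * (p1 - p0)
    d1 = 2 * (p2 - p1)

    def speed(t):
        vx = (1 - t) * d0[0] + t * d1[0]
        vy = (1 - t) * d0[1] + t * d1[1]
        return np.hypot(vx, vy)

    val, _ = quad(speed, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10)
    return val


def leaf_control_points(leaf: LeafSpec, length: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bezier control points of a leaf of given arc ``length``.

    In the leaf's local frame: origin at the collar, x toward the leaf side,
    y up. The chord elevation decreases with ``droop`` and with accumulated
    ``arch * length`` so older (longer) leaves bow outward and down.
    """
    s = 1.0 if leaf.side == RIGHT else -1.0
    th0 = leaf.base_angle
    thc = th0 * (1.0 - leaf.droop) - leaf.arch * length
    thc = max(thc, -0.35)  # keep the tip from folding under the blade
    u0 = np.array([s * math.cos(th0), math.sin(th0)])
    chord_dir = np.array([s * math.cos(thc), math.sin(thc)])
    p0 = np.zeros(2)
    p1u = _CTRL_FRACTION * u0
    p2u = chord_dir
    unit_len = _bezier_arclength(p0, p1u, p2u)
    c = length / unit_len
    return p0, c * p1u, c * p2u


def leaf_polyline(leaf: LeafSpec, length: float, n: int = 200) -> np.ndarray:
    """Sampled center-line (local x, y-up), collar to tip."""
    p0, p1, p2 = leaf_control_points(leaf, length)
    return _bezier(p0, p1, p2, np.linspace(0.0, 1.0, n))


def leaf_truth_values(leaf: LeafSpec, length: float) -> tuple[float, float, float]:
    """(arc length, chord length, enclosed area) in closed form."""
    p0, p1, p2 = leaf_control_points(leaf, length)
    chord = float(np.hypot(*(p2 - p0)))
    tri = 0.5 * abs(
        (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
    )
    return length, chord, (2.0 / 3.0) * tri


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _hsv_to_uint8(hsv: tuple[float, float, float]) -> np.ndarray:
    rgb = hsv2rgb(np.asarray(hsv, dtype=float).reshape(1, 1, 3))[0, 0]
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)


def _to_raster(points_xy: np.ndarray, base_rc: tuple[int, int]) -> np.ndarray:
    """Local (x, y-up) points -> integer raster (row, col)."""
    rows = np.round(base_rc[0] - points_xy[:, 1]).astype(int)
    cols = np.round(base_rc[1] + points_xy[:, 0]).astype(int)
    return np.stack([rows, cols], axis=1)


def _draw_polyline(canvas: np.ndarray, pts_rc: np.ndarray) -> None:
    nrow, ncol = canvas.shape
    for (r0, c0), (r1, c1) in zip(pts_rc[:-1], pts_rc[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
        canvas[rr[keep], cc[keep]] = True


def _emerged(spec: PlantSpec, day: int) -> list[tuple[int, LeafSpec]]:
    return [(i + 1, l) for i, l in enumerate(spec.leaf_specs)
            if l.emergence_day <= day]


def stem_height_on(spec: PlantSpec, day: int) -> float:
    """Visible stem length on ``day``: up to the topmost emerged junction."""
    emerged = _emerged(spec, day)
    if emerged:
        return max(l.junction_height for _, l in emerged)
    return min(spec.stem_growth_rate * day, 0.75 * spec.image_size[0])


def render_centerline(spec: PlantSpec, day: int) -> np.ndarray:
    """1-px-wide boolean center-line raster for ``day``."""
    canvas = np.zeros(spec.image_size, dtype=bool)
    base = spec.base_position
    dx, dy = spec.stem_direction
    h = stem_height_on(spec, day)
    stem_pts = np.linspace(0.0, h, max(int(h), 2))[:, None] * np.array([dx, dy])
    _draw_polyline(canvas, _to_raster(stem_pts, base))
    for _, leaf in _emerged(spec, day):
        length = leaf.length_on(day)
        jx, jy = spec.junction_xy(leaf)
        pts = leaf_polyline(leaf, length) + np.array([jx, jy])
        _draw_polyline(canvas, _to_raster(pts, base))
    return canvas


def render_background(spec: PlantSpec) -> np.ndarray:
    """Plant-free background frame (uint8 RGB)."""
    bg = _hsv_to_uint8(spec.background_color)
    out = np.empty(spec.image_size + (3,), dtype=np.uint8)
    out[:] = bg
    return out


def render_frame(spec: PlantSpec, day: int) -> RenderedFrame:
    """Render one imaging day: RGB frame, binary mask and exact ground truth."""
    if day < 1:
        raise InvalidArgumentError("day must be >= 1")
    center = render_centerline(spec, day)
    mask = dilation(center, disk(spec.stroke_width // 2))
    rgb = render_background(spec)
    rgb[mask] = _hsv_to_uint8(spec.plant_color)

    base = spec.base_position
    leaves_truth: list[LeafTruth] = []
    annotations: list[LeafAnnotation] = []
    for rank, leaf in _emerged(spec, day):
        length = leaf.length_on(day)
        jx, jy = spec.junction_xy(leaf)
        p0, p1, p2 = leaf_control_points(leaf, length)
        tip_local = p2 + np.array([jx, jy])
        collar_rc = _to_raster(np.array([[jx, jy]]), base)[0]
        tip_rc = _to_raster(tip_local[None, :], base)[0]
        arc, chord, area = leaf_truth_values(leaf, length)
        collar_xy = (int(collar_rc[1]), int(collar_rc[0]))
        tip_xy = (int(tip_rc[1]), int(tip_rc[0]))
        leaves_truth.append(LeafTruth(rank, arc, chord, area, collar_xy, tip_xy))
        annotations.append(LeafAnnotation(rank, "alive", tip_xy, collar_xy))

    truth = GroundTruthPlant(
        plant_image_id=f"{spec.plant_id}_day{day:03d}",
        base=(base[1], base[0]),
        leaves=annotations,
    )
    return RenderedFrame(day, rgb, mask, truth, leaves_truth,
                         abs(spec.stem_tilt))


def render_sequence(spec: PlantSpec, days: list[int]) -> list[RenderedFrame]:
    """Render a chronological sequence of frames."""
    if not days:
        raise InvalidArgumentError("days must be nonempty")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise InvalidArgumentError("days must be strictly increasing")
    return [render_frame(spec, d) for d in days]


def render_top_view(spec: PlantSpec, day: int) -> tuple[np.ndarray, np.ndarray]:
    """Schematic top-view frame: a filled disk of the plant's lateral spread.

    Returns ``(rgb, mask)``. The disk diameter equals twice the maximum
    horizontal extent of the plant plus the stroke width, which is what the
    minimum enclosing circle of a real top view would capture.
    """
    if day < 1:
        raise InvalidArgumentError("day must be >= 1")
    spread = spec.stroke_width / 2.0
    for _, leaf in _emerged(spec, day):
        pts = leaf_polyline(leaf, leaf.length_on(day))
        jx, _ = spec.junction_xy(leaf)
        spread = max(spread, float(np.max(np.abs(pts[:, 0] + jx))))
    mask = np.zeros(spec.image_size, dtype=bool)
    rr, cc = np.ogrid[: spec.image_size[0], : spec.image_size[1]]
    r0 = spec.image_size[0] // 2
    c0 = spec.base_position[1]
    mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= spread**2] = True
    rgb = render_background(spec)
    rgb[mask] = _hsv_to_uint8(spec.plant_color)
    return rgb, mask


# ---------------------------------------------------------------------------
# Specification sampling
# ---------------------------------------------------------------------------

#: Default parameter ranges for :func:`sample_plant_spec`. Values are the
#: generator's study conditions for a vegetative-stage maize plant imaged at
#: 420x560 px (roughly 1/16 the native chamber resolution).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "emergence_gap": (2, 3),        # days between successive leaf emergences
    "junction_spacing": (22, 30),   # px of stem between successive collars
    "first_junction": (30, 42),     # px from base to the first collar
    "elongation_rate": (15, 25),    # px/day
    "max_length": (90, 130),        # px
    "arch": (0.002, 0.006),         # 1/px
    "droop": (0.10, 0.30),
    "base_angle": (0.90, 1.20),     # rad above horizontal at the collar
    "stem_tilt": (-0.12, 0.12),     # rad from vertical, signed
}

_MIN_CLEARANCE_FACTOR = 2.2  # min center-line separation, in stroke widths


def _leaf_clearance_ok(spec: PlantSpec) -> bool:
    """True when leaf center-lines keep clear of each other away from the stem."""
    margin = _MIN_CLEARANCE_FACTOR * spec.stroke_width
    stem_d = np.array(spec.stem_direction)
    clouds = []
    for _, leaf in _emerged(spec, 10**6):
        j = np.array(spec.junction_xy(leaf))
        pts = [leaf_polyline(leaf, frac * leaf.max_length, n=80) + j
               for frac in (0.4, 0.7, 1.0)]
        pts = np.vstack(pts)
        # ignore the sheath region near the stem axis
        along = pts @ stem_d
        perp = pts - along[:, None] * stem_d
        far = np.hypot(perp[:, 0], perp[:, 1]) > 2.5 * spec.stroke_width
        clouds.append(pts[far])
    for i in range(len(clouds)):
        if len(clouds[i]) == 0:
            continue
        tree = cKDTree(clouds[i])
        for k in range(i + 1, len(clouds)):
            if len(clouds[k]) == 0:
                continue
            d, _ = tree.query(clouds[k], k=1)
            if float(np.min(d)) < margin:
                return False
    return True


def _in_bounds(spec: PlantSpec) -> bool:
    rows, cols = spec.image_size
    for _, leaf in _emerged(spec, 10**6):
        j = np.array(spec.junction_xy(leaf))
        pts = leaf_polyline(leaf, leaf.max_length, n=80) + j
        rc = _to_raster(pts, spec.base_position)
        if (rc[:, 0] < 12).any() or (rc[:, 0] >= rows - 4).any():
            return False
        if (rc[:, 1] < 12).any() or (rc[:, 1] >= cols - 12).any():
            return False
    return True


def _clamp_arch(leaf: LeafSpec) -> LeafSpec:
    """Reduce arch until the tip tangent stays above horizontal-ish."""
    arch = leaf.arch
    for _ in range(20):
        cand = replace(leaf, arch=arch)
        p0, p1, p2 = leaf_control_points(cand, cand.max_length)
        tangent = p2 - p1
        elev = math.atan2(tangent[1], abs(tangent[0]))
        if elev >= 0.05:
            return cand
        arch *= 0.8
    return replace(leaf, arch=0.0)


def sample_plant_spec(
    seed: int,
    n_leaves: int = 6,
    ranges: dict[str, tuple[float, float]] | None = None,
    plant_id: str | None = None,
    alternate_sides: bool = True,
    max_attempts: int = 60,
) -> PlantSpec:
    """Draw a reproducible no-crossover plant specification.

    Rejection-samples until leaf center-lines are pairwise clear of each
    other (except at the stem) and the mature plant fits in the frame.
    """
    if n_leaves < 0:
        raise InvalidArgumentError("n_leaves must be >= 0")
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if hi < lo:
            raise InvalidArgumentError(f"degenerate range for {key!r}")
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5EED])
    for attempt in range(max_attempts):
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        leaves = []
        day = 1
        height = rng.uniform(*r["first_junction"])
        first_side = LEFT if rng.random() < 0.5 else RIGHT
        for i in range(n_leaves):
            if alternate_sides:
                side = first_side if i % 2 == 0 else (RIGHT if first_side == LEFT else LEFT)
            else:
                side = LEFT if rng.random() < 0.5 else RIGHT
            leaf = LeafSpec(
                emergence_day=day,
                side=side,
                junction_height=height,
                elongation_rate=rng.uniform(*r["elongation_rate"]),
                max_length=rng.uniform(*r["max_length"]),
                arch=rng.uniform(*r["arch"]),
                droop=rng.uniform(*r["droop"]),
                base_angle=rng.uniform(*r["base_angle"]),
            )
            leaves.append(_clamp_arch(leaf))
            gap_lo, gap_hi = r["emergence_gap"]
            day += int(rng.integers(int(gap_lo), int(gap_hi) + 1))
            height += rng.uniform(*r["junction_spacing"])
        spec = PlantSpec(
            plant_id=plant_id or f"synthetic_{seed:06d}",
            leaf_specs=tuple(leaves),
            stem_tilt=rng.uniform(*r["stem_tilt"]),
            seed=seed,
        )
        if n_leaves == 0 or (_leaf_clearance_ok(spec) and _in_bounds(spec)):
            return spec
    raise InvalidArgumentError(
        f"could not sample a no-crossover spec in {max_attempts} attempts"
    )


def make_crossover_spec(seed: int = 0) -> PlantSpec:
    """A plant whose two upper same-side leaves cross, forming a skeleton cycle.

    Exercises the documented failure mode: crossing blades create a cycle in
    the skeleton graph, which architecture classification refuses.
    """
    leaves = (
        LeafSpec(1, RIGHT, 60.0, 20.0, 120.0, 0.0, 0.15, base_angle=0.25),
        LeafSpec(3, LEFT, 95.0, 20.0, 110.0, 0.002, 0.2, base_angle=1.0),
        # steep lower leaf crossing the flat first leaf on the same side
        LeafSpec(5, RIGHT, 35.0, 20.0, 130.0, 0.0, 0.0, base_angle=0.9),
    )
    # third leaf rises steeply from below leaf 1's collar and crosses it:
    # leaf 1 spans y ~= 60+ at x in (0, 115); leaf 3 starts at y=35 and
    # climbs through that band.
    return PlantSpec(plant_id=f"crossover_{seed:06d}", leaf_specs=tuple(
        sorted(leaves, key=lambda l: l.emergence_day)), seed=seed)
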