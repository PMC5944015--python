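"""Ground-truth I/O and leaf-detection accuracy.

Reads and writes UNL-CPPD-dialect ground-truth XML (one document per plant
image: plant id, base pixel, and per-leaf id / status / tip / collar), and
scores a detected plant graph against it with the plant-level accuracy

    accuracy = mean_i ( (N_d,i - N_f,i) / N_G,i )

where, per image i, ``N_d`` is the number of detected leaves, ``N_f`` the
number of wrongly detected leaves and ``N_G`` the number of ground-truth
leaves. Coordinates are image pixels, ``(x, y) = (column, row)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from lxml import etree

from .errors import SchemaError, UndefinedFrameError

VALID_STATUSES = ("alive", "dead", "missing")

#: Statuses whose tips take part in coordinate matching. ``missing`` leaves
#: are not visible in the image, so they are excluded from the matchable set
#: and from N_G.
MATCHABLE_STATUSES = ("alive", "dead")


@dataclass
class LeafAnnotation:
    """One annotated leaf: emergence-order id, status, tip and collar pixels."""

    leaf_id: int
    status: str
    tip: tuple[int, int]
    collar: tuple[int, int]

    def __post_init__(self) -> None:
        if self.leaf_id < 1:
            raise SchemaError(f"leaf id must be >= 1, got {self.leaf_id}")
        if self.status not in VALID_STATUSES:
            raise SchemaError(
                f"leaf status {self.status!r} not in {VALID_STATUSES}"
            )


@dataclass
class GroundTruthPlant:
    """Ground truth for one plant image."""

    plant_image_id: str
    base: tuple[int, int]
    leaves: list[LeafAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [leaf.leaf_id for leaf in self.leaves]
        if len(ids) != len(set(ids)):
            raise SchemaError(f"duplicate leaf ids in {self.plant_image_id!r}")

    @property
    def n_visible(self) -> int:
        """Number of leaves visible in the image (alive or dead)."""
        return sum(1 for l in self.leaves if l.status in MATCHABLE_STATUSES)


# ---------------------------------------------------------------------------
# XML round trip
# ---------------------------------------------------------------------------


def _read_point(parent: etree._Element, name: str) -> tuple[int, int]:
    el = parent.find(name)
    if el is None:
        raise SchemaError(f"missing element <{name}> under <{parent.tag}>")
    try:
        x = int(el.findtext("x"))
        y = int(el.findtext("y"))
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"malformed coordinates in <{name}>: {exc}") from exc
    return (x, y)


def read_gt_xml(source) -> GroundTruthPlant:
    """Parse a ground-truth document.

    ``source`` may be a path, an open file, or a ``bytes``/``str`` document.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    elif isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source)).getroot()
    if root.tag != "plant":
        raise SchemaError(f"root element must be <plant>, got <{root.tag}>")
    plant_id = root.findtext("id")
    if plant_id is None:
        raise SchemaError("missing element <id> under <plant>")
    base = _read_point(root, "base")
    leaves = []
    for leaf_el in root.findall("leaf"):
        try:
            leaf_id = int(leaf_el.findtext("id"))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"malformed <id> in <leaf>: {exc}") from exc
        status = leaf_el.findtext("status")
        if status not in VALID_STATUSES:
            raise SchemaError(
                f"leaf status {status!r} not in {VALID_STATUSES}"
            )
        tip = _read_point(leaf_el, "tip")
        collar = _read_point(leaf_el, "collar")
        leaves.append(LeafAnnotation(leaf_id, status, tip, collar))
    return GroundTruthPlant(plant_id, base, leaves)


def _point_el(parent: etree._Element, name: str, pt: tuple[int, int]) -> None:
    el = etree.SubElement(parent, name)
    etree.SubElement(el, "x").text = str(int(round(pt[0])))
    etree.SubElement(el, "y").text = str(int(round(pt[1])))


def write_gt_xml(gt: GroundTruthPlant, path=None) -> bytes:
    """Serialize a :class:`GroundTruthPlant`; returns the XML bytes.

    Leaf order (emergence order) is preserved; coordinates are written as
    integer pixel locations, so ``read_gt_xml(write_gt_xml(gt)) == gt`` for
    integer-coordinate records.
    """
    root = etree.Element("plant")
    etree.SubElement(root, "id").text = gt.plant_image_id
    _point_el(root, "base", gt.base)
    for leaf in gt.leaves:
        leaf_el = etree.SubElement(root, "leaf")
        etree.SubElement(leaf_el, "id").text = str(leaf.leaf_id)
        etree.SubElement(leaf_el, "status").text = leaf.status
        _point_el(leaf_el, "tip", leaf.tip)
        _point_el(leaf_el, "collar", leaf.collar)
    doc = etree.tostring(root, pretty_print=True, xml_declaration=True,
                         encoding="UTF-8")
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(doc)
    return doc


# ---------------------------------------------------------------------------
# Detection matching and accuracy
# ---------------------------------------------------------------------------


def match_tips(
    detected_tips: Sequence[tuple[float, float]],
    gt: GroundTruthPlant,
    radius: float = 15.0,
) -> tuple[int, int, list[tuple[int, int]]]:
    """One-to-one nearest-tip assignment of detections to ground truth.

    Solved as an optimal assignment (Hungarian algorithm) over tip
    distances, with pairs beyond ``radius`` inadmissible — this maximizes
    the number of matches and, among maximum matchings, minimizes total tip
    distance, so it agrees with brute-force enumeration on small instances.
    Returns ``(N_d, N_f, pairs)`` where ``pairs`` holds
    ``(detected_index, leaf_id)``; unmatched detections count toward ``N_f``.
    """
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    gt_leaves = [l for l in gt.leaves if l.status in MATCHABLE_STATUSES]
    n_d = len(detected_tips)
    if n_d == 0 or not gt_leaves:
        return n_d, n_d, []
    big = 1e9
    cost = np.full((n_d, len(gt_leaves)), big)
    for i, (dx, dy) in enumerate(detected_tips):
        for j, leaf in enumerate(gt_leaves):
            d = math.hypot(dx - leaf.tip[0], dy - leaf.tip[1])
            if d <= radius:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), gt_leaves[j].leaf_id)
        for i, j in zip(rows, cols)
        if cost[i, j] < big
    ]
    pairs.sort()
    return n_d, n_d - len(pairs), pairs


def match_leaves(graph, gt: GroundTruthPlant, radius: float = 15.0):
    """:func:`match_tips` applied to the LEAF-edge tips of a typed plant graph."""
    from .skeleton_graph import leaf_tips  # local import: avoid cycle

    tips = [(c, r) for (r, c) in leaf_tips(graph)]
    return match_tips(tips, gt, radius=radius)


def plant_level_accuracy(
    per_image: Iterable[tuple[int, int, int]],
    exclude_empty: bool = False,
) -> float:
    """Mean over images of ``(N_d - N_f) / N_G``.

    ``per_image`` is a sequence of ``(N_d, N_f, N_G)`` triples. A frame with
    ``N_G == 0`` makes the ratio undefined and raises
    :class:`UndefinedFrameError` unless ``exclude_empty`` is set, in which
    case the frame is dropped.
    """
    ratios = []
    for n_d, n_f, n_g in per_image:
        if n_g == 0:
            if exclude_empty:
                continue
            raise UndefinedFrameError(
                "frame with zero ground-truth leaves; pass exclude_empty=True "
                "to drop it"
            )
        ratios.append((n_d - n_f) / n_g)
    if not ratios:
        raise UndefinedFrameError("no frames with ground truth")
    return sum(ratios) / len(ratios)


def aggregate_accuracy(per_image: Iterable[tuple[int, int, int]]) -> float:
    """Sequence-aggregate ratio ``(sum N_d - sum N_f) / sum N_G``."""
    n_d = n_f = n_g = 0
    for d, f, g in per_image:
        n_d += d
        n_f += f
        n_g += g
    if n_g == 0:
        raise UndefinedFrameError("sequence has zero ground-truth leaves")
    return (n_d - n_f) / n_g


# ---------------------------------------------------------------------------
# Published UNL-CPPD benchmark counts
# ---------------------------------------------------------------------------

#: Published per-sequence leaf-detection results on the UNL-CPPD benchmark
#: (13 maize plant sequences, two dataset versions: CPPD-I = first 27 days,
#: no crossovers; CPPD-II = 32 days including crossovers). Columns:
#: sequence, dataset, n_leaves (summed ground truth over the sequence),
#: detected, false, accuracy (the published per-sequence plant-level value).
UNL_CPPD_BENCHMARK = pd.DataFrame(
    [
        ("Plant_001-9", "CPPD-I", 116, 93, 1, 0.79),
        ("Plant_001-9", "CPPD-II", 168, 157, 5, 0.83),
        ("Plant_006-25", "CPPD-I", 138, 136, 0, 0.98),
        ("Plant_006-25", "CPPD-II", 205, 188, 5, 0.91),
        ("Plant_008-19", "CPPD-I", 142, 140, 0, 0.98),
        ("Plant_008-19", "CPPD-II", 210, 200, 9, 0.86),
        ("Plant_016-20", "CPPD-I", 103, 86, 0, 0.83),
        ("Plant_016-20", "CPPD-II", 141, 129, 0, 0.88),
        ("Plant_023-1", "CPPD-I", 113, 101, 0, 0.89),
        ("Plant_023-1", "CPPD-II", 154, 135, 8, 0.83),
        ("Plant_045-1", "CPPD-I", 122, 120, 3, 0.96),
        ("Plant_045-1", "CPPD-II", 177, 170, 6, 0.93),
        ("Plant_047-25", "CPPD-I", 148, 142, 2, 0.94),
        ("Plant_047-25", "CPPD-II", 212, 196, 5, 0.88),
        ("Plant_063-32", "CPPD-I", 149, 138, 0, 0.93),
        ("Plant_063-32", "CPPD-II", 214, 174, 18, 0.72),
        ("Plant_070-11", "CPPD-I", 125, 111, 0, 0.89),
        ("Plant_070-11", "CPPD-II", 177, 148, 5, 0.83),
        ("Plant_071-8", "CPPD-I", 141, 131, 0, 0.93),
        ("Plant_071-8", "CPPD-II", 199, 163, 7, 0.77),
        ("Plant_076-24", "CPPD-I", 135, 126, 2, 0.92),
        ("Plant_076-24", "CPPD-II", 191, 152, 2, 0.78),
        ("Plant_104-24", "CPPD-I", 144, 140, 0, 0.97),
        ("Plant_104-24", "CPPD-II", 186, 185, 0, 0.96),
        ("Plant_191-28", "CPPD-I", 137, 111, 0, 0.96),
        ("Plant_191-28", "CPPD-II", 178, 151, 7, 0.81),
    ],
    columns=["sequence", "dataset", "n_leaves", "detected", "false", "accuracy"],
)


def benchmark_mean_accuracy(dataset: str) -> float:
    """Mean of the published per-sequence accuracies for one dataset version."""
    sub = UNL_CPPD_BENCHMARK[UNL_CPPD_BENCHMARK["dataset"] == dataset]
    if sub.empty:
        raise KeyError(f"unknown dataset {dataset!r}")
    return float(sub["accuracy"].mean())


def benchmark_aggregate_accuracy(sequence: str, dataset: str) -> float:
    """``(detected - false) / n_leaves`` from the published aggregate counts."""
    sub = UNL_CPPD_BENCHMARK[
        (UNL_CPPD_BENCHMARK["sequence"] == sequence)
        & (UNL_CPPD_BENCHMARK["dataset"] == dataset)
    ]
    if sub.empty:
        raise KeyError(f"unknown benchmark row ({sequence!r}, {dataset!r})")
    row = sub.iloc[0]
    return float((row["detected"] - row["false"]) / row["n_leaves"])
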