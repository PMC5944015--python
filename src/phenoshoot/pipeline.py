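"""Sequence-level orchestration: simulate, segment, detect, measure, evaluate.

The on-disk dataset layout mirrors a greenhouse imaging campaign: a manifest
CSV with one row per (plant, day, view) pointing at the frame, the
plant-free background, an optional top-view frame and optional ground-truth
XML. :func:`run_sequence` consumes a manifest and writes per-sequence CSVs
(holistic, component, stem, accuracy) plus a frame-level log;
:func:`simulate` writes a complete synthetic dataset the pipeline can be
run on end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import gt_eval, holistic_phenotypes as hol, segmentation as seg
from . import component_phenotypes as comp
from . import skeleton_graph as sg
from . import synthetic_plants as synth
from .errors import EmptyInputError, PhenoshootError, UnsupportedTopologyError

logger = logging.getLogger("phenoshoot")

MANIFEST_COLUMNS = ["plant_id", "day", "view", "image", "background", "top", "gt"]


@dataclass
class RunConfig:
    manifest: Path
    out_dir: Path
    segmentation: seg.SegmentationConfig = field(default_factory=seg.SegmentationConfig)
    spur_threshold: float = sg.DEFAULT_SPUR_THRESHOLD
    match_radius: float = 15.0
    max_poly_order: int = comp.DEFAULT_MAX_ORDER
    seed: int = 0
    write_overlays: bool = False

    def __post_init__(self):
        if self.spur_threshold < 0:
            raise PhenoshootError("spur threshold must be >= 0")


def overlay_png(mask: np.ndarray, graph: sg.PlantGraph) -> np.ndarray:
    """Annotated overlay: mask in gray, each leaf path in a distinct color."""
    palette = np.array(
        [
            [228, 26, 28], [55, 126, 184], [77, 175, 74], [152, 78, 163],
            [255, 127, 0], [166, 86, 40], [247, 129, 191], [153, 153, 153],
            [255, 255, 51], [0, 206, 209],
        ],
        dtype=np.uint8,
    )
    out = np.zeros(mask.shape + (3,), dtype=np.uint8)
    out[np.asarray(mask, dtype=bool)] = (90, 90, 90)
    for i, rec in enumerate(sg.leaf_edges(graph)):
        color = palette[i % len(palette)]
        for r, c in rec["path"]:
            out[r, c] = color
    _, stem_path = sg.extract_stem(graph)
    for r, c in stem_path:
        out[r, c] = (255, 255, 255)
    return out


def _analyze_frame(image_path, background_path, config: RunConfig):
    image = iio.imread(image_path)
    background = iio.imread(background_path)
    mask = seg.segment(image, background, config.segmentation)
    if not mask.any():
        raise EmptyInputError("segmentation produced an empty mask")
    metrics = hol.shape_metrics(mask)
    return mask, metrics


def run_sequence(config: RunConfig) -> dict:
    """Run the full pipeline over a manifest; returns the output bundle paths.

    Per day the side view with the larger convex-hull area is analyzed for
    architecture. Frames that fail (unreadable, empty mask, cyclic skeleton
    from leaf crossover) are logged and skipped; the run fails only if every
    frame fails.
    """
    manifest = pd.read_csv(config.manifest)
    if manifest.empty:
        raise EmptyInputError("empty manifest")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "overlays").mkdir(exist_ok=True)

    holistic_rows, component_rows, stem_rows, accuracy_rows, log_rows = (
        [], [], [], [], []
    )
    graphs_by_plant: dict[str, list[tuple[int, sg.PlantGraph]]] = {}
    n_failed = 0
    n_frames = 0

    for (plant_id, day), group in manifest.groupby(["plant_id", "day"], sort=True):
        views = {}
        for _, row in group.iterrows():
            n_frames += 1
            try:
                mask, metrics = _analyze_frame(row["image"], row["background"],
                                               config)
                views[row["view"]] = (row, mask, metrics)
            except (OSError, PhenoshootError) as exc:
                n_failed += 1
                log_rows.append({"plant_id": plant_id, "day": day,
                                 "view": row["view"], "status": f"error: {exc}",
                                 "n_leaves": np.nan})
        if not views:
            continue
        area = {v: m.hull_area for v, (_, _, m) in views.items()}
        if {0, 90} <= set(area):
            selected = hol.select_view(area[0], area[90])
        else:
            selected = next(iter(views))
        row, mask, metrics = views[selected]

        rec = {
            "plant_id": plant_id,
            "day": day,
            "selected_view": selected,
            "cv_area0": area.get(0, np.nan),
            "cv_area90": area.get(90, np.nan),
            "ba_chr": np.nan,
            "par": np.nan,
            "pad": hol.plant_aerial_density(metrics.plant_pixels,
                                            metrics.hull_area)
            if metrics.hull_area > 0 else np.nan,
        }
        if {0, 90} <= set(area) and area[90] > 0:
            rec["ba_chr"] = hol.bi_angular_chr(area[0], area[90])
        top_path = row.get("top")
        if isinstance(top_path, str) and top_path:
            top_mask = seg.segment(iio.imread(top_path),
                                   iio.imread(row["background"]),
                                   config.segmentation)
            if top_mask.any():
                top_metrics = hol.shape_metrics(top_mask)
                if top_metrics.mec_diameter > 0:
                    rec["par"] = hol.plant_aspect_ratio(
                        metrics.br_height, top_metrics.mec_diameter)
        holistic_rows.append(rec)

        try:
            graph = sg.mask_to_graph(mask, spur_threshold=config.spur_threshold)
        except UnsupportedTopologyError as exc:
            n_failed += 1
            log_rows.append({"plant_id": plant_id, "day": day,
                             "view": selected, "status": f"unanalyzable: {exc}",
                             "n_leaves": np.nan})
            continue
        graphs_by_plant.setdefault(plant_id, []).append((day, graph))
        leaves, stem = comp.measure_plant(graph, max_order=config.max_poly_order)
        for leaf in leaves:
            leaf.pop("apex_points", None)
            component_rows.append({"plant_id": plant_id, "day": day, **leaf})
        stem_rows.append(
            {
                "plant_id": plant_id,
                "day": day,
                "n_junctions": len(stem.junctions),
                "stem_angle": stem.stem_angle,
                "stem_height": stem.stem_height,
            }
        )
        n_leaves = sg.count_leaves(graph)
        log_rows.append({"plant_id": plant_id, "day": day, "view": selected,
                         "status": "ok", "n_leaves": n_leaves})
        if config.write_overlays:
            iio.imwrite(out_dir / "overlays" / f"{plant_id}_day{day:03d}.png",
                        overlay_png(mask, graph))

        gt_path = row.get("gt")
        if isinstance(gt_path, str) and gt_path:
            gt = gt_eval.read_gt_xml(gt_path)
            n_d, n_f, _ = gt_eval.match_leaves(graph, gt,
                                               radius=config.match_radius)
            accuracy_rows.append({"plant_id": plant_id, "day": day,
                                  "n_detected": n_d, "n_false": n_f,
                                  "n_ground_truth": gt.n_visible})

    if n_frames and n_failed == n_frames:
        raise PhenoshootError("all frames failed")

    outputs = {}
    frames = {
        "holistic": pd.DataFrame(holistic_rows),
        "components": pd.DataFrame(component_rows),
        "stem": pd.DataFrame(stem_rows),
        "log": pd.DataFrame(log_rows),
    }
    if accuracy_rows:
        acc = pd.DataFrame(accuracy_rows)
        per_plant = []
        for plant_id, sub in acc.groupby("plant_id"):
            triples = list(
                zip(sub["n_detected"], sub["n_false"], sub["n_ground_truth"])
            )
            triples_ok = [t for t in triples if t[2] > 0]
            per_plant.append(
                {
                    "plant_id": plant_id,
                    "n_images": len(triples_ok),
                    "n_leaves": int(sub["n_ground_truth"].sum()),
                    "detected": int(sub["n_detected"].sum()),
                    "false": int(sub["n_false"].sum()),
                    "accuracy": gt_eval.plant_level_accuracy(
                        triples, exclude_empty=True),
                    "aggregate_accuracy": gt_eval.aggregate_accuracy(triples_ok),
                }
            )
        frames["accuracy"] = acc
        frames["accuracy_summary"] = pd.DataFrame(per_plant)
    for name, df in frames.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        outputs[name] = path
    outputs["graphs_by_plant"] = graphs_by_plant
    outputs["n_frames"] = n_frames
    outputs["n_failed"] = n_failed
    return outputs


# ---------------------------------------------------------------------------
# Synthetic dataset on disk
# ---------------------------------------------------------------------------


def simulate(
    seed: int,
    n_plants: int,
    n_days: int,
    out_dir,
    n_leaves: int = 6,
    views: tuple[int, ...] = (0, 90),
    with_top: bool = True,
) -> Path:
    """Write a synthetic dataset (frames, backgrounds, GT XML, manifest CSV).

    The two side views are rendered as independent draws of the same growth
    schedule (no 3-D consistency is attempted). Deterministic under
    ``seed``; returns the manifest path.
    """
    if n_plants < 1 or n_days < 1:
        raise PhenoshootError("n_plants and n_days must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed & 0x7FFFFFFF)
    plant_seeds = [int(s) & 0x7FFFFFFF
                   for s in ss.generate_state(2 * n_plants)]
    manifest_rows = []
    days = list(range(1, n_days + 1))
    for p in range(n_plants):
        plant_id = f"plant_{p + 1:03d}"
        for vi, view in enumerate(views):
            spec = synth.sample_plant_spec(
                plant_seeds[2 * p + vi], n_leaves=n_leaves,
                plant_id=plant_id)
            bg_path = out_dir / f"{plant_id}_v{view}_background.png"
            iio.imwrite(bg_path, synth.render_background(spec))
            for frame in synth.render_sequence(spec, days):
                stem_name = f"{plant_id}_v{view}_day{frame.day:03d}"
                img_path = out_dir / f"{stem_name}.png"
                gt_path = out_dir / f"{stem_name}.xml"
                iio.imwrite(img_path, frame.rgb)
                gt_eval.write_gt_xml(frame.truth, gt_path)
                top_path = ""
                if with_top and view == views[0]:
                    rgb_top, _ = synth.render_top_view(spec, frame.day)
                    top_path = out_dir / f"{stem_name}_top.png"
                    iio.imwrite(top_path, rgb_top)
                manifest_rows.append(
                    {
                        "plant_id": plant_id,
                        "day": frame.day,
                        "view": view,
                        "image": str(img_path),
                        "background": str(bg_path),
                        "top": str(top_path),
                        "gt": str(gt_path),
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False)
    return manifest
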