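"""End-to-end validation suites on synthetic plants with known truth.

These routines regenerate their inputs from seeds at run time, push them
through the full segmentation -> skeleton-graph -> phenotype pipeline in
memory, and score the results against the generator's closed-form truth.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import component_phenotypes as comp
from . import effects_model as em
from . import gt_eval
from . import segmentation as seg
from . import skeleton_graph as sg
from . import synthetic_plants as synth
from .errors import PhenoshootError


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed & 0x7FFFFFFF)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def evaluate_architecture_suite(
    seed: int,
    n_plants: int = 50,
    n_days: int = 20,
    n_leaves: int = 6,
    match_radius: float = 15.0,
) -> dict:
    """Score leaf detection and component phenotypes on seeded plants.

    For every (plant, day) frame the RGB frame is segmented against its
    background, reduced to a typed plant graph, and compared with the
    generator's truth:

    * leaf-count agreement (detected LEAF edges vs emerged leaves);
    * per-leaf length relative error for tip-matched pairs;
    * absolute stem-angle error on frames with >= 2 detected junctions;
    * plant-level accuracy from tip matching;
    * segmentation mask IoU against the rendered truth mask.
    """
    plant_seeds = _subseeds(seed, n_plants)
    ious: list[float] = []
    length_rel_errors: list[float] = []
    stem_angle_errors: list[float] = []
    accuracy_triples: list[tuple[int, int, int]] = []
    n_agree = 0
    n_frames = 0
    n_refused = 0

    for pseed in plant_seeds:
        spec = synth.sample_plant_spec(pseed, n_leaves=n_leaves)
        background = synth.render_background(spec)
        for day in range(1, n_days + 1):
            frame = synth.render_frame(spec, day)
            n_frames += 1
            mask = seg.segment(frame.rgb, background)
            ious.append(seg.mask_iou(mask, frame.mask))
            try:
                graph = sg.mask_to_graph(mask)
            except PhenoshootError:
                n_refused += 1
                continue
            n_detected = sg.count_leaves(graph)
            n_true = len(frame.leaf_truth)
            if n_detected == n_true:
                n_agree += 1
            n_d, n_f, pairs = gt_eval.match_leaves(graph, frame.truth,
                                                   radius=match_radius)
            accuracy_triples.append((n_d, n_f, frame.truth.n_visible))

            truth_by_id = {lt.rank: lt for lt in frame.leaf_truth}
            records = sg.leaf_edges(graph)
            trim = comp.JUNCTION_TRIM_FACTOR * (graph.stroke_radius or 0.0)
            _, stem_path = sg.extract_stem(graph)
            stem_xy = np.array([(c, r) for (r, c) in stem_path], dtype=float)
            for det_i, leaf_id in pairs:
                lt = truth_by_id.get(leaf_id)
                if lt is None or lt.length <= 0:
                    continue
                try:
                    geom = comp.leaf_geometry_from_record(
                        records[det_i], junction_trim=trim)
                    comp.anchor_to_stem(geom, stem_xy)
                    est = comp.leaf_length(geom)
                except PhenoshootError:
                    continue
                length_rel_errors.append(abs(est - lt.length) / lt.length)

            stem = comp.measure_stem(graph)
            if stem.stem_angle is not None:
                stem_angle_errors.append(abs(stem.stem_angle
                                             - frame.stem_angle_true))

    result = {
        "n_frames": n_frames,
        "n_refused": n_refused,
        "count_agreement_rate": n_agree / n_frames,
        "length_median_rel_error": float(np.median(length_rel_errors))
        if length_rel_errors else float("nan"),
        "n_length_pairs": len(length_rel_errors),
        "stem_angle_mean_abs_error": float(np.mean(stem_angle_errors))
        if stem_angle_errors else float("nan"),
        "n_stem_frames": len(stem_angle_errors),
        "mean_iou": float(np.mean(ious)),
        "min_iou": float(np.min(ious)),
        "plant_level_accuracy": gt_eval.plant_level_accuracy(
            accuracy_triples, exclude_empty=True),
    }
    return result


def evaluate_effects_model(
    seed: int,
    n_replicates: int = 1000,
    sigma: float = 0.1,
    level: float = 0.95,
) -> dict:
    """Zero-noise recovery error and Monte-Carlo CI coverage of the day model.

    Coverage pools every non-reference block and genotype coefficient over
    ``n_replicates`` simulated datasets.
    """
    rng = np.random.Generator(np.random.PCG64(seed & 0x7FFFFFFF))

    table0, truth0 = em.simulate_phenotype_table(rng, sigma=0.0)
    fit0 = em.fit_day_model(table0, day=1, response="pad")
    err0 = max(
        abs(fit0.intercept - truth0["intercept"]),
        max(abs(fit0.block_effects[b] - truth0["alpha"][b])
            for b in truth0["alpha"]),
        max(abs(fit0.genotype_effects[g] - truth0["gamma"][g])
            for g in truth0["gamma"]),
    )

    covered = 0
    total = 0
    for _ in range(n_replicates):
        table, truth = em.simulate_phenotype_table(rng, sigma=sigma)
        fit = em.fit_day_model(table, day=1, response="pad")
        tcrit = stats.t.ppf(0.5 + level / 2, fit.df_resid)
        for label, true_val in truth["alpha"].items():
            if label == fit.benchmark_block:
                continue
            est = fit.block_effects[label]
            se = fit.block_se[label]
            covered += (est - tcrit * se <= true_val <= est + tcrit * se)
            total += 1
        for label, true_val in truth["gamma"].items():
            if label == fit.benchmark_genotype:
                continue
            est = fit.genotype_effects[label]
            se = fit.genotype_se[label]
            covered += (est - tcrit * se <= true_val <= est + tcrit * se)
            total += 1
    return {
        "zero_noise_max_abs_error": float(err0),
        "ci_coverage": covered / total,
        "n_intervals": total,
        "n_replicates": n_replicates,
    }


def xml_roundtrip_suite(seed: int, n_records: int = 100) -> float:
    """Fraction of random ground-truth records surviving an XML round trip."""
    rng = np.random.Generator(np.random.PCG64(seed & 0x7FFFFFFF))
    ok = 0
    for i in range(n_records):
        n_leaves = int(rng.integers(0, 12))
        leaves = [
            gt_eval.LeafAnnotation(
                leaf_id=j + 1,
                status=str(rng.choice(gt_eval.VALID_STATUSES)),
                tip=(int(rng.integers(0, 2454)), int(rng.integers(0, 2056))),
                collar=(int(rng.integers(0, 2454)), int(rng.integers(0, 2056))),
            )
            for j in range(n_leaves)
        ]
        gt = gt_eval.GroundTruthPlant(
            plant_image_id=f"roundtrip_{i:03d}",
            base=(int(rng.integers(0, 2454)), int(rng.integers(0, 2056))),
            leaves=leaves,
        )
        ok += gt_eval.read_gt_xml(gt_eval.write_gt_xml(gt)) == gt
    return ok / n_records
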