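"""Detection metrics: IoU matching, precision/recall/F1, sensitivity sweeps.

A pick is a true positive when its square box (side = particle
diameter, centered on the pick) overlaps an *unmatched* ground-truth box
with IoU >= 0.5; each ground truth can be matched only once, so repeated
detections of the same particle count as false positives, as do picks
overlapping nothing.  Unmatched truths are false negatives.  Matching is
greedy in descending pick-score order (ties by ascending pick index);
for the small fixtures in the test suite this agrees with the optimal
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    pairs: list = field(default_factory=list)  # matched (pick_idx, gt_idx)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two axis-aligned boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValueError("boxes must have positive width and height")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def center_iou(center_a, center_b, diameter: float) -> float:
    """IoU of two diameter-sized squares centered on (x, y) coordinates."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r = diameter / 2.0
    ax, ay = center_a
    bx, by = center_b
    return iou((ax - r, ay - r, ax + r, ay + r), (bx - r, by - r, bx + r, by + r))


def match_picks(pick_centers, ground_truth_centers, diameter: float,
                iou_threshold: float = 0.5,
                pick_scores=None) -> MatchResult:
    """One-to-one greedy matching of picks against ground truth.

    ``pick_scores`` orders the matching (descending, ties by index);
    without scores the original pick order is used.  Conventions:
    precision := 0 with no picks; f1 := 0 when precision + recall = 0.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    picks = np.atleast_2d(np.asarray(pick_centers, dtype=float))
    truths = np.atleast_2d(np.asarray(ground_truth_centers, dtype=float))
    if picks.size == 0:
        picks = picks.reshape(0, 2)
    if truths.size == 0:
        truths = truths.reshape(0, 2)
    n_picks, n_truth = len(picks), len(truths)
    if pick_scores is None:
        order = np.arange(n_picks)
    else:
        scores = np.asarray(pick_scores, dtype=float)
        order = np.argsort(-scores, kind="stable")  # stable: ties by pick index
    matched_truth = np.zeros(n_truth, dtype=bool)
    pairs = []
    tp = 0
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(n_truth):
            if matched_truth[j]:
                continue
            v = center_iou(picks[i], truths[j], diameter)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_truth[best_j] = True
            pairs.append((int(i), int(best_j)))
            tp += 1
    fp = n_picks - tp
    fn = n_truth - tp
    precision = tp / n_picks if n_picks else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MatchResult(tp, fp, fn, precision, recall, f1, pairs)


def summarize(results: dict) -> pd.DataFrame:
    """Per-micrograph metric table plus a pooled summary row."""
    rows = []
    for mic_id, r in results.items():
        rows.append({"micrograph_id": mic_id, "tp": r.tp, "fp": r.fp, "fn": r.fn,
                     "precision": r.precision, "recall": r.recall, "f1": r.f1})
    tp = sum(r.tp for r in results.values())
    fp = sum(r.fp for r in results.values())
    fn = sum(r.fn for r in results.values())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    rows.append({"micrograph_id": "ALL", "tp": tp, "fp": fp, "fn": fn,
                 "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows)


def evaluate_picks(pick_sets, truths, diameter: float,
                   iou_threshold: float = 0.5) -> pd.DataFrame:
    """Evaluate a list of PickSets against matching GroundTruth objects."""
    results = {}
    for ps, gt in zip(pick_sets, truths):
        results[ps.micrograph_id] = match_picks(
            ps.picked_centers, gt.centers, diameter, iou_threshold,
            pick_scores=ps.picked_scores)
    return summarize(results)


def sensitivity_sweep(bundle, axis: str, values, mae_cfg, plan, loss_cfg,
                      pick_cfg, iou_threshold: float = 0.5,
                      model=None) -> pd.DataFrame:
    """Sweep exemplar count or sliding stride on a synthetic bundle.

    ``axis='exemplars'`` retrains per value (with the first ``v``
    exemplar coordinates); ``axis='stride'`` trains once (or reuses the
    given ``model``) and only re-runs the scan.  Returns one pooled
    metric row per value.
    """
    from .pick import pick_particles
    from .train import extract_exemplars, resize_crops, train_reference

    if not len(values):
        raise ValueError("values must be nonempty")
    if axis not in ("exemplars", "stride"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    diameter = bundle.params.particle_diameter
    rows = []
    if axis == "stride":
        if model is None:
            model, _ = train_reference(bundle.reference, bundle.exemplar_centers,
                                       mae_cfg, plan, loss_cfg, crop_size=diameter)
        ex_crops = extract_exemplars(bundle.reference, bundle.exemplar_centers,
                                     diameter)[: plan.m]
        feats = model.embed(resize_crops(ex_crops, mae_cfg.input_size))
        for v in values:
            cfg_v = dc_replace(pick_cfg, stride=int(v))
            table = _run_queries(model, feats, bundle, cfg_v, diameter, iou_threshold)
            rows.append({"axis": axis, "value": v, **table})
    else:
        for v in values:
            plan_v = dc_replace(plan, m=int(v))
            model_v, _ = train_reference(bundle.reference,
                                         bundle.exemplar_centers[: int(v)],
                                         mae_cfg, plan_v, loss_cfg,
                                         crop_size=diameter)
            ex_crops = extract_exemplars(bundle.reference,
                                         bundle.exemplar_centers[: int(v)],
                                         diameter)
            feats = model_v.embed(resize_crops(ex_crops, mae_cfg.input_size))
            table = _run_queries(model_v, feats, bundle, pick_cfg, diameter,
                                 iou_threshold)
            rows.append({"axis": axis, "value": v, **table})
    return pd.DataFrame(rows)


def _run_queries(model, feats, bundle, pick_cfg, diameter, iou_threshold):
    from .pick import pick_particles

    pick_sets, truths = [], []
    for mic, gt in bundle.queries:
        pick_sets.append(pick_particles(model, mic, feats, pick_cfg))
        truths.append(gt)
    table = evaluate_picks(pick_sets, truths, diameter, iou_threshold)
    pooled = table[table.micrograph_id == "ALL"].iloc[0]
    return {"tp": int(pooled.tp), "fp": int(pooled.fp), "fn": int(pooled.fn),
            "precision": float(pooled.precision), "recall": float(pooled.recall),
            "f1": float(pooled.f1)}
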