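"""Stage 2: scan query micrographs, auto-threshold, and score the picks.

Runs the full pipeline at the package's default desk-scale study
conditions (1024x1024 micrographs, 64 px particles, ~40 particles per
field): train on one reference with 15 exemplars, slide the encoder
over two query micrographs at stride 28, score windows by max cosine
similarity to the exemplar features, cut the score list with the
density-based rule, and evaluate picks against ground truth at
IoU >= 0.5 (duplicate detections count as false positives).  Takes
about a minute on one CPU core.
"""

from maepick import (LossConfig, MaeConfig, PickConfig, SimParams, TrainPlan,
                     evaluate_picks, extract_exemplars, make_dataset,
                     pick_particles, resize_crops, train_reference)

params = SimParams(snr=2.0, seed=1)  # defaults: 1024^2, diameter 64, 40 particles
bundle = make_dataset(params, n_query=2, n_exemplars=15)

model, _ = train_reference(bundle.reference, bundle.exemplar_centers,
                           MaeConfig.desk_scale(), TrainPlan(seed=1),
                           LossConfig(), crop_size=64)

crops = extract_exemplars(bundle.reference, bundle.exemplar_centers, 64)
feats = model.embed(resize_crops(crops, model.cfg.input_size))

pick_sets, truths = [], []
for mic, gt in bundle.queries:
    ps = pick_particles(model, mic, feats, PickConfig())
    print(f"{mic.micrograph_id}: {len(ps.scores)} windows scanned, "
          f"threshold {ps.threshold:.3f}, {len(ps.picked_centers)} picked "
          f"({len(gt.centers)} true particles)")
    pick_sets.append(ps)
    truths.append(gt)

table = evaluate_picks(pick_sets, truths, diameter=64)
print(table.to_string(index=False))
print("(tp+fn = true particles per micrograph; the ALL row pools queries;")
print(" duplicate windows over one particle are counted as false positives)")
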