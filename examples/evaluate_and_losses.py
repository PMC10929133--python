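"""Evaluation tables and reference loss values on phantom data.

Compares measured stages against ground-truth stages for a small phantom
cohort (one-vs-rest staging table), scores a deliberately corrupted region
map against the clean one, and prints the analytic reference values of the
two segmentation losses.
"""

import numpy as np

from rblkit import (
    RegionMap,
    ToothSpec,
    crop_and_merge,
    cross_entropy_loss,
    generate_panorama,
    measure_rbl,
    multilabel_loss,
    segmentation_report,
    stage_report,
)
from rblkit.metrics import format_table

rng = np.random.default_rng(0)
fractions = rng.uniform(0.05, 0.8, size=12)
truth = generate_panorama(
    [ToothSpec(tooth_number=2 + i, bone_loss_fraction=float(f))
     for i, f in enumerate(fractions)],
    canvas=(220, 1100), seed=0,
)
_, teeth = crop_and_merge(truth.positions, truth.region_map)
pred = [measure_rbl(t).stage for t in teeth]
ref = [truth.stages[t.tooth_number] for t in teeth]

print("staging evaluation (measured vs ground truth, one-vs-rest):")
print(format_table(stage_report(pred, ref)))

# corrupt 3% of region-map pixels and score the segmentation
labels = truth.region_map.labels.copy()
noise = rng.random(labels.shape) < 0.03
labels[noise] = rng.integers(0, 4, size=int(noise.sum()))
print("\nsegmentation scores of a 3%-corrupted region map:")
print(format_table(segmentation_report([RegionMap(labels=labels)], [truth.region_map])))

# analytic loss reference points
y = np.zeros((8, 8, 32)); y[..., 4] = 1
print(f"\nmulti-label loss at p=0.5 everywhere: {multilabel_loss(np.full(y.shape, 0.5), y):.6f}"
      f"  (= ln 2 = {np.log(2):.6f})")
y4 = np.zeros((8, 8, 4)); y4[..., 1] = 1
print(f"cross-entropy at uniform logits, 4 classes: {cross_entropy_loss(np.zeros(y4.shape), y4):.6f}"
      f"  (= ln 4 = {np.log(4):.6f})")
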