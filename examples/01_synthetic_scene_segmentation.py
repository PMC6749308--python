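"""Segment a synthetic canopy scene with the 7-class colour model.

Generates a vineyard-style scene with known per-pixel truth, labels 500
pixels per class (the manual-labelling budget of a field campaign), trains
the multinomial logistic colour classifier and reports per-class accuracy
against the truth map.
"""

import numpy as np

from vinecompact import colorseg, fixtures, metrics

scene = fixtures.generate_scene(480, 480, 3, (0.3, 0.9), seed=7)
print(f"scene: {scene.truth.shape[1]}x{scene.truth.shape[0]} px, "
      f"{len(scene.clusters)} clusters")

coords, labels = fixtures.sample_labeled_pixels(scene, per_class=500, seed=1)
features = colorseg.pixel_features(scene.image, coords)
model = colorseg.train_mlr(features, labels)

segmap = colorseg.segment(model, scene.image)
print(f"\n{'class':8s} {'sensitivity':>11s} {'specificity':>11s} {'f1':>7s}")
for idx, name in enumerate(fixtures.CLASS_NAMES):
    counts = metrics.one_vs_rest_eval(segmap.labels, scene.truth, idx)
    m = metrics.binary_metrics(counts, ("sensitivity", "specificity", "f1"))
    print(f"{name:8s} {m['sensitivity']:11.4f} {m['specificity']:11.4f} "
          f"{m['f1']:7.4f}")

accuracy = float(np.mean(segmap.labels == scene.truth))
print(f"\noverall pixel accuracy: {accuracy:.4f}")
print("Values near 1 mean the colour classes are recovered almost exactly —"
      "\nexpected here, since the synthetic class colours are separable by"
      "\nconstruction; field imagery is harder.")
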