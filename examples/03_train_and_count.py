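"""Small end-to-end run: train a patch classifier, then detect and count.

Uses the shallow baseline network and a handful of scenes so the whole
script finishes in a couple of minutes on one CPU; swap in
DenseNetConfig(layers_per_block=4) and more scenes for a stronger model.
"""

import numpy as np

from podquant import (LeNetConfig, TrainConfig, apply_normalization,
                      assemble_patchsets, build_model, count_agreement,
                      count_image, fit_normalization, generate_scene,
                      mask_background, predict_image, reconstruct_labels,
                      split_images, train_classifier, SceneSpec)
from podquant.synth import scene_spec_for_count

rng = np.random.default_rng(0)
seeds = rng.integers(0, 2 ** 31 - 1, 14)

# 1. training pool with complete annotations
images, annotations, ids = {}, [], []
for i in range(8):
    truth = generate_scene(SceneSpec(seed=int(seeds[i])), image_id=f"s{i}")
    images[truth.image_id] = truth.image
    annotations.extend(truth.annotations)
    ids.append(truth.image_id)

# 2. image-level split, patch extraction, normalization
split = split_images(ids, seed=0)
sets = assemble_patchsets(images, annotations, split, augment_per_point=4,
                          seed=0)
stats = fit_normalization(sets["train"][0])
norm = lambda x: apply_normalization(x, stats)

# 3. train the baseline classifier (15 epochs, batch 64)
model = build_model(LeNetConfig(), seed=0)
model, history = train_classifier(
    model, (norm(sets["train"][0]), sets["train"][1]),
    (norm(sets["val"][0]), sets["val"][1]),
    TrainConfig(epochs=15, batch_size=64, seed=0))
print(f"patch validation accuracy: "
      f"{max(h['val_accuracy'] for h in history):.3f}")

# 4. predict, reconstruct and count held-out scenes
preds, truths = [], []
for i in range(6):
    truth = generate_scene(scene_spec_for_count(
        int(rng.integers(5, 15)), seed=int(seeds[8 + i]), n_overlap_pairs=1))
    grid = predict_image(model, truth.image, stats)
    labels = mask_background(reconstruct_labels(grid), truth.image)
    preds.append(count_image(labels).count)
    truths.append(truth.true_count)
    print(f"scene {i}: true {truths[-1]:2d}  predicted {preds[-1]:2d}")

agreement = count_agreement(np.array(preds, float), np.array(truths, float))
print(f"Pearson r = {agreement.correlation_coefficient:.3f}, "
      f"RMSE = {agreement.rmse:.2f} fruits over {len(preds)} scenes")
# r near 1 and RMSE of a fruit or two indicate the patch classifier plus
# vote fusion and angle-based assembly track the true per-scene counts.
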