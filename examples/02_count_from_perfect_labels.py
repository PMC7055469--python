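"""Count siliques from ground-truth labels, bypassing the classifier.

Downsampling the generator's pixel mask to the 16 px sub-patch lattice
gives the same kind of label image the CNN pathway produces, so the
assembly/counting stage can be exercised (and validated) in isolation.
The overlapping pair placed at 0.3 rad is split by the angle rule; run
with overlap_angle_range=(0.02, 0.02) to see the pair merge instead.
"""

from podquant import CounterConfig, count_image, downsample_mask, generate_scene
from podquant.synth import scene_spec_for_count

spec = scene_spec_for_count(12, seed=5, n_overlap_pairs=1,
                            overlap_angle_range=(0.3, 0.3))
truth = generate_scene(spec)
labels = downsample_mask(truth.mask)
result = count_image(labels, CounterConfig(angle_threshold=0.05))

print(f"true count: {truth.true_count}, recovered count: {result.count}")
summary = result.summary()
print(f"mean length {summary['mean_length_px']:.0f} px "
      f"(range {summary['min_length_px']:.0f}-{summary['max_length_px']:.0f})")
for s in result.siliques:
    flag = " (merged pair)" if s.merged_from > 1 else ""
    print(f"  silique: length {s.length:6.1f} px, area {s.area} sub-patches{flag}")
# On perfect labels the recovered count equals the generator's truth; the
# lengths are centroid-to-centroid estimates on the 16 px lattice.
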