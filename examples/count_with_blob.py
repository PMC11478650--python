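"""Count larvae with the classical blob detector and score the result.

The blob detector (Otsu threshold, connected components, area filter) is a
reference detector for well-separated larvae; the pipeline around it —
tiling, boundary classification, overlap-ratio matching, re-detection —
is identical to what a trained detector would use.
"""

from larvacount import (
    BlobDetector,
    SceneConfig,
    count_image,
    counting_accuracy,
    evaluate_detections,
    generate_scene,
)

scene = generate_scene(
    SceneConfig(width_px=1000, height_px=1000, n_larvae=110,
                clump_fraction=0.0, overlap_fraction=0.0, seed=3)
)
result = count_image(scene.image, tile_size=100, detector=BlobDetector())
truth_n = len(scene.truth_boxes)
accuracy = counting_accuracy(truth_n, result.total_count)
quality = evaluate_detections(result.final_boxes, scene.truth_boxes, match_radius_px=8)

print(f"true count:     {truth_n}")
print(f"counted:        {result.total_count}")
print(f"accuracy A:     {accuracy:.2f}%")
print(f"precision/recall at 8 px: {quality.precision:.3f} / {quality.recall:.3f}")
# A = 100 * (Ac - |Id - Ac|) / Ac: 100 means a perfect count, and over- and
# undercounts of the same size are penalised equally.
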