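"""Generate a synthetic larvae scene with known ground truth and save it.

Prints the number of larvae placed and basic image statistics; the saved
truth CSV/YOLO files are what the counting pipeline is evaluated against.
"""

from pathlib import Path

from larvacount import SceneConfig, generate_scene, save_scene

out = Path("example_output")
out.mkdir(exist_ok=True)

config = SceneConfig(
    width_px=1000,
    height_px=1000,
    n_larvae=250,
    clump_fraction=0.15,
    overlap_fraction=0.05,
    seed=42,
)
scene = generate_scene(config)
save_scene(scene, out / "scene.png", out / "scene.csv")

print(f"placed {len(scene.truth_boxes)} larvae in a "
      f"{config.width_px}x{config.height_px} px field")
print(f"image intensity range: {scene.image.min()}..{scene.image.max()} "
      f"(background {config.background_level})")
print(f"wrote {out / 'scene.png'}, truth boxes in {out / 'scene.csv'} "
      f"and {out / 'scene.txt'}")
# Each truth box is a 10x10 px square on a larval head; heads, not whole
# bodies, are the annotation unit the detector and stitcher work with.
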