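"""The conventional 2D comparison: total multi-view pixel count.

Renders 120 views of a synthetic panicle with green checkerboard-square
distractors, segments each frame by the fixed chamber HSV threshold,
rejects square-like regions by solidity/eccentricity and tiny regions by
area, and sums the surviving panicle pixels over all views.
"""

from paniclepheno.multiview import total_pixel_count
from paniclepheno.preprocess import segment_background
from paniclepheno.synthetic import SyntheticPanicleSpec, make_scene, render_views

cloud, _ = make_scene(SyntheticPanicleSpec(week=2, rng_seed=42))
images, masks, truth = render_views(cloud, n_views=120,
                                    distractor_squares=4, rng_seed=42)
segmented = [segment_background(image) for image in images]

total = total_pixel_count(segmented, expected_images=120)
print(f"views                 : {len(images)}")
print(f"true panicle pixels   : {sum(truth.pixel_counts)}")
print(f"filtered session total: {total}")
print("Distractor squares pass color segmentation (they are panicle-green)")
print("but are rejected by shape, so the total matches the rendered truth.")
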