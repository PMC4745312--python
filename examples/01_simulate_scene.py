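"""Render a synthetic smear slide scene and inspect its ground truth.

The generator places stained elliptical cells on a bright background with a
smooth illumination gradient. Unsuitable objects come in three phenotypes:
debris-covered, folded and overlapping cells.
"""

from collections import Counter

from cellcull.slidemap import stitch_tiles
from cellcull.synthetic import SceneSpec, generate_slide_scene

spec = SceneSpec(image_height=1024, image_width=1280, tile_rows=2,
                 tile_cols=2, n_suitable=6, n_unsuitable=6, seed=42)
tiles, background, truth = generate_slide_scene(spec)
slide = stitch_tiles(tiles, (spec.tile_rows, spec.tile_cols))

print(f"slide-map: {slide.pixels.shape[0]} x {slide.pixels.shape[1]} px, "
      f"{len(tiles)} tiles of {spec.tile_shape}")
print(f"planted objects: {len(truth)}")
print("phenotypes:", dict(Counter(o.phenotype for o in truth.objects)))
areas = [int(o.mask.sum()) for o in truth.objects]
print(f"object areas: min {min(areas)} px^2, max {max(areas)} px^2")
# Each truth object carries its mask and suitability label; the background
# image holds only the illumination gradient and is the flat-field reference.
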