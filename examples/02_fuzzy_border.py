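"""Detect a lesion border with the fuzzy edge filter.

The filter builds Dark/Median/Bright fuzzy concepts from the image
histogram and responds where the membership-weighted neighborhood standard
deviations are nonzero, i.e. across gray-level transitions.
"""

import numpy as np

from fmlp import ShapeSpec, create_concepts, extract_border, make_mask
from fmlp.pipeline import border_image

mask = make_mask(ShapeSpec(kind="irregular", image_side=128, base_radius=30,
                           roughness=0.4, seed=5))
gray = mask.astype(np.uint8) * 255

concepts = create_concepts(gray)
print("concept centers:", {c.name: c.m for c in concepts})

border = border_image(mask)
contour = extract_border(border)
print(f"border image: {int(border.sum())} marked pixels")
print(f"traced contour: {contour.shape[0]} ordered points, "
      f"starts at {tuple(contour[0])}")
# The marked pixels form a closed ring hugging the mask boundary; the
# contour is the ordered clockwise walk around the largest ring.
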