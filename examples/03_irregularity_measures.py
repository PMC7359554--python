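"""Measure border irregularity: box-counting fractal dimension + convexity.

A straight line has dimension 1 and a convex shape has convexity 1;
ragged borders push the dimension up and the convexity down.
"""

import numpy as np

from fmlp import (ShapeSpec, convexity, extract_features, fractal_dimension,
                  make_curve, make_mask)
from fmlp.pipeline import border_image

line = make_curve("line", image_side=64)
print(f"straight line: D = {fractal_dimension(line):.3f} (analytic: 1)")

koch = make_curve("koch", level=4, image_side=729)
d = fractal_dimension(koch, sizes=[8, 16, 32, 64])
print(f"Koch curve:    D = {d:.3f} (analytic: {np.log(4)/np.log(3):.3f})")

square = make_mask(ShapeSpec(kind="square", image_side=64, base_radius=16))
print(f"filled square: convexity = {convexity(square):.6f} (exact: 1)")

for kind, rough in (("regular", 0.0), ("irregular", 0.4)):
    mask = make_mask(ShapeSpec(kind=kind, image_side=128, base_radius=30,
                               roughness=rough, seed=5))
    vec = extract_features(mask, border_image(mask), kind)
    print(f"{kind:9s} lesion: D = {vec.fractal_dimension:.3f}, "
          f"convexity = {vec.convexity:.3f}")
# Irregular lesions score a higher fractal dimension and a lower
# convexity than regular ones — the two-value measure the classifier uses.
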