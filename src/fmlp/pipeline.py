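"""End-to-end glue: masks -> fuzzy borders -> irregularity feature table.

Mirrors the full lesion-analysis flow: each binary mask is rescaled to an
8-bit grayscale image, the fuzzy border filter marks the boundary, the
fractal dimension is measured on the border image and the convexity on the
mask, and everything is collected into a feature table ready for training.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import convexity, fractal_dimension
from .fuzzedge import fuzzedge_filter
from .synthetic import MaskDataset

__all__ = ["border_image", "compute_feature_table"]


def border_image(mask: np.ndarray) -> np.ndarray:
    """Boolean border image of a lesion mask via the fuzzy edge filter.

    Binary masks occupy only the Dark and Bright ends of the gray axis, so
    the (expected) empty-Median-interval warning is suppressed here.
    """
    gray = np.asarray(mask, dtype=bool).astype(np.uint8) * 255
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no pixels in the Median")
        response = fuzzedge_filter(gray)
    return response > 0


def compute_feature_table(dataset: MaskDataset) -> pd.DataFrame:
    """Feature table with columns id, fractal_dimension, convexity, label."""
    rows = []
    for mask, mask_id, label in zip(dataset.masks, dataset.ids, dataset.labels):
        border = border_image(mask)
        rows.append(
            {
                "id": mask_id,
                "fractal_dimension": fractal_dimension(border),
                "convexity": convexity(mask),
                "label": int(label),
            }
        )
    return pd.DataFrame(rows)
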