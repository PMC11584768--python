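"""Region-partition overlays: boundaries plus red receptive-field boxes."""

from __future__ import annotations

import numpy as np

from .dra import RegionPartition

__all__ = ["partition_overlay", "save_partition_overlay"]


def partition_overlay(image: np.ndarray, part: RegionPartition,
                      n_boxes: int = 3) -> np.ndarray:
    """Return an RGB float image with region boundaries marked and the
    bounding boxes of the ``n_boxes`` largest regions drawn in red — the
    per-region receptive field of the attention gate."""
    from skimage.segmentation import mark_boundaries

    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape[:2] != part.labels.shape:
        from skimage.transform import resize
        img = resize(img, part.labels.shape, order=1, preserve_range=True)
    out = mark_boundaries(img, part.labels.astype(int), color=(1.0, 1.0, 0.2))
    sizes = np.bincount(part.labels.ravel(), minlength=part.k)
    for r in np.argsort(sizes)[::-1][:n_boxes]:
        ys, xs = np.nonzero(part.labels == r)
        if ys.size == 0:
            continue
        y0, y1, x0, x1 = ys.min(), ys.max(), xs.min(), xs.max()
        out[y0, x0:x1 + 1] = (1.0, 0.0, 0.0)
        out[y1, x0:x1 + 1] = (1.0, 0.0, 0.0)
        out[y0:y1 + 1, x0] = (1.0, 0.0, 0.0)
        out[y0:y1 + 1, x1] = (1.0, 0.0, 0.0)
    return np.clip(out, 0.0, 1.0)


def save_partition_overlay(image: np.ndarray, part: RegionPartition, path,
                           n_boxes: int = 3):
    from PIL import Image

    overlay = partition_overlay(image, part, n_boxes)
    Image.fromarray((overlay * 255 + 0.5).astype(np.uint8)).save(path)
    return path
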