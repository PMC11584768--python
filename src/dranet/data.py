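"""Dataset reading and writing: image/mask directory trees with split lists."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import InvalidInputError
from .synthetic import SegmentationSample

__all__ = ["load_image", "load_mask", "nearest_resize", "load_dataset", "save_mask_png"]

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".bmp")


def load_image(path) -> np.ndarray:
    """Read an RGB image (PNG/TIFF/BMP) as float in [0, 1], shape (H, W, 3)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def load_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG, strictly binarized to {0, 1}."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def save_mask_png(mask: np.ndarray, path):
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def nearest_resize(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor mask resize with half-pixel source sampling."""
    h, w = mask.shape
    oh, ow = size
    ii = np.minimum((np.floor((np.arange(oh) + 0.5) * h / oh)).astype(int), h - 1)
    jj = np.minimum((np.floor((np.arange(ow) + 0.5) * w / ow)).astype(int), w - 1)
    return mask[np.ix_(ii, jj)]


def bilinear_image_resize(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == tuple(size):
        return img
    return _sk_resize(img, size, order=1, preserve_range=True, anti_aliasing=False)


def _find_image(images_dir: Path, name: str) -> Path:
    for ext in _IMAGE_EXTS:
        p = images_dir / f"{name}{ext}"
        if p.exists():
            return p
    raise InvalidInputError(f"no image found for {name!r} under {images_dir}")


def load_dataset(root, split: str, input_size: int | tuple[int, int] | None = None
                 ) -> list[SegmentationSample]:
    """Load aligned, optionally resized image/mask pairs for a split.

    Expects ``root/images/``, ``root/masks/`` and ``root/<split>.txt``
    listing sample names (one per line, extensionless).  Masks are strictly
    binarized; ordering follows the split list.
    """
    root = Path(root)
    split_file = root / f"{split}.txt"
    if not split_file.exists():
        raise InvalidInputError(f"split list not found: {split_file}")
    names = [ln.strip() for ln in split_file.read_text().splitlines() if ln.strip()]
    if input_size is not None and not isinstance(input_size, tuple):
        input_size = (int(input_size), int(input_size))
    samples = []
    for name in names:
        img_path = _find_image(root / "images", name)
        mask_path = root / "masks" / f"{name}.png"
        if not mask_path.exists():
            raise InvalidInputError(f"missing mask for image {name!r}: {mask_path}")
        img = load_image(img_path)
        mask = load_mask(mask_path)
        if img.shape[:2] != mask.shape:
            target = img.shape[:2] if input_size is None else input_size
            mask = nearest_resize(mask, target)
        if input_size is not None:
            img = bilinear_image_resize(img, input_size)
            if mask.shape != tuple(input_size):
                mask = nearest_resize(mask, input_size)
        samples.append(SegmentationSample(image=img, mask=mask,
                                          provenance=str(img_path), name=name))
    return samples
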