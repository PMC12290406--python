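"""Image, mask, and array file handling.

PNG I/O is 8-bit (intensities scaled by 255); masks are stored as PNGs
with 255 = observed, 0 = missing.  NIfTI volumes yield one axial slice,
min-max normalized to [0, 1].
"""

from __future__ import annotations

import numpy as np
from PIL import Image as PILImage

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "load_nifti_slice", "save_array", "load_array"]


def read_image(path) -> np.ndarray:
    """8-bit grayscale or RGB PNG to a float array in [0, 1]."""
    with PILImage.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB" if "A" in img.mode or
                              img.mode in ("P", "CMYK") else "L")
        arr = np.asarray(img, dtype=float) / 255.0
    return arr


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image, dtype=float)
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L" if arr.ndim == 2 else "RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Mask PNG (255 = observed) to a {0, 1} uint8 array."""
    with PILImage.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) != 0).astype(np.uint8) * 255
    PILImage.fromarray(arr, mode="L").save(path)


def load_nifti_slice(path, index: int | None = None, axis: int = 2
                     ) -> np.ndarray:
    """Extract one 2-D slice from a NIfTI volume, min-max normalized.

    ``index`` defaults to the middle slice along ``axis``.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    while vol.ndim > 3:
        vol = vol[..., 0]
    if vol.ndim == 2:
        sl = vol
    else:
        if index is None:
            index = vol.shape[axis] // 2
        sl = np.take(vol, index, axis=axis)
    lo, hi = np.nanmin(sl), np.nanmax(sl)
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    else:
        sl = np.zeros_like(sl)
    return np.nan_to_num(sl, nan=0.0)


def save_array(path, array: np.ndarray) -> None:
    np.savez_compressed(path, array=np.asarray(array))


def load_array(path) -> np.ndarray:
    with np.load(path, allow_pickle=False) as data:
        return data["array"]
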