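"""Image file I/O.

The in-memory convention is always (H, W, 3) uint8 in red, green, blue
order; readers promote grayscale to 3 channels and drop alpha, writers emit
lossless PNG (JPEG is accepted on read only).
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .imops import as_image

__all__ = ["read_image", "write_image"]


def read_image(path: str | os.PathLike) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_image(arr)


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    iio.imwrite(path, as_image(image))
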