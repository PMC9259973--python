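"""Multivector encoding of color images and patch extraction/reconstruction.

A three-channel image is encoded pixel-wise as ``0 + R·γ1 + G·γ2 + B·γ12``:
the scalar slot is structurally zero and the color channels ride on the three
non-scalar blades, so one multivector carries one pixel and channel
correlation survives every algebraic operation downstream.

Patches are n×n sliding windows flattened **column-major** into length-n²
multivector vectors; reconstruction overlap-averages every patch copy of a
pixel.  Extraction followed by reconstruction is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ga import mv  # noqa: F401  (re-export convenience)

__all__ = [
    "GAImage",
    "PatchSet",
    "encode_image",
    "decode_image",
    "extract_patches",
    "reconstruct_image",
    "read_image",
    "write_image",
]

log = logging.getLogger(__name__)


@dataclass
class GAImage:
    """An H×W field of multivectors; ``pixels`` has shape (H, W, 4)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 4:
            raise ValueError(f"GAImage needs (H, W, 4) components, got {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PatchSet:
    """Column-stacked patch vectors: ``vectors`` is (N, K, 4) with N = n²."""

    vectors: np.ndarray
    positions: list
    patch_size: int
    source_shape: tuple
    step: int = 1

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]


def encode_image(rgb: np.ndarray) -> GAImage:
    """Encode an H×W×3 array in [0, 1] as a GAImage (R→γ1, G→γ2, B→γ12)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an H×W×3 array, got shape {rgb.shape}")
    if not np.isfinite(rgb).all():
        raise ValueError("image contains non-finite values")
    lo, hi = rgb.min(), rgb.max()
    if lo < 0.0 or hi > 1.0:
        log.warning("encode_image: values outside [0,1] (min=%g, max=%g); rescaling", lo, hi)
        rgb = (rgb - lo) / (hi - lo) if hi > lo else np.zeros_like(rgb)
    H, W, _ = rgb.shape
    px = np.zeros((H, W, 4), dtype=float)
    px[..., 1:] = rgb
    return GAImage(px)


def decode_image(img: GAImage, e0_tolerance: float = 1e-3) -> np.ndarray:
    """Decode a GAImage back to an H×W×3 array, clipped to [0, 1].

    The scalar slot is structurally zero under the encoding; residual scalar
    energy (e.g. acquired through full-multivector dictionary products) is
    discarded, and logged when it exceeds ``e0_tolerance``.
    """
    e0_max = np.abs(img.pixels[..., 0]).max() if img.pixels.size else 0.0
    if e0_max > e0_tolerance:
        log.warning("decode_image: discarding scalar residue (max |e0| = %.3g > %.3g)", e0_max, e0_tolerance)
    return np.clip(img.pixels[..., 1:], 0.0, 1.0)


def extract_patches(img: GAImage, n: int, step: int = 1) -> PatchSet:
    """Slide an n×n window over the image and flatten each window column-major.

    Windows are enumerated in row-major scan order of their top-left corner;
    entry ``wr + n·wc`` of a patch vector is window pixel (row wr, col wc).
    """
    H, W = img.height, img.width
    if n < 1 or n > min(H, W):
        raise ValueError(f"patch size {n} incompatible with image {H}×{W}")
    if step < 1:
        raise ValueError("step must be ≥ 1")
    view = np.lib.stride_tricks.sliding_window_view(img.pixels, (n, n), axis=(0, 1))
    view = view[::step, ::step]  # (H', W', 4, n, n) — window dims appended last
    Hp, Wp = view.shape[:2]
    # column-major flatten: order axes (wc, wr) then C-reshape → index wr + n*wc
    vectors = view.transpose(0, 1, 4, 3, 2).reshape(Hp * Wp, n * n, 4)
    vectors = np.ascontiguousarray(vectors.transpose(1, 0, 2))
    positions = [(r * step, c * step) for r in range(Hp) for c in range(Wp)]
    return PatchSet(vectors=vectors, positions=positions, patch_size=n, source_shape=(H, W), step=step)


def reconstruct_image(patches: PatchSet) -> GAImage:
    """Overlap-average a PatchSet back into a GAImage.

    Every pixel must be covered by at least one patch; with step > 1 the
    trailing rows/columns can fall outside every window, which is an error.
    """
    H, W = patches.source_shape
    n = patches.patch_size
    acc = np.zeros((H, W, 4), dtype=float)
    cnt = np.zeros((H, W), dtype=float)
    for j, (r, c) in enumerate(patches.positions):
        block = patches.vectors[:, j, :].reshape(n, n, 4, order="F")  # (wr, wc, comp)
        acc[r : r + n, c : c + n] += block
        cnt[r : r + n, c : c + n] += 1.0
    if (cnt == 0).any():
        rows, cols = np.nonzero(cnt == 0)
        raise ValueError(
            "uncovered pixels: rows %d–%d, cols %d–%d (step too large for patch grid)"
            % (rows.min(), rows.max(), cols.min(), cols.max())
        )
    return GAImage(acc / cnt[..., None])


def read_image(path) -> np.ndarray:
    """Read a PNG or TIFF image as an H×W×3 float array in [0, 1].

    8-/16-bit integer data are divided by their type maximum; float data are
    taken as already unit-range.  Grayscale inputs are promoted to three
    identical channels (logged); an alpha channel is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        log.info("read_image: grayscale input %s promoted to 3 identical channels", path.name)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[-1] == 4:
        log.info("read_image: dropping alpha channel of %s", path.name)
        arr = arr[..., :3]
    elif arr.shape[-1] != 3:
        raise ValueError(f"{path}: unsupported channel count {arr.shape[-1]}")
    return np.clip(arr, 0.0, 1.0)


def write_image(path, rgb: np.ndarray) -> None:
    """Write an H×W×3 unit-range array as 8-bit PNG or 16-bit TIFF."""
    path = Path(path)
    rgb = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), np.round(rgb * 65535).astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), np.round(rgb * 255).astype(np.uint8))
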