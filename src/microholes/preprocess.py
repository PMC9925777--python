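"""Whole-image binarization and patch extraction.

Greyscale microscopy exports (8-bit, 0 = black / no signal, 255 = white /
signal) are thresholded with Otsu's method on the *whole* image, trimmed of
empty borders, padded to a multiple of the patch size and tiled into
non-overlapping binary patches.  All-background tiles are discarded: the
downstream topological analysis only makes sense where some signal phase is
present.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BinaryPatch",
    "load_image",
    "otsu_threshold",
    "trim_empty_borders",
    "pad_and_patch",
    "binarize_and_patch",
    "write_patches",
    "OtsuBinarizer",
    "PatchExtractor",
]


@dataclass(frozen=True)
class BinaryPatch:
    """A fixed-size binary tile of a thresholded image.

    ``mask`` is boolean with True = white (signal, "bone") and False = black
    (micro-hole or exterior background).  ``origin`` is the (row, col) of the
    tile's top-left corner in the padded source image, so patch provenance
    survives the whole pipeline.
    """

    mask: np.ndarray
    origin: tuple[int, int] = (0, 0)
    source: str = ""
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise ValueError("patch mask must be 2-D")

    @property
    def side(self) -> int:
        return self.mask.shape[0]

    @property
    def n_white(self) -> int:
        return int(self.mask.sum())

    @property
    def patch_index(self) -> tuple[int, int]:
        """(row, col) index of the tile in the patch grid."""
        return (self.origin[0] // self.mask.shape[0], self.origin[1] // self.mask.shape[1])


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit single-channel PNG/TIFF as a 2-D uint8 array.

    Multi-channel input is rejected rather than silently converted.
    """
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel greyscale image, got shape {img.shape}"
        )
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.max() <= 255 and img.min() >= 0:
            img = img.astype(np.uint8)
        else:
            raise ValueError(f"{path}: expected 8-bit intensities, got dtype {img.dtype}")
    return img


def otsu_threshold(img: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu-binarize a whole greyscale image.

    Returns ``(t, binary)`` where ``t`` is the integer threshold maximising
    the between-class variance of the image histogram and ``binary`` marks
    pixels with intensity strictly greater than ``t`` as white (True).
    Thresholding is done on the whole image before any patching, so every
    patch of one image shares the same threshold.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("expected integer intensities in [0, 255]")
    if np.unique(img).size < 2:
        raise ValueError("degenerate histogram: image has a single intensity value")
    t = int(threshold_otsu(img))
    return t, img > t


def trim_empty_borders(binary: np.ndarray) -> np.ndarray:
    """Crop leading/trailing all-black rows and columns.

    The exterior background of a trimmed sample would otherwise dominate the
    black phase; trimming keeps it as small as the bounding box allows.  An
    all-black image yields an empty (0-sized) array.
    """
    binary = np.asarray(binary, dtype=bool)
    rows = np.flatnonzero(binary.any(axis=1))
    cols = np.flatnonzero(binary.any(axis=0))
    if rows.size == 0:
        return binary[:0, :0]
    return binary[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def pad_and_patch(
    binary: np.ndarray,
    side: int = 300,
    stride: int | None = None,
    source: str = "",
    labels: dict | None = None,
) -> list[BinaryPatch]:
    """Pad with black to a multiple of ``side`` and tile row-major.

    Padding is added on the bottom/right only, so the coordinates of existing
    pixels (and hence patch origins) are preserved.  Tiles containing zero
    white pixels are discarded.  ``stride`` defaults to ``side`` so that
    patches partition the padded image without overlap.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    stride = side if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    binary = np.asarray(binary, dtype=bool)
    labels = dict(labels or {})
    if binary.size == 0:
        return []
    h, w = binary.shape
    hp = int(np.ceil(h / side)) * side
    wp = int(np.ceil(w / side)) * side
    padded = np.zeros((hp, wp), dtype=bool)
    padded[:h, :w] = binary
    patches = []
    for r in range(0, hp - side + 1, stride):
        for c in range(0, wp - side + 1, stride):
            tile = padded[r : r + side, c : c + side]
            if tile.any():
                patches.append(
                    BinaryPatch(mask=tile.copy(), origin=(r, c), source=source, labels=labels)
                )
    return patches


def binarize_and_patch(
    img: np.ndarray,
    side: int = 300,
    stride: int | None = None,
    source: str = "",
    labels: dict | None = None,
) -> tuple[int, list[BinaryPatch]]:
    """Whole-image Otsu, border trim, pad and tile — the full preprocessing step."""
    t, binary = otsu_threshold(img)
    trimmed = trim_empty_borders(binary)
    return t, pad_and_patch(trimmed, side=side, stride=stride, source=source, labels=labels)


def write_patches(patches: list[BinaryPatch], out_dir: str | Path) -> Path:
    """Write patches as PNGs plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "patches.csv"
    label_keys = sorted({k for p in patches for k in p.labels})
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_id", "source", "row", "col", "n_white", *label_keys])
        for i, p in enumerate(patches):
            name = f"patch_{i:05d}.png"
            iio.imwrite(out_dir / name, (p.mask.astype(np.uint8) * 255))
            writer.writerow(
                [name, p.source, p.origin[0], p.origin[1], p.n_white]
                + [p.labels.get(k, "") for k in label_keys]
            )
    return manifest


class OtsuBinarizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: list of greyscale images -> list of binary images."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        out = []
        for img in X:
            _, binary = otsu_threshold(img)
            out.append(binary)
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class PatchExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of binary images -> flat list of :class:`BinaryPatch`.

    Trims empty borders, pads and tiles each input image; the number of output
    samples generally differs from the number of inputs.
    """

    def __init__(self, side: int = 300, stride: int | None = None, trim: bool = True):
        self.side = side
        self.stride = stride
        self.trim = trim

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        patches: list[BinaryPatch] = []
        for i, binary in enumerate(X):
            if self.trim:
                binary = trim_empty_borders(binary)
            new = pad_and_patch(binary, side=self.side, stride=self.stride, source=str(i))
            if not new:
                warnings.warn(f"image {i}: no non-background patches emitted")
            patches.extend(new)
        return patches
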