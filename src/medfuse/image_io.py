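"""Raster image I/O and the HSV colour model used throughout the pipeline.

All fusion arithmetic happens on 2-D float64 arrays ("gray images") with a
nominal [0, 1] range.  Colour is carried as an :class:`HsvImage` — three
equally shaped gray channels (hue in [0, 1) cyclic, saturation and value in
[0, 1]) following the hexcone convention of ``skimage.color``.  Files are
converted to this representation once, at read time, so no quantization
drifts through the filtering levels; quantization back to 8 bits happens
once, at write time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color

from .exceptions import DimensionError, FormatError

__all__ = ["HsvImage", "read_image", "write_image", "to_working_pair"]


@dataclass
class HsvImage:
    """Hue/saturation/value triple of equally shaped float64 channels."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if not (self.h.shape == self.s.shape == self.v.shape):
            raise DimensionError(
                f"HSV channels must share one shape, got "
                f"{self.h.shape}, {self.s.shape}, {self.v.shape}"
            )
        if self.h.ndim != 2:
            raise DimensionError(f"channels must be 2-D, got {self.h.ndim}-D")
        for name, c in (("h", self.h), ("s", self.s), ("v", self.v)):
            if not np.isfinite(c).all():
                raise ValueError(f"non-finite values in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape

    @classmethod
    def from_gray(cls, v: np.ndarray) -> "HsvImage":
        """Wrap a grayscale field as HSV with zero hue and saturation."""
        v = np.asarray(v, dtype=np.float64)
        return cls(h=np.zeros_like(v), s=np.zeros_like(v), v=v)

    @classmethod
    def from_rgb(cls, rgb: np.ndarray) -> "HsvImage":
        hsv = color.rgb2hsv(np.asarray(rgb, dtype=np.float64))
        return cls(h=hsv[..., 0], s=hsv[..., 1], v=hsv[..., 2])

    def to_rgb(self) -> np.ndarray:
        """Inverse hexcone transform; channels are clipped to their domains."""
        hsv = np.stack(
            [np.mod(self.h, 1.0), np.clip(self.s, 0, 1), np.clip(self.v, 0, 1)],
            axis=-1,
        )
        return color.hsv2rgb(hsv)


def read_image(path: str | Path) -> HsvImage:
    """Read a PNG/TIFF/JPEG file into the internal HSV representation.

    Integer files are scaled by their bit-depth maximum into [0, 1]; float
    files are clipped to [0, 1].  Single-channel files map to h=0, s=0 so
    structural (MRI-like) and functional (PET/SPECT-like) inputs travel the
    same code path.
    """
    arr = iio.imread(Path(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    if arr.ndim == 2:
        return HsvImage.from_gray(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return HsvImage.from_rgb(arr)
    raise FormatError(
        f"{path}: unsupported layout {arr.shape}; expected 1 or 3 channels"
    )


def write_image(img: HsvImage, path: str | Path) -> Path:
    """Inverse HSV transform, clip to [0, 1], quantize to 8 bit and write.

    The format follows the file extension (default recommendation: PNG).
    ``read_image(write_image(x))`` reproduces ``x`` within one quantization
    step (1/255) per channel.
    """
    path = Path(path)
    rgb = np.clip(img.to_rgb(), 0.0, 1.0)
    iio.imwrite(path, (rgb * 255.0).round().astype(np.uint8))
    return path


def to_working_pair(
    structural: HsvImage, functional: HsvImage
) -> tuple[np.ndarray, np.ndarray, HsvImage]:
    """Split a registered pair into the channels the pipeline works on.

    Returns ``(structural value, functional value, functional HsvImage)``:
    fusion operates on the two value channels while the functional image's
    hue and saturation are carried through to reconstruction.  Registration
    is a precondition — mismatched shapes are a hard error, never resampled.
    """
    if structural.shape != functional.shape:
        raise DimensionError(
            f"registered pair required: {structural.shape} vs {functional.shape}"
        )
    return structural.v, functional.v, functional
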