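"""Reading and writing frame sequences and result tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .preprocess import IntensityFrame

__all__ = ["read_frames", "write_frames", "write_ground_truth"]


def _to_frames(stack: np.ndarray, fps: float, pixel_size: float | None) -> list[IntensityFrame]:
    if stack.ndim == 2:
        stack = stack[None]
    scale = 255.0 / 65535.0 if stack.dtype == np.uint16 else 1.0
    depth = 16 if stack.dtype == np.uint16 else 8
    return [
        IntensityFrame(
            pixels=page.astype(np.float64) * scale,
            bit_depth=depth,
            pixel_size=pixel_size,
            timestamp=i / fps,
            frame_index=i,
        )
        for i, page in enumerate(stack)
    ]


def read_frames(
    path, fps: float = 10.0, pixel_size: float | None = None
) -> list[IntensityFrame]:
    """Read a multi-page TIFF, a single image, or a directory of numbered
    PNG/TIFF frames (sorted by filename) into a frame list.

    16-bit input is mapped onto the internal [0, 255] float scale.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no frame images found in {path}")
        pages = [iio.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError("frame images in a sequence must share one shape")
        return _to_frames(np.stack(pages), fps, pixel_size)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _to_frames(tifffile.imread(path), fps, pixel_size)
    return _to_frames(iio.imread(path), fps, pixel_size)


def write_frames(frames: Sequence[IntensityFrame], path, fmt: str = "tiff") -> Path:
    """Write frames as one multi-page 8-bit TIFF or numbered PNGs.

    With ``fmt='tiff'``, ``path`` is the output file; with ``fmt='png'`` it
    is a directory receiving ``frame_0000.png`` etc. Returns the path
    written.
    """
    path = Path(path)
    stack = np.stack([f.to_uint8() for f in frames])
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack, photometric="minisblack")
        return path
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, page in enumerate(stack):
            iio.imwrite(path / f"frame_{i:04d}.png", page)
        return path
    raise ValueError("fmt must be 'tiff' or 'png'")


def write_ground_truth(truth: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False)
    return path
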