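"""Per-frame preprocessing for bright-field micrographs of cells in shear flow.

The chain mirrors the standard bright-field workflow for edge-based cell
counting: rolling-ball background correction (removes the smooth halogen
illumination ramp), percentile contrast stretching (makes the dark cell rims
prominent), Sobel gradient magnitude (isolates cell outlines), and Gaussian
smoothing of the edge map (suppresses small noise particles before counting).

All processing is carried out in floating point on the 8-bit intensity scale
[0, 255]; images are quantized only on export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage import restoration, transform
from skimage.measure import block_reduce

__all__ = [
    "IntensityFrame",
    "EdgeMap",
    "subtract_background",
    "enhance_contrast",
    "sobel_magnitude",
    "gaussian_smooth",
    "rescale_to_8bit",
    "preprocess_frame",
]

#: full scale of the internal intensity representation
INTENSITY_MAX = 255.0

MIN_FRAME_SIDE = 64


@dataclass
class IntensityFrame:
    """One 2-D grayscale micrograph plus acquisition metadata.

    ``pixels`` is kept as float64 on the [0, 255] scale regardless of the
    source bit depth; ``bit_depth`` records the acquisition depth.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float | None = None  # µm per pixel
    timestamp: float | None = None  # seconds since sequence start
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("frame must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite values")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_uint8(self) -> np.ndarray:
        """Quantize for export."""
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


@dataclass
class EdgeMap:
    """Gradient-magnitude map derived from a frame, with step provenance."""

    magnitude: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.ndim != 2:
            raise ValueError("edge map must be 2-D")
        if np.any(self.magnitude < 0):
            raise ValueError("edge magnitudes must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape  # type: ignore[return-value]


def _rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background with the ImageJ-style shrink speed-up.

    For large radii the image is reduced with a block minimum (background lies
    under the features), the ball rolled on the small image, and the result
    upsampled; the background is clipped to stay under the surface.
    """
    if radius <= 12:
        return restoration.rolling_ball(image, radius=radius)
    shrink = 4 if radius <= 64 else 8
    pad_r = (-image.shape[0]) % shrink
    pad_c = (-image.shape[1]) % shrink
    padded = np.pad(image, ((0, pad_r), (0, pad_c)), mode="edge")
    small = block_reduce(padded, (shrink, shrink), np.min)
    bg_small = restoration.rolling_ball(small, radius=radius / shrink)
    bg = transform.resize(
        bg_small,
        padded.shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )[: image.shape[0], : image.shape[1]]
    return np.minimum(bg, image)


def subtract_background(
    frame: IntensityFrame,
    ball_radius: float = 80,
    light_background: bool = True,
) -> IntensityFrame:
    """Remove smooth illumination with the rolling-ball algorithm.

    ``ball_radius`` must exceed the diameter of the largest cell so that the
    ball cannot descend into cell footprints. With ``light_background`` (the
    bright-field case) the ball is rolled on the inverted image, so the
    corrected background sits at the top of the intensity range.
    """
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1 pixel")
    img = frame.pixels
    if light_background:
        inverted = INTENSITY_MAX - img
        bg_inv = _rolling_ball_background(inverted, ball_radius)
        corrected = INTENSITY_MAX - (inverted - bg_inv)
    else:
        bg = _rolling_ball_background(img, ball_radius)
        corrected = img - bg
    corrected = np.clip(corrected, 0, INTENSITY_MAX)
    return replace(frame, pixels=corrected)


def enhance_contrast(
    frame: IntensityFrame, saturation_fraction: float = 0.0035
) -> IntensityFrame:
    """Percentile linear stretch to the full 8-bit range.

    The (``saturation_fraction``, 1 − ``saturation_fraction``) intensity
    quantiles are mapped to (0, 255); values beyond them saturate. The mapping
    is monotone in input intensity. A degenerate (constant) frame is returned
    unchanged with a warning.
    """
    if not 0 <= saturation_fraction < 0.5:
        raise ValueError("saturation_fraction must lie in [0, 0.5)")
    img = frame.pixels
    lo, hi = np.quantile(img, [saturation_fraction, 1 - saturation_fraction])
    if hi <= lo:
        warnings.warn(
            "degenerate frame (no intensity spread); contrast left unchanged",
            stacklevel=2,
        )
        return replace(frame, pixels=img.copy())
    stretched = np.clip((img - lo) * (INTENSITY_MAX / (hi - lo)), 0, INTENSITY_MAX)
    return replace(frame, pixels=stretched)


def sobel_magnitude(frame: IntensityFrame) -> EdgeMap:
    """Gradient magnitude sqrt(Gx² + Gy²) from the standard 3×3 Sobel kernels.

    Borders are handled by reflection.
    """
    img = frame.pixels
    if min(img.shape) < 3:
        raise ValueError("frame must be at least 3×3 for the Sobel operator")
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    return EdgeMap(
        magnitude=np.hypot(gx, gy),
        provenance=("sobel_magnitude",),
        frame_index=frame.frame_index,
    )


def gaussian_smooth(edge_map: EdgeMap, sigma: float = 5.0) -> EdgeMap:
    """Isotropic Gaussian smoothing of the edge map (reflective borders).

    The default σ = 5 px suppresses responses from small noise particles
    before cell counting while leaving cell-scale structure intact.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = ndi.gaussian_filter(edge_map.magnitude, sigma=sigma, mode="reflect")
    return EdgeMap(
        magnitude=np.maximum(smoothed, 0.0),
        provenance=edge_map.provenance + (f"gaussian_smooth(sigma={sigma})",),
        frame_index=edge_map.frame_index,
    )


def rescale_to_8bit(edge_map: EdgeMap) -> EdgeMap:
    """Affine rescale of the edge map onto [0, 255].

    This fixes the scale on which the prominence acceptance threshold is
    expressed (the conventional convert-to-8-bit step). A constant map is
    returned as zeros.
    """
    m = edge_map.magnitude
    lo, hi = float(m.min()), float(m.max())
    scaled = np.zeros_like(m) if hi <= lo else (m - lo) * (INTENSITY_MAX / (hi - lo))
    return EdgeMap(
        magnitude=scaled,
        provenance=edge_map.provenance + ("rescale_to_8bit",),
        frame_index=edge_map.frame_index,
    )


def preprocess_frame(
    frame: IntensityFrame,
    ball_radius: float = 80,
    saturation_fraction: float = 0.0035,
    sigma: float = 5.0,
    smooth_before_edges: bool = False,
    light_background: bool = True,
) -> tuple[IntensityFrame, EdgeMap]:
    """Run the full chain: background → contrast → Sobel → Gaussian → 8-bit.

    Returns the background-corrected, contrast-stretched intensity frame (used
    for per-cell crops) and the smoothed 8-bit edge map (used for counting).
    ``smooth_before_edges`` applies the Gaussian to the intensity frame before
    the Sobel step instead of to the edge map (the alternative reading of the
    processing order); the default smooths the edge map.
    """
    if min(frame.shape) < MIN_FRAME_SIDE:
        raise ValueError(f"frames must be at least {MIN_FRAME_SIDE} px per side")
    corrected = subtract_background(frame, ball_radius, light_background)
    corrected = enhance_contrast(corrected, saturation_fraction)
    if smooth_before_edges:
        blurred = replace(
            corrected,
            pixels=ndi.gaussian_filter(corrected.pixels, sigma=sigma, mode="reflect"),
        )
        edges = sobel_magnitude(blurred)
        edges = EdgeMap(
            edges.magnitude,
            (f"gaussian_smooth(sigma={sigma})",) + edges.provenance,
            edges.frame_index,
        )
    else:
        edges = gaussian_smooth(sobel_magnitude(corrected), sigma)
    edges = rescale_to_8bit(edges)
    edges = EdgeMap(
        edges.magnitude,
        (
            f"subtract_background(radius={ball_radius})",
            f"enhance_contrast(saturation={saturation_fraction})",
        )
        + edges.provenance,
        frame.frame_index,
    )
    return corrected, edges
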