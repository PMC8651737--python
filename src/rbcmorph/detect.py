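"""Cell counting by prominence-filtered local maxima on the smoothed edge map,
plus per-cell crop extraction and the intact-cell / fragment split.

Each accepted local maximum marks one object (cell or fragment). A maximum is
accepted when it rises at least ``min_prominence`` grayscale units above both
the frame's noise floor (the map median) and its topographic key saddle —
the "prominence over the noise threshold" acceptance rule, evaluated on the
8-bit-rescaled smoothed edge map. Because Gaussian smoothing of a cell rim
produces a blob or annular crest rather than a sharp point, accepted peaks
are refined to the intensity-weighted centroid of their superlevel region,
which coincides with the cell centre for both blob- and ring-shaped
responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import reconstruction
from skimage.segmentation import flood

from .morphometry import BinaryMask
from .preprocess import EdgeMap, IntensityFrame

__all__ = [
    "DetectionPoint",
    "CellCrop",
    "find_cell_maxima",
    "peak_prominence",
    "peak_prominences",
    "extract_crop",
    "split_cells_fragments",
]


@dataclass(frozen=True)
class DetectionPoint:
    """One detected object location on the edge map."""

    position: tuple[float, float]  # (row, col), sub-pixel after refinement
    prominence: float
    height: float = 0.0
    frame_index: int = 0


@dataclass
class CellCrop:
    """Square sub-image around one detection, for morphometry."""

    patch: np.ndarray
    origin: tuple[int, int]  # (row, col) of patch[0, 0] in the parent frame
    source_point: DetectionPoint
    boundary_truncated: bool = False


def peak_prominence(magnitude: np.ndarray, peak: tuple[int, int]) -> float:
    """Topographic prominence of a local maximum.

    The key-saddle level is the highest level at which the peak's superlevel
    component still connects to strictly higher terrain, obtained with one
    grayscale reconstruction seeded by everything above the peak; the global
    maximum's prominence is its height above the map minimum.
    """
    v = float(magnitude[peak])
    floor = float(magnitude.min())
    seed = np.where(magnitude > v, magnitude, floor)
    if not (seed > floor).any():
        return v - floor
    rec = reconstruction(seed, magnitude, method="dilation")
    return v - float(rec[peak])


@numba.njit(cache=False)
def _persistence_pass(flat, order, height, width):  # pragma: no cover - jit
    """Superlevel-set persistence of a 2-D field by union-find.

    Pixels are inserted in descending value order; each union-find root is
    the index of its component's peak. When two components meet at a saddle
    the lower peak dies and its prominence (peak − saddle) is recorded.
    Returns per-pixel prominences (−1 for non-peaks) and, for each pixel, the
    root of its component at insertion time (used to look up the prominence
    of plateau members).
    """
    n = flat.size
    parent = np.full(n, -1, dtype=np.int64)
    prom = np.full(n, -1.0)
    rep = np.full(n, -1, dtype=np.int64)

    for k in range(n):
        idx = order[k]
        v = flat[idx]
        parent[idx] = idx
        r = idx // width
        c = idx % width
        for dr in range(-1, 2):
            rr = r + dr
            if rr < 0 or rr >= height:
                continue
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                cc = c + dc
                if cc < 0 or cc >= width:
                    continue
                nb = rr * width + cc
                if parent[nb] == -1:
                    continue
                # find roots with path halving
                ra = idx
                while parent[ra] != ra:
                    parent[ra] = parent[parent[ra]]
                    ra = parent[ra]
                rb = nb
                while parent[rb] != rb:
                    parent[rb] = parent[parent[rb]]
                    rb = parent[rb]
                if ra == rb:
                    continue
                if flat[ra] > flat[rb] or (flat[ra] == flat[rb] and ra < rb):
                    higher, lower = ra, rb
                else:
                    higher, lower = rb, ra
                prom[lower] = flat[lower] - v
                parent[lower] = higher
        rr2 = idx
        while parent[rr2] != rr2:
            parent[rr2] = parent[parent[rr2]]
            rr2 = parent[rr2]
        rep[idx] = rr2

    last = order[n - 1]
    root = last
    while parent[root] != root:
        root = parent[root]
    prom[root] = flat[root] - flat[last]
    return prom, rep


def peak_prominences(
    magnitude: np.ndarray, peaks: list[tuple[int, int]]
) -> list[float]:
    """Topographic prominence of several local maxima in one pass.

    Computes the full superlevel-set persistence of the map (8-connected) and
    reads off each peak's value; the global maximum's prominence is its
    height above the map minimum. Equivalent to calling
    :func:`peak_prominence` per peak, but one sweep over the image.
    """
    flat = np.ascontiguousarray(magnitude, dtype=np.float64).ravel()
    # stable sort: descending value, ties by ascending index
    order = np.argsort(-flat, kind="stable")
    prom, rep = _persistence_pass(flat, order, *magnitude.shape)
    out = []
    for r, c in peaks:
        idx = r * magnitude.shape[1] + c
        root = rep[idx]
        out.append(float(prom[root]) if flat[root] == flat[idx] else 0.0)
    return out


def _refine_position(
    magnitude: np.ndarray, peak: tuple[int, int], level: float
) -> tuple[float, float]:
    """Weighted centroid of the peak's connected superlevel region {m ≥ level}.

    The level sits just above the noise floor, so the region covers the
    object's whole edge response (an annulus for a cell rim, a blob for a
    fragment); its magnitude-weighted centroid lands on the object centre
    even when the raw maximum sits on an apex of the rim. Duplicate maxima on
    one rim refine to the same centre and are merged by the min-distance
    suppression.
    """
    delta = float(magnitude[peak]) - level
    if delta <= 0:
        return (float(peak[0]), float(peak[1]))
    region = flood(magnitude, peak, tolerance=delta)
    weights = np.where(region, magnitude - level, 0.0)
    total = weights.sum()
    if total <= 0:
        return (float(peak[0]), float(peak[1]))
    com = ndi.center_of_mass(weights)
    return (float(com[0]), float(com[1]))


def find_cell_maxima(
    edge_map: EdgeMap | np.ndarray,
    min_prominence: float = 50.0,
    min_distance: int = 20,
    noise_floor: str | float = "median",
    refine: bool = True,
    frame_index: int | None = None,
) -> list[DetectionPoint]:
    """Detect one point per object on a preprocessed edge map.

    Candidates are local maxima at least ``min_prominence`` above the noise
    floor; each must additionally have topographic prominence ≥
    ``min_prominence``. Surviving points closer than ``min_distance`` px are
    reduced to the highest-prominence one (ties broken by lower (row, col)).
    An empty or flat map yields an empty list.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1 px")
    if isinstance(edge_map, EdgeMap):
        magnitude = edge_map.magnitude
        fidx = edge_map.frame_index if frame_index is None else frame_index
    else:
        magnitude = np.asarray(edge_map, dtype=np.float64)
        fidx = 0 if frame_index is None else frame_index
    if magnitude.size == 0 or np.ptp(magnitude) == 0:
        return []
    floor = float(np.median(magnitude)) if noise_floor == "median" else float(noise_floor)
    coords = peak_local_max(
        magnitude,
        min_distance=3,
        threshold_abs=floor + min_prominence,
        exclude_border=False,
    )
    proms = peak_prominences(magnitude, [(int(r), int(c)) for r, c in coords])
    candidates = []
    for (r, c), prom in zip(coords, proms):
        if prom >= min_prominence:
            candidates.append(((int(r), int(c)), prom, float(magnitude[r, c])))
    if not candidates:
        return []
    if refine:
        level = floor + min_prominence / 2.0
        refined = [
            (_refine_position(magnitude, pk, level), prom, h)
            for pk, prom, h in candidates
        ]
    else:
        refined = [((float(pk[0]), float(pk[1])), prom, h) for pk, prom, h in candidates]
    refined.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))
    accepted: list[DetectionPoint] = []
    for pos, prom, h in refined:
        if all(math.dist(pos, p.position) >= min_distance for p in accepted):
            accepted.append(DetectionPoint(pos, prom, h, fidx))
    accepted.sort(key=lambda p: p.position)
    return accepted


def extract_crop(
    frame: IntensityFrame, point: DetectionPoint, window: int = 64
) -> CellCrop:
    """Square ``window``-sized patch centred on a detection point.

    Crops running past the frame border are clipped and flagged
    ``boundary_truncated`` (such partial cells are excluded from morphometry
    by default and tallied separately).
    """
    if window < 2:
        raise ValueError("window must be >= 2 px")
    h, w = frame.shape
    r, c = (int(round(point.position[0])), int(round(point.position[1])))
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"detection point {point.position} outside frame {frame.shape}")
    half = window // 2
    r0, r1 = r - half, r - half + window
    c0, c1 = c - half, c - half + window
    truncated = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    rr0, cc0 = max(r0, 0), max(c0, 0)
    patch = frame.pixels[rr0 : min(r1, h), cc0 : min(c1, w)].copy()
    return CellCrop(patch, (rr0, cc0), point, truncated)


def split_cells_fragments(
    crops: list[CellCrop], masks: list[BinaryMask], min_cell_area: float = 200.0
) -> tuple[list[tuple[CellCrop, BinaryMask]], list[tuple[CellCrop, BinaryMask]]]:
    """Route detected objects into intact cells vs. fragments by mask area.

    Objects whose binary footprint is smaller than ``min_cell_area`` px² are
    fragments/extracellular vesicles: tallied per frame but excluded from
    asymmetry and EI analysis.
    """
    if len(crops) != len(masks):
        raise ValueError("crops and masks must pair one-to-one")
    cells, fragments = [], []
    for crop, bmask in zip(crops, masks):
        if bmask.valid and bmask.area >= min_cell_area:
            cells.append((crop, bmask))
        else:
            fragments.append((crop, bmask))
    return cells, fragments
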