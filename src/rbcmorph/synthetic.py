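"""Ground-truthed synthetic bright-field micrographs of cells in shear flow.

Emulates the optical structure the analysis pipeline assumes: a bright
halogen-illuminated background with a smooth illumination ramp, dark-rimmed
ellipsoidal cells (sheared red blood cells deform into ellipsoids in a
viscous medium), two-lobe asymmetric cells standing in for morphologically
aberrant cells, and small dark fragments/vesicles, plus additive Gaussian
sensor noise. Every frame carries a per-cell ground-truth table so each
downstream stage can be tested without microscope data.

The canonical "abnormal" shape is a two-lobe composite: two half-ellipses
joined at a shared minor axis, the apex-side semi-major scaled by
``lobe_factor`` ≥ 1. It reduces exactly to a symmetric ellipse at
``lobe_factor`` = 1 and admits a closed-form radial profile per half, giving
an analytic oracle for the asymmetry score.

Orientation convention used package-wide: degrees counterclockwise from the
image-horizontal (+column) axis, with the row axis pointing down (so a 90°
orientation points toward smaller row indices, i.e. "up" on screen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .preprocess import IntensityFrame

__all__ = [
    "CellSpec",
    "FrameSpec",
    "SequenceSpec",
    "render_cell_mask",
    "render_frame",
    "render_sequence",
    "symmetric_cell_spec",
    "two_lobe_cell_spec",
    "fragment_spec",
]

SHAPE_KINDS = ("symmetric_ellipse", "two_lobe", "fragment")

#: largest semi-major axis (px) an object may have and still count as a fragment
DEFAULT_FRAGMENT_CAP = 4.0

DEFAULT_BACKGROUND = 200.0
DEFAULT_GRADIENT = 25.0
DEFAULT_NOISE_SD = 3.0
DEFAULT_EDGE_DROP = 120.0
#: interior darkening as a fraction of the rim drop (bright-field cells show a
#: dark rim and a lighter, but not background-bright, interior)
DEFAULT_INTERIOR_FRACTION = 0.45
DEFAULT_RIM_WIDTH = 2


@dataclass(frozen=True)
class CellSpec:
    """Geometry and contrast of one rendered object.

    ``center`` is the (row, col) of the geometric reference point: the ellipse
    centre, or for two-lobe shapes the midpoint of the shared minor axis.
    """

    shape_kind: str
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    lobe_factor: float = 1.0
    orientation: float = 0.0  # degrees CCW from image-horizontal
    edge_intensity_drop: float = DEFAULT_EDGE_DROP
    interior_drop_fraction: float = DEFAULT_INTERIOR_FRACTION
    fragment_cap: float = DEFAULT_FRAGMENT_CAP

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.lobe_factor < 1:
            raise ValueError("lobe_factor must be >= 1")
        if self.shape_kind == "fragment" and self.semi_major > self.fragment_cap:
            raise ValueError(
                f"fragment semi_major {self.semi_major} exceeds cap {self.fragment_cap}"
            )
        if self.edge_intensity_drop < 0:
            raise ValueError("edge_intensity_drop must be non-negative")

    @property
    def max_extent(self) -> float:
        """Largest distance from ``center`` to the boundary."""
        lam = self.lobe_factor if self.shape_kind == "two_lobe" else 1.0
        return self.semi_major * lam

    @property
    def true_elongation_index(self) -> float:
        """(A − B)/(A + B) from the full major/minor extents of the shape."""
        lam = self.lobe_factor if self.shape_kind == "two_lobe" else 1.0
        a_full = self.semi_major * (1.0 + lam)
        b_full = 2.0 * self.semi_minor
        return (a_full - b_full) / (a_full + b_full)

    @property
    def true_centroid(self) -> tuple[float, float]:
        """Analytic area centroid in frame coordinates (row, col)."""
        if self.shape_kind != "two_lobe" or self.lobe_factor == 1.0:
            return self.center
        # composite of two half-ellipses: centroid offset along the apex
        # direction is (4a/3π)(λ − 1) from the shared-axis midpoint
        a, lam = self.semi_major, self.lobe_factor
        offset = 4.0 * a * (lam - 1.0) / (3.0 * math.pi)
        theta = math.radians(self.orientation)
        d_col = offset * math.cos(theta)
        d_row = -offset * math.sin(theta)  # row axis points down
        return (self.center[0] + d_row, self.center[1] + d_col)


@dataclass(frozen=True)
class FrameSpec:
    """Parameters of one synthetic frame."""

    height: int = 256
    width: int = 256
    background_level: float = DEFAULT_BACKGROUND
    gradient_amplitude: float = DEFAULT_GRADIENT
    noise_sd: float = DEFAULT_NOISE_SD
    cells: tuple[CellSpec, ...] = ()
    seed: int = 0
    rim_width: int = DEFAULT_RIM_WIDTH
    allow_boundary: bool = False

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of a synthetic frame sequence.

    ``asymmetric_fraction_schedule`` maps frame index → expected fraction of
    intact cells rendered as two-lobe asymmetric shapes; each cell draws its
    kind independently (Bernoulli), and the realized fraction is recorded in
    the ground truth.
    """

    n_frames: int
    fps: float = 10.0
    asymmetric_fraction_schedule: Callable[[int], float] | Sequence[float] = 0.0  # type: ignore[assignment]
    n_cells: int = 8
    n_fragments: int = 2
    height: int = 448
    width: int = 448
    background_level: float = DEFAULT_BACKGROUND
    gradient_amplitude: float = DEFAULT_GRADIENT
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    margin: int = 68  # keeps crops un-truncated at the frame border
    min_separation: float = 85.0  # centre-to-centre, px
    cell_semi_major: tuple[float, float] = (22.0, 27.0)
    cell_aspect: tuple[float, float] = (1.7, 2.3)
    lobe_factor: float = 1.5
    fragment_semi_major: tuple[float, float] = (2.0, 3.5)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def schedule_value(self, frame_index: int) -> float:
        sched = self.asymmetric_fraction_schedule
        value = (
            float(sched)
            if isinstance(sched, (int, float))
            else float(sched(frame_index))
            if callable(sched)
            else float(sched[frame_index])
        )
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"schedule value {value} outside [0, 1]")
        return value


def _local_coords(
    spec: CellSpec, shape_hw: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rotated cell-frame coordinates (u along major axis, v along minor)."""
    rows = np.arange(shape_hw[0], dtype=np.float64)[:, None]
    cols = np.arange(shape_hw[1], dtype=np.float64)[None, :]
    x = cols - spec.center[1]
    y = spec.center[0] - rows  # y increases upward
    theta = math.radians(spec.orientation)
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    return u, v


def render_cell_mask(
    spec: CellSpec, shape_hw: tuple[int, int], allow_boundary: bool = False
) -> np.ndarray:
    """Render the filled binary footprint of one cell on a pixel grid.

    A two-lobe shape is two half-ellipses sharing the minor axis: semi-major
    ``semi_major * lobe_factor`` on the apex side and ``semi_major`` on the
    base side. Raises if the footprint would leave the grid unless
    ``allow_boundary`` is set.
    """
    r0, c0 = spec.center
    reach = spec.max_extent
    if not allow_boundary and (
        r0 - reach < -0.5
        or c0 - reach < -0.5
        or r0 + reach > shape_hw[0] - 0.5
        or c0 + reach > shape_hw[1] - 0.5
    ):
        raise ValueError("cell footprint exceeds the frame; set allow_boundary to permit")
    u, v = _local_coords(spec, shape_hw)
    a, b = spec.semi_major, spec.semi_minor
    if spec.shape_kind == "two_lobe" and spec.lobe_factor != 1.0:
        a_apex = a * spec.lobe_factor
        mask = np.where(
            u >= 0,
            (u / a_apex) ** 2 + (v / b) ** 2 <= 1.0,
            (u / a) ** 2 + (v / b) ** 2 <= 1.0,
        )
    else:
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def render_frame(spec: FrameSpec) -> tuple[IntensityFrame, pd.DataFrame]:
    """Render one frame and its ground-truth table.

    The frame is background + illumination ramp, minus per-cell intensity
    drops (full ``edge_intensity_drop`` on a rim of ``rim_width`` px, a
    fraction of it over the interior), plus clipped additive Gaussian noise.
    Deterministic for a fixed seed. Overlapping cells are flagged in the
    ground truth (detection guarantees are void for them).
    """
    h, w = spec.height, spec.width
    rows = np.linspace(0.0, 1.0, h)[:, None]
    cols = np.linspace(0.0, 1.0, w)[None, :]
    canvas = spec.background_level + spec.gradient_amplitude * (0.7 * cols + 0.3 * rows)

    drop = np.zeros((h, w))
    occupancy = np.zeros((h, w), dtype=np.int16)
    records = []
    masks = []
    for cid, cell in enumerate(spec.cells):
        mask = render_cell_mask(cell, (h, w), allow_boundary=spec.allow_boundary)
        interior = ndi.binary_erosion(mask, iterations=spec.rim_width)
        rim = mask & ~interior
        cell_drop = np.zeros((h, w))
        cell_drop[rim] = cell.edge_intensity_drop
        cell_drop[interior] = cell.edge_intensity_drop * cell.interior_drop_fraction
        drop = np.maximum(drop, cell_drop)
        occupancy += mask
        masks.append(mask)
        cr, cc = cell.true_centroid
        records.append(
            dict(
                cell_id=cid,
                kind=cell.shape_kind,
                center_row=cell.center[0],
                center_col=cell.center[1],
                centroid_row=cr,
                centroid_col=cc,
                semi_major=cell.semi_major,
                semi_minor=cell.semi_minor,
                lobe_factor=cell.lobe_factor,
                orientation=cell.orientation,
                true_ei=cell.true_elongation_index,
                overlaps=False,
            )
        )
    overlap_region = occupancy > 1
    if overlap_region.any():
        for rec, mask in zip(records, masks):
            rec["overlaps"] = bool((mask & overlap_region).any())

    canvas = canvas - drop
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    truth = pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "kind",
            "center_row",
            "center_col",
            "centroid_row",
            "centroid_col",
            "semi_major",
            "semi_minor",
            "lobe_factor",
            "orientation",
            "true_ei",
            "overlaps",
        ],
    )
    return IntensityFrame(pixels=canvas, bit_depth=8), truth


def symmetric_cell_spec(
    center: tuple[float, float], semi_major: float, semi_minor: float, orientation: float
) -> CellSpec:
    return CellSpec("symmetric_ellipse", center, semi_major, semi_minor, 1.0, orientation)


def two_lobe_cell_spec(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    lobe_factor: float,
    orientation: float,
) -> CellSpec:
    return CellSpec("two_lobe", center, semi_major, semi_minor, lobe_factor, orientation)


def fragment_spec(
    center: tuple[float, float], semi_major: float, semi_minor: float, orientation: float = 0.0
) -> CellSpec:
    return CellSpec("fragment", center, semi_major, semi_minor, 1.0, orientation)


def _place_centers(
    rng: np.random.Generator, n: int, spec: SequenceSpec
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping cell centres inside the safe margin."""
    lo_r, hi_r = spec.margin, spec.height - spec.margin
    lo_c, hi_c = spec.margin, spec.width - spec.margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("margin leaves no room for cell placement")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place cells at the requested density")
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(math.dist(cand, c) >= spec.min_separation for c in centers):
            centers.append(cand)
    return centers


def _frame_cells(
    rng: np.random.Generator, spec: SequenceSpec, p_asym: float
) -> tuple[tuple[CellSpec, ...], int]:
    centers = _place_centers(rng, spec.n_cells + spec.n_fragments, spec)
    cells: list[CellSpec] = []
    n_asym = 0
    for i in range(spec.n_cells):
        a = rng.uniform(*spec.cell_semi_major)
        b = a / rng.uniform(*spec.cell_aspect)
        ori = rng.uniform(0.0, 180.0)
        if rng.random() < p_asym:
            n_asym += 1
            cells.append(two_lobe_cell_spec(centers[i], a, b, spec.lobe_factor, ori))
        else:
            cells.append(symmetric_cell_spec(centers[i], a, b, ori))
    for j in range(spec.n_fragments):
        a = rng.uniform(*spec.fragment_semi_major)
        b = a / rng.uniform(1.0, 1.3)
        cells.append(
            fragment_spec(centers[spec.n_cells + j], a, b, rng.uniform(0.0, 180.0))
        )
    return tuple(cells), n_asym


def render_sequence(
    spec: SequenceSpec,
) -> tuple[list[IntensityFrame], pd.DataFrame, pd.DataFrame]:
    """Render an ordered frame sequence with per-frame and per-cell truth.

    Returns ``(frames, cell_truth, frame_truth)``; ``frame_truth`` records the
    realized asymmetric count/fraction per frame (the schedule is matched in
    expectation, per-cell draws are Bernoulli).
    """
    root = np.random.SeedSequence(spec.seed)
    frame_seeds = root.generate_state(spec.n_frames * 2, dtype=np.uint32)
    frames: list[IntensityFrame] = []
    cell_tables = []
    frame_records = []
    for i in range(spec.n_frames):
        p = spec.schedule_value(i)
        rng = np.random.default_rng(int(frame_seeds[2 * i]))
        cells, n_asym = _frame_cells(rng, spec, p)
        fspec = FrameSpec(
            height=spec.height,
            width=spec.width,
            background_level=spec.background_level,
            gradient_amplitude=spec.gradient_amplitude,
            noise_sd=spec.noise_sd,
            cells=cells,
            seed=int(frame_seeds[2 * i + 1]),
        )
        frame, truth = render_frame(fspec)
        frame = replace(frame, frame_index=i, timestamp=i / spec.fps)
        truth.insert(0, "frame_index", i)
        frames.append(frame)
        cell_tables.append(truth)
        frame_records.append(
            dict(
                frame_index=i,
                time_s=i / spec.fps,
                n_cells=spec.n_cells,
                n_fragments=spec.n_fragments,
                n_asymmetric_true=n_asym,
                scheduled_fraction=p,
                realized_fraction=n_asym / spec.n_cells if spec.n_cells else 0.0,
            )
        )
    cell_truth = pd.concat(cell_tables, ignore_index=True)
    frame_truth = pd.DataFrame(frame_records)
    return frames, cell_truth, frame_truth
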