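"""Per-cell shape analysis: binarization, apex alignment, radial profiles,
asymmetry scoring, and the elongation index.

The asymmetry score of a cell is computed from its radius-vs-angle profile:
after binarizing the crop and aligning the cell's apex vertically, the
distance from the centroid to the cell edge is measured for each angular
degree counterclockwise. The resulting bimodal curve (an elongated cell has
two radius peaks, one per apex) is split at its central nadir into two
half-curves with areas A1 and A2, and the score is the absolute relative
difference |(A1 − A2)/A1| × 100, in percent. A mirror-symmetric cell scores
zero. Because the score is a ratio of areas under the same curve, it is
invariant to area normalization (radii divided by the equivalent-circle
radius sqrt(area/π)), which is nevertheless applied so that profiles from
different magnifications and cell sizes are directly comparable.

Angle convention: 0° points along +column ("right"), angles increase
counterclockwise (toward smaller rows); after alignment the apex sits at 90°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure, transform
from skimage.filters import threshold_otsu

__all__ = [
    "BinaryMask",
    "RadialProfile",
    "NadirResult",
    "AsymmetryResult",
    "EIResult",
    "binarize_crop",
    "align_apex",
    "radial_profile",
    "normalize_profile",
    "find_central_nadir",
    "asymmetry_score",
    "score_from_areas",
    "elongation_index",
    "score_mask",
]

#: eigenvalue ratio of the inertia tensor below which a mask is isotropic
ISOTROPY_RATIO = 1.02

#: ray-marching step along each radial ray, px
RAY_STEP = 0.25

#: highest Fourier harmonic kept when locating profile extrema; the low-pass
#: suppresses pixel-quantization wiggles while keeping the bimodal structure
EXTREMA_HARMONICS = 8

#: minimum peak-to-peak variation of the low-passed profile, as a fraction of
#: the mean radius, for the profile to count as bimodal
MIN_PROFILE_VARIATION = 0.02

#: minima whose depth is within this fraction of the profile range of the
#: global minimum are treated as tied
MIN_TIE_FRACTION = 0.02


@dataclass
class BinaryMask:
    """Single-component binary cell footprint with sub-pixel centroid."""

    mask: np.ndarray
    area: int = 0
    centroid: tuple[float, float] = (0.0, 0.0)
    valid: bool = True
    flags: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_array(cls, mask: np.ndarray, flags: tuple[str, ...] = ()) -> "BinaryMask":
        mask = np.asarray(mask, dtype=bool)
        area = int(mask.sum())
        if area == 0:
            return cls(mask, 0, (0.0, 0.0), valid=False, flags=flags + ("empty",))
        centroid = ndi.center_of_mass(mask)
        return cls(mask, area, (float(centroid[0]), float(centroid[1])), True, flags)


@dataclass
class RadialProfile:
    """Per-degree centroid-to-edge radii of one binarized cell.

    ``radii[k]`` is the radius at angle ``k * angular_resolution`` degrees,
    counterclockwise from the +column direction.
    """

    radii: np.ndarray
    angular_resolution: float = 1.0
    normalized: bool = False
    equivalent_radius: float | None = None
    centroid_inside: bool = True

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=np.float64)
        expected = int(round(360.0 / self.angular_resolution))
        if len(self.radii) != expected:
            raise ValueError(
                f"profile length {len(self.radii)} != 360/resolution = {expected}"
            )

    @property
    def n(self) -> int:
        return len(self.radii)


@dataclass
class NadirResult:
    shift: float  # angle (deg) of the start minimum: the profile origin
    nadir_index: float  # angle (deg) of the central nadir past the start
    n_peaks: int
    valid: bool


@dataclass
class AsymmetryResult:
    nadir_index: float  # degrees past the start minimum
    shift: float  # degrees; start-minimum angle in the aligned frame
    A1: float
    A2: float
    score: float  # percent
    valid: bool
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class EIResult:
    major_axis_A: float
    minor_axis_B: float
    EI: float
    valid: bool = True


def binarize_crop(patch: np.ndarray, anchor: tuple[float, float] | None = None) -> BinaryMask:
    """Threshold a cell crop (Otsu on the crop histogram) into a binary mask.

    Cells are darker than the bright-field background, so the foreground is
    the sub-threshold region. The connected component nearest ``anchor``
    (default: the crop centre, where the detection point sits) is retained,
    interior holes are filled, and the centroid is the foreground's centre of
    mass. Returns an invalid mask if thresholding leaves no foreground.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a non-empty 2-D array")
    if np.ptp(patch) == 0:
        return BinaryMask(np.zeros(patch.shape, bool), valid=False, flags=("degenerate",))
    thr = threshold_otsu(patch)
    fg = patch < thr
    if not fg.any():
        return BinaryMask(fg, valid=False, flags=("empty_foreground",))
    labels, n_labels = ndi.label(fg)
    if anchor is None:
        anchor = ((patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0)
    if n_labels > 1:
        # keep the component closest to the anchor point
        rr, cc = np.nonzero(fg)
        d2 = (rr - anchor[0]) ** 2 + (cc - anchor[1]) ** 2
        target = labels[rr[np.argmin(d2)], cc[np.argmin(d2)]]
        fg = labels == target
    fg = ndi.binary_fill_holes(fg)
    return BinaryMask.from_array(fg)


def _principal_orientation(mask: np.ndarray) -> tuple[float, float]:
    """(orientation, eigenvalue ratio) from second-order central moments.

    Orientation follows the regionprops convention: angle in (−π/2, π/2]
    between the row axis and the major axis, counterclockwise.
    """
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    ev = rp.inertia_tensor_eigvals
    ratio = math.inf if ev[1] == 0 else ev[0] / ev[1]
    return rp.orientation, ratio


def _pad_for_rotation(mask: np.ndarray) -> np.ndarray:
    diag = int(math.ceil(math.hypot(*mask.shape)))
    pad_r = (diag - mask.shape[0]) // 2 + 2
    pad_c = (diag - mask.shape[1]) // 2 + 2
    return np.pad(mask, ((pad_r, pad_r), (pad_c, pad_c)))


def align_apex(bmask: BinaryMask) -> BinaryMask:
    """Rotate a mask about its centroid so the major axis is vertical, apex up.

    The principal axis comes from the second-order central moments; of the two
    vertical orientations, the apex — the major-axis extreme point farther
    from the centroid — is made to point toward smaller row indices. The mask
    is re-binarized after interpolation. Isotropic masks (inertia eigenvalue
    ratio < 1.02) are returned unrotated with an ``isotropic`` flag.
    """
    if not bmask.valid or bmask.area == 0:
        return bmask
    orientation, ratio = _principal_orientation(bmask.mask)
    if ratio < ISOTROPY_RATIO:
        return BinaryMask.from_array(bmask.mask, flags=bmask.flags + ("isotropic",))
    padded = _pad_for_rotation(bmask.mask)
    com = ndi.center_of_mass(padded)
    # regionprops orientation is measured CCW from the row axis in (row, col)
    # coordinates; skimage.transform.rotate with this angle brings the major
    # axis onto the row (vertical) axis.
    rotated = transform.rotate(
        padded.astype(np.float64),
        angle=-math.degrees(orientation),
        center=(com[1], com[0]),  # (col, row)
        order=1,
        preserve_range=True,
    )
    aligned = rotated >= 0.5
    aligned = ndi.binary_fill_holes(aligned)
    labels, n_labels = ndi.label(aligned)
    if n_labels == 0:
        return BinaryMask(aligned, valid=False, flags=bmask.flags + ("lost_in_rotation",))
    if n_labels > 1:
        sizes = ndi.sum_labels(aligned, labels, index=np.arange(1, n_labels + 1))
        aligned = labels == (1 + int(np.argmax(sizes)))
    result = BinaryMask.from_array(aligned, flags=bmask.flags + ("aligned",))
    rows = np.nonzero(result.mask.any(axis=1))[0]
    top_reach = result.centroid[0] - rows[0]
    bottom_reach = rows[-1] - result.centroid[0]
    if bottom_reach > top_reach:
        flipped = result.mask[::-1, ::-1]
        result = BinaryMask.from_array(flipped, flags=result.flags + ("apex_flipped",))
    return result


def radial_profile(
    bmask: BinaryMask,
    angular_resolution: float = 1.0,
    ray_step: float = RAY_STEP,
    angle_offset_deg: float = 0.0,
) -> RadialProfile:
    """Centroid-to-edge radius for each angular step, counterclockwise.

    Rays are marched outward from the centroid in ``ray_step`` px increments
    on the bilinearly interpolated mask; the radius is the first background
    crossing (mask value passing below 0.5), located sub-pixel by linear
    interpolation between the bracketing samples. A centroid that falls
    outside the foreground (extremely concave object) yields an invalid
    profile.

    ``angle_offset_deg`` casts the ray for profile entry k at absolute image
    angle ``k·resolution + offset``: profiling an unrotated mask with the
    offset set to its principal-axis angle − 90° is exactly the profile of
    the apex-aligned cell, without the interpolation error of resampling the
    mask raster.
    """
    n = int(round(360.0 / angular_resolution))
    maskf = bmask.mask.astype(np.float64)
    r0, c0 = bmask.centroid
    inside = (
        0 <= round(r0) < maskf.shape[0]
        and 0 <= round(c0) < maskf.shape[1]
        and bmask.mask[int(round(r0)), int(round(c0))]
    )
    if not inside:
        return RadialProfile(
            np.zeros(n), angular_resolution, centroid_inside=False
        )
    theta = np.deg2rad(np.arange(n) * angular_resolution + angle_offset_deg)
    max_r = math.hypot(*maskf.shape)
    steps = np.arange(ray_step, max_r + ray_step, ray_step)
    rr = r0 - np.outer(np.sin(theta), steps)  # CCW: +angle goes to smaller rows
    cc = c0 + np.outer(np.cos(theta), steps)
    values = ndi.map_coordinates(
        maskf, [rr.ravel(), cc.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(n, len(steps))
    first_bg = np.argmax(values < 0.5, axis=1)
    radii = np.empty(n)
    for k in range(n):
        i = first_bg[k]
        if values[k, i] >= 0.5:  # never crossed (should not happen)
            radii[k] = steps[-1]
            continue
        if i == 0:
            v_in, v_out = 1.0, values[k, 0]
            s_in = 0.0
        else:
            v_in, v_out = values[k, i - 1], values[k, i]
            s_in = steps[i - 1]
        frac = (v_in - 0.5) / (v_in - v_out) if v_in > v_out else 0.5
        radii[k] = s_in + frac * ray_step
    return RadialProfile(radii, angular_resolution)


def normalize_profile(profile: RadialProfile, area: float) -> RadialProfile:
    """Divide radii by the equivalent-circle radius sqrt(area/π).

    Area normalization makes profiles comparable across magnifications and
    cell volumes; the asymmetry score is unchanged (the factor cancels).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    r_eq = math.sqrt(area / math.pi)
    return RadialProfile(
        profile.radii / r_eq,
        profile.angular_resolution,
        normalized=True,
        equivalent_radius=r_eq,
        centroid_inside=profile.centroid_inside,
    )


def _circular_lowpass(values: np.ndarray, harmonics: int = EXTREMA_HARMONICS) -> np.ndarray:
    """Keep only Fourier harmonics up to ``harmonics`` of a circular signal."""
    spectrum = np.fft.rfft(values)
    spectrum[harmonics + 1 :] = 0.0
    return np.fft.irfft(spectrum, n=len(values))


#: a valley's region is the connected span below its minimum plus this
#: fraction of the profile range; deep enough to absorb low-pass ringing
#: micro-bumps, shallow enough never to cross the profile's main peaks
VALLEY_LEVEL_FRACTION = 0.35


def _valley_center(lp: np.ndarray, minimum: int) -> float:
    """Sub-bin valley position: depth-weighted angular centroid of the valley.

    The argmin of a flat valley is ill-conditioned (minute low-frequency
    profile error moves it by degrees, and the asymmetry score is sensitive
    to the split position), so the valley position is instead the centroid of
    the connected region around ``minimum`` lying below
    ``min + VALLEY_LEVEL_FRACTION·range``, weighted by depth below that
    level. Minima separated only by ringing bumps share a region and thus a
    centre. Returns a fractional circular index.
    """
    n = len(lp)
    level = lp[minimum] + VALLEY_LEVEL_FRACTION * np.ptp(lp)
    members = [0]
    for direction in (-1, +1):
        off = direction
        while abs(off) < n // 2 and lp[(minimum + off) % n] <= level:
            members.append(off)
            off += direction
    offsets = np.array(members, dtype=np.float64)
    weights = level - lp[(minimum + offsets.astype(int)) % n]
    if weights.sum() <= 0:
        return float(minimum)
    return float((minimum + np.sum(offsets * weights) / np.sum(weights)) % n)


def find_central_nadir(profile: RadialProfile) -> NadirResult:
    """Locate the nadir separating the two peaks of a bimodal radial profile.

    Extrema are located on a low-pass (first 8 circular harmonics) copy of the
    profile — pixel-quantization wiggles otherwise dominate the argmin — and
    refined to sub-degree positions with a depth-weighted valley centroid.
    The profile origin is placed at a global minimum so both peaks are
    interior; minima tied within 2% of the profile range are resolved to the
    one nearest the 0° direction (the cell's right side in the apex-aligned
    frame), which pins the half-curve ordering reproducibly for
    mirror-symmetric shapes. The central nadir is then the deepest minimum
    over the interior (90°, 270°) window past the origin. Profiles without
    two local maxima, or with peak-to-peak variation under 2% of the mean
    radius (e.g. a disk), are not bimodal and come back invalid.
    """
    if not profile.centroid_inside:
        return NadirResult(0.0, 0.0, 0, valid=False)
    r = profile.radii
    n = profile.n
    res = profile.angular_resolution
    lp = _circular_lowpass(r)
    mean_r = float(np.mean(r))
    if mean_r <= 0 or np.ptp(lp) < MIN_PROFILE_VARIATION * mean_r:
        return NadirResult(0.0, 0.0, 0, valid=False)
    prev_lp, next_lp = np.roll(lp, 1), np.roll(lp, -1)
    n_peaks = int(np.sum((lp > prev_lp) & (lp >= next_lp)))
    minima = np.nonzero((lp < prev_lp) & (lp <= next_lp))[0]
    if n_peaks < 2 or len(minima) < 2:
        return NadirResult(0.0, 0.0, n_peaks, valid=False)
    # one (centre, depth) entry per distinct valley: minima separated only by
    # low-pass ringing share a valley centre and collapse together
    valleys: dict[float, float] = {}
    for m in minima:
        center = round(_valley_center(lp, int(m)) * res, 3)
        depth = float(lp[m])
        valleys[center] = min(depth, valleys.get(center, math.inf))
    if len(valleys) < 2:
        return NadirResult(0.0, 0.0, n_peaks, valid=False)
    centers = np.array(sorted(valleys))
    depths = np.array([valleys[c] for c in centers])
    tol = MIN_TIE_FRACTION * np.ptp(lp)
    tied = centers[depths <= depths.min() + tol]
    # circular distance of each tied valley centre to the 0° direction
    dist0 = np.minimum(tied, 360.0 - tied)
    start = float(tied[np.argmin(dist0)])
    # central nadir: deepest valley in the interior window past the start
    rel = (centers - start) % 360.0
    interior = (rel > 90.0) & (rel < 270.0)
    if not interior.any():
        return NadirResult(start % 360.0, 0.0, n_peaks, valid=False)
    nadir_center = centers[interior][np.argmin(depths[interior])]
    nadir = (nadir_center - start) % 360.0
    return NadirResult(start % 360.0, nadir, n_peaks, valid=True)


def score_from_areas(a1: float, a2: float) -> float:
    """Absolute relative half-curve area difference, percent: |(A1−A2)/A1|·100."""
    if a1 == 0:
        raise ValueError("A1 must be non-zero")
    return abs((a1 - a2) / a1) * 100.0


def _circular_cumtrapz(radii: np.ndarray, res: float, angle: float) -> float:
    """∫₀^angle of the piecewise-linear circular profile (degree units)."""
    n = len(radii)
    angle = angle % 360.0
    pos = angle / res
    k = int(pos)
    frac = pos - k
    closed = np.append(radii, radii[0])
    full = np.cumsum(0.5 * (closed[:-1] + closed[1:]) * res)
    base = full[k - 1] if k > 0 else 0.0
    if frac > 0:
        r_at = closed[k] + frac * (closed[k + 1] - closed[k])
        base += 0.5 * (closed[k] + r_at) * frac * res
    return float(base)


def asymmetry_score(profile: RadialProfile, nadir: NadirResult) -> AsymmetryResult:
    """Split the profile at the central nadir and compare half-curve areas.

    A1 is the trapezoidal area under the radius-vs-angle curve from the start
    minimum to the nadir (traversed counterclockwise), A2 the remainder of
    the full turn; the score is |(A1 − A2)/A1| × 100 in percent. Areas are
    computed from the unsmoothed profile, with fractional-angle endpoints
    handled by linear interpolation.
    """
    if not nadir.valid or not profile.centroid_inside:
        return AsymmetryResult(0.0, 0.0, 0.0, 0.0, math.nan, valid=False, flags=("invalid_nadir",))
    res = profile.angular_resolution
    r = profile.radii
    total = float(np.trapezoid(np.append(r, r[0]), dx=res))
    c_start = _circular_cumtrapz(r, res, nadir.shift)
    c_nadir = _circular_cumtrapz(r, res, (nadir.shift + nadir.nadir_index) % 360.0)
    a1 = c_nadir - c_start
    if a1 < 0:
        a1 += total
    a2 = total - a1
    if a1 <= 0:
        return AsymmetryResult(
            nadir.nadir_index, nadir.shift, a1, a2, math.nan, valid=False, flags=("zero_area",)
        )
    return AsymmetryResult(
        nadir.nadir_index, nadir.shift, a1, a2, score_from_areas(a1, a2), valid=True
    )


def elongation_index(bmask: BinaryMask) -> EIResult:
    """EI = (A − B)/(A + B) from the aligned mask's axis extents.

    A is the extent along the principal (vertical, post-alignment) axis and B
    the perpendicular extent, measured between extreme foreground pixel
    centres. Degenerate masks (area < 4 px) are invalid.
    """
    if not bmask.valid or bmask.area < 4:
        return EIResult(0.0, 0.0, 0.0, valid=False)
    rows = np.nonzero(bmask.mask.any(axis=1))[0]
    cols = np.nonzero(bmask.mask.any(axis=0))[0]
    ext_v = float(rows[-1] - rows[0])
    ext_h = float(cols[-1] - cols[0])
    a, b = max(ext_v, ext_h), min(ext_v, ext_h)
    if b <= 0:
        return EIResult(a, b, 0.0, valid=False)
    return EIResult(a, b, (a - b) / (a + b), valid=True)


def principal_axis_angle(bmask: BinaryMask) -> float:
    """Major-axis direction in degrees CCW from +column (image convention).

    Computed from the second-order central moments of the foreground; the
    returned angle is in [0, 180).
    """
    rr, cc = np.nonzero(bmask.mask)
    x = cc - bmask.centroid[1]
    y = bmask.centroid[0] - rr  # y up
    var_x, var_y = np.mean(x * x), np.mean(y * y)
    cov_xy = np.mean(x * y)
    return math.degrees(0.5 * math.atan2(2.0 * cov_xy, var_x - var_y)) % 180.0


def score_mask(
    bmask: BinaryMask, angular_resolution: float = 1.0
) -> tuple[AsymmetryResult, EIResult, BinaryMask]:
    """Full per-cell morphometry: align, profile, normalize, nadir, score, EI.

    The profile is taken in the apex-aligned frame by casting rays at offset
    angles on the original mask (equivalent to profiling the rotated mask,
    minus the raster-resampling error); the apex — the major-axis direction
    with the larger centroid-to-edge radius — is placed at 90°. The aligned
    raster (used for the elongation-index extents) is also returned.
    """
    aligned = align_apex(bmask)
    if not aligned.valid:
        return (
            AsymmetryResult(0.0, 0.0, 0.0, 0.0, math.nan, False, aligned.flags),
            EIResult(0.0, 0.0, 0.0, valid=False),
            aligned,
        )
    if "isotropic" in aligned.flags:
        profile = radial_profile(bmask, angular_resolution)
    else:
        offset = principal_axis_angle(bmask) - 90.0
        profile = radial_profile(bmask, angular_resolution, angle_offset_deg=offset)
        if profile.centroid_inside:
            n = profile.n
            if profile.radii[(3 * n) // 4] > profile.radii[n // 4]:
                # apex was pointing down: rotate the frame by 180°
                profile = RadialProfile(
                    np.roll(profile.radii, -(n // 2)),
                    profile.angular_resolution,
                    centroid_inside=True,
                )
    profile = (
        normalize_profile(profile, bmask.area) if profile.centroid_inside else profile
    )
    nadir = find_central_nadir(profile)
    asym = asymmetry_score(profile, nadir)
    ei = elongation_index(aligned)
    return asym, ei, aligned
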