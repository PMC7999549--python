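"""Single-cell measurements from paired phase-contrast/fluorescence images.

Cells are segmented from the phase image (dark objects on a light
background), measured along their principal axes, and their fluorescence is
profiled along the normalised long or short axis. Populations are grouped
into cell-cycle stages by width or area (this symbiont widens as it
divides), group-mean demograph-style profiles are formed, and total
fluorescence is regressed on cell width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.measure import regionprops
from skimage.segmentation import clear_border


@dataclass
class CellMask:
    """One segmented cell: pixel coordinates (row, col) and the pixel size."""

    label: int
    coords: np.ndarray  # (n, 2) int array of (row, col)
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class CellGeometry:
    label: int
    length_um: float
    width_um: float
    area_um2: float
    volume_um3: float
    total_fluor: float
    concentration: float


@dataclass
class AxisProfile:
    """Unit-sum fluorescence distribution along a normalised cell axis."""

    axis: Literal["long", "short"]
    positions: np.ndarray  # bin centers in [0, 1]
    values: np.ndarray  # sums to 1


@dataclass
class ProfileGroup:
    n_cells: int
    key_range: tuple[float, float]
    profile: AxisProfile


@dataclass
class GroupedProfiles:
    sort_key: Literal["width", "area"]
    fractions: tuple[float, ...]
    groups: list[ProfileGroup]


def segment_cells(
    phase_image: np.ndarray, pixel_size_um: float, min_area_px: int = 50
) -> list[CellMask]:
    """Otsu-threshold dark-on-light cells, 8-connected components.

    Components smaller than ``min_area_px`` or touching the image border are
    discarded; surviving labels are dense from 1. An image without objects
    yields an empty list.
    """
    img = np.asarray(phase_image)
    if img.ndim != 2:
        raise ValueError("phase image must be a single 2-D channel")
    if img.max() == img.min():
        return []
    thresh = threshold_otsu(img)
    mask = img < thresh
    labeled = clear_border(_label(mask, connectivity=2))
    masks = []
    for prop in regionprops(labeled):
        if prop.area < min_area_px:
            continue
        masks.append(CellMask(len(masks) + 1, prop.coords.copy(), pixel_size_um))
    return masks


def capsule_volume(length_um: float, width_um: float) -> float:
    """Rod volume: cylinder with hemispherical caps; sphere when l < w."""
    r = width_um / 2.0
    if length_um >= width_um:
        return np.pi * r * r * (length_um - width_um) + (4.0 / 3.0) * np.pi * r**3
    return (4.0 / 3.0) * np.pi * r**3


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center, major axis, minor axis unit vectors from second moments."""
    pts = coords.astype(float)
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = eigvecs[:, -1]
    minor = eigvecs[:, 0]
    return center, major, minor


def _extent_um(proj: np.ndarray, pixel_size_um: float) -> float:
    # +1 pixel: projections are of pixel centers, extent spans whole pixels
    return (float(proj.max() - proj.min()) + 1.0) * pixel_size_um


def measure_cell(
    mask: CellMask, fluor_image: np.ndarray, background: float = 0.0
) -> CellGeometry:
    """Axis extents, background-subtracted fluorescence, model-based volume."""
    if len(mask.coords) < 5:
        raise ValueError("mask too small to measure (< 5 pixels)")
    center, major, minor = _principal_axes(mask.coords)
    d = mask.coords.astype(float) - center
    length = _extent_um(d @ major, mask.pixel_size_um)
    width = _extent_um(d @ minor, mask.pixel_size_um)
    if width > length:
        length, width = width, length
    area = len(mask.coords) * mask.pixel_size_um**2
    pix = fluor_image[mask.coords[:, 0], mask.coords[:, 1]].astype(float)
    total_fluor = float(np.clip(pix - background, 0.0, None).sum())
    volume = capsule_volume(length, width)
    return CellGeometry(
        label=mask.label,
        length_um=length,
        width_um=width,
        area_um2=area,
        volume_um3=volume,
        total_fluor=total_fluor,
        concentration=total_fluor / volume,
    )


def axis_profile(
    mask: CellMask,
    fluor_image: np.ndarray,
    background: float = 0.0,
    axis: Literal["long", "short"] = "long",
    n_bins: int = 100,
) -> AxisProfile:
    """Bin background-subtracted fluorescence along a normalised principal axis.

    Pixel coordinates are projected onto the chosen axis, min-max normalised
    to [0, 1] and binned; the profile is normalised to unit sum. The axis is
    oriented deterministically: the end whose pixels have the lower mean row
    index (mean column as tiebreak) is position 0.
    """
    center, major, minor = _principal_axes(mask.coords)
    vec = major if axis == "long" else minor
    d = mask.coords.astype(float) - center
    proj = d @ vec
    span = proj.max() - proj.min()
    if span == 0:
        raise ValueError("degenerate axis: zero variance along projection")
    low = proj <= np.median(proj)
    high = ~low
    if not np.any(high):
        high = proj > proj.min()
        low = ~high
    key_low = (mask.coords[low, 0].mean(), mask.coords[low, 1].mean())
    key_high = (mask.coords[high, 0].mean(), mask.coords[high, 1].mean())
    if key_low > key_high:
        proj = -proj
    norm = (proj - proj.min()) / span
    bins = np.clip((norm * n_bins).astype(int), 0, n_bins - 1)
    weights = np.clip(
        fluor_image[mask.coords[:, 0], mask.coords[:, 1]].astype(float) - background,
        0.0,
        None,
    )
    values = np.bincount(bins, weights=weights, minlength=n_bins)
    total = values.sum()
    if total <= 0:
        raise ValueError("no fluorescence above background in mask")
    positions = (np.arange(n_bins) + 0.5) / n_bins
    return AxisProfile(axis=axis, positions=positions, values=values / total)


def apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer group sizes from fractions by cumulative-remainder rounding.

    At each step the current group receives ``round_half_up(remaining_n *
    f_i / remaining_fraction)``, so sizes always sum to ``n`` (e.g. 1258
    cells at 0.6/0.2/0.1/0.1 -> 755, 252, 126, 125).
    """
    fr = [float(f) for f in fractions]
    if any(f <= 0 for f in fr):
        raise ValueError("fractions must be positive")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fr) > n:
        raise ValueError("more groups than cells")
    sizes = []
    remaining_n, remaining_f = n, sum(fr)
    for f in fr[:-1]:
        share = remaining_n * f / remaining_f
        size = int(np.floor(share + 0.5))  # round half up
        sizes.append(size)
        remaining_n -= size
        remaining_f -= f
    sizes.append(remaining_n)
    return sizes


def group_cells(
    cells: Sequence[CellGeometry],
    profiles: Sequence[AxisProfile],
    sort_key: Literal["width", "area"] = "width",
    fractions: Sequence[float] = (0.6, 0.2, 0.1, 0.1),
) -> GroupedProfiles:
    """Sort cells ascending by width or area and average profiles per group.

    Group sizes come from :func:`apportion`; each group's profile is the
    arithmetic mean of its members' unit-sum profiles, renormalised to unit
    sum. Groups are ordered thinnest/smallest first.
    """
    if len(cells) == 0:
        raise ValueError("no cells to group")
    if len(cells) != len(profiles):
        raise ValueError("cells and profiles must align")
    key = "width_um" if sort_key == "width" else "area_um2"
    values = np.array([getattr(c, key) for c in cells])
    order = np.argsort(values, kind="stable")
    sizes = apportion(len(cells), fractions)
    groups = []
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        start += size
        member_vals = values[idx]
        stacked = np.stack([profiles[i].values for i in idx])
        mean = stacked.mean(axis=0)
        mean = mean / mean.sum()
        groups.append(
            ProfileGroup(
                n_cells=size,
                key_range=(float(member_vals.min()), float(member_vals.max())),
                profile=AxisProfile(
                    axis=profiles[idx[0]].axis,
                    positions=profiles[idx[0]].positions,
                    values=mean,
                ),
            )
        )
    return GroupedProfiles(sort_key=sort_key, fractions=tuple(fractions), groups=groups)


def fluor_vs_width_fit(cells: Sequence[CellGeometry]) -> tuple[float, float, float]:
    """OLS of total fluorescence on cell width: (slope, intercept, pearson_r)."""
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for a fit")
    widths = np.array([c.width_um for c in cells])
    fluor = np.array([c.total_fluor for c in cells])
    if np.var(widths) == 0:
        raise ValueError("zero variance in cell width")
    fit = linregress(widths, fluor)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def count_profile_peaks(profile: AxisProfile, min_prominence: float = 0.2) -> int:
    """Local maxima after 3-bin smoothing with prominence >= fraction of max.

    An exactly flat profile has no local maxima and returns 0.
    """
    kernel = np.ones(3)
    # edge-corrected moving average: flat input stays exactly flat
    smoothed = np.convolve(profile.values, kernel, mode="same") / np.convolve(
        np.ones_like(profile.values), kernel, mode="same"
    )
    peak_max = smoothed.max()
    if peak_max <= 0 or np.ptp(smoothed) == 0:
        return 0
    peaks, _ = find_peaks(smoothed, prominence=min_prominence * peak_max)
    return int(len(peaks))


def estimate_background(image: np.ndarray, masks: Sequence[CellMask]) -> float:
    """Scalar background: mode of non-cell pixels (median for float images)."""
    covered = np.zeros(image.shape, dtype=bool)
    for m in masks:
        covered[m.coords[:, 0], m.coords[:, 1]] = True
    outside = np.asarray(image)[~covered]
    if outside.size == 0:
        return 0.0
    if np.issubdtype(outside.dtype, np.integer):
        return float(np.argmax(np.bincount(outside.ravel())))
    return float(np.median(outside))


def cells_to_frame(cells: Sequence[CellGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [c.label for c in cells],
            "length_um": [c.length_um for c in cells],
            "width_um": [c.width_um for c in cells],
            "area_um2": [c.area_um2 for c in cells],
            "volume_um3": [c.volume_um3 for c in cells],
            "total_fluor": [c.total_fluor for c in cells],
            "concentration": [c.concentration for c in cells],
        }
    )


def analyze_pair(
    phase_image: np.ndarray,
    fluor_image: np.ndarray,
    pixel_size_um: float,
    min_area_px: int = 50,
    background: float | None = None,
    n_bins: int = 100,
) -> tuple[list[CellGeometry], list[AxisProfile], list[AxisProfile], float]:
    """Segment, measure and profile one image pair.

    Returns (geometries, long-axis profiles, short-axis profiles,
    background used). Cells whose profile is degenerate are dropped from all
    outputs in lockstep.
    """
    masks = segment_cells(phase_image, pixel_size_um, min_area_px)
    if background is None:
        background = estimate_background(fluor_image, masks)
    geoms, longs, shorts = [], [], []
    for m in masks:
        try:
            geom = measure_cell(m, fluor_image, background)
            longp = axis_profile(m, fluor_image, background, "long", n_bins)
            shortp = axis_profile(m, fluor_image, background, "short", n_bins)
        except ValueError:
            continue
        geoms.append(geom)
        longs.append(longp)
        shorts.append(shortp)
    return geoms, longs, shorts, float(background)
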