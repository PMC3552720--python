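"""Myocardial regions, sector partition, curve extraction, Simpson volumes.

The analysis works on a single mid-ventricular short-axis slice.  The left
ventricle appears as a bright cavity (blood pool) surrounded by the
myocardial ring, which is divided into four equal angular sectors —
anterior, lateral, inferior and septal — about the cavity center.  One
static mask per physiologic state is applied to every frame of that state.

Coordinate conventions
----------------------
Pixels are addressed as ``(row, col)`` with 0-based indices.  Angles are
measured with ``x = col - center_col`` and ``y = -(row - center_row)`` so
that angles increase counter-clockwise in the displayed image, starting
from the anterior reference angle.  Frame indices are 0-based heartbeat
counts (one frame per heartbeat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, InputError, ParameterError

#: Sector names in counter-clockwise order starting at the reference angle.
SECTOR_NAMES_4 = ("anterior", "lateral", "inferior", "septal")


@dataclass
class TimeIntensityCurve:
    """Mean signal of one region over the dynamic series.

    Parameters
    ----------
    frames : array of int
        0-based frame indices in heartbeat units, strictly increasing.
    values : array of float
        Mean signal of the region at each frame; finite.
    region : str
        Region label, e.g. ``"cavity"`` or a sector name.
    state : str or None
        Physiologic state label (``rest``/``stress``/``recovery``).
    """

    frames: np.ndarray
    values: np.ndarray
    region: str = ""
    state: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape or self.frames.ndim != 1:
            raise InputError("frames and values must be 1-D and equal length")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise InputError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"non-finite values in curve for region {self.region!r}")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SegmentationMask:
    """Cavity and myocardium masks with per-pixel sector labels.

    ``sector_index`` holds ``-1`` outside the myocardium and ``0..n-1``
    inside, where index ``i`` maps to ``sector_names[i]``.
    """

    cavity: np.ndarray
    myocardium: np.ndarray
    sector_index: np.ndarray
    center: tuple[float, float]
    reference_angle: float = 0.0
    sector_names: tuple[str, ...] = SECTOR_NAMES_4

    def __post_init__(self) -> None:
        self.cavity = np.asarray(self.cavity, dtype=bool)
        self.myocardium = np.asarray(self.myocardium, dtype=bool)
        self.sector_index = np.asarray(self.sector_index, dtype=int)
        if np.any(self.cavity & self.myocardium):
            raise GeometryError("cavity and myocardium masks overlap")
        if np.any((self.sector_index >= 0) != self.myocardium):
            raise GeometryError("sector labels must exactly cover the myocardium")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cavity.shape

    def sector_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named sector."""
        try:
            idx = self.sector_names.index(name)
        except ValueError:
            raise InputError(f"unknown sector {name!r}") from None
        return self.sector_index == idx

    def sector_masks(self) -> dict[str, np.ndarray]:
        return {name: self.sector_index == i for i, name in enumerate(self.sector_names)}


@dataclass
class ContourStack:
    """Per-slice endocardial/epicardial areas for Simpson-disk volumetry.

    Areas are in mm^2; slice thickness and inter-slice gap in mm.
    """

    endo_areas_mm2: np.ndarray
    epi_areas_mm2: np.ndarray
    thickness_mm: float = 8.0
    gap_mm: float = 2.0

    def __post_init__(self) -> None:
        self.endo_areas_mm2 = np.atleast_1d(np.asarray(self.endo_areas_mm2, dtype=float))
        self.epi_areas_mm2 = np.atleast_1d(np.asarray(self.epi_areas_mm2, dtype=float))
        if self.endo_areas_mm2.size == 0:
            raise InputError("contour stack needs at least one slice")
        if np.any(self.endo_areas_mm2 < 0) or np.any(self.epi_areas_mm2 < 0):
            raise InputError("contour areas must be non-negative")
        if self.thickness_mm <= 0 or self.gap_mm < 0:
            raise ParameterError("thickness must be > 0 and gap >= 0")


def pixel_angles(
    shape: tuple[int, int], center: tuple[float, float]
) -> np.ndarray:
    """Counter-clockwise angle of every pixel about ``center`` (radians)."""
    rows, cols = np.indices(shape)
    x = cols - center[1]
    y = -(rows - center[0])  # image rows increase downward
    return np.arctan2(y, x)


def partition_sectors(
    cavity: np.ndarray,
    myocardium: np.ndarray,
    center: tuple[float, float],
    reference_angle: float = 0.0,
    n_sectors: int = 4,
) -> SegmentationMask:
    """Partition the myocardial ring into equal angular sectors.

    Each myocardial pixel is assigned by its polar angle about ``center``
    into one of ``n_sectors`` equal wedges of width ``2*pi/n_sectors``.
    Wedge 0 is *centered* on ``reference_angle`` and labeled ``anterior``;
    subsequent wedges proceed counter-clockwise through ``lateral``,
    ``inferior`` and ``septal`` (generic ``sector_i`` names when
    ``n_sectors != 4``).

    Raises
    ------
    GeometryError
        If the myocardium is empty.
    ParameterError
        If ``n_sectors < 1``.
    """
    myocardium = np.asarray(myocardium, dtype=bool)
    cavity = np.asarray(cavity, dtype=bool)
    if n_sectors < 1:
        raise ParameterError("n_sectors must be >= 1")
    if not myocardium.any():
        raise GeometryError("myocardium mask is empty")

    theta = pixel_angles(myocardium.shape, center)
    width = 2.0 * np.pi / n_sectors
    # shift by half a wedge so wedge 0 is centered on the reference angle
    rel = np.mod(theta - reference_angle + width / 2.0, 2.0 * np.pi)
    idx = np.floor(rel / width).astype(int)
    idx[idx == n_sectors] = 0  # guard against rel == 2*pi after rounding
    sector_index = np.where(myocardium, idx, -1)

    if n_sectors == 4:
        names = SECTOR_NAMES_4
    else:
        names = tuple(f"sector_{i}" for i in range(n_sectors))
    return SegmentationMask(
        cavity=cavity,
        myocardium=myocardium,
        sector_index=sector_index,
        center=center,
        reference_angle=reference_angle,
        sector_names=names,
    )


def extract_time_intensity(
    series: np.ndarray,
    region: np.ndarray,
    region_label: str = "",
    state: str | None = None,
) -> TimeIntensityCurve:
    """Region-mean time-intensity curve of a dynamic series.

    ``series`` has shape ``(n_frames, rows, cols)``; ``region`` is a boolean
    mask on the frame grid.  The value at frame ``t`` is the arithmetic mean
    of the pixels in the region at that frame.
    """
    series = np.asarray(series, dtype=float)
    region = np.asarray(region, dtype=bool)
    if series.ndim != 3:
        raise InputError("series must have shape (n_frames, rows, cols)")
    if region.shape != series.shape[1:]:
        raise GeometryError("region mask does not match the frame grid")
    if not region.any():
        raise GeometryError(f"region {region_label!r} is empty")
    values = series[:, region].mean(axis=1)
    return TimeIntensityCurve(
        frames=np.arange(series.shape[0]), values=values,
        region=region_label, state=state,
    )


def extract_all_curves(series: np.ndarray, mask: SegmentationMask,
                       state: str | None = None) -> dict[str, TimeIntensityCurve]:
    """Cavity plus per-sector curves, keyed by region label."""
    curves = {"cavity": extract_time_intensity(series, mask.cavity, "cavity", state)}
    for name, sector in mask.sector_masks().items():
        curves[name] = extract_time_intensity(series, sector, name, state)
    return curves


def simpson_volume(stack: ContourStack, which: str = "endocardial") -> float:
    """Simpson method-of-disks volume in mL.

    Each slice contributes ``area * (thickness + gap)``; the disk height
    includes the inter-slice gap, the common clinical convention for gapped
    short-axis stacks.  Result is converted mm^3 -> mL.
    """
    if which == "endocardial":
        areas = stack.endo_areas_mm2
    elif which == "epicardial":
        areas = stack.epi_areas_mm2
    else:
        raise InputError("which must be 'endocardial' or 'epicardial'")
    height = stack.thickness_mm + stack.gap_mm
    return float(np.sum(areas) * height / 1000.0)


def ejection_fraction(ed_stack: ContourStack, es_stack: ContourStack) -> float:
    """LV ejection fraction (EDV - ESV) / EDV from two contour stacks."""
    edv = simpson_volume(ed_stack, "endocardial")
    esv = simpson_volume(es_stack, "endocardial")
    if edv <= 0:
        raise InputError("end-diastolic volume must be positive")
    return (edv - esv) / edv
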