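"""Semi-automated geographic-atrophy quantification.

The depolarizing-RPE mask is reduced to an en-face *thickness map* by
counting depolarizing pixels along each A-line within an axial *evaluation
band* centred on the RPE/Bruch complex (excluding choroidal depolarizing
signal below the band).  The thickness map is binarized — atrophy is absence
of depolarizing tissue — smoothed, and partitioned into 8-connected patches
whose areas follow from the known en-face pixel area.  Patches at or above
the detection floor (0.1 mm^2) are geographic-atrophy lesions; smaller ones
are kept as sub-threshold components and feed the focal-atrophy classifier.

The band is fitted automatically from the mask's per-A-line depth centroid;
per-B-scan manual overrides reproduce the study's "semi-automated" band
adjustment in a file-driven, reproducible way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .dopu import RpeMask
from .geometry import ScanGeometry

__all__ = [
    "EvaluationBand",
    "ThicknessMap",
    "AtrophyMap",
    "GaLesion",
    "GaLesionSet",
    "fit_evaluation_band",
    "depolarizing_thickness_map",
    "binarize_and_smooth",
    "detect_ga_lesions",
]


@dataclass
class EvaluationBand:
    """Axial band per A-line: depths in ``[upper, lower)`` are evaluated."""

    upper: np.ndarray  # (n_bscans, n_ascans) int
    lower: np.ndarray
    source: str = "auto"
    overridden_bscans: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.upper.shape != self.lower.shape:
            raise ValueError("band bound arrays must share a shape")
        if np.any(self.upper < 0) or np.any(self.upper >= self.lower):
            raise ValueError("band requires 0 <= upper < lower for every A-line")


@dataclass
class ThicknessMap:
    """En-face counts of depolarizing pixels within the evaluation band."""

    counts: np.ndarray  # (n_bscans, n_ascans) int
    geometry: ScanGeometry
    band: EvaluationBand | None = None


@dataclass
class AtrophyMap:
    """Binarized, smoothed en-face atrophy grid with its parameters."""

    atrophic: np.ndarray  # bool
    geometry: ScanGeometry
    atrophy_count_max: int = 0
    smooth_radius_px: int = 1


@dataclass
class GaLesion:
    lesion_id: int
    pixels: np.ndarray  # (n, 2) array of (b_scan, a_scan) indices
    n_pixels: int
    area_mm2: float
    centroid_x_mm: float
    centroid_y_mm: float


@dataclass
class GaLesionSet:
    """Connected atrophic patches split at the minimal detectable GA area."""

    lesions: list[GaLesion]
    subthreshold: list[GaLesion]
    min_area_mm2: float
    geometry: ScanGeometry
    total_area_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_area_mm2 = float(sum(l.area_mm2 for l in self.lesions))

    def subthreshold_enface(self) -> np.ndarray:
        """Boolean en-face grid of all sub-threshold component pixels."""
        grid = np.zeros(
            (self.geometry.n_bscans, self.geometry.n_ascans), dtype=bool
        )
        for lesion in self.subthreshold:
            grid[lesion.pixels[:, 0], lesion.pixels[:, 1]] = True
        return grid


def _interp_nan(values: np.ndarray) -> np.ndarray:
    """Fill NaN runs by linear interpolation from flanking finite samples."""
    out = values.copy()
    bad = ~np.isfinite(out)
    if bad.all():
        return out
    idx = np.arange(out.size)
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def fit_evaluation_band(
    mask: RpeMask,
    margin_up_px: int = 12,
    margin_down_px: int = 12,
    manual: dict[int, tuple[int, int]] | None = None,
    median_window: int = 31,
) -> EvaluationBand:
    """Fit the evaluation band around the depolarizing-RPE depth centroid.

    Per A-line the band is ``[centroid - margin_up, centroid + margin_down]``
    (inclusive), with the centroid profile smoothed along the A-scan axis by
    a running median and holes (A-lines with no depolarizing pixel, e.g.
    inside atrophy) filled by interpolation from flanking A-lines.  Entries
    of ``manual`` — ``{b_scan: (upper, lower)}`` — replace the automatic
    bounds for whole B-scans.
    """
    m = mask.mask
    nb, na, nd = m.shape
    manual = manual or {}
    if not m.any() and not manual:
        raise ValueError(
            "cannot fit an evaluation band: empty mask and no manual overrides"
        )
    zs = np.arange(nd, dtype=np.float64)
    weight = m.sum(axis=2).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        centroid = (m * zs).sum(axis=2) / weight
    centroid[weight == 0] = np.nan

    upper = np.zeros((nb, na), dtype=np.int64)
    lower = np.zeros((nb, na), dtype=np.int64)
    for b in range(nb):
        row = _interp_nan(centroid[b])
        if not np.isfinite(row).any():
            if b in manual:
                continue  # will be overridden below
            raise ValueError(
                f"B-scan {b} has no depolarizing pixels and no manual override"
            )
        row = ndimage.median_filter(row, size=median_window, mode="nearest")
        c = np.rint(row).astype(np.int64)
        upper[b] = np.clip(c - margin_up_px, 0, nd - 1)
        lower[b] = np.clip(c + margin_down_px + 1, 1, nd)
    for b, (up, lo) in manual.items():
        upper[b] = up
        lower[b] = lo
    return EvaluationBand(
        upper=upper,
        lower=lower,
        source="manual" if manual else "auto",
        overridden_bscans=tuple(sorted(manual)),
    )


def depolarizing_thickness_map(mask: RpeMask, band: EvaluationBand) -> ThicknessMap:
    """Count depolarizing pixels per A-line within ``[upper, lower)``."""
    m = mask.mask
    if band.upper.shape != m.shape[:2]:
        raise ValueError(
            f"band shape {band.upper.shape} does not match mask en-face "
            f"shape {m.shape[:2]}"
        )
    zs = np.arange(m.shape[2])[None, None, :]
    in_band = (zs >= band.upper[:, :, None]) & (zs < band.lower[:, :, None])
    counts = (m & in_band).sum(axis=2)
    return ThicknessMap(counts=counts.astype(np.int64), geometry=mask.geometry, band=band)


def binarize_and_smooth(
    tmap: ThicknessMap, atrophy_count_max: int = 0, smooth_radius_px: int = 1
) -> AtrophyMap:
    """Binarize the thickness map and smooth the atrophy grid.

    A cell is atrophic when its depolarizing-pixel count is at most
    ``atrophy_count_max`` (default 0: atrophy is the absence of depolarizing
    RPE).  Smoothing is a 3x3 median filter followed by morphological
    closing then opening with a disc of ``smooth_radius_px`` (radius 0
    disables all smoothing).
    """
    if atrophy_count_max < 0:
        raise ValueError("atrophy_count_max must be >= 0")
    atrophic = tmap.counts <= atrophy_count_max
    if smooth_radius_px > 0:
        atrophic = ndimage.median_filter(atrophic, size=3, mode="nearest")
        footprint = morphology.disk(smooth_radius_px)
        atrophic = morphology.closing(atrophic, footprint)
        atrophic = morphology.opening(atrophic, footprint)
    return AtrophyMap(
        atrophic=atrophic,
        geometry=tmap.geometry,
        atrophy_count_max=atrophy_count_max,
        smooth_radius_px=smooth_radius_px,
    )


def detect_ga_lesions(
    amap: AtrophyMap, geometry: ScanGeometry | None = None, min_area_mm2: float = 0.1
) -> GaLesionSet:
    """8-connected atrophic patches, scaled by the known pixel area.

    Patches of area below ``min_area_mm2`` (the algorithm's minimal
    detectable GA area) are excluded from the lesion list but retained as
    sub-threshold components for the focal-atrophy classifier.  Lesions are
    sorted by area descending, ties broken by the top-left-most pixel.
    """
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    geometry = geometry or amap.geometry
    px_area = geometry.pixel_area_mm2
    labels = measure.label(amap.atrophic, connectivity=2)
    entries = []
    for region in measure.regionprops(labels):
        pixels = region.coords  # (n, 2): (row=b, col=a), sorted row-major
        area = region.num_pixels * px_area
        cy, cx = region.centroid
        entries.append(
            GaLesion(
                lesion_id=-1,
                pixels=pixels,
                n_pixels=region.num_pixels,
                area_mm2=float(area),
                centroid_x_mm=float((cx + 0.5) * geometry.pixel_width_mm),
                centroid_y_mm=float((cy + 0.5) * geometry.pixel_height_mm),
            )
        )
    entries.sort(key=lambda l: (-l.area_mm2, l.pixels[0, 0], l.pixels[0, 1]))
    lesions, sub = [], []
    for entry in entries:
        bucket = lesions if entry.area_mm2 >= min_area_mm2 else sub
        entry.lesion_id = len(bucket) + 1
        bucket.append(entry)
    return GaLesionSet(
        lesions=lesions,
        subthreshold=sub,
        min_area_mm2=min_area_mm2,
        geometry=geometry,
    )
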