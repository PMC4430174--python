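"""Rule-based classification of RPE lesion types on B-scans.

The study graded five lesion types as present/absent (0/1) on every B-scan
of every visit:

* **porosity** — a series of RPE gaps, with depolarizing residuals in
  between, spanning at least 20% of the B-scan width (cumulatively);
* **focal atrophy** — isolated atrophic regions too small to be quantified
  as geographic atrophy (the sub-threshold components of the GA detector);
* **thinning** — segmented band thinner than half the normal thickness over
  at least 10% of the B-scan width (contiguously);
* **accumulation at the RPE level** — band at least twice the normal
  thickness;
* **ectopic depolarizing material** — depolarizing foci in outer retinal
  layers, discontinuous from the RPE band.

"Normal" band thickness is the median of non-zero thickness counts outside
the lesion area.  Width thresholds flip exactly at the ceiling of the
fractional width, evaluated exactly (no float drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dopu import RpeMask
from .ga_quant import EvaluationBand, ThicknessMap

__all__ = [
    "RuleParams",
    "BScanGrade",
    "NormalRpeThickness",
    "EctopicFocus",
    "EyeVisitRecord",
    "estimate_normal_thickness",
    "gap_runs",
    "grade_bscan",
    "detect_ectopic_foci",
    "score_eye_visit",
]


@dataclass(frozen=True)
class RuleParams:
    """Tunable thresholds of the lesion rules.

    Fraction/factor values mirror the study's printed definitions; the
    pixel minima are plumbing floors that suppress single-pixel noise.
    """

    atrophy_count_max: int = 0
    min_gap_px: int = 3
    min_thick_px: int = 5
    min_sep_px: int = 5
    min_focus_voxels: int = 3
    porosity_min_gaps: int = 3
    porosity_min_residuals: int = 2
    porosity_width_fraction: float = 0.2
    porosity_cumulative: bool = True
    thinning_width_fraction: float = 0.1
    thinning_factor: float = 0.5
    accumulation_factor: float = 2.0


@dataclass
class BScanGrade:
    """0/1 grades for one B-scan plus the evidence behind each."""

    porosity: bool = False
    focal_atrophy: bool = False
    thinning: bool = False
    accumulation_rpe_level: bool = False
    gap_runs: list[tuple[int, int]] = field(default_factory=list)
    residual_runs: list[tuple[int, int]] = field(default_factory=list)
    thin_runs: list[tuple[int, int]] = field(default_factory=list)
    thick_runs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class NormalRpeThickness:
    """Reference band thickness in pixels with its estimation region."""

    value: float
    n_cells: int
    region: str = "all non-zero cells"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("normal RPE thickness must be positive")


@dataclass
class EctopicFocus:
    voxels: np.ndarray  # (n, 3) of (b, a, z)
    n_voxels: int
    centroid: tuple[float, float, float]


@dataclass
class EyeVisitRecord:
    """Per-eye per-visit unit of the cohort statistics."""

    eye_id: str
    visit_month: int
    porosity: int = 0
    focal_atrophy: int = 0
    thinning: int = 0
    accumulation_rpe_level: int = 0
    ectopic_material: int = 0
    ga: int = 0
    ga_area_mm2: float = 0.0
    crt_um: float | None = None
    bcva_letters: float | None = None
    flags: dict = field(default_factory=dict)

    LESION_TYPES = (
        "porosity",
        "focal_atrophy",
        "thinning",
        "accumulation_rpe_level",
        "ectopic_material",
        "ga",
    )

    def presence(self) -> dict[str, int]:
        return {t: getattr(self, t) for t in self.LESION_TYPES}


def width_threshold(n_ascans: int, fraction: float) -> int:
    """Smallest pixel width satisfying ``width >= fraction * n_ascans``.

    Evaluated with a tolerance so that e.g. 20% of 510 A-scans is exactly
    102 despite binary-float representation of 0.2.
    """
    return int(math.ceil(fraction * n_ascans - 1e-9))


def _runs(condition: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs ``(start, stop)``."""
    padded = np.diff(np.concatenate(([0], condition.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def estimate_normal_thickness(
    tmap: ThicknessMap,
    lesion_exclusion_mask: np.ndarray | None = None,
    min_cell_fraction: float = 0.05,
) -> NormalRpeThickness:
    """Median of non-zero thickness counts outside the excluded region."""
    counts = tmap.counts
    if lesion_exclusion_mask is None:
        available = np.ones_like(counts, dtype=bool)
        region = "all non-zero cells"
    else:
        if lesion_exclusion_mask.shape != counts.shape:
            raise ValueError("exclusion mask shape mismatch")
        available = ~lesion_exclusion_mask
        region = "non-zero cells outside exclusion mask"
    if available.sum() < min_cell_fraction * counts.size:
        raise ValueError(
            "fewer than {:.0%} of cells available for the normal-thickness "
            "estimate".format(min_cell_fraction)
        )
    values = counts[available & (counts > 0)]
    if values.size == 0:
        raise ValueError("no non-zero thickness cells to estimate from")
    return NormalRpeThickness(
        value=float(np.median(values)), n_cells=int(values.size), region=region
    )


def gap_runs(
    row: np.ndarray, atrophy_count_max: int = 0, min_gap_px: int = 3
) -> list[tuple[int, int]]:
    """Runs of at least ``min_gap_px`` consecutive gap A-lines."""
    runs = _runs(np.asarray(row) <= atrophy_count_max)
    return [(a, b) for a, b in runs if b - a >= min_gap_px]


def grade_bscan(
    bscan_tmap_row: np.ndarray,
    normal: "NormalRpeThickness | float",
    params: RuleParams = RuleParams(),
    subthreshold_enface_row: np.ndarray | None = None,
) -> BScanGrade:
    """Apply the porosity / focal-atrophy / thinning / accumulation rules.

    ``bscan_tmap_row`` is the thickness-map row of one B-scan (one count
    per A-line).  ``subthreshold_enface_row`` marks A-lines of this B-scan
    covered by sub-threshold atrophic components; a gap intersecting it is
    focal atrophy.
    """
    row = np.asarray(bscan_tmap_row)
    if row.size == 0:
        raise ValueError("zero-length thickness row")
    normal_value = normal.value if isinstance(normal, NormalRpeThickness) else float(normal)
    if normal_value <= 0:
        raise ValueError("normal thickness must be positive")
    n = row.size
    grade = BScanGrade()

    gaps = gap_runs(row, params.atrophy_count_max, params.min_gap_px)
    grade.gap_runs = gaps
    if gaps:
        # residual runs interleaved strictly between the first and last gap
        first, last = gaps[0][1], gaps[-1][0]
        interleaved = [
            (a, b)
            for a, b in _runs(row > params.atrophy_count_max)
            if a >= first and b <= last
        ]
        grade.residual_runs = interleaved
        if params.porosity_cumulative:
            gap_width = sum(b - a for a, b in gaps)
        else:
            gap_width = max(b - a for a, b in gaps)
        grade.porosity = (
            len(gaps) >= params.porosity_min_gaps
            and len(interleaved) >= params.porosity_min_residuals
            and gap_width >= width_threshold(n, params.porosity_width_fraction)
        )
        if subthreshold_enface_row is not None:
            sub = np.asarray(subthreshold_enface_row, dtype=bool)
            grade.focal_atrophy = any(sub[a:b].any() for a, b in gaps)

    thin = (row > params.atrophy_count_max) & (
        row < params.thinning_factor * normal_value
    )
    grade.thin_runs = _runs(thin)
    thin_min = width_threshold(n, params.thinning_width_fraction)
    grade.thinning = any(b - a >= thin_min for a, b in grade.thin_runs)

    thick = row >= params.accumulation_factor * normal_value
    grade.thick_runs = _runs(thick)
    grade.accumulation_rpe_level = any(
        b - a >= params.min_thick_px for a, b in grade.thick_runs
    )
    return grade


def detect_ectopic_foci(
    mask: RpeMask, band: EvaluationBand, params: RuleParams = RuleParams()
) -> list[EctopicFocus]:
    """Depolarizing foci in outer retinal layers, discontinuous from the RPE.

    26-connected components of the depolarizing mask qualify when their
    entire extent lies at least ``min_sep_px`` above the band's upper bound
    for every A-line they touch (so they share no connected path with any
    in-band component) and they contain at least ``min_focus_voxels`` voxels.
    """
    m = mask.mask
    if band.upper.shape != m.shape[:2]:
        raise ValueError("band does not match mask dimensions")
    labels, n_labels = ndimage.label(m, structure=np.ones((3, 3, 3), dtype=int))
    foci: list[EctopicFocus] = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab)
        upper = band.upper[coords[:, 0], coords[:, 1]]
        if np.all(coords[:, 2] <= upper - params.min_sep_px):
            if len(coords) >= params.min_focus_voxels:
                foci.append(
                    EctopicFocus(
                        voxels=coords,
                        n_voxels=len(coords),
                        centroid=tuple(coords.mean(axis=0)),
                    )
                )
    foci.sort(key=lambda f: f.centroid)
    return foci


def score_eye_visit(
    eye_id: str,
    visit_month: int,
    lesion_set,
    bscan_grades: list[BScanGrade],
    foci: list[EctopicFocus],
    n_bscans: int,
    crt_um: float | None = None,
    bcva_letters: float | None = None,
) -> EyeVisitRecord:
    """Roll per-B-scan grades up to the eye-visit 0/1 presence vector.

    A lesion type is present when any graded B-scan is positive; ectopic
    material and GA are evaluated at volume level (any focus / non-empty
    lesion set).  All B-scans must have been graded.
    """
    if len(bscan_grades) != n_bscans:
        raise ValueError(
            f"expected grades for {n_bscans} B-scans, got {len(bscan_grades)}"
        )
    return EyeVisitRecord(
        eye_id=eye_id,
        visit_month=visit_month,
        porosity=int(any(g.porosity for g in bscan_grades)),
        focal_atrophy=int(any(g.focal_atrophy for g in bscan_grades)),
        thinning=int(any(g.thinning for g in bscan_grades)),
        accumulation_rpe_level=int(
            any(g.accumulation_rpe_level for g in bscan_grades)
        ),
        ectopic_material=int(len(foci) > 0),
        ga=int(len(lesion_set.lesions) > 0),
        ga_area_mm2=float(lesion_set.total_area_mm2),
        crt_um=crt_um,
        bcva_letters=bcva_letters,
    )
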