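"""Synthetic polarization-sensitive OCT phantoms with known ground truth.

No imaging data accompany the study this package operationalizes, so every
stage of the pipeline is exercised against seeded synthetic volumes that
emulate the acquisition protocol: a 6.2 x 6.7 mm^2 raster of B-scans, a
depolarizing RPE band at a configurable depth, and plantable lesions drawn
from the study's taxonomy (gap series / porosity, focal atrophy, geographic
atrophy patches, thinning, thickening, ectopic depolarizing foci).

Depolarization model
--------------------
Every voxel is fully polarized per pixel; tissue outside the RPE carries a
common incident Stokes direction, while RPE voxels carry directions obtained
by spherical interpolation (slerp) between the incident direction and an
independent uniformly random unit direction, with weight ``depol_strength``.
Window-averaged DOPU therefore decreases monotonically with
``depol_strength`` while each voxel remains physical (sqrt(Q^2+U^2+V^2) <= I).
Ground truth is a function of the phantom specification alone and is
invariant to the noise seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage import measure

from .dopu import StokesVolume
from .geometry import ScanGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "LesionRecord",
    "EyeSpec",
    "CohortSpec",
    "CohortRecord",
    "generate_phantom",
    "generate_cohort",
    "eligibility_filter",
    "INCIDENT_STOKES_DIRECTION",
]

#: Normalized Stokes direction of the (noise-free) incident / preserved state.
INCIDENT_STOKES_DIRECTION = np.array([1.0, 0.0, 0.0])

LESION_KINDS = (
    "gap_series",
    "focal_atrophy",
    "ga_patch",
    "thinning",
    "thickening",
    "ectopic_focus",
)


@dataclass
class LesionSpec:
    """En-face footprint and axial parameters of one planted lesion.

    ``center_mm`` is (x, y) with x along the fast axis.  ``ga_patch`` uses
    ``radius_mm`` (circular in physical mm, hence elliptical in pixels);
    rectangular kinds use ``width_mm``/``height_mm``; ``gap_series`` plants
    ``n_gaps`` gaps of ``gap_width_mm`` separated by ``residual_width_mm``
    starting at ``start_mm``; ``ectopic_focus`` plants a cube of side
    ``size_px`` whose bottom lies ``depth_offset_px`` above the RPE top.
    """

    kind: str
    center_mm: tuple[float, float] | None = None
    radius_mm: float | None = None
    width_mm: float | None = None
    height_mm: float | None = None
    thickness_factor: float | None = None
    start_mm: float | None = None
    n_gaps: int | None = None
    gap_width_mm: float | None = None
    residual_width_mm: float | None = None
    depth_offset_px: int | None = None
    size_px: int = 3
    lesion_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")

    # ---- en-face extent in mm, used for the inside-scan-area check ----
    def extent_mm(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the en-face footprint."""
        if self.kind == "gap_series":
            if None in (self.start_mm, self.n_gaps, self.gap_width_mm,
                        self.residual_width_mm, self.center_mm, self.height_mm):
                raise ValueError("gap_series requires start_mm, n_gaps, "
                                 "gap_width_mm, residual_width_mm, center_mm "
                                 "(y) and height_mm")
            span = (self.n_gaps * self.gap_width_mm
                    + (self.n_gaps - 1) * self.residual_width_mm)
            y = self.center_mm[1]
            return (self.start_mm, self.start_mm + span,
                    y - self.height_mm / 2, y + self.height_mm / 2)
        if self.center_mm is None:
            raise ValueError(f"{self.kind} requires center_mm")
        x, y = self.center_mm
        if self.kind == "ga_patch":
            if not self.radius_mm or self.radius_mm <= 0:
                raise ValueError("ga_patch requires a positive radius_mm")
            r = self.radius_mm
            return (x - r, x + r, y - r, y + r)
        if self.kind == "ectopic_focus":
            return (x, x, y, y)
        if not self.width_mm or not self.height_mm:
            raise ValueError(f"{self.kind} requires width_mm and height_mm")
        return (x - self.width_mm / 2, x + self.width_mm / 2,
                y - self.height_mm / 2, y + self.height_mm / 2)

    def footprint(self, geometry: ScanGeometry) -> np.ndarray:
        """Rasterized boolean en-face footprint ``(n_bscans, n_ascans)``."""
        pw, ph = geometry.pixel_width_mm, geometry.pixel_height_mm
        xc = (np.arange(geometry.n_ascans) + 0.5) * pw
        yc = (np.arange(geometry.n_bscans) + 0.5) * ph
        xx, yy = np.meshgrid(xc, yc)
        if self.kind == "ga_patch":
            x0, y0 = self.center_mm
            return ((xx - x0) ** 2 + (yy - y0) ** 2) <= self.radius_mm**2
        if self.kind == "gap_series":
            y0 = self.center_mm[1]
            in_y = np.abs(yc - y0) <= self.height_mm / 2
            in_x = np.zeros(geometry.n_ascans, dtype=bool)
            for g in range(self.n_gaps):
                lo = self.start_mm + g * (self.gap_width_mm + self.residual_width_mm)
                in_x |= (xc >= lo) & (xc < lo + self.gap_width_mm)
            return in_y[:, None] & in_x[None, :]
        if self.kind == "ectopic_focus":
            fp = np.zeros((geometry.n_bscans, geometry.n_ascans), dtype=bool)
            a0 = geometry.ascan_index(self.center_mm[0])
            b0 = geometry.bscan_index(self.center_mm[1])
            h = self.size_px // 2
            fp[max(0, b0 - h):b0 + h + 1, max(0, a0 - h):a0 + h + 1] = True
            return fp
        x0, y0 = self.center_mm
        return (np.abs(xx - x0) <= self.width_mm / 2) & (
            np.abs(yy - y0) <= self.height_mm / 2
        )

    def analytic_area_mm2(self) -> float | None:
        """Exact en-face area for kinds where it is known in closed form."""
        if self.kind == "ga_patch":
            return float(np.pi * self.radius_mm**2)
        if self.kind in ("focal_atrophy", "thinning", "thickening"):
            return float(self.width_mm * self.height_mm)
        if self.kind == "gap_series":
            return float(self.n_gaps * self.gap_width_mm * self.height_mm)
        return None


@dataclass
class PhantomSpec:
    """Full description of one synthetic volume."""

    geometry: ScanGeometry
    rpe_depth_px: int = 70
    rpe_thickness_px: int = 8
    depol_strength: float = 0.9
    noise_sd: float = 0.005
    lesions: list[LesionSpec] = field(default_factory=list)
    retina_top_px: int | None = None
    vitreous_intensity: float = 0.05
    tissue_intensity: float = 1.0
    choroid_intensity: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.depol_strength <= 1:
            raise ValueError("depol_strength must lie in [0, 1]")
        if self.rpe_depth_px + self.rpe_thickness_px >= self.geometry.n_depth:
            raise ValueError("RPE band must fit inside the axial range")
        if self.retina_top_px is None:
            self.retina_top_px = self.geometry.n_depth // 4


@dataclass
class LesionRecord:
    """Ground-truth bookkeeping for one planted lesion."""

    lesion_id: str
    kind: str
    area_mm2: float
    center_x_mm: float
    center_y_mm: float
    footprint: np.ndarray


@dataclass
class GroundTruth:
    """Voxel labels, lesion records and expected grades for one phantom.

    ``label_map`` holds 0 (background), 1 (RPE) or 2 (ectopic focus) and has
    the volume's dimensions.  ``expected_bscan_grades`` applies the study's
    lesion definitions to the *true* geometry, one entry per B-scan;
    ``expected_presence`` is the per-volume 0/1 roll-up.
    """

    label_map: np.ndarray
    lesions: list[LesionRecord]
    thickness_px: np.ndarray
    expected_bscan_grades: list[dict]
    expected_presence: dict[str, int]
    ga_true_areas_mm2: list[float]


def _expected_grades(
    thickness: np.ndarray,
    spec: PhantomSpec,
    geometry: ScanGeometry,
    ectopic_rows: np.ndarray,
    min_area_mm2: float = 0.1,
) -> tuple[list[dict], dict[str, int], list[float]]:
    """Apply the lesion definitions to the true (noise-free) geometry."""
    from .lesion_rules import RuleParams, grade_bscan

    params = RuleParams()
    atrophic = thickness == 0
    labels = measure.label(atrophic, connectivity=2)
    px_area = geometry.pixel_area_mm2
    sub_rows = np.zeros_like(atrophic)
    ga_areas: list[float] = []
    for region in measure.regionprops(labels):
        area = region.num_pixels * px_area
        if area < min_area_mm2:
            sub_rows[labels == region.label] = True
        else:
            ga_areas.append(area)
    grades = []
    for b in range(geometry.n_bscans):
        g = grade_bscan(
            thickness[b],
            normal=float(spec.rpe_thickness_px),
            params=params,
            subthreshold_enface_row=sub_rows[b],
        )
        g = dict(g.__dict__)
        g["ectopic_material"] = bool(ectopic_rows[b])
        grades.append(g)
    presence = {
        "porosity": int(any(g["porosity"] for g in grades)),
        "focal_atrophy": int(any(g["focal_atrophy"] for g in grades)),
        "thinning": int(any(g["thinning"] for g in grades)),
        "accumulation_rpe_level": int(
            any(g["accumulation_rpe_level"] for g in grades)
        ),
        "ectopic_material": int(any(g["ectopic_material"] for g in grades)),
        "ga": int(len(ga_areas) > 0),
    }
    return grades, presence, ga_areas


def _slerp(u: np.ndarray, r: np.ndarray, t: float) -> np.ndarray:
    """Spherical interpolation from unit vector ``u`` towards unit rows ``r``."""
    if t <= 0:
        return np.broadcast_to(u, r.shape).copy()
    if t >= 1:
        return r.copy()
    dots = np.clip(r @ u, -1.0, 1.0)
    theta = np.arccos(dots)
    sin_theta = np.sin(theta)
    # near-parallel: fall back to linear interpolation + renormalization
    small = sin_theta < 1e-8
    w_u = np.where(small, 1.0 - t, np.sin((1.0 - t) * theta) / np.where(small, 1.0, sin_theta))
    w_r = np.where(small, t, np.sin(t * theta) / np.where(small, 1.0, sin_theta))
    out = w_u[:, None] * u[None, :] + w_r[:, None] * r
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[StokesVolume, GroundTruth]:
    """Build one seeded Stokes volume plus its ground truth.

    Identical ``(spec, seed)`` produce identical volumes; the ground truth
    depends on the phantom specification alone.
    """
    geo = spec.geometry
    nb, na, nd = geo.shape
    width, height = geo.width_mm, geo.height_mm

    # --- validate lesions and assign ids -------------------------------
    lesions: list[LesionSpec] = []
    for k, lesion in enumerate(spec.lesions):
        lid = lesion.lesion_id or f"lesion-{k:02d}"
        x0, x1, y0, y1 = lesion.extent_mm()
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
            raise ValueError(
                f"lesion {lid} ({lesion.kind}) footprint "
                f"[{x0:.2f},{x1:.2f}]x[{y0:.2f},{y1:.2f}] mm lies outside "
                f"the {width} x {height} mm scan area"
            )
        lesion.lesion_id = lid
        lesions.append(lesion)

    # --- RPE band geometry (top depth + thickness per A-line) ----------
    top = np.full((nb, na), spec.rpe_depth_px, dtype=np.int32)
    thick = np.full((nb, na), spec.rpe_thickness_px, dtype=np.int32)
    band_center = spec.rpe_depth_px + spec.rpe_thickness_px / 2.0
    records: list[LesionRecord] = []
    ectopic_boxes: list[tuple[int, int, int, int, int, int]] = []
    ectopic_rows = np.zeros(nb, dtype=bool)

    for lesion in lesions:
        fp = lesion.footprint(geo)
        if lesion.kind in ("ga_patch", "focal_atrophy", "gap_series"):
            thick[fp] = 0
        elif lesion.kind == "thinning":
            f = lesion.thickness_factor if lesion.thickness_factor else 0.25
            thick[fp] = max(1, int(round(f * spec.rpe_thickness_px)))
        elif lesion.kind == "thickening":
            f = lesion.thickness_factor if lesion.thickness_factor else 3.0
            new_t = int(round(f * spec.rpe_thickness_px))
            new_top = max(0, int(round(band_center - new_t / 2.0)))
            if new_top + new_t >= nd:
                raise ValueError(
                    f"lesion {lesion.lesion_id}: thickened band exceeds depth range"
                )
            top[fp] = new_top
            thick[fp] = new_t
        elif lesion.kind == "ectopic_focus":
            a0 = geo.ascan_index(lesion.center_mm[0])
            b0 = geo.bscan_index(lesion.center_mm[1])
            s = lesion.size_px
            h = s // 2
            offset = lesion.depth_offset_px if lesion.depth_offset_px else 25
            z1 = spec.rpe_depth_px - offset  # bottom row (exclusive)
            z0 = z1 - s
            if z0 < 0:
                raise ValueError(
                    f"lesion {lesion.lesion_id}: focus extends above the volume"
                )
            box = (max(0, b0 - h), min(nb, b0 + h + 1),
                   max(0, a0 - h), min(na, a0 + h + 1), z0, z1)
            ectopic_boxes.append(box)
            ectopic_rows[box[0]:box[1]] = True
        if lesion.center_mm is not None:
            cx, cy = lesion.center_mm
        else:
            x0, x1, y0, y1 = lesion.extent_mm()
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
        area = lesion.analytic_area_mm2()
        if area is None:
            area = float(fp.sum()) * geo.pixel_area_mm2
        records.append(
            LesionRecord(lesion.lesion_id, lesion.kind, area, cx, cy, fp)
        )

    # --- label map -----------------------------------------------------
    zs = np.arange(nd, dtype=np.int32)[None, None, :]
    in_band = (zs >= top[:, :, None]) & (zs < (top + thick)[:, :, None])
    label = np.zeros((nb, na, nd), dtype=np.uint8)
    label[in_band] = 1
    for b0, b1, a0, a1, z0, z1 in ectopic_boxes:
        label[b0:b1, a0:a1, z0:z1] = 2

    # --- intensity profile ---------------------------------------------
    choroid_top = min(nd, spec.rpe_depth_px + 3 * spec.rpe_thickness_px + 2)
    choroid_bottom = min(nd, choroid_top + nd // 4)
    profile = np.full(nd, spec.vitreous_intensity, dtype=np.float64)
    profile[spec.retina_top_px:choroid_top] = spec.tissue_intensity
    profile[choroid_top:choroid_bottom] = spec.choroid_intensity
    intensity = np.broadcast_to(profile, (nb, na, nd)).copy()
    intensity[label > 0] = spec.tissue_intensity

    # --- polarization states -------------------------------------------
    rng = np.random.default_rng(seed)
    direction = np.broadcast_to(
        INCIDENT_STOKES_DIRECTION, (nb, na, nd, 3)
    ).copy()
    depol_idx = label > 0
    n_depol = int(depol_idx.sum())
    if n_depol:
        raw = rng.normal(size=(n_depol, 3))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        direction[depol_idx] = _slerp(
            INCIDENT_STOKES_DIRECTION, raw, spec.depol_strength
        )

    quv = intensity[..., None] * direction
    if spec.noise_sd > 0:
        quv = quv + rng.normal(scale=spec.noise_sd, size=quv.shape)
    # physicality: sqrt(Q^2+U^2+V^2) <= I  (rescale offending voxels)
    norms = np.linalg.norm(quv, axis=-1)
    excess = norms > intensity
    scale = np.ones_like(norms)
    scale[excess] = intensity[excess] / norms[excess]
    quv *= scale[..., None]

    volume = StokesVolume(
        i=intensity.astype(np.float32),
        q=quv[..., 0].astype(np.float32),
        u=quv[..., 1].astype(np.float32),
        v=quv[..., 2].astype(np.float32),
        geometry=geo,
    )

    grades, presence, ga_areas = _expected_grades(thick, spec, geo, ectopic_rows)
    truth = GroundTruth(
        label_map=label,
        lesions=records,
        thickness_px=thick,
        expected_bscan_grades=grades,
        expected_presence=presence,
        ga_true_areas_mm2=ga_areas,
    )
    return volume, truth


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------


@dataclass
class EyeSpec:
    """Per-eye manifest: lesions planted per visit plus clinical numbers."""

    eye_id: str
    lesions: dict[int, list[LesionSpec]] = field(default_factory=dict)
    crt_um: dict[int, float] = field(default_factory=dict)
    bcva_letters: dict[int, float] = field(default_factory=dict)


@dataclass
class CohortSpec:
    """A schedule of visits over a set of eyes sharing one phantom profile."""

    geometry: ScanGeometry
    schedule_months: Sequence[int]
    eyes: list[EyeSpec]
    seed: int = 0
    rpe_depth_px: int = 70
    rpe_thickness_px: int = 8
    depol_strength: float = 0.9
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if len(self.eyes) < 1:
            raise ValueError("cohort requires at least one eye")
        months = list(self.schedule_months)
        if not months:
            raise ValueError("visit schedule must not be empty")
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit months must be strictly increasing")


@dataclass
class CohortRecord:
    """One generated eye-visit: volume, ground truth and clinical numbers."""

    eye_id: str
    visit_month: int
    volume: StokesVolume
    truth: GroundTruth
    crt_um: float | None
    bcva_letters: float | None
    flags: dict = field(default_factory=dict)


def generate_cohort(cohort: CohortSpec) -> list[CohortRecord]:
    """Generate one volume + truth per eye per visit.

    Lesion manifests are applied cumulatively: a lesion introduced at month
    m is present at every later visit.  Fully deterministic under the
    cohort seed.
    """
    out: list[CohortRecord] = []
    for e, eye in enumerate(cohort.eyes):
        for v, month in enumerate(cohort.schedule_months):
            lesions = [
                les
                for m in sorted(eye.lesions)
                if m <= month
                for les in eye.lesions[m]
            ]
            spec = PhantomSpec(
                geometry=cohort.geometry,
                rpe_depth_px=cohort.rpe_depth_px,
                rpe_thickness_px=cohort.rpe_thickness_px,
                depol_strength=cohort.depol_strength,
                noise_sd=cohort.noise_sd,
                lesions=[
                    LesionSpec(**{
                        k: val for k, val in les.__dict__.items()
                    })
                    for les in lesions
                ],
            )
            child = np.random.SeedSequence([cohort.seed, e, v])
            sub_seed = int(child.generate_state(1)[0])
            volume, truth = generate_phantom(spec, seed=sub_seed)
            out.append(
                CohortRecord(
                    eye_id=eye.eye_id,
                    visit_month=month,
                    volume=volume,
                    truth=truth,
                    crt_um=eye.crt_um.get(month),
                    bcva_letters=eye.bcva_letters.get(month),
                )
            )
    return out


def eligibility_filter(records: Iterable, crt_threshold_um: float = 250.0) -> list:
    """Keep records whose CRT strictly exceeds the threshold.

    Mirrors the study's inclusion criterion (retinal thickening >250 um).
    Records with a missing CRT are flagged, excluded and logged; input
    order is preserved.
    """
    kept = []
    for rec in records:
        crt = getattr(rec, "crt_um", None)
        if crt is None or (isinstance(crt, float) and np.isnan(crt)):
            if hasattr(rec, "flags"):
                rec.flags["missing_crt"] = True
            logger.warning(
                "record %s excluded: missing CRT",
                getattr(rec, "eye_id", "<unknown>"),
            )
            continue
        if crt > crt_threshold_um:
            kept.append(rec)
    return kept
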