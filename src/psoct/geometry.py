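"""Scan geometry of a raster polarization-sensitive OCT volume.

Conventions used throughout the package:

* volume arrays are indexed ``[b_scan, a_scan, depth]`` (0-based);
* the millimetre origin sits at the scan corner, ``x`` runs along the fast
  (A-scan) axis, ``y`` along the slow (B-scan) axis;
* depth increases away from the vitreous.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class ScanGeometry:
    """Physical extent and sampling of one raster volume.

    Parameters
    ----------
    width_mm : float
        Extent of the fast (A-scan) axis in millimetres.
    height_mm : float
        Extent of the slow (B-scan) axis in millimetres.
    n_ascans : int
        A-scans per B-scan.
    n_bscans : int
        B-scans per volume.
    n_depth : int
        Axial samples per A-scan.
    axial_step_um : float
        Axial sampling step in micrometres.
    """

    width_mm: float
    height_mm: float
    n_ascans: int
    n_bscans: int
    n_depth: int
    axial_step_um: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "axial_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_ascans", "n_bscans", "n_depth"):
            value = getattr(self, name)
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a strictly positive integer")

    @property
    def pixel_width_mm(self) -> float:
        """En-face pixel size along the fast axis."""
        return self.width_mm / self.n_ascans

    @property
    def pixel_height_mm(self) -> float:
        """En-face pixel size along the slow axis."""
        return self.height_mm / self.n_bscans

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one en-face pixel, mm^2 (anisotropic pixels used as-is)."""
        return self.pixel_width_mm * self.pixel_height_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume array shape ``(n_bscans, n_ascans, n_depth)``."""
        return (self.n_bscans, self.n_ascans, self.n_depth)

    def ascan_index(self, x_mm: float) -> int:
        """A-scan column whose pixel contains the fast-axis position ``x_mm``."""
        return min(max(int(x_mm / self.pixel_width_mm), 0), self.n_ascans - 1)

    def bscan_index(self, y_mm: float) -> int:
        """B-scan row whose pixel contains the slow-axis position ``y_mm``."""
        return min(max(int(y_mm / self.pixel_height_mm), 0), self.n_bscans - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            width_mm=float(d["width_mm"]),
            height_mm=float(d["height_mm"]),
            n_ascans=int(d["n_ascans"]),
            n_bscans=int(d["n_bscans"]),
            n_depth=int(d["n_depth"]),
            axial_step_um=float(d["axial_step_um"]),
        )


#: Acquisition protocol of the imaged cohort: 6.2 x 6.7 mm^2 raster,
#: 512 A-scans x 128 B-scans, 4.5 um axial sampling.
DEFAULT_GEOMETRY = ScanGeometry(
    width_mm=6.2,
    height_mm=6.7,
    n_ascans=512,
    n_bscans=128,
    n_depth=256,
    axial_step_um=4.5,
)

#: Down-sampled profile used for simulation studies and tests: same field of
#: view, a quarter of the lateral and half of the axial sampling.
TEST_GEOMETRY = ScanGeometry(
    width_mm=6.2,
    height_mm=6.7,
    n_ascans=128,
    n_bscans=64,
    n_depth=128,
    axial_step_um=9.0,
)
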