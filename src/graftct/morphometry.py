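"""Physical morphometry of labeled graft volumes.

Quantities follow the workflow of per-slice cross-sectional analysis of a
tubular graft: an ``AreaPerSlice`` profile (mm^2 per slice) for each
material, material volume V (mm^3), graft length L (mm) from slice
numbering, and the headline metric — average luminal cross-sectional area
A = V / L (mm^2), i.e. luminal volume per unit length.

Length convention: the occupied span runs from the first to the last slice
containing the material, inclusive; interior empty slices (a fully occluded
segment is still graft length) are counted.  Slice indices are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import LabelVolume

__all__ = [
    "SliceProfile",
    "GraftMetrics",
    "CaliperRecord",
    "ConservationResult",
    "area_per_slice",
    "volume_of",
    "length_of",
    "average_area",
    "lumen_from_subtraction",
    "profile_stats",
    "conservation_residuals",
    "metrics_for",
]


@dataclass(frozen=True)
class SliceProfile:
    """Ordered per-slice cross-sectional areas of one material.

    ``areas[z]`` is the area in mm^2 occupied by ``material`` in slice ``z``;
    ``slice_spacing`` is dz in mm.
    """

    material: str
    areas: np.ndarray
    slice_spacing: float

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1:
            raise ValueError("areas must be a 1D per-slice sequence")
        if np.any(areas < 0):
            raise ValueError("areas must be non-negative")
        if not self.slice_spacing > 0:
            raise ValueError("slice_spacing must be positive")
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "slice_spacing", float(self.slice_spacing))

    def __len__(self) -> int:
        return len(self.areas)

    def crop(self, start: int, stop: int) -> "SliceProfile":
        """Profile restricted to the half-open slice range [start, stop)."""
        return SliceProfile(self.material, self.areas[start:stop], self.slice_spacing)

    def to_csv(self, path) -> None:
        import pandas as pd

        z = np.arange(len(self.areas))
        pd.DataFrame(
            {"slice_index": z, "z_mm": z * self.slice_spacing, "area_mm2": self.areas}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class GraftMetrics:
    """Volume/length morphometry of one material on one sample.

    ``average_area`` is volume/length; ``area_mean``/``area_sd`` summarize
    the per-slice areas over the occupied span (sample SD, n-1).  The slice
    indices are ``None`` for metrics not derived from a per-slice profile
    (the caliper-subtraction lumen of thrombus-opaque samples).
    """

    material: str
    volume: float
    length: float
    average_area: float
    area_mean: float | None = None
    area_sd: float | None = None
    first_slice: int | None = None
    last_slice: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class CaliperRecord:
    """Digital-caliper measurements of one graft sample (all mm)."""

    length: float
    outer_diameter: float
    inner_diameter: float
    wall_thickness: float

    def __post_init__(self) -> None:
        vals = (self.length, self.outer_diameter, self.inner_diameter, self.wall_thickness)
        if any(not v > 0 for v in vals):
            raise ValueError(f"caliper measurements must be positive, got {vals}")
        if not self.inner_diameter < self.outer_diameter:
            raise ValueError("inner diameter must be smaller than outer diameter")

    @property
    def internal_area(self) -> float:
        """Cross-sectional internal (lumen-capacity) area, pi*(d/2)^2 in mm^2."""
        return math.pi * (self.inner_diameter / 2.0) ** 2

    @property
    def cylinder_volume(self) -> float:
        """Internal volume of the cylindrical approximation, mm^3."""
        return self.internal_area * self.length


def load_caliper_csv(path) -> dict[str, CaliperRecord]:
    """Caliper records keyed by sample id.

    Expects columns sample_id, length, outer_diameter, inner_diameter,
    wall_thickness (mm).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_id", "length", "outer_diameter", "inner_diameter", "wall_thickness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"caliper table missing columns {sorted(missing)}")
    return {
        str(row.sample_id): CaliperRecord(
            length=float(row.length),
            outer_diameter=float(row.outer_diameter),
            inner_diameter=float(row.inner_diameter),
            wall_thickness=float(row.wall_thickness),
        )
        for row in df.itertuples()
    }


def area_per_slice(labels: LabelVolume, material: str) -> SliceProfile:
    """Per-slice cross-sectional area of one material: pixel count x dy x dx."""
    mask = labels.mask_of(material)  # raises on unknown material
    counts = mask.sum(axis=(1, 2))
    return SliceProfile(material, counts * labels.pixel_area, labels.spacing[0])


def volume_of(labels: LabelVolume, material: str) -> float:
    """Material volume in mm^3 (voxel count x dz x dy x dx).

    Identically equals ``sum(area_per_slice(...).areas) * dz``.
    """
    return int(labels.mask_of(material).sum()) * labels.voxel_volume


def length_of(labels: LabelVolume, material: str) -> float:
    """Axial length of a material's occupied span in mm.

    (last occupied slice - first occupied slice + 1) x dz; interior empty
    slices are inside the span and counted.
    """
    occupied = np.flatnonzero(labels.mask_of(material).any(axis=(1, 2)))
    if occupied.size == 0:
        raise ValueError(f"material {material!r} occupies no slice")
    return float(occupied[-1] - occupied[0] + 1) * labels.spacing[0]


def average_area(volume: float, length: float) -> float:
    """Average cross-sectional area (mm^2) by length normalization, V/L."""
    if not length > 0:
        raise ValueError(f"length must be positive, got {length}")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return volume / length


def lumen_from_subtraction(
    caliper: CaliperRecord, measured_length: float, thrombus_volume: float
) -> float:
    """Luminal volume of a thrombus-opaque sample by cylinder subtraction.

    The open lumen cannot be segmented directly when only the thrombus is
    radiopaque; it is computed as the caliper-based cylindrical internal
    volume pi*(d/2)^2 * L minus the measured thrombus volume.
    """
    if thrombus_volume < 0:
        raise ValueError("thrombus volume must be non-negative")
    if not measured_length > 0:
        raise ValueError("measured length must be positive")
    cylinder = caliper.internal_area * measured_length
    lumen = cylinder - thrombus_volume
    if lumen < 0:
        raise ValueError(
            f"thrombus volume {thrombus_volume:.3f} mm^3 exceeds the cylinder "
            f"volume {cylinder:.3f} mm^3 — inconsistent measurements"
        )
    return lumen


def profile_stats(profile: SliceProfile) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-slice areas over the occupied span.

    The span runs from the first to the last slice with non-zero area;
    interior zero-area (occluded) slices are included in the statistics.
    """
    occupied = np.flatnonzero(profile.areas > 0)
    if len(profile.areas) == 0 or occupied.size == 0:
        raise ValueError("profile has no occupied slice")
    span = profile.areas[occupied[0] : occupied[-1] + 1]
    mean = float(np.mean(span))
    sd = float(np.std(span, ddof=1)) if span.size > 1 else 0.0
    return mean, sd


@dataclass(frozen=True)
class ConservationResult:
    """Per-slice residuals of the lumen+thrombus area-conservation check.

    ``residuals[z] = lumen[z] + thrombus[z] - pi*(d/2)^2`` where d is the
    caliper-measured inner diameter; positive values indicate
    over-segmentation relative to the caliper cylinder.
    """

    residuals: np.ndarray
    expected_area: float

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))

    @property
    def mean_residual(self) -> float:
        return float(np.mean(self.residuals))


def conservation_residuals(
    lumen: SliceProfile, thrombus: SliceProfile, caliper: CaliperRecord
) -> ConservationResult:
    """Validate lumen and thrombus areas jointly against the caliper cylinder.

    In every cross-sectional slice the open lumen plus the thrombus should
    tile the graft's internal cross-section, so their summed areas are
    compared with the caliper-derived internal area.  Profiles must be
    aligned to the same slices.
    """
    if len(lumen) != len(thrombus):
        raise ValueError(
            f"profile length mismatch: lumen {len(lumen)} vs thrombus {len(thrombus)}"
        )
    residuals = lumen.areas + thrombus.areas - caliper.internal_area
    return ConservationResult(residuals, caliper.internal_area)


def metrics_for(labels: LabelVolume, material: str) -> GraftMetrics:
    """Full :class:`GraftMetrics` for one material of a label volume."""
    profile = area_per_slice(labels, material)
    volume = volume_of(labels, material)
    length = length_of(labels, material)
    mean, sd = profile_stats(profile)
    occupied = np.flatnonzero(profile.areas > 0)
    return GraftMetrics(
        material=material,
        volume=volume,
        length=length,
        average_area=average_area(volume, length),
        area_mean=mean,
        area_sd=sd,
        first_slice=int(occupied[0]),
        last_slice=int(occupied[-1]),
    )
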